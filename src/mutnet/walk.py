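"""Random Walk with Restart (RWR) on a column-normalized interaction network.

The walker iterates ``p_{t+1} = (1 - r) W p_t + r p_0`` where ``W`` is the
column-normalized adjacency matrix (each column spreads a node's probability
uniformly over its neighbors), ``r`` the restart probability and ``p_0`` the
restart vector (uniform over the seed genes). Iteration stops when the L1
difference between successive iterates falls below a tolerance. For each
seed gene the stationary probabilities rank the network by accessibility
from the seed; the top-k non-seed genes are its candidate interactors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp

log = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    def __init__(self, max_iter: int, last_diff: float):
        super().__init__(f"RWR did not converge in {max_iter} iterations (last L1 diff {last_diff:.3g})")
        self.last_diff = last_diff


@dataclass
class TransitionMatrix:
    """Sparse column-stochastic transition structure over named nodes.

    Nodes are ordered lexicographically, so stable sorts on probability
    resolve ties by gene symbol automatically. Degree-0 nodes are excluded
    (their columns cannot be normalized).
    """

    W: sp.csr_matrix  # csr for fast W @ dense
    nodes: np.ndarray  # lexicographically sorted symbols
    index: dict[str, int]

    @property
    def n(self) -> int:
        return len(self.nodes)


def column_normalize(net: nx.Graph) -> TransitionMatrix:
    """Column-normalized adjacency of the network's non-isolated nodes."""
    nodes = sorted(n for n in net.nodes() if net.degree(n) > 0)
    n_dropped = net.number_of_nodes() - len(nodes)
    if n_dropped:
        log.info("excluding %d isolated node(s) from the walk", n_dropped)
    index = {g: i for i, g in enumerate(nodes)}
    rows, cols, vals = [], [], []
    for u, v in net.edges():
        if u == v:
            continue
        iu, iv = index[u], index[v]
        rows.append(iu); cols.append(iv)
        rows.append(iv); cols.append(iu)
    rows = np.array(rows, dtype=np.int64)
    cols = np.array(cols, dtype=np.int64)
    deg = np.bincount(cols, minlength=len(nodes)).astype(float)
    vals = 1.0 / deg[cols]
    W = sp.csr_matrix((vals, (rows, cols)), shape=(len(nodes), len(nodes)))
    return TransitionMatrix(W=W, nodes=np.array(nodes), index=index)


@dataclass
class WalkResult:
    """Stationary RWR distribution for one restart set."""

    seeds: tuple[str, ...]
    nodes: np.ndarray
    stationary: np.ndarray
    iterations: int

    def probability(self, gene: str) -> float:
        idx = np.searchsorted(self.nodes, gene)
        if idx < len(self.nodes) and self.nodes[idx] == gene:
            return float(self.stationary[idx])
        raise KeyError(gene)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.nodes.tolist(), self.stationary.tolist()))


def _iterate(
    W: sp.csr_matrix,
    P0: np.ndarray,
    r: float,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, int]:
    """Batched power iteration; columns of P0 are independent walks."""
    P = P0.copy()
    rP0 = r * P0
    for it in range(1, max_iter + 1):
        P_next = (1.0 - r) * (W @ P) + rP0
        diff = np.abs(P_next - P).sum(axis=0).max()
        P = P_next
        if diff < tol:
            return P, it
    raise ConvergenceError(max_iter, float(diff))


def rwr(
    T: TransitionMatrix,
    seeds: Iterable[str],
    r: float = 0.5,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> WalkResult:
    """Run RWR restarting uniformly over ``seeds``; returns the stationary vector."""
    seeds = tuple(sorted(set(seeds)))
    if not seeds:
        raise ValueError("seeds must be non-empty")
    missing = [s for s in seeds if s not in T.index]
    if missing:
        raise ValueError(f"seed gene(s) not in network: {missing[:5]}")
    if not 0.0 < r <= 1.0:
        raise ValueError(f"restart probability must lie in (0, 1], got {r}")
    p0 = np.zeros((T.n, 1))
    for s in seeds:
        p0[T.index[s], 0] = 1.0 / len(seeds)
    p, iterations = _iterate(T.W, p0, r, tol, max_iter)
    return WalkResult(seeds=seeds, nodes=T.nodes, stationary=p[:, 0], iterations=iterations)


def top_interactors(
    result: WalkResult,
    k: int = 10,
    exclude_seed: bool = True,
) -> list[str]:
    """The k genes of highest stationary probability (ties: lexicographic).

    Seeds are excluded by default since the walk collects *interactors* of
    the seed gene. If the network holds fewer than k eligible nodes, all of
    them are returned (logged).
    """
    # stable sort on descending probability; node order is lexicographic
    order = np.argsort(-result.stationary, kind="stable")
    banned = set(result.seeds) if exclude_seed else set()
    out: list[str] = []
    for idx in order:
        g = str(result.nodes[idx])
        if g in banned:
            continue
        out.append(g)
        if len(out) == k:
            break
    if len(out) < k:
        log.info("network smaller than k=%d: returning %d interactors", k, len(out))
    return out


def rwr_topk_table(
    T: TransitionMatrix,
    seed_genes: Sequence[str],
    r: float = 0.5,
    tol: float = 1e-6,
    k: int = 10,
    exclude_seed: bool = True,
    max_iter: int = 10_000,
    chunk: int = 1024,
) -> dict[str, tuple[str, ...]]:
    """Top-k interactor lists for many single-seed walks at once.

    Equivalent to running :func:`rwr` + :func:`top_interactors` per seed but
    batched column-wise for speed; identical probabilities and tie-breaking.
    """
    seed_genes = sorted(set(seed_genes))
    missing = [s for s in seed_genes if s not in T.index]
    if missing:
        raise ValueError(f"seed gene(s) not in network: {missing[:5]}")
    out: dict[str, tuple[str, ...]] = {}
    for start in range(0, len(seed_genes), chunk):
        block = seed_genes[start : start + chunk]
        P0 = np.zeros((T.n, len(block)))
        cols = np.arange(len(block))
        rows = np.array([T.index[s] for s in block])
        P0[rows, cols] = 1.0
        P, _ = _iterate(T.W, P0, r, tol, max_iter)
        order = np.argsort(-P, axis=0, kind="stable")
        for j, s in enumerate(block):
            top: list[str] = []
            for idx in order[: k + 1, j]:
                g = str(T.nodes[idx])
                if exclude_seed and g == s:
                    continue
                top.append(g)
                if len(top) == k:
                    break
            out[s] = tuple(top)
    return out
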