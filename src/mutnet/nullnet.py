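"""Degree-preserving network randomization and empirical edge significance.

Candidate interactors found by the walk are scored against an ensemble of
random networks produced by edge switching: repeatedly pick two edges
(a,b), (c,d) and rewire them to (a,d),(c,b) or (a,c),(b,d), rejecting any
proposal that would create a self-loop or duplicate edge. Every accepted
swap preserves each node's degree exactly, so the ensemble shares the
original degree sequence while scrambling everything else. Re-running the
identical walk on each null network yields, per (seed, candidate) pair, the
empirical probability ``p_edge`` that the candidate ranks in the seed's
top-k by topology alone; only pairs with small ``p_edge`` survive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .walk import TransitionMatrix, column_normalize, rwr_topk_table

log = logging.getLogger(__name__)


def switch_randomize(
    net: nx.Graph,
    n_swaps_per_edge: float = 10,
    seed: int | np.random.Generator | None = None,
) -> nx.Graph:
    """One degree-preserving randomization of a simple undirected graph.

    Performs ``n_swaps_per_edge * |E|`` switching attempts; attempts that
    would break simplicity are skipped, so highly constrained graphs (e.g. a
    triangle) come back unchanged.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    edges = [tuple(sorted(e)) for e in net.edges() if e[0] != e[1]]
    E = len(edges)
    out = nx.Graph()
    out.add_nodes_from(net.nodes())
    if E < 2:
        out.add_edges_from(edges)
        return out
    eset = set(edges)
    attempts = int(round(n_swaps_per_edge * E))
    pick = rng.integers(0, E, size=(attempts, 2))
    orient = rng.integers(0, 2, size=attempts)
    for t in range(attempts):
        i, j = pick[t]
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if orient[t]:
            e1, e2 = (a, d), (c, b)
        else:
            e1, e2 = (a, c), (b, d)
        if e1[0] == e1[1] or e2[0] == e2[1]:
            continue
        e1 = (e1[0], e1[1]) if e1[0] < e1[1] else (e1[1], e1[0])
        e2 = (e2[0], e2[1]) if e2[0] < e2[1] else (e2[1], e2[0])
        if e1 == e2 or e1 in eset or e2 in eset:
            continue
        eset.discard(edges[i])
        eset.discard(edges[j])
        eset.add(e1)
        eset.add(e2)
        edges[i] = e1
        edges[j] = e2
    out.add_edges_from(eset)
    return out


@dataclass
class NullEnsemble:
    """A set of degree-matched random networks sharing the original node set."""

    networks: list[nx.Graph]
    n_swaps_per_edge: float
    seed: int | None

    def __len__(self) -> int:
        return len(self.networks)


def build_ensemble(
    net: nx.Graph,
    n: int = 100,
    n_swaps_per_edge: float = 10,
    seed: int | None = None,
) -> NullEnsemble:
    """Build ``n`` independent degree-preserving randomizations.

    Member seeds derive deterministically from ``seed`` so two ensembles
    built with the same seed are identical edge-for-edge. The degree
    sequence of every member is asserted against the original.
    """
    if n < 1:
        raise ValueError(f"ensemble size must be >= 1, got {n}")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n)
    ref_deg = dict(net.degree())
    networks = []
    for child in children:
        g = switch_randomize(net, n_swaps_per_edge, np.random.default_rng(child))
        assert dict(g.degree()) == ref_deg, "degree sequence broken by switching (internal bug)"
        networks.append(g)
    return NullEnsemble(networks=networks, n_swaps_per_edge=n_swaps_per_edge, seed=seed)


@dataclass
class EdgeSignificance:
    """Empirical p-values for observed (seed, interactor) pairs."""

    p: dict[tuple[str, str], float]
    n_null: int

    def significant_pairs(self, cutoff: float = 0.05) -> set[tuple[str, str]]:
        return {pair for pair, pv in self.p.items() if pv < cutoff}


def null_topk_tables(
    ensemble: NullEnsemble,
    seed_genes: Sequence[str],
    r: float = 0.5,
    tol: float = 1e-6,
    k: int = 10,
    exclude_seed: bool = True,
    max_iter: int = 10_000,
) -> list[dict[str, tuple[str, ...]]]:
    """Per-null-network top-k tables for the given walk seeds.

    Exposed separately so callers evaluating many cohorts against one
    reference network can compute the null walks once.
    """
    tables = []
    for g in ensemble.networks:
        T = column_normalize(g)
        missing = [s for s in seed_genes if s not in T.index]
        assert not missing, "switching must preserve node degrees, so no seed can vanish"
        tables.append(rwr_topk_table(T, seed_genes, r=r, tol=tol, k=k,
                                     exclude_seed=exclude_seed, max_iter=max_iter))
    return tables


def edge_pvalues(
    observed_top: Mapping[str, Sequence[str]],
    ensemble: NullEnsemble,
    r: float = 0.5,
    tol: float = 1e-6,
    k: int = 10,
    exclude_seed: bool = True,
    max_iter: int = 10_000,
    null_tables: Sequence[Mapping[str, Sequence[str]]] | None = None,
) -> EdgeSignificance:
    """Empirical chance of each observed candidate under topology alone.

    For seed s and observed candidate g, ``p_edge(s, g)`` is the fraction of
    null networks in which g appears in s's top-k list, using the identical
    walk parameters, seed exclusion and tie-breaking as the observed run.
    ``null_tables`` may supply precomputed per-network top-k tables.
    """
    seeds = sorted(observed_top)
    if null_tables is None:
        null_tables = null_topk_tables(ensemble, seeds, r=r, tol=tol, k=k,
                                       exclude_seed=exclude_seed, max_iter=max_iter)
    counts: dict[tuple[str, str], int] = {
        (s, g): 0 for s in seeds for g in observed_top[s]
    }
    for table in null_tables:
        for s in seeds:
            null_set = set(table[s])
            for g in observed_top[s]:
                if g in null_set:
                    counts[(s, g)] += 1
    n = len(null_tables)
    return EdgeSignificance(p={pair: c / n for pair, c in counts.items()}, n_null=n)
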