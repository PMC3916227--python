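"""Cohort-level consensus mutation network and evaluation statistics.

Per-sample significant (seed, interactor) pairs are pooled over the cohort;
each unordered edge carries an *occurrence* — the number of samples whose
significant set contains it. Edge counts decay roughly geometrically with
occurrence, so a straight line fits log10(#edges) against occurrence; the
point where the observed tail drifts above that line marks unusually
recurrent interactions and suggests the occurrence cutoff. Retained edges
must additionally join two genes that are mutated somewhere in the cohort
and survive the mutation-recurrence (mr) filter, which removes heavily but
never-recurrently mutated genes (hallmark of large passenger targets, since
driver mutations cluster at hotspots).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSet

log = logging.getLogger(__name__)


@dataclass
class EdgePool:
    """Cohort-pooled significant interactions with per-sample occurrence."""

    occurrence: dict[tuple[str, str], int]
    n_samples: int

    def __len__(self) -> int:
        return len(self.occurrence)

    def table(self) -> pd.DataFrame:
        rows = [(a, b, o) for (a, b), o in sorted(self.occurrence.items())]
        return pd.DataFrame(rows, columns=["geneA", "geneB", "occurrence"])


def _canon(pair: Sequence[str]) -> tuple[str, str]:
    a, b = pair
    return (a, b) if a <= b else (b, a)


def pool_edges(per_sample_significant: Mapping[str, Iterable[Sequence[str]]]) -> EdgePool:
    """Tabulate how many samples contain each significant interaction.

    Pairs are unordered; an edge reached from both endpoints as walk seeds
    within one sample still counts once for that sample.
    """
    occurrence: dict[tuple[str, str], int] = {}
    for sample in per_sample_significant:
        edges = {_canon(p) for p in per_sample_significant[sample]}
        for e in edges:
            occurrence[e] = occurrence.get(e, 0) + 1
    return EdgePool(occurrence=occurrence, n_samples=len(per_sample_significant))


@dataclass
class CutoffDiagnostics:
    cutoff: int
    no_drift: bool
    r_squared: float
    table: pd.DataFrame  # occurrence, n_edges, log10_n, fitted, residual


def suggest_cutoff(pool: EdgePool, residual_tol: float = 1e-9) -> CutoffDiagnostics:
    """Occurrence cutoff from the log-linear edge-count distribution.

    Fits OLS of log10(#edges at occurrence o) on o over the occupied
    occurrences. The drift point is the smallest occupied occurrence o*
    exceeding the median occupied occurrence such that every occupied
    occurrence >= o* sits above the fitted line (positive residual). When no
    such point exists the counts are consistent with pure log-linear decay:
    the maximum occurrence is returned with ``no_drift`` set, and the caller
    should consider a manual cutoff (expert adjustment is expected practice,
    e.g. to recover known disease genes).
    """
    occ = np.array(sorted({o for o in pool.occurrence.values()}))
    if len(occ) < 3:
        raise ValueError(
            f"only {len(occ)} distinct occurrence value(s); too few for the "
            "log-linear fit — supply a manual cutoff"
        )
    counts = np.array([sum(1 for v in pool.occurrence.values() if v == o) for o in occ], dtype=float)
    logn = np.log10(counts)
    slope, intercept = np.polyfit(occ, logn, 1)
    fitted = slope * occ + intercept
    resid = logn - fitted
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((logn - logn.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    table = pd.DataFrame(
        {"occurrence": occ, "n_edges": counts.astype(int), "log10_n": logn,
         "fitted": fitted, "residual": resid}
    )
    med = float(np.median(occ))
    cutoff = None
    for i, o in enumerate(occ):
        if o > med and np.all(resid[i:] > residual_tol):
            cutoff = int(o)
            break
    if cutoff is None:
        return CutoffDiagnostics(cutoff=int(occ.max()), no_drift=True, r_squared=r2, table=table)
    return CutoffDiagnostics(cutoff=cutoff, no_drift=False, r_squared=r2, table=table)


def mr_index(site_tallies: Mapping[str, Sequence[tuple[str, int]]]) -> pd.DataFrame:
    """Mutation recurrence index per gene from cohort site multisets.

    ``mr = n_all / n_unique`` where ``n_all`` counts every deleterious
    mutation of the gene across samples and ``n_unique`` its distinct
    (chrom, pos) coordinates. mr = 1 means no site recurs; hotspot-driven
    genes have mr well above 1. Genes with empty site lists are excluded.
    """
    rows = []
    for gene in sorted(site_tallies):
        sites = list(site_tallies[gene])
        if not sites:
            continue
        n_all = len(sites)
        n_unique = len(set(sites))
        rows.append((gene, n_all, n_unique, n_all / n_unique))
    return pd.DataFrame(rows, columns=["gene", "n_all", "n_unique", "mr"]).set_index("gene")


@dataclass
class ConsensusNetwork:
    """Final consensus subnetwork with occurrence, components and orphan flags."""

    graph: nx.Graph  # edge attr "occurrence"; node attr "n_samples_mutated"
    subgraph_ids: dict[str, int]
    orphan_ids: set[int]  # components consisting of exactly one edge
    cutoff: int

    @property
    def genes(self) -> set[str]:
        return set(self.graph.nodes())

    def n_subgraphs(self) -> int:
        return len(set(self.subgraph_ids.values()))


def build_consensus(
    pool: EdgePool,
    mr: pd.DataFrame,
    cohort_mutgenes: set[str],
    cutoff: int,
    mr_min: float = 1.05,
    mr_min_mutations: int = 20,
    sample_counts: Mapping[str, int] | None = None,
) -> ConsensusNetwork:
    """Assemble the consensus network from the pooled interactions.

    Keeps edges with occurrence >= ``cutoff`` whose endpoints are both
    cohort MutGenes (mutated in the same or different samples) and neither
    endpoint fails the mr rule. The mr rule flags a gene only when it is
    heavily mutated yet its sites essentially never recur —
    ``n_all > mr_min_mutations`` and ``mr < mr_min`` — so singleton-mutation
    genes (mr = 1 with one site) are untouched. Components are labelled;
    one-edge components are orphans.
    """
    if cutoff < 1:
        raise ValueError(f"cutoff must be >= 1, got {cutoff}")

    def flagged(g: str) -> bool:
        if g not in mr.index:
            return False
        row = mr.loc[g]
        return bool(row["n_all"] > mr_min_mutations and row["mr"] < mr_min)

    graph = nx.Graph()
    for (a, b), occ in pool.occurrence.items():
        if occ < cutoff:
            continue
        if a not in cohort_mutgenes or b not in cohort_mutgenes:
            continue
        if flagged(a) or flagged(b):
            continue
        graph.add_edge(a, b, occurrence=occ)
    counts = sample_counts or {}
    for g in graph.nodes():
        graph.nodes[g]["n_samples_mutated"] = counts.get(g, 0)
    comps = sorted(nx.connected_components(graph), key=lambda c: min(c))
    subgraph_ids = {g: i for i, comp in enumerate(comps) for g in comp}
    orphan_ids = {
        i for i, comp in enumerate(comps)
        if graph.subgraph(comp).number_of_edges() == 1
    }
    return ConsensusNetwork(graph=graph, subgraph_ids=subgraph_ids,
                            orphan_ids=orphan_ids, cutoff=cutoff)


def enrichment_test(
    net_genes: Iterable[str],
    target: GeneSet | Iterable[str],
    universe: Iterable[str],
) -> tuple[np.ndarray, float]:
    """One-sided Fisher exact test for target-gene enrichment in the network.

    Builds the 2x2 table (in-network x in-target) over the universe; the
    target is intersected with the universe first. Returns (table, p) with
    the enrichment (greater) alternative.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    net = set(net_genes) & uni
    tgt = (set(target.members) if isinstance(target, GeneSet) else set(target)) & uni
    a = len(net & tgt)
    b = len(net - tgt)
    c = len(tgt - net)
    d = len(uni) - a - b - c
    table = np.array([[a, b], [c, d]])
    _, p = stats.fisher_exact(table, alternative="greater")
    return table, float(p)


@dataclass
class OverlapResult:
    observed: int
    count: int  # permutations with overlap >= observed
    n_perm: int

    @property
    def p(self) -> float:
        return self.count / self.n_perm

    @property
    def label(self) -> str:
        return f"< {1 / self.n_perm:g}" if self.count == 0 else f"{self.p:g}"


def overlap_significance(
    genes_a: Iterable[str],
    genes_b: Iterable[str],
    universe: Iterable[str],
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> OverlapResult:
    """Randomization test for the overlap of two gene sets.

    Draws ``n_perm`` uniform random sets of size |A| from the universe and
    counts how often their overlap with B reaches the observed |A ∩ B|.
    A zero count is reported as "< 1/n_perm".
    """
    uni = np.array(sorted(set(universe)))
    a = set(genes_a)
    b = set(genes_b)
    if len(a) > len(uni):
        raise ValueError("set A larger than the universe")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    b_mask = np.isin(uni, sorted(b))
    observed = len(a & b)
    count = 0
    for _ in range(n_perm):
        idx = rng.choice(len(uni), size=len(a), replace=False)
        if int(b_mask[idx].sum()) >= observed:
            count += 1
    return OverlapResult(observed=observed, count=count, n_perm=n_perm)
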