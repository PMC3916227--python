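"""End-to-end orchestration of the four-stage prioritization pipeline.

Stages 1–3 run per sample against a shared reference network; stage 4 pools
the cohort:

1. *filter* — classify deleterious mutations, fit the length model (sample-
   specific when the sample has enough MutGenes, else the cohort-wide
   universal model), run the weighted resampling null, drop genes random
   sampling reproduces at >= ``freq_cutoff``, keep whitelisted anchor genes,
   and drop genes farther than ``max_anchor_distance`` steps from every
   anchor in the network.
2. *walk* — RWR from every retained MutGene; collect top-k interactors.
3. *null* — re-run the identical walks on degree-preserving random networks
   and keep (seed, interactor) pairs with ``p_edge < p_edge_cutoff``.
4. *consensus* — pool significant pairs over samples, pick/accept an edge
   occurrence cutoff, apply the both-endpoints-mutated and mutation-
   recurrence rules, and label the consensus subgraphs.

Everything derives from one master seed; per-sample resampling streams are
keyed by (master seed, sample id) so results are independent of sample
order and parallel scheduling.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import consensus as cns
from . import filters, length_model, nullnet, walk
from .io import GeneSet, MutationRecord, SampleProfile, write_network

log = logging.getLogger(__name__)


class DependencyError(RuntimeError):
    """A later stage was invoked without its upstream artifact."""


@dataclass(frozen=True)
class RunConfig:
    """All pipeline tunables with their standard defaults.

    Defaults: restart probability 0.5, L1 convergence tolerance 1e-6, top 10
    interactors per walk, 1000 weighted resamples with a 5% frequency
    cutoff, 50 MutGenes required for a sample-specific length model, 100
    degree-preserving null networks with p_edge < 0.05, consensus edges by
    occurrence cutoff (auto-suggested from the log-linear fit, manually
    overridable), the mr < 1.05 recurrence rule applied to genes with > 20
    cohort mutations, and anchor genes within 2 network steps.
    """

    restart_prob: float = 0.5
    tol: float = 1e-6
    max_iter: int = 10_000
    top_k: int = 10
    exclude_seed: bool = True
    n_resamples: int = 1000
    freq_cutoff: float = 0.05
    min_mutgenes_for_sample_model: int = 50
    n_knots: int = 6
    log_length: bool = False
    n_random_networks: int = 100
    n_swaps_per_edge: float = 10
    p_edge_cutoff: float = 0.05
    mr_min: float = 1.05
    mr_min_mutations: int = 20
    max_anchor_distance: float = 2
    edge_cutoff: int | str = "auto"
    missense_default_deleterious: bool = False
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.restart_prob <= 1.0:
            raise ValueError("restart_prob must lie in (0, 1]")
        for name in ("freq_cutoff", "p_edge_cutoff"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.edge_cutoff != "auto" and int(self.edge_cutoff) < 1:
            raise ValueError("edge_cutoff must be 'auto' or a positive integer")
        for name in ("top_k", "n_resamples", "n_random_networks", "max_iter"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def rule(self) -> filters.DeleteriousRule:
        return filters.DeleteriousRule(
            missense_default_deleterious=self.missense_default_deleterious
        )


def sample_seed(master_seed: int, sample_id: str) -> np.random.SeedSequence:
    """Deterministic, order-independent per-sample random stream."""
    return np.random.SeedSequence([master_seed, zlib.crc32(sample_id.encode())])


def _derived_seed(master_seed: int, tag: int) -> int:
    state = np.random.SeedSequence([master_seed, tag]).generate_state(1)[0]
    return int(state % (2**31 - 1))


@dataclass
class SampleFilterRecord:
    """Per-sample retention accounting through the filter stage."""

    sample_id: str
    provenance: str
    n_mutgenes: int
    n_after_resample: int
    n_after_network: int
    n_after_anchor: int
    freq: dict[str, float]


@dataclass
class FilterStage:
    profiles: list[SampleProfile]
    universal_pwv: length_model.ProbabilityWeightVector
    significant: dict[str, set[str]]  # sample -> retained MutGenes
    accounting: list[SampleFilterRecord]

    def seed_union(self) -> set[str]:
        out: set[str] = set()
        for s in self.significant.values():
            out |= s
        return out


def filter_stage(
    profiles: Sequence[SampleProfile],
    lengths: Mapping[str, int],
    net: nx.Graph,
    retain: Optional[GeneSet],
    anchors: Optional[GeneSet],
    cfg: RunConfig,
) -> FilterStage:
    """Stage 1: length-model + resampling + anchor filters, per sample."""
    known = set(lengths)
    cohort = filters.cohort_mutgenes(profiles) & known
    dropped = len(filters.cohort_mutgenes(profiles)) - len(cohort)
    if dropped:
        log.info("filter: %d cohort MutGene(s) missing from the length table", dropped)
    universal = length_model.fit_pwv(
        cohort, lengths, n_knots=cfg.n_knots, log_length=cfg.log_length,
        provenance="universal",
    )
    significant: dict[str, set[str]] = {}
    accounting: list[SampleFilterRecord] = []
    for prof in profiles:
        mutgenes = prof.mutgenes & known
        if not mutgenes:
            significant[prof.sample_id] = set()
            accounting.append(SampleFilterRecord(prof.sample_id, "none", 0, 0, 0, 0, {}))
            continue
        pwv = length_model.choose_model(
            prof, universal, lengths,
            min_mutgenes=cfg.min_mutgenes_for_sample_model,
            n_knots=cfg.n_knots, log_length=cfg.log_length,
        )
        rng = np.random.default_rng(sample_seed(cfg.master_seed, prof.sample_id))
        rr = length_model.resample_null(pwv, m=len(mutgenes), B=cfg.n_resamples, seed=rng)
        sub = SampleProfile(prof.sample_id, mutgenes, {g: prof.sites[g] for g in mutgenes})
        kept = length_model.filter_mutgenes(sub, rr, retain=retain, freq_cutoff=cfg.freq_cutoff)
        in_net = {g for g in kept if g in net}
        if anchors is not None and cfg.max_anchor_distance != float("inf"):
            final = length_model.anchor_distance_filter(
                in_net, net, anchors, max_dist=cfg.max_anchor_distance
            )
        else:
            final = in_net
        significant[prof.sample_id] = final
        accounting.append(
            SampleFilterRecord(
                prof.sample_id, pwv.provenance, len(mutgenes), len(kept),
                len(in_net), len(final), {g: rr.get(g) for g in mutgenes},
            )
        )
        log.info(
            "filter[%s]: %d MutGenes -> %d after resampling -> %d in network -> %d near anchors (%s model)",
            prof.sample_id, len(mutgenes), len(kept), len(in_net), len(final), pwv.provenance,
        )
    return FilterStage(list(profiles), universal, significant, accounting)


@dataclass
class WalkStage:
    transition: walk.TransitionMatrix
    topk: dict[str, tuple[str, ...]]  # seed gene -> observed top-k interactors


def walk_stage(net: nx.Graph, seed_genes: Iterable[str], cfg: RunConfig) -> WalkStage:
    """Stage 2: observed top-k interactors for every retained MutGene."""
    T = walk.column_normalize(net)
    seeds = sorted(set(seed_genes) & set(T.index))
    topk = walk.rwr_topk_table(
        T, seeds, r=cfg.restart_prob, tol=cfg.tol, k=cfg.top_k,
        exclude_seed=cfg.exclude_seed, max_iter=cfg.max_iter,
    )
    return WalkStage(transition=T, topk=topk)


def null_stage(
    net: nx.Graph,
    observed_topk: Mapping[str, Sequence[str]],
    cfg: RunConfig,
    ensemble: Optional[nullnet.NullEnsemble] = None,
    null_tables: Optional[Sequence[Mapping[str, Sequence[str]]]] = None,
) -> nullnet.EdgeSignificance:
    """Stage 3: empirical p_edge for every observed (seed, interactor) pair.

    One shared ensemble (randomizations of the reference network) serves all
    samples. A precomputed ensemble and/or null top-k tables may be passed
    in, e.g. when several cohorts are scored against one network.
    """
    if ensemble is None:
        ensemble = nullnet.build_ensemble(
            net, n=cfg.n_random_networks, n_swaps_per_edge=cfg.n_swaps_per_edge,
            seed=_derived_seed(cfg.master_seed, 0xE5),
        )
    return nullnet.edge_pvalues(
        observed_topk, ensemble, r=cfg.restart_prob, tol=cfg.tol, k=cfg.top_k,
        exclude_seed=cfg.exclude_seed, max_iter=cfg.max_iter, null_tables=null_tables,
    )


@dataclass
class ConsensusResult:
    pool: cns.EdgePool
    diagnostics: Optional[cns.CutoffDiagnostics]
    mr: pd.DataFrame
    network: cns.ConsensusNetwork
    per_sample_significant: dict[str, set[tuple[str, str]]]


def consensus_stage(
    profiles: Sequence[SampleProfile],
    significant: Mapping[str, set[str]],
    observed_topk: Mapping[str, Sequence[str]],
    sig: nullnet.EdgeSignificance,
    cfg: RunConfig,
) -> ConsensusResult:
    """Stage 4: pool per-sample significant interactions into the consensus."""
    sig_pairs = sig.significant_pairs(cfg.p_edge_cutoff)
    per_sample: dict[str, set[tuple[str, str]]] = {}
    for sample, seeds in significant.items():
        pairs = set()
        for s in seeds:
            for g in observed_topk.get(s, ()):
                if (s, g) in sig_pairs:
                    pairs.add((s, g))
        per_sample[sample] = pairs
    pool = cns.pool_edges(per_sample)

    diagnostics = None
    if cfg.edge_cutoff == "auto":
        try:
            diagnostics = cns.suggest_cutoff(pool)
            cutoff = diagnostics.cutoff
            if diagnostics.no_drift:
                log.warning(
                    "consensus: edge counts are consistent with log-linear decay "
                    "(no drift point); using the maximum occurrence %d — consider "
                    "a manual edge_cutoff", cutoff,
                )
        except ValueError as exc:
            log.warning("consensus: %s; defaulting to cutoff 1", exc)
            cutoff = 1
    else:
        cutoff = int(cfg.edge_cutoff)

    mr = cns.mr_index(filters.cohort_sites(profiles))
    network = cns.build_consensus(
        pool, mr, filters.cohort_mutgenes(profiles), cutoff,
        mr_min=cfg.mr_min, mr_min_mutations=cfg.mr_min_mutations,
        sample_counts=filters.sample_counts(profiles),
    )
    return ConsensusResult(pool=pool, diagnostics=diagnostics, mr=mr,
                           network=network, per_sample_significant=per_sample)


@dataclass
class PipelineResult:
    config: RunConfig
    filter: FilterStage
    walk: WalkStage
    significance: nullnet.EdgeSignificance
    consensus: ConsensusResult


def run_all(
    records: Sequence[MutationRecord],
    net: nx.Graph,
    lengths: Mapping[str, int],
    retain: Optional[GeneSet] = None,
    anchors: Optional[GeneSet] = None,
    cfg: RunConfig = RunConfig(),
    ensemble: Optional[nullnet.NullEnsemble] = None,
    null_tables: Optional[Sequence[Mapping[str, Sequence[str]]]] = None,
) -> PipelineResult:
    """Run the four stages end to end on in-memory inputs."""
    profiles = filters.build_profiles(records, cfg.rule())
    fs = filter_stage(profiles, lengths, net, retain, anchors, cfg)
    ws = walk_stage(net, fs.seed_union(), cfg)
    sig = null_stage(net, ws.topk, cfg, ensemble=ensemble, null_tables=null_tables)
    cs = consensus_stage(profiles, fs.significant, ws.topk, sig, cfg)
    return PipelineResult(config=cfg, filter=fs, walk=ws, significance=sig, consensus=cs)


# ---------------------------------------------------------------------------
# artifact serialization


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(outdir: Path, cfg: RunConfig, inputs: Mapping[str, str | Path]) -> Path:
    from . import __version__

    manifest = {
        "version": __version__,
        "config": {k: v for k, v in cfg.to_dict().items()},
        "inputs": {name: {"path": str(p), "sha256": _sha256(p)} for name, p in inputs.items()},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def manifest_matches(outdir: Path, cfg: RunConfig, inputs: Mapping[str, str | Path]) -> bool:
    path = outdir / "manifest.json"
    if not path.exists():
        return False
    try:
        old = json.loads(path.read_text())
    except json.JSONDecodeError:
        return False
    new = {name: {"path": str(p), "sha256": _sha256(p)} for name, p in inputs.items()}
    return old.get("config") == {k: v for k, v in cfg.to_dict().items()} and old.get("inputs") == new


def write_outputs(result: PipelineResult, outdir: str | Path,
                  gene_sets: Sequence[GeneSet] = ()) -> dict[str, Path]:
    """Write all stage artifacts as TSVs under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    p = paths["significant"] = outdir / "significant_mutgenes.tsv"
    with p.open("w") as fh:
        fh.write("sample\tgene\n")
        for sample in sorted(result.filter.significant):
            for g in sorted(result.filter.significant[sample]):
                fh.write(f"{sample}\t{g}\n")

    p = paths["accounting"] = outdir / "filter_accounting.tsv"
    with p.open("w") as fh:
        fh.write("sample\tmodel\tn_mutgenes\tn_after_resample\tn_in_network\tn_near_anchors\n")
        for rec in result.filter.accounting:
            fh.write(
                f"{rec.sample_id}\t{rec.provenance}\t{rec.n_mutgenes}\t"
                f"{rec.n_after_resample}\t{rec.n_after_network}\t{rec.n_after_anchor}\n"
            )

    p = paths["topk"] = outdir / "top_interactors.tsv"
    with p.open("w") as fh:
        fh.write("seed\trank\tinteractor\n")
        for s in sorted(result.walk.topk):
            for rank, g in enumerate(result.walk.topk[s], start=1):
                fh.write(f"{s}\t{rank}\t{g}\n")

    p = paths["edge_pvalues"] = outdir / "edge_pvalues.tsv"
    with p.open("w") as fh:
        fh.write("seed\tinteractor\tp_edge\n")
        for (s, g) in sorted(result.significance.p):
            fh.write(f"{s}\t{g}\t{result.significance.p[(s, g)]:.6g}\n")

    paths["pool"] = outdir / "edge_pool.tsv"
    result.consensus.pool.table().to_csv(paths["pool"], sep="\t", index=False)

    if result.consensus.diagnostics is not None:
        paths["diagnostics"] = outdir / "cutoff_diagnostics.tsv"
        result.consensus.diagnostics.table.to_csv(paths["diagnostics"], sep="\t", index=False)

    paths["mr"] = outdir / "mr_index.tsv"
    result.consensus.mr.to_csv(paths["mr"], sep="\t")

    cn = result.consensus.network
    paths["consensus"] = outdir / "consensus_edges.tsv"
    paths["consensus_nodes"] = outdir / "consensus_nodes.tsv"
    write_network(
        cn.graph, paths["consensus"], paths["consensus_nodes"],
        occurrence={e: cn.graph.edges[e]["occurrence"] for e in cn.graph.edges()},
        node_mutation_counts={g: cn.graph.nodes[g]["n_samples_mutated"] for g in cn.graph.nodes()},
        gene_sets=gene_sets,
        subgraph_ids=cn.subgraph_ids,
        orphan_ids=cn.orphan_ids,
    )
    return paths
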