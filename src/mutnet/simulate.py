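"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates three features of real tumor sequencing cohorts:

* passenger mutations land in genes with probability increasing in cDNA
  length (logistic in log-length), so long genes are recurrently mutated by
  chance alone;
* a small set of driver genes sits in a densely connected module of the
  interaction network and is mutated in a configured fraction of samples;
* driver mutations recur at hotspot coordinates shared across samples,
  while passenger sites are scattered.

Driver deleteriousness is encoded through prediction scores beyond the
classification thresholds (e.g. SIFT < 0.05) so the classification stage is
exercised rather than bypassed, and a sprinkle of silent / benign-missense
records exercises the non-deleterious path. Ground truth is returned in
separate tables that the pipeline never reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import expit

from .io import GeneSet, MutationRecord, VariantClass

MAF_HEADER = [
    "Tumor_Sample_Barcode", "Hugo_Symbol", "Chromosome", "Start_Position",
    "Variant_Classification", "SIFT", "PolyPhen2",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults describe a desk-scale cohort: 2000 genes, 60 samples, a 20-gene
    planted driver module mutated in 30% of samples, log-normal cDNA lengths
    (median ~2.2 kb) and a passenger rate logistic in log-length calibrated
    to ~130 mutated genes per sample.
    """

    n_genes: int = 2000
    n_samples: int = 60
    pa_edges_per_node: int = 3  # preferential-attachment parameter
    length_log_mean: float = 7.7  # natural-log bp
    length_log_sd: float = 0.6
    passenger_intercept: float = -10.45  # logit scale, on ln(length)
    passenger_slope: float = 1.0
    module_size: int = 20
    module_edge_prob: float = 0.6
    module_fraction: float = 0.3  # per-gene fraction of samples mutated
    hotspot_prob: float = 0.7
    anchor_module_overlap: float = 0.5
    n_extra_anchors: int = 40
    nondeleterious_rate: float = 0.015  # benign records per gene per sample
    master_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_samples, self.pa_edges_per_node) < 1:
            raise ValueError("counts must be positive")
        if self.module_size > self.n_genes:
            raise ValueError("module larger than gene universe")
        for name in ("module_edge_prob", "module_fraction", "hotspot_prob",
                     "anchor_module_overlap", "nondeleterious_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"G{i:0{width}d}" for i in range(n)]


def simulate_network(
    cfg: SimConfig, seed: int | np.random.Generator | None = None
) -> tuple[nx.Graph, list[str]]:
    """Preferential-attachment graph with a connected planted module.

    The module genes are chosen at random and wired together: a random
    spanning tree guarantees a connected induced subgraph, and each further
    module pair is linked with probability ``module_edge_prob``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        cfg.master_seed if seed is None else seed
    )
    names = _gene_names(cfg.n_genes)
    ba_seed = int(rng.integers(0, 2**31 - 1))
    g = nx.barabasi_albert_graph(cfg.n_genes, cfg.pa_edges_per_node, seed=ba_seed)
    g = nx.relabel_nodes(g, dict(enumerate(names)))
    if cfg.module_size == 0:
        return g, []
    idx = rng.choice(cfg.n_genes, size=cfg.module_size, replace=False)
    module = [names[i] for i in sorted(idx)]
    order = list(rng.permutation(module))
    for i in range(1, len(order)):  # spanning tree keeps the module connected
        j = int(rng.integers(0, i))
        g.add_edge(order[i], order[j])
    for i in range(len(module)):
        for j in range(i + 1, len(module)):
            if rng.random() < cfg.module_edge_prob:
                g.add_edge(module[i], module[j])
    return g, module


@dataclass
class SimCohort:
    """Generated cohort plus ground truth (truth is for evaluation only)."""

    records: list[MutationRecord]
    lengths: dict[str, int]
    anchors: GeneSet
    gene_truth: pd.DataFrame  # gene, length, is_driver, p_passenger, hotspot
    sample_truth: pd.DataFrame  # sample, gene, is_driver


def simulate_cohort(
    cfg: SimConfig,
    net: nx.Graph,
    module: list[str],
    seed: int | np.random.Generator | None = None,
) -> SimCohort:
    """Draw per-sample mutation records over the given network's genes."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        cfg.master_seed if seed is None else seed
    )
    names = sorted(net.nodes())
    n = len(names)
    lengths_arr = np.maximum(
        150, rng.lognormal(cfg.length_log_mean, cfg.length_log_sd, n)
    ).astype(int)
    lengths = dict(zip(names, (int(v) for v in lengths_arr)))
    p_passenger = expit(cfg.passenger_intercept + cfg.passenger_slope * np.log(lengths_arr))
    chrom = {g: f"chr{1 + i % 22}" for i, g in enumerate(names)}
    start = {g: 1 + (i // 22) * 10_000_000 for i, g in enumerate(names)}
    module_set = set(module)
    hotspot = {
        g: start[g] + int(rng.integers(0, lengths[g])) for g in module
    }

    def _pos(g: str) -> int:
        return start[g] + int(rng.integers(0, lengths[g]))

    def _passenger_record(sample: str, g: str) -> MutationRecord:
        u = rng.random()
        pos = _pos(g)
        if u < 0.40:
            return MutationRecord(sample, g, chrom[g], pos, VariantClass.MISSENSE,
                                  sift=round(float(rng.uniform(0.0, 0.0499)), 4))
        if u < 0.60:
            return MutationRecord(sample, g, chrom[g], pos, VariantClass.MISSENSE,
                                  sift=round(float(rng.uniform(0.2, 1.0)), 4),
                                  polyphen2=round(float(rng.uniform(0.5, 1.0)), 4))
        if u < 0.80:
            return MutationRecord(sample, g, chrom[g], pos, VariantClass.FRAMESHIFT_INDEL)
        if u < 0.90:
            return MutationRecord(sample, g, chrom[g], pos, VariantClass.NONSENSE)
        return MutationRecord(sample, g, chrom[g], pos, VariantClass.SPLICE_SITE)

    def _benign_record(sample: str, g: str) -> MutationRecord:
        pos = _pos(g)
        if rng.random() < 0.6:
            return MutationRecord(sample, g, chrom[g], pos, VariantClass.SILENT)
        return MutationRecord(sample, g, chrom[g], pos, VariantClass.MISSENSE,
                              sift=round(float(rng.uniform(0.1, 1.0)), 4),
                              polyphen2=round(float(rng.uniform(0.0, 0.4999)), 4))

    records: list[MutationRecord] = []
    sample_rows: list[tuple[str, str, bool]] = []
    samples = [f"S{j:03d}" for j in range(cfg.n_samples)]
    is_module = np.array([g in module_set for g in names])
    for sample in samples:
        # module genes mutate only through the driver process so their site
        # recurrence reflects the configured hotspot probability exactly
        passenger_mask = (rng.random(n) < p_passenger) & ~is_module
        for i in np.flatnonzero(passenger_mask):
            g = names[i]
            for _ in range(1 + int(rng.random() < 0.3)):
                records.append(_passenger_record(sample, g))
            sample_rows.append((sample, g, False))
        for g in module:
            if rng.random() >= cfg.module_fraction:
                continue
            pos = hotspot[g] if rng.random() < cfg.hotspot_prob else _pos(g)
            records.append(
                MutationRecord(sample, g, chrom[g], pos, VariantClass.MISSENSE,
                               sift=round(float(rng.uniform(0.0, 0.0499)), 4))
            )
            sample_rows.append((sample, g, True))
        benign_mask = rng.random(n) < cfg.nondeleterious_rate
        for i in np.flatnonzero(benign_mask):
            records.append(_benign_record(sample, names[i]))

    n_anchor_mod = int(round(cfg.anchor_module_overlap * len(module)))
    anchor_mod = [module[i] for i in sorted(rng.choice(len(module), n_anchor_mod, replace=False))] if n_anchor_mod else []
    non_module = [g for g in names if g not in module_set]
    extra_idx = sorted(rng.choice(len(non_module), min(cfg.n_extra_anchors, len(non_module)), replace=False))
    anchors = GeneSet("anchors", frozenset(anchor_mod) | frozenset(non_module[i] for i in extra_idx))

    gene_truth = pd.DataFrame(
        {
            "gene": names,
            "length": [lengths[g] for g in names],
            "is_driver": [g in module_set for g in names],
            "p_passenger": p_passenger,
            "hotspot_pos": [hotspot.get(g, -1) for g in names],
        }
    ).set_index("gene")
    sample_truth = pd.DataFrame(sample_rows, columns=["sample", "gene", "is_driver"])
    return SimCohort(records=records, lengths=lengths, anchors=anchors,
                     gene_truth=gene_truth, sample_truth=sample_truth)


@dataclass
class Simulation:
    config: SimConfig
    network: nx.Graph
    module: list[str]
    cohort: SimCohort


def simulate(cfg: SimConfig, seed: int | None = None) -> Simulation:
    """Network + cohort from one master seed (identical seed => identical data)."""
    rng = np.random.default_rng(cfg.master_seed if seed is None else seed)
    net, module = simulate_network(cfg, rng)
    cohort = simulate_cohort(cfg, net, module, rng)
    return Simulation(config=cfg, network=net, module=module, cohort=cohort)


def write_simulation(sim: Simulation, outdir: str | Path) -> dict[str, Path]:
    """Write MAF-like cohort, network, lengths, anchors and truth tables.

    All outputs are plain TSV/text and parse back through the package
    readers; truth tables live under ``truth/`` and are never consumed by
    the pipeline.
    """
    outdir = Path(outdir)
    (outdir / "truth").mkdir(parents=True, exist_ok=True)
    paths = {
        "maf": outdir / "cohort.maf.tsv",
        "network": outdir / "network.tsv",
        "lengths": outdir / "lengths.tsv",
        "anchors": outdir / "anchors.txt",
        "gene_truth": outdir / "truth" / "genes.tsv",
        "sample_truth": outdir / "truth" / "sample_mutgenes.tsv",
        "module": outdir / "truth" / "module.txt",
    }
    with paths["maf"].open("w") as fh:
        fh.write("\t".join(MAF_HEADER) + "\n")
        for r in sim.cohort.records:
            fh.write(
                "\t".join(
                    [
                        r.sample_id, r.gene, r.chrom, str(r.pos), r.variant_class.value,
                        "" if r.sift is None else f"{r.sift:.4f}",
                        "" if r.polyphen2 is None else f"{r.polyphen2:.4f}",
                    ]
                )
                + "\n"
            )
    with paths["network"].open("w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in sim.network.edges()):
            fh.write(f"{a}\t{b}\n")
    with paths["lengths"].open("w") as fh:
        for g in sorted(sim.cohort.lengths):
            fh.write(f"{g}\t{sim.cohort.lengths[g]}\n")
    paths["anchors"].write_text("".join(f"{g}\n" for g in sorted(sim.cohort.anchors.members)))
    sim.cohort.gene_truth.to_csv(paths["gene_truth"], sep="\t")
    sim.cohort.sample_truth.to_csv(paths["sample_truth"], sep="\t", index=False)
    paths["module"].write_text("".join(f"{g}\n" for g in sim.module))
    return paths
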