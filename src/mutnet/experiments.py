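"""Benchmark experiments on synthetic cohorts.

These are the package's built-in evaluations: recovery of a planted driver
module from a length-confounded cohort, and the cohort-level false-positive
calibration on matched cohorts without any driver signal. Both are used by
the test suite and the examples.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np

from . import consensus as cns
from . import nullnet, walk
from .filters import build_profiles
from .pipeline import PipelineResult, RunConfig, run_all
from .simulate import SimConfig, Simulation, simulate, simulate_cohort, simulate_network

log = logging.getLogger(__name__)


@dataclass
class RecoveryResult:
    simulation: Simulation
    pipeline: PipelineResult
    enrichment_table: np.ndarray
    enrichment_p: float

    @property
    def consensus_genes(self) -> set[str]:
        return self.pipeline.consensus.network.genes


def planted_module_recovery(
    seed: int = 0,
    sim_cfg: SimConfig | None = None,
    run_cfg: RunConfig | None = None,
) -> RecoveryResult:
    """Full pipeline on a planted-module cohort + module-enrichment test.

    Simulates a cohort at the generator's study conditions, runs the four
    pipeline stages, and Fisher-tests the consensus network's genes for
    enrichment of the planted driver module over the network's gene
    universe. The anchor list written by the generator plays the role of
    the curated cancer-gene whitelist (retention + distance filter).
    """
    sim_cfg = sim_cfg if sim_cfg is not None else SimConfig(master_seed=seed)
    run_cfg = run_cfg if run_cfg is not None else RunConfig(master_seed=seed)
    sim = simulate(sim_cfg, seed=seed)
    result = run_all(
        sim.cohort.records, sim.network, sim.cohort.lengths,
        retain=sim.cohort.anchors, anchors=sim.cohort.anchors, cfg=run_cfg,
    )
    table, p = cns.enrichment_test(
        result.consensus.network.genes, sim.module, sim.network.nodes()
    )
    return RecoveryResult(simulation=sim, pipeline=result,
                          enrichment_table=table, enrichment_p=p)


@dataclass
class NullCalibrationResult:
    p_values: list[float]
    fraction_below: float
    alpha: float


def null_cohort_calibration(
    n_cohorts: int = 20,
    seed: int = 0,
    alpha: float = 0.05,
    sim_cfg: SimConfig | None = None,
    run_cfg: RunConfig | None = None,
) -> NullCalibrationResult:
    """False-positive calibration on cohorts with no planted structure.

    One reference network is simulated with no module at all (no planted
    edges, no elevated mutation rates); ``n_cohorts`` independent
    length-driven passenger cohorts are then drawn against it. Because the
    null ensemble and the per-seed walk results depend only on the network,
    they are computed once for all nodes and shared across cohorts; only
    the cohort mutation randomness varies. For each cohort the consensus
    network is tested for enrichment of a freshly drawn phantom gene set of
    the module's size; a well-calibrated pipeline should rarely reach
    significance.
    """
    sim_cfg = sim_cfg if sim_cfg is not None else SimConfig(master_seed=seed)
    phantom_size = sim_cfg.module_size
    null_sim_cfg = dataclasses.replace(sim_cfg, module_size=0, module_fraction=0.0)
    run_cfg = run_cfg if run_cfg is not None else RunConfig(master_seed=seed)

    rng = np.random.default_rng(seed)
    net, module = simulate_network(null_sim_cfg, rng)
    # shared across cohorts: ensemble, observed and null walks for all nodes
    ensemble = nullnet.build_ensemble(
        net, n=run_cfg.n_random_networks, n_swaps_per_edge=run_cfg.n_swaps_per_edge,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    T = walk.column_normalize(net)
    all_nodes = list(T.nodes)
    null_tables = nullnet.null_topk_tables(
        ensemble, all_nodes, r=run_cfg.restart_prob, tol=run_cfg.tol,
        k=run_cfg.top_k, exclude_seed=run_cfg.exclude_seed, max_iter=run_cfg.max_iter,
    )
    nodes = sorted(net.nodes())
    p_values = []
    for i in range(n_cohorts):
        cohort = simulate_cohort(null_sim_cfg, net, module, seed=rng)
        phantom = [nodes[j] for j in rng.choice(len(nodes), size=phantom_size, replace=False)]
        result = run_all(
            cohort.records, net, cohort.lengths,
            retain=cohort.anchors, anchors=cohort.anchors,
            cfg=run_cfg.replace(master_seed=int(rng.integers(0, 2**31 - 1))),
            ensemble=ensemble, null_tables=null_tables,
        )
        _, p = cns.enrichment_test(result.consensus.network.genes, phantom, net.nodes())
        p_values.append(p)
        log.info("null cohort %d: consensus %d genes, enrichment p = %.3g",
                 i, len(result.consensus.network.genes), p)
    frac = float(np.mean([p < alpha for p in p_values]))
    return NullCalibrationResult(p_values=p_values, fraction_below=frac, alpha=alpha)
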