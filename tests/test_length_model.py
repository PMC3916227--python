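"""Length-model fitting, weighted resampling and the MutGene filters."""

import math

import networkx as nx
import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import spearmanr

from mutnet.io import GeneSet, SampleProfile
from mutnet.length_model import (
    ConfigurationError,
    anchor_distance_filter,
    choose_model,
    filter_mutgenes,
    fit_pwv,
    resample_null,
)


def _universe(n, rng, log_mean=7.7, log_sd=0.6):
    genes = [f"G{i:04d}" for i in range(n)]
    arr = np.maximum(150, rng.lognormal(log_mean, log_sd, n)).astype(int)
    return genes, dict(zip(genes, map(int, arr)))


class TestFitPwv:
    def test_identical_lengths_give_uniform_weights(self):
        lengths = {f"G{i}": 1000 for i in range(20)}
        pwv = fit_pwv(["G0", "G3"], lengths)
        assert np.allclose(pwv.weights, 1 / 20)

    def test_recovers_logistic_length_effect(self, rng):
        genes, lengths = _universe(800, rng)
        x = np.array([lengths[g] for g in genes])
        true_p = expit(-9.5 + 1.1 * np.log(x))
        mut = [g for g, p in zip(genes, true_p) if rng.random() < p]
        pwv = fit_pwv(mut, lengths)
        assert not pwv.fallback
        tp = dict(zip(genes, true_p))
        rho = spearmanr(pwv.fitted_prob, [tp[g] for g in pwv.genes]).statistic
        assert rho > 0.9

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_weights_monotone_in_length(self, seed):
        rng = np.random.default_rng(seed)
        genes, lengths = _universe(400, rng)
        mut = [g for g in genes if rng.random() < 0.1]
        pwv = fit_pwv(mut, lengths)
        order = np.argsort([lengths[g] for g in pwv.genes], kind="stable")
        assert np.all(np.diff(pwv.weights[order]) >= -1e-12)

    def test_weights_positive_and_normalized(self, rng):
        genes, lengths = _universe(200, rng)
        pwv = fit_pwv(genes[:5], lengths)
        assert np.all(pwv.weights > 0)
        assert pwv.weights.sum() == pytest.approx(1.0)

    def test_mutgene_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            fit_pwv(["X"], {"A": 100, "B": 200, "C": 300, "D": 400})


class TestChooseModel:
    def _profile(self, n, lengths):
        genes = sorted(lengths)[:n]
        return SampleProfile("S", set(genes), {g: [("chr1", 1)] for g in genes})

    def test_cutoff_boundary(self, rng):
        genes, lengths = _universe(500, rng)
        cohort = fit_pwv(genes[:120], lengths, provenance="universal")
        assert choose_model(self._profile(49, lengths), cohort, lengths).provenance == "universal"
        assert choose_model(self._profile(50, lengths), cohort, lengths).provenance == "sample_specific"

    def test_zero_cutoff_always_sample_specific(self, rng):
        genes, lengths = _universe(100, rng)
        cohort = fit_pwv(genes[:30], lengths, provenance="universal")
        chosen = choose_model(self._profile(3, lengths), cohort, lengths, min_mutgenes=0)
        assert chosen.provenance == "sample_specific"


class TestResampleNull:
    def test_concentrated_weights_force_inclusion(self):
        lengths = {f"G{i}": 100 + 100 * (i >= 7) for i in range(10)}
        pwv = fit_pwv([f"G{i}" for i in range(10)], lengths)
        # overwrite with a concentrated vector: 3 genes hold nearly all mass
        w = np.full(10, 1e-9)
        w[-3:] = 1 / 3
        pwv.weights = w / w.sum()
        rr = resample_null(pwv, m=3, B=200, seed=0)
        assert np.all(rr.freq[-3:] > 0.999)

    def test_uniform_calibration_within_4_se(self):
        lengths = {f"G{i}": 1000 for i in range(10)}
        pwv = fit_pwv(["G0"], lengths)
        rr = resample_null(pwv, m=2, B=1000, seed=0)
        se = math.sqrt(0.2 * 0.8 / 1000)
        assert np.all(np.abs(rr.freq - 0.2) < 4 * se)

    @pytest.mark.parametrize("m,B", [(0, 10), (11, 10), (2, 0)])
    def test_degenerate_arguments_rejected(self, m, B):
        lengths = {f"G{i}": 1000 for i in range(10)}
        pwv = fit_pwv(["G0"], lengths)
        with pytest.raises(ValueError):
            resample_null(pwv, m=m, B=B, seed=0)

    def test_same_seed_same_frequencies(self, rng):
        genes, lengths = _universe(50, rng)
        pwv = fit_pwv(genes[:10], lengths)
        a = resample_null(pwv, m=10, B=100, seed=5)
        b = resample_null(pwv, m=10, B=100, seed=5)
        assert np.array_equal(a.freq, b.freq)


class TestFilterMutgenes:
    def _setup(self):
        genes = np.array(["A", "B", "C"])
        profile = SampleProfile("S", {"A", "B", "C"}, {g: [("chr1", 1)] for g in "ABC"})
        from mutnet.length_model import ResampleResult

        rr = ResampleResult(genes=genes, freq=np.array([0.06, 0.04, 0.06]), B=1000, m=3)
        return profile, rr

    def test_threshold_semantics(self):
        profile, rr = self._setup()
        kept = filter_mutgenes(profile, rr, retain=None, freq_cutoff=0.05)
        assert kept == {"B"}  # 0.06 removed, 0.04 kept

    def test_retained_set_overrides_frequency(self):
        profile, rr = self._setup()
        kept = filter_mutgenes(profile, rr, retain=GeneSet("cgc", frozenset({"A"})))
        assert kept == {"A", "B"}

    def test_output_subset_of_input(self, small_sim, rng):
        from mutnet.filters import build_profiles

        profiles = build_profiles(small_sim.cohort.records)
        lengths = small_sim.cohort.lengths
        prof = profiles[0]
        pwv = fit_pwv(prof.mutgenes & set(lengths), lengths)
        rr = resample_null(pwv, m=len(prof.mutgenes), B=200, seed=0)
        kept = filter_mutgenes(prof, rr)
        assert kept <= prof.mutgenes


class TestAnchorDistance:
    def test_path_graph_distance_two(self):
        net = nx.path_graph(["A", "B", "C", "D"])
        anchors = GeneSet("a", frozenset({"A"}))
        kept = anchor_distance_filter({"A", "B", "C", "D"}, net, anchors, max_dist=2)
        assert kept == {"A", "B", "C"}

    def test_disconnected_gene_removed(self):
        net = nx.Graph([("A", "B")])
        net.add_node("Z")
        anchors = GeneSet("a", frozenset({"A"}))
        assert anchor_distance_filter({"B", "Z"}, net, anchors) == {"B"}

    def test_infinite_distance_keeps_all_in_network(self):
        net = nx.Graph([("A", "B")])
        net.add_node("Z")
        anchors = GeneSet("a", frozenset({"A"}))
        kept = anchor_distance_filter({"B", "Z", "Q"}, net, anchors, max_dist=math.inf)
        assert kept == {"B", "Z"}

    def test_no_anchor_in_network_is_config_error(self):
        net = nx.Graph([("A", "B")])
        with pytest.raises(ConfigurationError):
            anchor_distance_filter({"A"}, net, GeneSet("a", frozenset({"X"})))


def test_planted_drivers_survive_filter_more_than_length_matched_passengers(small_sim):
    """Sensitivity analog: modest-length drivers pass the resampling filter
    at a higher rate than the cohort's long passenger genes."""
    from mutnet.filters import build_profiles
    from mutnet.pipeline import RunConfig, filter_stage

    cfg = RunConfig(n_resamples=300, master_seed=3)
    profiles = build_profiles(small_sim.cohort.records)
    fs = filter_stage(
        profiles, small_sim.cohort.lengths, small_sim.network,
        retain=None, anchors=None, cfg=cfg,
    )
    module = set(small_sim.module)
    driver_rates, passenger_rates = [], []
    for prof in profiles:
        kept = fs.significant[prof.sample_id]
        for g in prof.mutgenes:
            (driver_rates if g in module else passenger_rates).append(g in kept)
    assert np.mean(driver_rates) > np.mean(passenger_rates)
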