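"""Edge pooling, occurrence cutoff, mr index and evaluation statistics."""

import numpy as np
import pytest
from scipy.stats import hypergeom

from mutnet.consensus import (
    build_consensus,
    enrichment_test,
    mr_index,
    overlap_significance,
    pool_edges,
    suggest_cutoff,
)
from mutnet.io import GeneSet


class TestPoolEdges:
    def test_same_edge_from_both_seeds_counts_once_per_sample(self):
        pool = pool_edges({"S1": [("A", "B"), ("B", "A")]})
        assert pool.occurrence == {("A", "B"): 1}

    def test_occurrence_counts_samples(self):
        per_sample = {
            "S1": [("A", "B")],
            "S2": [("B", "A")],
            "S3": [("A", "B")],
            "S4": [],
            "S5": [("C", "D")],
        }
        pool = pool_edges(per_sample)
        assert pool.occurrence[("A", "B")] == 3
        assert pool.occurrence[("C", "D")] == 1
        assert pool.n_samples == 5

    def test_empty_pool(self):
        pool = pool_edges({"S1": [], "S2": []})
        assert len(pool) == 0


class TestSuggestCutoff:
    def test_exact_geometric_counts_report_no_drift(self):
        # counts 1000, 100, 10, 1 at occurrences 1..4: exactly log-linear
        occurrence = {}
        i = 0
        for occ, n in [(1, 1000), (2, 100), (3, 10), (4, 1)]:
            for _ in range(n):
                occurrence[(f"A{i}", f"B{i}")] = occ
                i += 1
        from mutnet.consensus import EdgePool

        diag = suggest_cutoff(EdgePool(occurrence=occurrence, n_samples=10))
        assert diag.no_drift
        assert diag.cutoff == 4
        assert diag.r_squared == pytest.approx(1.0)

    def test_inflated_tail_detected_at_drift_point(self):
        # geometric bulk over occurrences 1..11, inflated tail from 12
        counts = {o: int(round(3000 * 10 ** (-0.3 * o))) for o in range(1, 12)}
        counts.update({12: 40, 13: 30, 14: 25})
        occurrence = {}
        i = 0
        for occ, n in counts.items():
            for _ in range(n):
                occurrence[(f"A{i}", f"B{i}")] = occ
                i += 1
        from mutnet.consensus import EdgePool

        diag = suggest_cutoff(EdgePool(occurrence=occurrence, n_samples=20))
        assert not diag.no_drift
        assert diag.cutoff == 12

    def test_single_occupied_occurrence_errors(self):
        from mutnet.consensus import EdgePool

        pool = EdgePool(occurrence={("A", "B"): 2, ("C", "D"): 2}, n_samples=5)
        with pytest.raises(ValueError, match="manual"):
            suggest_cutoff(pool)


class TestMrIndex:
    def test_boundary_value(self):
        sites = [("chr1", i) for i in range(1, 21)] + [("chr1", 1)]
        table = mr_index({"G": sites})
        assert table.loc["G", "n_all"] == 21
        assert table.loc["G", "n_unique"] == 20
        assert table.loc["G", "mr"] == pytest.approx(1.05)

    def test_all_unique_gives_one(self):
        table = mr_index({"G": [("chr1", i) for i in range(5)]})
        assert table.loc["G", "mr"] == 1.0

    def test_hotspot_ratio(self):
        table = mr_index({"G": [("chr1", 1), ("chr1", 1), ("chr2", 2), ("chr2", 2)]})
        assert table.loc["G", "mr"] == 2.0

    def test_mr_at_least_one_and_one_iff_no_recurrence(self, rng):
        sites = {
            f"G{i}": [("chr1", int(p)) for p in rng.integers(1, 30, size=rng.integers(1, 20))]
            for i in range(30)
        }
        table = mr_index(sites)
        assert (table.mr >= 1.0).all()
        no_recur = table.index[table.mr == 1.0]
        for g in no_recur:
            assert len(set(sites[g])) == len(sites[g])


class TestBuildConsensus:
    @staticmethod
    def _pool(edges):
        from mutnet.consensus import EdgePool

        return EdgePool(occurrence=dict(edges), n_samples=20)

    def test_heavily_mutated_never_recurrent_endpoint_removed(self):
        pool = self._pool({("A", "B"): 12})
        mr = mr_index({"A": [("chr1", i) for i in range(30)], "B": [("chr2", 1)]})
        net = build_consensus(pool, mr, {"A", "B"}, cutoff=10)
        assert net.graph.number_of_edges() == 0  # A: n_all=30, mr=1.0 -> flagged

    def test_singleton_mutation_gene_kept(self):
        pool = self._pool({("A", "B"): 12})
        mr = mr_index({"A": [("chr1", 1)], "B": [("chr2", 1)]})
        net = build_consensus(pool, mr, {"A", "B"}, cutoff=10)
        assert set(net.graph.edges()) == {("A", "B")}

    def test_recurrent_hotspot_gene_kept_despite_many_mutations(self):
        sites_a = [("chr1", 1)] * 10 + [("chr1", i) for i in range(2, 22)]
        pool = self._pool({("A", "B"): 12})
        mr = mr_index({"A": sites_a, "B": [("chr2", 1)]})
        net = build_consensus(pool, mr, {"A", "B"}, cutoff=10)
        assert ("A", "B") in net.graph.edges() or ("B", "A") in net.graph.edges()

    def test_cutoff_and_orphan_labelling(self):
        pool = self._pool({("A", "B"): 12, ("C", "D"): 9, ("E", "F"): 15})
        mr = mr_index({g: [("chr1", 1)] for g in "ABCDEF"})
        net = build_consensus(pool, mr, set("ABCDEF"), cutoff=10)
        assert net.graph.number_of_edges() == 2
        assert net.n_subgraphs() == 2
        assert len(net.orphan_ids) == 2  # two disjoint single-edge components

    def test_both_endpoints_must_be_cohort_mutgenes(self):
        pool = self._pool({("A", "B"): 12})
        mr = mr_index({"A": [("chr1", 1)]})
        net = build_consensus(pool, mr, {"A"}, cutoff=10)
        assert net.graph.number_of_edges() == 0

    def test_raising_cutoff_is_monotone(self):
        pool = self._pool({("A", "B"): 3, ("B", "C"): 7, ("C", "D"): 11})
        mr = mr_index({g: [("chr1", 1)] for g in "ABCD"})
        genes = set("ABCD")
        for c in range(1, 12):
            lo = build_consensus(pool, mr, genes, cutoff=c)
            hi = build_consensus(pool, mr, genes, cutoff=c + 1)
            assert set(map(frozenset, hi.graph.edges())) <= set(map(frozenset, lo.graph.edges()))


class TestEnrichment:
    def test_network_equal_to_target_is_minimal_p(self):
        universe = [f"G{i}" for i in range(50)]
        net = universe[:10]
        table, p = enrichment_test(net, net, universe)
        # the most extreme table attainable given the margins: P(X >= 10)
        assert p == pytest.approx(hypergeom.sf(9, 50, 10, 10))

    def test_matches_hypergeometric_tail(self):
        universe = [f"G{i}" for i in range(100)]
        net = set(universe[:10])
        target = set(universe[5:15])  # overlap 5
        _, p = enrichment_test(net, target, universe)
        oracle = sum(hypergeom.pmf(k, 100, 10, 10) for k in range(5, 11))
        assert p == pytest.approx(oracle, rel=1e-9)

    def test_overlap_at_expectation_is_not_significant(self):
        universe = [f"G{i}" for i in range(100)]
        net = set(universe[:10])
        target = set(universe[9:19])  # overlap 1 = 10*10/100 expectation
        _, p = enrichment_test(net, target, universe)
        assert 0.5 <= p <= 1.0

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            enrichment_test({"A"}, {"A"}, [])


class TestOverlapSignificance:
    def test_identical_sets_floor_reported(self):
        universe = [f"G{i}" for i in range(200)]
        a = universe[:12]
        res = overlap_significance(a, a, universe, n_perm=1000, seed=0)
        assert res.count == 0
        assert res.label == "< 0.001"

    def test_disjoint_small_sets_near_one(self):
        universe = [f"G{i}" for i in range(500)]
        res = overlap_significance(universe[:5], universe[490:], universe, n_perm=300, seed=1)
        assert res.p > 0.9

    def test_set_larger_than_universe_rejected(self):
        with pytest.raises(ValueError):
            overlap_significance(["A", "B"], ["A"], ["A"], n_perm=10)
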