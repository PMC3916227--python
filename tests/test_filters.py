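"""Deleterious classification and per-sample profile construction."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import spearmanr

from mutnet.filters import (
    DeleteriousRule,
    build_profiles,
    classify_deleterious,
    length_mutation_curve,
)
from mutnet.io import MutationRecord, VariantClass


def _rec(vclass, sift=None, poly=None, sample="S1", gene="G1", pos=100):
    return MutationRecord(sample, gene, "chr1", pos, vclass, sift=sift, polyphen2=poly)


RULE = DeleteriousRule()


@pytest.mark.parametrize(
    "vclass,sift,poly,expected",
    [
        (VariantClass.MISSENSE, 0.01, None, True),  # damaging by SIFT alone
        (VariantClass.MISSENSE, 0.50, 0.9, True),  # damaging by PolyPhen2 alone
        (VariantClass.MISSENSE, 0.50, 0.49, False),  # benign by both
        (VariantClass.MISSENSE, None, None, False),  # unscored: conservative default
        (VariantClass.FRAMESHIFT_INDEL, None, None, True),  # indels always deleterious
        (VariantClass.INFRAME_INDEL, None, None, True),
        (VariantClass.NONSENSE, None, None, True),
        (VariantClass.NONSTOP, None, None, True),
        (VariantClass.SPLICE_SITE, None, None, True),
        (VariantClass.TRANSLATION_START, None, None, True),
        (VariantClass.DNP_NONSILENT, None, None, True),
        (VariantClass.TNP_NONSILENT, None, None, True),
        (VariantClass.SILENT, 0.0, 1.0, False),  # silent never deleterious
        (VariantClass.OTHER_NONCODING, 0.0, 1.0, False),
    ],
)
def test_classification_rules(vclass, sift, poly, expected):
    assert classify_deleterious(_rec(vclass, sift, poly), RULE) is expected


def test_missense_default_flag_inverts_unscored_call():
    rule = DeleteriousRule(missense_default_deleterious=True)
    assert classify_deleterious(_rec(VariantClass.MISSENSE), rule)


@given(
    sift=st.one_of(st.none(), st.floats(0, 1)),
    poly=st.one_of(st.none(), st.floats(0, 1)),
    delta=st.floats(0, 1),
)
def test_classification_monotone_in_scores(sift, poly, delta):
    """Lowering SIFT or raising PolyPhen2 never flips a damaging call to benign."""
    base = classify_deleterious(_rec(VariantClass.MISSENSE, sift, poly), RULE)
    if sift is not None:
        worse = classify_deleterious(
            _rec(VariantClass.MISSENSE, max(sift - delta, 0.0), poly), RULE
        )
        assert worse >= base
    if poly is not None:
        worse = classify_deleterious(
            _rec(VariantClass.MISSENSE, sift, min(poly + delta, 1.0)), RULE
        )
        assert worse >= base


class TestBuildProfiles:
    def test_sample_without_deleterious_mutation_absent(self):
        recs = [
            _rec(VariantClass.MISSENSE, sift=0.01, sample="A"),
            _rec(VariantClass.SILENT, sample="B"),
        ]
        profiles = build_profiles(recs)
        assert [p.sample_id for p in profiles] == ["A"]

    def test_duplicate_site_kept_in_multiset(self):
        recs = [
            _rec(VariantClass.MISSENSE, sift=0.01, pos=5),
            _rec(VariantClass.MISSENSE, sift=0.02, pos=5),
        ]
        (prof,) = build_profiles(recs)
        assert prof.mutgenes == {"G1"}
        assert prof.sites["G1"] == [("chr1", 5), ("chr1", 5)]

    def test_order_invariance(self, rng):
        recs = [
            _rec(VariantClass.MISSENSE, sift=0.01, sample=f"S{i%3}", gene=f"G{i%5}", pos=10 + i)
            for i in range(20)
        ]
        shuffled = [recs[i] for i in rng.permutation(len(recs))]
        assert build_profiles(recs) == build_profiles(shuffled)

    def test_matches_generator_bookkeeping(self, small_sim):
        profiles = build_profiles(small_sim.cohort.records)
        truth = small_sim.cohort.sample_truth
        expected = truth.groupby("sample")["gene"].nunique().to_dict()
        got = {p.sample_id: len(p.mutgenes) for p in profiles}
        assert got == {s: n for s, n in expected.items() if n > 0}


class TestLengthCurve:
    def test_equal_lengths_single_occupied_bin(self):
        recs = [_rec(VariantClass.MISSENSE, sift=0.01, gene="A")]
        table = length_mutation_curve(build_profiles(recs), {"A": 500, "B": 500, "C": 500}, n_bins=4)
        occupied = table[table.n_genes > 0]
        assert len(occupied) == 1
        assert occupied.prop_all.iloc[0] == pytest.approx(1 / 3)

    def test_recurrent_curve_below_all_curve(self, small_sim):
        profiles = build_profiles(small_sim.cohort.records)
        table = length_mutation_curve(profiles, small_sim.cohort.lengths, n_bins=8)
        ok = table.dropna()
        assert (ok.prop_recurrent <= ok.prop_all + 1e-12).all()

    def test_logistic_length_effect_gives_increasing_curve(self, small_sim):
        profiles = build_profiles(small_sim.cohort.records)
        table = length_mutation_curve(profiles, small_sim.cohort.lengths, n_bins=6).dropna()
        rho = spearmanr(table.length_mid, table.prop_all).statistic
        assert rho > 0

    def test_requires_two_bins(self):
        with pytest.raises(ValueError):
            length_mutation_curve([], {"A": 10}, n_bins=1)
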