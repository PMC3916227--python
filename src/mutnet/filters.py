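"""Deleterious-mutation classification and per-sample mutation profiles.

A gene is a *MutGene* in a sample when it harbors at least one non-silent
deleterious mutation there. Missense SNVs are deleterious when predicted
damaging by either annotator (SIFT below a cutoff OR PolyPhen2 at/above a
cutoff); truncating and splice classes, non-silent DNP/TNP substitutions and
all coding indels are deleterious unconditionally; silent and unclassified
variants never are.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import MutationRecord, SampleProfile, VariantClass

#: Classes treated as deleterious without consulting prediction scores.
ALWAYS_DELETERIOUS: frozenset[VariantClass] = frozenset(
    {
        VariantClass.NONSENSE,
        VariantClass.NONSTOP,
        VariantClass.SPLICE_SITE,
        VariantClass.TRANSLATION_START,
        VariantClass.DNP_NONSILENT,
        VariantClass.TNP_NONSILENT,
        VariantClass.FRAMESHIFT_INDEL,
        VariantClass.INFRAME_INDEL,
    }
)


@dataclass(frozen=True)
class DeleteriousRule:
    """Thresholds for calling a missense SNV deleterious.

    ``missense_default_deleterious`` controls the call for a missense with
    neither score available: the default (False) is conservative and keeps
    such variants out of the MutGene tally.
    """

    sift_max: float = 0.05
    polyphen_min: float = 0.5
    missense_default_deleterious: bool = False

    def __post_init__(self) -> None:
        for name in ("sift_max", "polyphen_min"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


DEFAULT_RULE = DeleteriousRule()


def classify_deleterious(rec: MutationRecord, rule: DeleteriousRule = DEFAULT_RULE) -> bool:
    """Return True iff the record counts as a deleterious mutation."""
    if rec.variant_class in ALWAYS_DELETERIOUS:
        return True
    if rec.variant_class is not VariantClass.MISSENSE:
        return False
    if rec.sift is None and rec.polyphen2 is None:
        return rule.missense_default_deleterious
    # OR over the available annotators.
    if rec.sift is not None and rec.sift < rule.sift_max:
        return True
    if rec.polyphen2 is not None and rec.polyphen2 >= rule.polyphen_min:
        return True
    return False


def build_profiles(
    records: Iterable[MutationRecord], rule: DeleteriousRule = DEFAULT_RULE
) -> list[SampleProfile]:
    """Group deleterious mutations into per-sample profiles.

    Samples with no deleterious mutation yield no profile. Site multisets
    keep duplicates at identical coordinates (needed later by the mutation
    recurrence index). Output is sorted by sample id and independent of the
    input record order.
    """
    by_sample: dict[str, SampleProfile] = {}
    for rec in records:
        if not classify_deleterious(rec, rule):
            continue
        prof = by_sample.get(rec.sample_id)
        if prof is None:
            prof = by_sample[rec.sample_id] = SampleProfile(rec.sample_id)
        prof.add_site(rec.gene, rec.site)
    profiles = [by_sample[s] for s in sorted(by_sample)]
    for prof in profiles:  # canonical site order for determinism
        for g in prof.sites:
            prof.sites[g].sort()
    return profiles


def cohort_mutgenes(profiles: Sequence[SampleProfile]) -> set[str]:
    """Union of MutGenes over all samples."""
    out: set[str] = set()
    for p in profiles:
        out |= p.mutgenes
    return out


def sample_counts(profiles: Sequence[SampleProfile]) -> dict[str, int]:
    """Number of samples in which each gene is a MutGene."""
    counts: dict[str, int] = defaultdict(int)
    for p in profiles:
        for g in p.mutgenes:
            counts[g] += 1
    return dict(counts)


def cohort_sites(profiles: Sequence[SampleProfile]) -> dict[str, list[tuple[str, int]]]:
    """Pooled per-gene deleterious site multisets across the cohort."""
    sites: dict[str, list[tuple[str, int]]] = defaultdict(list)
    for p in profiles:
        for g, ss in p.sites.items():
            sites[g].extend(ss)
    return {g: sorted(ss) for g, ss in sites.items()}


def length_mutation_curve(
    profiles: Sequence[SampleProfile],
    lengths: Mapping[str, int],
    n_bins: int = 20,
) -> pd.DataFrame:
    """Proportion of genes that are MutGenes, by cDNA-length bin.

    Returns one row per equal-width length bin with the bin midpoint, the
    number of genes in the bin, and the mutated proportion under two set
    definitions: *all* (MutGene in >=1 sample) and *recurrent* (MutGene in
    >=2 samples). Empty bins carry NaN proportions. This is the diagnostic
    used to visualize the gene-length mutation bias that motivates the
    length model.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    genes = np.array(sorted(lengths))
    x = np.array([lengths[g] for g in genes], dtype=float)
    counts = sample_counts(profiles)
    n_samp = np.array([counts.get(g, 0) for g in genes])

    edges = np.linspace(x.min(), x.max(), n_bins + 1)
    # right-inclusive last bin
    idx = np.clip(np.digitize(x, edges[1:-1]), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = idx == b
        n = int(mask.sum())
        mid = 0.5 * (edges[b] + edges[b + 1])
        if n == 0:
            rows.append((mid, 0, np.nan, np.nan))
        else:
            rows.append(
                (
                    mid,
                    n,
                    float((n_samp[mask] >= 1).mean()),
                    float((n_samp[mask] >= 2).mean()),
                )
            )
    return pd.DataFrame(rows, columns=["length_mid", "n_genes", "prop_all", "prop_recurrent"])
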