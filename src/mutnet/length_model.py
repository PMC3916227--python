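"""Gene-length mutation background model and resampling-based filters.

Long genes accumulate more passenger mutations purely by target size. For a
sample with mutation-status indicator :math:`y_i` over the gene universe and
cDNA lengths :math:`x_i`, we model

.. math:: \\operatorname{logit} P(y_i = 1) = f(x_i)

with :math:`f` a monotone non-decreasing cubic spline (six knots at
equispaced length quantiles) fit by maximum binomial likelihood. The fitted
per-gene probability, floored at a small epsilon and normalized, is the
*probability weight vector* (PWV): a gene's relative chance of being mutated
by target-size chance alone in that sample.

Weighted resampling of gene sets of the observed size under the PWV then
yields, per gene, the frequency with which it shows up in random MutGene
sets. Genes that random length-driven sampling reproduces at >= 5% frequency
are treated as likely passengers and filtered, with an optional whitelist of
anchor genes (e.g. a cancer-gene census) that is always retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import networkx as nx
import numpy as np
from scipy.interpolate import BSpline
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.isotonic import IsotonicRegression

from .io import GeneSet, SampleProfile

log = logging.getLogger(__name__)

EPS_WEIGHT = 1e-9


class ConfigurationError(ValueError):
    """Inputs are structurally valid but inconsistent with the analysis."""


@dataclass
class ProbabilityWeightVector:
    """Per-gene relative mutation weights over the gene universe.

    ``weights`` are positive and sum to 1 and are non-decreasing in cDNA
    length; ``fitted_prob`` is the raw fitted mutation probability before
    flooring/normalization. ``pi`` records the MutGene proportion of the
    sample the model was fit on (a diagnostic).
    """

    genes: np.ndarray  # sorted gene symbols
    weights: np.ndarray
    fitted_prob: np.ndarray
    provenance: str  # "sample_specific" | "universal"
    n_mutgenes_fit: int
    pi: float
    fallback: bool = False

    def __post_init__(self) -> None:
        if np.any(self.weights <= 0):
            raise ValueError("PWV weights must be strictly positive")
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("PWV weights must sum to 1")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.genes.tolist(), self.weights.tolist()))

    @property
    def index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes.tolist())}


@dataclass
class ResampleResult:
    """Per-gene frequency of inclusion in ``B`` weighted random gene sets."""

    genes: np.ndarray
    freq: np.ndarray
    B: int
    m: int

    def get(self, gene: str) -> float:
        idx = np.searchsorted(self.genes, gene)
        if idx < len(self.genes) and self.genes[idx] == gene:
            return float(self.freq[idx])
        return 0.0

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.genes.tolist(), self.freq.tolist()))


def _monotone_spline_design(x: np.ndarray, n_knots: int) -> np.ndarray | None:
    """Cubic B-spline design matrix with clamped knots at length quantiles.

    Returns None when the covariate is too degenerate to support a spline
    (fewer distinct values than knots).
    """
    qs = np.linspace(0.0, 1.0, n_knots)
    knots = np.unique(np.quantile(x, qs))
    if len(knots) < 4:
        return None
    t = np.concatenate([[knots[0]] * 3, knots, [knots[-1]] * 3])
    return BSpline.design_matrix(x, t, 3, extrapolate=True).toarray()


def fit_pwv(
    mutgenes: Iterable[str],
    lengths: Mapping[str, int],
    n_knots: int = 6,
    log_length: bool = False,
    provenance: str = "sample_specific",
    eps: float = EPS_WEIGHT,
) -> ProbabilityWeightVector:
    """Fit the monotone-spline binomial model and return the PWV.

    Monotonicity is enforced structurally: the spline's B-spline coefficients
    are parameterized as a free intercept plus non-negative increments, which
    makes the fitted curve non-decreasing in length for any parameter value;
    the binomial log-likelihood stays concave under this (linear)
    reparameterization. Degenerate covariates (e.g. all lengths equal) yield
    uniform weights; optimizer failure falls back to isotonic regression of
    the indicator on length (logged).
    """
    genes = np.array(sorted(lengths))
    if len(genes) == 0:
        raise ValueError("empty gene universe")
    mutset = set(mutgenes)
    missing = mutset - set(lengths)
    if missing:
        raise ValueError(f"{len(missing)} MutGenes absent from the length table, e.g. {sorted(missing)[:3]}")
    if not mutset:
        raise ValueError("need at least one MutGene to fit")
    y = np.array([g in mutset for g in genes], dtype=float)
    x = np.array([lengths[g] for g in genes], dtype=float)
    if log_length:
        x = np.log(x)
    pi = float(y.mean())

    def _finish(prob: np.ndarray, fallback: bool) -> ProbabilityWeightVector:
        w = np.maximum(prob, eps)
        return ProbabilityWeightVector(
            genes=genes,
            weights=w / w.sum(),
            fitted_prob=prob,
            provenance=provenance,
            n_mutgenes_fit=len(mutset & set(genes)),
            pi=pi,
            fallback=fallback,
        )

    B = _monotone_spline_design(x, n_knots)
    if B is None:
        # no usable covariate signal: constant fit at pi
        return _finish(np.full(len(genes), pi), fallback=False)

    K = B.shape[1]
    L = np.tril(np.ones((K, K)))  # c = L @ theta, theta[1:] >= 0

    def objective(theta: np.ndarray) -> tuple[float, np.ndarray]:
        c = L @ theta
        eta = B @ c
        # log(1 + e^eta) - y*eta, numerically stable
        nll = float(np.sum(np.logaddexp(0.0, eta) - y * eta))
        p = expit(eta)
        grad_c = B.T @ (p - y)
        grad = L.T @ grad_c
        # tiny ridge on increments for identifiability in flat regions
        nll += 1e-6 * float(theta[1:] @ theta[1:])
        grad[1:] += 2e-6 * theta[1:]
        return nll, grad

    theta0 = np.zeros(K)
    theta0[0] = np.log(pi / (1 - pi)) if 0 < pi < 1 else 0.0
    bounds = [(None, None)] + [(0.0, None)] * (K - 1)
    res = minimize(objective, theta0, jac=True, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 500})
    if res.success and np.all(np.isfinite(res.x)):
        prob = expit(B @ (L @ res.x))
        return _finish(prob, fallback=False)

    log.warning("monotone spline fit failed (%s); falling back to isotonic regression", res.message)
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    prob = iso.fit_transform(x, y)
    return _finish(np.asarray(prob, dtype=float), fallback=True)


def choose_model(
    profile: SampleProfile,
    cohort_pwv: ProbabilityWeightVector,
    lengths: Mapping[str, int],
    min_mutgenes: int = 50,
    n_knots: int = 6,
    log_length: bool = False,
) -> ProbabilityWeightVector:
    """Sample-specific PWV when the sample has enough MutGenes, else universal.

    Small mutation profiles do not support a stable per-sample fit; below
    ``min_mutgenes`` (default 50) the cohort-wide ("universal") PWV — fit on
    the union of all cohort MutGenes — is used instead.
    """
    in_universe = {g for g in profile.mutgenes if g in lengths}
    if min_mutgenes <= 0 or len(in_universe) >= min_mutgenes:
        return fit_pwv(in_universe, lengths, n_knots=n_knots, log_length=log_length,
                       provenance="sample_specific")
    return cohort_pwv


def resample_null(
    pwv: ProbabilityWeightVector,
    m: int,
    B: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> ResampleResult:
    """Frequency of each gene across ``B`` weighted draws of ``m`` genes.

    Each replicate draws ``m`` distinct genes without replacement with
    selection probability proportional to the PWV (sequential renormalized
    draws, realized by exponential-race keys, which gives the identical
    distribution). ``freq(g)`` is the fraction of replicates containing g.
    """
    n = len(pwv.genes)
    if not 1 <= m <= n:
        raise ValueError(f"m must be in [1, {n}], got {m}")
    if B < 1:
        raise ValueError(f"B must be >= 1, got {B}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    keys = rng.standard_exponential((B, n)) / pwv.weights
    if m < n:
        chosen = np.argpartition(keys, m - 1, axis=1)[:, :m]
    else:
        chosen = np.tile(np.arange(n), (B, 1))
    counts = np.bincount(chosen.ravel(), minlength=n)
    return ResampleResult(genes=pwv.genes, freq=counts / B, B=B, m=m)


def filter_mutgenes(
    profile: SampleProfile,
    rr: ResampleResult,
    retain: Optional[GeneSet] = None,
    freq_cutoff: float = 0.05,
) -> set[str]:
    """Drop MutGenes that weighted random sampling reproduces too often.

    A gene survives when its resampling frequency is below ``freq_cutoff``
    (default 5%) or it belongs to the retained whitelist (anchor genes are
    kept regardless of frequency).
    """
    keep: set[str] = set()
    for g in profile.mutgenes:
        if rr.get(g) < freq_cutoff or (retain is not None and g in retain):
            keep.add(g)
    return keep


def anchor_distance_filter(
    genes: Iterable[str],
    net: nx.Graph,
    anchors: GeneSet,
    max_dist: float = 2,
) -> set[str]:
    """Keep genes within ``max_dist`` network steps of the nearest anchor.

    Known cancer genes cluster tightly in the interactome, so candidates far
    from every anchor (shortest path > ``max_dist``, anchors themselves at
    distance 0) are removed. Genes absent from the network are removed first.
    Pass ``max_dist=math.inf`` to apply only the in-network restriction.
    """
    present_anchors = [a for a in anchors.members if a in net]
    if not present_anchors:
        raise ConfigurationError(f"no anchor from set {anchors.name!r} present in the network")
    in_net = {g for g in genes if g in net}
    if max_dist == float("inf"):
        return in_net
    # multi-source BFS up to max_dist
    dist = {a: 0 for a in present_anchors}
    frontier = list(present_anchors)
    d = 0
    while frontier and d < max_dist:
        d += 1
        nxt = []
        for u in frontier:
            for v in net[u]:
                if v not in dist:
                    dist[v] = d
                    nxt.append(v)
        frontier = nxt
    return {g for g in in_net if g in dist}
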