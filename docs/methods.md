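# Methods

This note records the models behind `mutnet`, the choices made where the
design was genuinely open, and what the synthetic benchmarks do and do not
demonstrate.

## Deleterious-mutation classification

A gene is a *MutGene* in a sample when it carries ≥ 1 deleterious mutation
there. Missense SNVs are deleterious when predicted damaging by either
annotator — SIFT < `sift_max` (default 0.05) OR PolyPhen2 ≥ `polyphen_min`
(default 0.5) — applying the OR over whichever scores are present.
Truncating classes (nonsense, nonstop, splice site, translation start),
non-silent DNP/TNP substitutions and all coding indels are deleterious
unconditionally; silent and unclassified variants never are. A missense
with no score at all is called benign by default: the alternative inflates
the MutGene sets whenever annotation is incomplete, and the
`missense_default_deleterious` flag inverts it for fully curated inputs.
Mutation identity is the coordinate pair (chrom, 1-based pos); alleles and
strand are ignored everywhere, including in recurrence counting. Rows
flagged in an optional boolean `is_known_snp` column are dropped at parse
time, since germline polymorphisms masquerade as recurrent somatic sites.

## The gene-length model and the resampling filter

Passenger mutations accumulate roughly in proportion to target size, so the
per-sample background is modelled as
`logit P(y_i = 1) = f(length_i)` with `f` monotone non-decreasing. `f` is a
cubic B-spline on six knots at equispaced length quantiles whose
coefficients are parameterized as a free intercept plus non-negative
increments; any such coefficient vector yields a non-decreasing spline, the
reparameterization is linear, and the binomial log-likelihood therefore
stays concave. The fit uses L-BFGS-B with an analytic gradient and a tiny
ridge (1e-6) on the increments for identifiability in flat regions. The
covariate enters raw by default with a `log_length` option; with monotone
splines the two differ only in knot placement. If the optimizer fails, the
model falls back to isotonic regression of the indicator on length
(logged); if the covariate is degenerate (fewer distinct lengths than
knots), weights are uniform. Fitted probabilities are floored at 1e-9 —
so no gene is unsampleable — and normalized into the probability weight
vector (PWV).

Samples with ≥ 50 MutGenes (after intersection with the length-table
universe) get a sample-specific fit; smaller samples reuse the universal
PWV fit on the union of all cohort MutGenes. The resampling null draws
`B = 1000` gene sets of the observed MutGene count, without replacement,
with PWV-proportional inclusion — implemented with exponential race keys
(`Exp(1)/w_i`, keep the `m` smallest), which is distributionally identical
to sequential renormalized draws but vectorizes. Genes reproduced in
≥ 5% of random sets are filtered; whitelist (anchor) genes are always
retained. The anchor-distance filter then keeps only genes within 2
unweighted network steps of the nearest anchor (anchors at distance 0),
reflecting the tight interactome clustering of known cancer genes; it runs
after the resampling filter, operating on the already-reduced set.

## Random walk and candidate interactors

The walk iterates `p ← (1 − r) W p + r p0` with `W` the column-normalized
adjacency over non-isolated nodes, `r = 0.5`, and uniform restart over the
seeds. Per-sample walks restart from one MutGene at a time (multi-seed
restart vectors are supported for generality). Convergence is declared when
the L1 difference between iterates falls below `tol = 1e-6`; with
contraction factor `1 − r` this takes ~20 iterations at the defaults, and
batching many seed columns through one sparse-dense product makes
cohort-scale walks cheap. Each seed's candidates are the `k = 10`
highest-probability non-seed genes; ties are broken lexicographically by
symbol (nodes are stored in lexicographic order, so a stable sort on
descending probability realizes this deterministically).

## Topology null

Null networks come from edge switching: `n_swaps_per_edge × |E|` attempts
(default 10 per edge, common practice for this scheme) at rewiring two
uniformly chosen edges, skipping any proposal that would create a
self-loop or duplicate. Each member of the 100-network ensemble has exactly
the original degree multiset (asserted). One shared ensemble serves all
samples — the randomization targets the reference network, not per-sample
graphs — and the null walks reuse the observed walks' parameters, seed
exclusion and tie-breaking, which is required for a valid empirical p.
`p_edge(s, g)` is the plain proportion of null networks in which `g`
re-enters `s`'s top-k (no +1 smoothing, so p < 0.05 is attainable as
≤ 4/100); pairs below 0.05 survive.

## Consensus construction

Per-sample significant pairs are pooled; an edge's occurrence counts each
sample once even when the edge was reached from both endpoints. The
occurrence cutoff is suggested by OLS of log10(edge count) on occurrence
over occupied occurrences: the drift point is the smallest occurrence above
the median occupied occurrence from which every occupied occurrence has a
positive residual. This is a deliberate formalization of "the tail rises
above the line"; exactly geometric counts produce no drift point, in which
case the maximum occurrence is returned with a `no_drift` flag and a manual
cutoff (`edge_cutoff`) is recommended — expert adjustment of this cutoff,
e.g. to recover known disease genes, is expected practice. Retained edges
must join two cohort-level MutGenes (mutated in the same or different
samples). The mutation-recurrence index `mr = n_all / n_unique` is computed
from cohort-pooled deleterious sites; a gene is flagged only when
`n_all > 20` AND `mr < 1.05` — heavy mutation with essentially no site
recurrence, the signature of a large passenger target. The conditional form
matters: a literal `mr < 1.05` filter would delete every
singleton-mutation gene (`mr = 1`), exactly the infrequently mutated
drivers the method exists to keep. Components are labelled by connected
components; a component with exactly one edge is an orphan.

Evaluation statistics are a one-sided Fisher exact test for gene-set
enrichment over a stated universe, and a uniform-resampling randomization
test for the overlap of two gene sets (p floored at 1/n_perm, reported as
"< 1/n_perm" when no permutation reaches the observed overlap). Cohort
strata (e.g. by exposure) are handled by subsetting the input mutation
table, not by special-cased logic; small strata typically need a manual
cutoff.

## Synthetic cohorts

The generator emulates: log-normal cDNA lengths (ln-mean 7.7, ln-sd 0.6,
median ≈ 2.2 kb); passenger inclusion logistic in ln-length
(slope 1.0, intercept −10.45, calibrated to ≈ 130 MutGenes per 2000-gene
sample so most samples clear the 50-MutGene bar for sample-specific fits);
a scale-free interactome (preferential attachment, 3 edges per node) with
a planted 20-gene module wired by a random spanning tree plus pairwise
edges at probability 0.6; module genes mutated in 30% of samples with
hotspot recurrence probability 0.7; an anchor list covering half the
module plus 40 random genes (standing in for a curated cancer-gene list);
and benign records (silent / low-PolyPhen2 missense) to exercise the
classification path. Driver deleteriousness is encoded through scores past
the thresholds, not by bypassing classification. Module genes mutate only
through the driver process, so their site recurrence reflects the hotspot
probability exactly. Truth tables are separate files the pipeline never
reads.

What the generator does not emulate: trinucleotide signatures, copy
number, expression, regional mutation-rate covariates (replication timing,
chromatin), or the curation biases of real interactomes. Passing the
planted-module benchmark therefore shows the machinery is correct and
calibrated under the model's own assumptions, not that it will rank real
drivers correctly in any given tumor type.

## Benchmark design and problem sizes

The planted-module recovery benchmark runs the full pipeline at the
generator defaults (2000 genes, 60 samples) and Fisher-tests the consensus
genes for module enrichment. The false-positive calibration draws 20
cohorts with no planted structure (no module edges, no elevated rates) and
tests each consensus against a freshly drawn random "phantom module" of
the same size; since the null ensemble and all per-seed walk tables depend
only on the reference network, they are computed once for all nodes and
shared across the 20 cohorts, with only the cohort mutation randomness
varying. An earlier design kept the module's dense edges in the null
network with zero mutation elevation; topology alone then recruited the
dense subgraph through reciprocal top-k membership in most cohorts. That
observation is worth keeping in mind for real data — a densely
interconnected gene family needs only scattered passenger hits to surface
— but it is a property of dense subgraphs, not a mutation signal, so the
calibration uses the structureless null.

## Numerical and degenerate-input conventions

* RWR requires non-empty seeds present in the network; isolated nodes are
  excluded before normalization; non-convergence raises with the last L1
  difference.
* `resample_null` validates `1 ≤ m ≤ N` and `B ≥ 1`; identical seeds give
  identical frequencies.
* All randomness flows from one master seed: per-sample resampling streams
  are `SeedSequence([master, crc32(sample_id)])`, so results are
  independent of sample order and scheduling; the null-ensemble seed is
  derived from the master seed; generator outputs are byte-identical under
  a fixed config and seed.
* `suggest_cutoff` needs ≥ 3 occupied occurrence values and otherwise
  raises with instructions to set a manual cutoff; the pipeline wrapper
  falls back to cutoff 1 with a warning so smoke-scale runs still complete.
* Empty length bins in the length–mutation diagnostic are reported as
  missing, not zero.

## Known limitations

* The length model uses cDNA length as the only covariate by design;
  cohorts with strong non-length covariates will leak passengers through.
* `p_edge` resolution is 1/100 at the default ensemble size; finer
  thresholds require a larger ensemble.
* The drift rule is a heuristic; on small cohorts the occurrence
  distribution is noisy and the automatic cutoff should be reviewed
  against the diagnostics table the pipeline writes.
* Candidate pairs are only (walk seed, significant interactor); edges
  between two interactors that were never seeds do not enter the pool.
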