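# Methods

This note records the models the package implements, the defaults and why
they were chosen, what the synthetic generator does and does not emulate,
and the numerical decisions a maintainer would want to know about.

## The classification model

The TGx-DDI biomarker treats a chemical exposure as a 64-dimensional
vector of per-gene log2 fold changes against its matched vehicle control
and asks whether that vector looks like the transcriptional DNA-damage
response (largely p53-driven) of the DDI reference chemicals.

**Nearest shrunken centroids (PA).**  Standard NSC with the class factor
`m_k = sqrt(1/n_k − 1/n)`, pooled within-class standard deviations
`s_j` and fudge `s0 = median(s_j)`.  The soft threshold Δ zeroes the
standardized differences of non-discriminating genes; Δ = 0 reproduces
plain standardized centroids and Δ ≥ max|d_kj| collapses both class
centroids onto the overall centroid, at which point the posteriors
degenerate to the priors (both limits are asserted in tests).  Posteriors
use the squared-distance discriminant with a `−2 ln π_k` prior term and a
max-shifted softmax for numerical stability.  Priors default to class
proportions; uniform priors are a parameter.  Δ defaults to
leave-one-chemical-out selection over a 0–6 grid (step 0.25), smallest Δ
among accuracy ties, which is fully deterministic; a fixed Δ can be
supplied for exact reproducibility.  The 0.90 posterior threshold is the
published assignment rule; what happens *below* 0.90 is not published, so
the package emits an explicit `indeterminate`, which the vote treats as
non-positive.  This is configurable.

**PCA projection.**  Components are fitted to the gene-centered training
matrix without variance scaling (the inputs are already log-ratios on one
scale; scaling would up-weight noisy genes).  Classification uses
component 1 only — the published rule is a single dividing line at zero —
with the sign convention that the DDI training mean is positive.  An
exactly zero score is indeterminate (a measure-zero boundary case).

**Branch classification (2DC).**  UPGMA (unweighted average linkage,
Euclidean) over the 28 training profiles plus *one* test profile at a
time; the tree is cut at the root into two clusters and the test profile
takes the majority training label of its cluster, with the branch purity
reported.  Clustering test profiles one at a time means test–test
similarity can never create or flip a call; joint dendrograms are for
display only.  If the root cut isolates the test profile (possible for
extreme outliers), the call is indeterminate with a warning.

**Integration.**  A tier is DDI if any of PA/PCA/2DC says DDI; a chemical
is DDI if any tier is.  The vote never treats indeterminate as positive.
All 27 combinations are covered by an exhaustive truth-table test.

## Expression preprocessing

Counts are normalized to reads-per-million only (no further
normalization), QC-screened by pairwise Pearson correlation of
log2(RPM + 0.5) with a 0.97 pass threshold that fails closed, and turned
into per-probe log2 ratios with delta-method Poisson variances
`(1/(n_t + 0.5) + 1/(n_c + 0.5)) / ln(2)²` on the raw counts.  The
"error-weighted average" that merges probes of one gene symbol is realized
as inverse-variance weighting (`w_i = 1/var_i`), which is the estimator's
standard form; the original weighting scheme is not published in detail,
so the weight function is pluggable.  A pseudo-count of 0.5 is used on
both RPM and raw counts because the pooled single-library design has no
replicates to rescue zeros.  Constant samples make correlations undefined;
such pairs are excluded from the QC minimum with a warning rather than
silently passing.

## MN / RS statistics

Wells are the sampling unit.  RS% is the mean-of-ratios convention: each
well's nuclei/bead ratio, averaged over replicates, relative to the mean
vehicle ratio.  The GEE for MN uses binomial variance `μ(1−μ)/n_cells`
with a log link; with one indicator per concentration the model is
saturated, so the fitted group rates equal pooled proportions
(total events / total cells) — the closed form the implementation checks
itself against, and the reason the choice of working correlation is
numerically immaterial here (independence is the default, recorded as
configurable).  The RS GEE is gaussian with identity link: group means.

Covariances: both the well-level sandwich (CR0 with an HC1-style
`N/(N−p)` factor) and the model-based covariance are computed.  With only
two wells per group the sandwich has ~2 residual degrees of freedom per
contrast, so normal-reference robust p-values are anti-conservative at
small α; the package therefore reports both, uses a t reference with the
residual degrees of freedom for the RS (identity-link) endpoint, and a
normal reference for the MN endpoint where the effective sample size is
the cell count.  Monte-Carlo calibration under the generator's truth: the
model-based MN test holds its level at α = 0.01, and the *decision rule*
(fold ≥ 2 AND p < 0.01) has a null positive-call rate indistinguishable
from zero with either covariance, because a twofold excess at a 0.6%
baseline over 40,000 cells is ~15 standard errors.  Power at a true
threefold induction exceeds 0.95.

Zero-event groups receive a Haldane-style 0.5-event continuity adjustment
(spread over the group's wells and flagged in the fit diagnostics) so the
log-link fit stays finite.  Significance defaults follow the assay
conventions: α = 0.01 for MN, α = 0.05 for RS; both two-sided Wald
(one-sided testing is a documented alternative, not the default).

Cytotoxic concentrations (RS < 40%) are excluded before any MN call.  The
low/mid/high selection takes the highest retained dose (capped at 10 mM
when no cytotoxicity is observed, if a cap is configured) and chooses the
pair below it closest to even thirds of the log-dose range, ties toward
lower doses, by exhaustive search over the at most C(5,2) candidate pairs.

## The synthetic study generator

The generator emulates the *structure* the statistics assume, not any
particular chemical's biology:

- 64 biomarker genes, of which 60% respond to DDI exposure (half up, half
  down by 1.0 log2 unit at the high tier — the two-block structure of the
  biomarker heatmap), plus 936 background genes; tier multipliers
  0.25/0.6/1.0 give the dose-response.
- A 28-chemical training set (14 DDI / 14 non-DDI by default; the true
  reference set's split is not published and this is explicitly a
  configurable default) with per-gene gaussian noise of 0.30 log2 units.
- One pooled sequencing library per condition (no replicates), library
  size 1e6, 1–3 probes per gene with Dirichlet shares over log-normal
  gene abundances, Poisson counts.  Treated expected counts are exactly
  `control rate × 2^(tier × effect)`; totals are not renormalized, so
  effect samples drift ~1% in library size by composition — zero-effect
  samples match the nominal library size to Poisson accuracy.
- Flow wells: duplicate wells, scored cells ~ round(N(20000, 667)) so the
  ±2000 envelope is a ~3σ band (the assay quotes a tolerance, not a
  distribution), MN events binomial at 0.6% baseline times a
  per-concentration fold curve, beads Poisson(5000), nuclei Poisson
  conditional on the drawn beads so the ratio is conditionally unbiased.
  RS follows a Hill curve in dose/top-dose (midpoint 0.7, slope 2.5 for
  chemicals flagged cytotoxic: top dose ~29% RS, mirroring the
  top-dose-only exclusions of the reference design; benign midpoint 3.0
  keeps RS > 90%).
- The default ten-chemical test panel carries the reference study's
  names, vehicles, dose series and cytotoxic flags; the aneugen
  (colchicine) gets an MN fold curve reaching 2.9 at the top dose with
  *zero* transcriptional effect — the discordance that motivates pairing
  the assays.

What it does **not** emulate: inter-donor or passage variability,
sequencing artifacts beyond Poisson counting error, probe-specific biases,
gene–gene correlation within the panel, extra-binomial MN dispersion, or
any real chemical's potency.  Passing the end-to-end tests therefore shows
the pipeline's logic and statistics are correct under the assumed data
model, not that the biomarker generalizes to real data — that evidence
comes from the published validation studies.  Chemical-specific magnitudes
(e.g. a particular fold induction) depend on unpublished raw event counts
and are not reproduced.

## Problem sizes and determinism

Default test-suite and acceptance problem sizes — 200 random training sets
for the oracle comparison, 1000 null / 500 alternative Monte-Carlo studies
for rule calibration, one full synthetic study end to end — were chosen so
the whole suite runs in well under a minute on a laptop core while keeping
Monte-Carlo error a small fraction of the asserted margins.  Every random
stream derives from a single seed via named `SeedSequence` children, so
identical parameters and seed give byte-identical artifacts (asserted down
to the written TSV bytes; readers use round-trip float parsing).

## Known limitations

- The sandwich covariance with duplicate wells is honest but noisy; if
  per-well overdispersion matters in real data, more replicate wells are
  the fix, not a different estimator.
- The NSC implementation supports K ≥ 2 classes, but the calling
  semantics (indeterminate band, positive-class conventions) are designed
  for the two-class DDI problem.
- `select_concentrations` assumes dose series are strictly increasing and
  positive; it operates on indices, so heterogeneous units (μM vs mM) are
  the caller's responsibility.
- The QC screen reports and gates; it does not attempt batch correction
  of failing runs.
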