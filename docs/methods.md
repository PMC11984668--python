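# Methods

`epiconcord` asks a single scientific question: when DNA-methylation
aging clocks are computed in several tissues collected from the same
person — buccal epithelium, saliva, dried blood spots (DBS), buffy
coat, peripheral blood mononuclear cells (PBMCs) — do the estimates
agree, absolutely and in rank order?  The package implements the full
analysis path from raw beta matrices to concordance tables, plus a
synthetic-cohort generator with known ground truth so that every stage
is verifiable without access to restricted human data.

## The synthetic cohort

The generator emulates a two-cohort within-person design: children
(default 36, ages ~9.4–13.9 y; buccal, saliva, DBS, buffy coat) and
adults (default 47, ages ~19.2–70.2 y; buccal, saliva, DBS, PBMC).
For each sample:

1. **Cell mixture.** Each tissue has K latent cell types (defaults:
   buccal 3, saliva 5, DBS/buffy 6, PBMC 5 — the oral K's match what
   reference-free decomposition of such tissues typically selects, the
   blood panels are the standard immune references).  A cell-type
   methylome matrix M (probes × K) is drawn once per tissue: ~30% of
   probes are "marker" probes with high (0.75–0.95) betas in a random
   subset of cell types and low (0.05–0.25) elsewhere; the rest share
   a common U-shaped baseline (0.02 + 0.96·Beta(0.45, 0.45)), matching
   the bimodal beta-value distributions of real arrays.  Sample
   weights w are Dirichlet
   with a per-tissue concentration (default 3.0; lower values give
   more extreme, more identifiable mixtures).  The noiseless mixture
   is `mix = M w`.
2. **Age effect.** A designated probe subset (default 200 of 2000) is
   cell-type-invariant and carries `beta_j = m_j + s_j * t(age)` with
   baselines m_j in [0.40, 0.55], slopes |s_j| in [0.05, 0.15] and t
   the log-linear age calibration (logarithmic below the knot
   `adult_age = 20`, linear above).  Because the age effect is linear
   on the *beta* scale and independent of the cell mixture, a linear
   clock can invert it exactly — this is the design choice that makes
   noiseless clock recovery an exact (≤1e−6 years) test rather than an
   approximate one.  Cell-composition differences therefore do not
   bias the toy clocks; they act on the non-age probes only.
3. **Batch and noise.** A plate is assigned per person (so both
   tissues of a person share it, as in real plating).  Per batch, a
   fixed shift vector (SD `batch_sd`, default 0.15) is added on the
   logit scale to a probe subset (default 20%) and to all control
   probes; i.i.d. Gaussian noise (SD `noise_sd`, default 0.05) is
   added on the logit scale; the result is inverse-logit transformed
   and clamped to [1e−6, 1−1e−6].  Logit-scale noise yields the
   heteroscedastic, range-respecting errors seen on arrays.  A
   `noise_scale="beta"` option adds the noise on the beta scale
   instead, which keeps the mixture mean structure exactly rank K —
   used by fixtures that probe model selection, where the logit
   curvature would otherwise contribute genuine above-rank structure.
4. **Array artifacts.** Probes are labeled type I/II (default 80%
   type II); an optional compression factor shrinks type II betas
   toward 0.5 (off by default, 0.8 in normalization experiments).
   Whole probes can be dropped per tissue (imputation targets), and QC
   failures are injected two ways: detection-p inflation over 10% of a
   sample's probes, or a bisulfite conversion rate drawn below 0.80.

All randomness flows from one `numpy.random.Generator`; identical
configs are bit-identical.  What the generator does **not** emulate:
Infinium chemistry (intensities, dye bias), genomic autocorrelation
between probes, age-varying cell composition, and real cell-type
methylome separations (the paper-scale separations are unknown; ours
are free parameters).  Passing tests therefore demonstrate algorithmic
correctness and recoverability under the stated model, not performance
on real arrays.

## QC

Samples are excluded iff detection p > 0.05 for *more than* 5% of
probes (strict) or bisulfite conversion < 80%.  Probes are excluded
iff bead count < 3 in *5% or more* samples (inclusive) or mean
detection p > 0.05 (strict).  Both passes evaluate fractions on the
original matrix, so sample-then-probe equals probe-then-sample.
Missing detection p-values count as failures and missing bead counts
as sub-threshold (conservative).

## BMIQ normalization

Per sample, three-state beta mixtures (U/H/M, ordered by mean) are fit
separately to type I and type II values by EM.  The M-step maximizes
the responsibility-weighted beta likelihood exactly via its sufficient
statistics (Σr·log x, Σr·log(1−x)) with analytic digamma gradients; a
candidate update is kept only if it does not decrease the component
likelihood, so the EM trace is monotone.  Initialization: splits at fixed
methylation levels 0.25/0.75 (empirical-quantile fallback when a
block is near-empty) with method-of-moments shapes — beta-value
distributions are bimodal, and quantile splits that straddle the
modes send EM to poor local optima; tolerance
1e−4 on the log-likelihood; at most 100 iterations; values clamped to
[1e−6, 1−1e−6] before fitting (the beta density is undefined at 0/1).

Type II probes are assigned to U/H/M by maximum posterior, then the
assignment is interval-ized (two cut points minimizing disagreement)
so the subsequent map is monotone.  U values map through
`F⁻¹_{U,I}(F_{U,II}(x))`, M values through the matching upper-tail
map, and H values are linearly dilated between the mapped U maximum
and mapped M minimum.  Mapped values leaving [0,1] are clamped and
counted.  Type I values pass through bitwise unchanged; samples are
normalized independently.

One guard: on some strongly compressed samples the mixture
likelihood's preferred solution concentrates most mass in a single
broad middle component, leaving spike-like U/M anchors that make the
linear H dilation distort the distribution.  When either fit assigns
the H state more than half the mass, the sample's type II values are
instead mapped through the full mixture CDFs
(`F⁻¹_I(F_II(x))`) — still monotone, and well behaved for any shape.

## Golden-standard imputation

Clock CpGs absent from a measured sample are filled from a probe ×
(tissue, age-group) table of arithmetic mean post-QC, post-BMIQ betas,
with strata {child: age < 18, adult: ≥ 18} and the fallback chain
stratum mean → tissue mean over strata → global mean.  Measured values
are never overwritten; imputation above a 20% cap (published clocks
needed at most ~18%) is an error, as is a probe absent from both the
measurement and the table.  PC clocks skip imputation: their scoring
substitutes the definition's center value for missing probes, which
is what makes them robust to probe dropout.

## Clock engine

Clocks are declarative files (JSON metadata + TSV coefficients) of
three kinds: linear (`intercept + Σ wᵢβᵢ`), PC (weights over principal
component scores of centered betas) and composite (two-stage:
covariate-bearing linear sub-scores feeding a combination layer, the
shape of GrimAge-style clocks).  Transforms: identity (years),
`horvath_age` (anti-transform `(A+1)e^s − 1` for s ≤ 0 else
`(A+1)s + A`, knot A = 20 by default and per-clock configurable), or
`rate` (unitless pace of aging).  Age acceleration is estimate minus
chronological age, in years, and is deliberately undefined for rate
clocks — requesting it raises.  No published coefficient tables are
bundled; the repository ships toy/synthetic definitions and any real
clock can be supplied as a plug-in file.  An optional reference-means
normalization hook exists for pace-style clocks (off by default).

## Cell deconvolution

**Reference-based** (blood tissues): per sample, minimize ‖y − Rw‖²
subject to w ≥ 0, Σw = 1, solved exactly by an active-set KKT method
(the equality constraint reflects that the panels describe complete
compositions).  Errors on rank-deficient panels or when more than a
configurable fraction of panel probes is missing.

**Reference-free** (oral tissues): on the top-n most-variable probes
(ties broken by probe id), factorize Y ≈ MΩᵀ with M ∈ [0,1] and Ω rows
on the simplex by alternating projected-gradient least squares (step
1/L with L the exact Lipschitz constant of each half-problem, 5 inner
steps per half), initialized from Ward hierarchical clustering of the
samples — deterministic, and the objective trace is monotone
non-increasing.  Convergence: objective decrease below `tol` × initial
objective (default 1e−6); K = 1 has the closed form M = row means.

**Choosing K**: for each candidate K the model is fit to the full
data; then for each bootstrap draw of samples (columns, with
replacement) the model is refit from a fresh cluster initialization
on the bootstrap columns and the Gaussian deviance (−2 log-likelihood
with per-probe residual variances from the bootstrap fit, floored at
1e−6) of the **out-of-bag** columns is evaluated, normalized per
column.  Overfitted K both deflates the variance estimates and chases
bootstrap-specific structure, which the out-of-bag term punishes, so
the profile has an interior minimum at the generative K; underfitted K
is punished by raw misfit.  The chosen K minimizes the per-tail
trimmed mean over bootstraps (default trim 0.25 per tail; trim 0 is
the plain mean).  Defaults follow the analysis being emulated — K in
1..15, 1000 bootstraps — while tests and the acceptance script run 50
bootstraps on 83-sample fixtures, which the selection experiments
showed is sufficient at desk scale.  An in-sample deviance profile is
reported alongside; it is monotone non-increasing in K by
construction and is not used for selection.

## Concordance statistics

* **Paired differences** (per clock and tissue pair): within-person
  differences d = estimate(a) − estimate(b), reported as mean ± SE
  with t = mean/SE on n−1 df and two-sided p; stars at 0.05/0.01/0.001.
  Zero-variance differences are flagged degenerate.  No
  multiple-testing correction is applied by default (raw p with
  stars); a Benjamini–Hochberg adjustment can be applied downstream.
* **Correlations**: person-paired Pearson r of acceleration values
  (rate clocks correlate the pace itself), pairwise-complete, cells
  with fewer than 3 pairs left missing, p from the t approximation.
* **Batch surrogate**: principal components of the probe-centered
  control-probe matrix, signs fixed (largest-|loading| positive).
  Default number of PCs: the smaller of 10 and the count explaining
  90% of control-probe variance.
* **Partial correlations**: each tissue's values are residualized by
  OLS on that sample's *own* cell-type proportions (last category
  dropped as reference) plus its control-probe PC scores; collinear
  covariate columns are dropped smallest-variance first; the residual
  correlation's p uses df = n − 2 − (number of covariates).  Cells
  whose residual variance collapses are flagged degenerate.  The
  own-sample covariate pairing is a documented design choice: tissue
  compositions are different objects per tissue, so there is no
  common covariate vector to share.
* **ICC**: all six classical variants (one-way random, two-way
  random, two-way mixed; single and average raters) from the two-way
  ANOVA mean squares on listwise-complete person × tissue tables,
  with the standard F-based confidence bounds.  All six are reported
  because published analyses rarely say which variant they print;
  downstream comparisons default to two-way random, single rater.
* **Descriptives**: per-cohort and pooled n, age mean/SD/range, sex
  and tissue counts with percentages (denominator = column persons,
  one decimal).  `pooled_mean_sd` combines stratum summaries by the
  exact ANOVA identity, which is how printed stratum statistics are
  checked against a printed pooled line.

## Pipeline and determinism

`run_pipeline` executes QC → BMIQ → deconvolution → golden standard →
imputation → clocks → acceleration → concordance, from either file
inputs or an embedded simulate-block (exactly one must be present),
writing tidy TSVs plus a JSON run manifest that records the seed,
thresholds and package version — but no timestamps, so identical
configs produce byte-identical output trees.  Any stage failure aborts
with the stage name in a machine-readable record.  The `epiconcord`
CLI exposes the stage prefixes (`qc`, `normalize`, `deconvolve`,
`clocks`, `concord`/`run`) plus `simulate`.

## Problem sizes used in tests and the acceptance script

Chosen as desk-scale versions of the emulated analysis: clock recovery
at 500 age probes of 2000 (28 samples); BMIQ at 50 samples × 20,000
probes; reference-based deconvolution at K=6, 50 samples, logit noise
0.02; reference-free K selection on 83-sample, 3000-probe fixtures
(800 variable probes, 50 bootstraps, K ranges 1–6 and 1–8, Dirichlet
concentration 0.5, beta-scale noise sd 0.02 so the mixture mean
structure is exactly rank K — the well-separated setting the
selection property is stated for; under logit-scale noise the
inverse-logit curvature adds genuine low-amplitude structure beyond
rank K and the deviance profile flattens); statistical null
simulations at 500 replicates of
n=50; the confounder experiment at 48 persons × 2 tissues with 4
plates and a narrow age band (34–36 y) so the plate effect is the only
shared person-level factor.  The narrow band matters: with a wide age
range the logit-scale plate shift interacts with the age-dependent
baseline (a real second-order effect of the generative model), and
that interaction is a person-level confounder that control-probe PCs
cannot represent.

## Known limitations

* The beta-mixture EM can place two components on one empirical mode
  for atypical distributions; the interval-ized state assignment keeps
  the map monotone regardless.
* The reference-free factorization is a local optimizer; the clustered
  initialization makes it deterministic but not globally optimal.
* K selection degrades when mixtures are near-uniform (high Dirichlet
  concentration) or when components are weakly separated; the
  in-sample deviance is then flat beyond the true K and the bootstrap
  argmin can jitter upward.
* ICC confidence bounds use the classical F approximations; for very
  small tables (n = 2) some bounds are undefined (reported as NaN).
* Composite clocks are structural stand-ins; no published surrogate
  coefficients are included.
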