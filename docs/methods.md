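# Methods

## Mixture model for significant p values

Reported p values below a significance threshold α (default 0.05) are
treated as positive results. Conditional on significance, false
discoveries are uniform on (0, α) and true discoveries follow a
Beta(a, b) distribution truncated to (0, α):

    f(p | a, b, π₀) = π₀ · U(0, α) + (1 − π₀) · tBeta(a, b),
    a > 0, b > 0,

with π₀ the empirical false discovery rate. The assumption doing the
work is that false-positive p values are uniform just below the
threshold while genuine effects concentrate near zero; the Beta shapes
absorb the shape of the true-discovery distribution.

Reports enter the likelihood according to how they were printed:

* **exact** (comparator `=`, three or more decimals, or scientific
  notation): point density;
* **rounded** (`=` with ≤ 2 decimals): probability of the half-unit
  rounding interval (v − ½·10⁻ᵈ, v + ½·10⁻ᵈ) intersected with (0, α];
* **truncated** (`<` or `≤`): probability of (0, t) for the reported
  threshold t.

A rounded `p = 0.05` is retained with its interval truncated at α,
consistent with the interval-integration logic; an exact `p = 0.05`
is not a positive result and is dropped. Records whose interval is
empty after intersection are excluded and counted.

## EM estimation

The E step computes each report's posterior probability of the uniform
component from the two components' densities or interval probabilities;
the M step sets π₀ to the weighted mean posterior and updates (a, b) by
bounded derivative-free maximisation (Nelder–Mead, box
a, b ∈ [10⁻³, 10³], optimised on the log scale) of the
posterior-weighted truncated-Beta interval log-likelihood. The
point-report part of that objective depends on the data only through
Σw·log p and Σw·log(1−p), so M-step evaluations are O(#unique
intervals); identical reports are aggregated with multiplicities.

Two numerical choices matter:

* **Ridge acceleration.** The likelihood has a strong π₀–b ridge
  (correlation ≈ 0.97 near typical fits), along which plain EM steps
  become tiny: runs routinely exceeded 2000 iterations without meeting
  the tolerance. Every 20 iterations the fitter therefore attempts a
  direct Nelder–Mead ascent over (logit π₀, log a, log b), accepted
  only when it increases the observed-data log-likelihood. This is a
  monotone generalized-EM move with the same fixed points; the
  log-likelihood trace is non-decreasing on every run (asserted in
  tests at tolerance 1e−8), and final log-likelihoods match or exceed
  an independent grid-search oracle.
* **Convergence and degeneracy.** Convergence is an absolute
  log-likelihood change < 1e−6 (max 2000 iterations); non-convergence
  is a first-class flagged outcome. π₀ is kept inside
  [10⁻⁶, 1 − 10⁻⁶] during iteration. Data in which every report spans
  all of (0, α) (e.g. only `p < 0.05` at α = 0.05) make the likelihood
  flat in all parameters and are flagged non-converged immediately.
  Fits need at least `min_count` reports (default 10). Initialisation
  is π₀ = 0.5, a = 1, b = 20, with optional multistart over
  a ∈ {0.5, 1, 2} × b ∈ {5, 20, 50}.

Journals with any non-converged (or under-sized) year are excluded from
downstream modelling and listed in a removal report.

### What the estimator can and cannot deliver

The π₀–b ridge is not a numerical nuisance but a genuine identifiability
limit: the Fisher information at (a, b) = (0.7, 30), α = 0.05 gives an
asymptotic sd of the π₀ maximum-likelihood estimate of ≈ 0.20 at
n = 2000 significant p values, nearly independent of π₀ in
[0.1, 0.5]. Individual journal-year estimates therefore scatter widely
(including exact-boundary collapses to π̂₀ ≈ 0, which grid-search
verification shows to be global maxima), while the estimator remains
close to median- and mean-unbiased: across 50 seeded journal-years the
pooled mean bias is ≈ −0.02 and the 60-seed median at π₀ = 0.2 is
0.247. Rank recovery of journals by π̂₀ requires the per-cell count to
push estimator noise below the cross-journal spread (Spearman ρ ≈ 0.74
at n = 20 000 per cell for a 0.1–0.4 spread, but ≈ 0 at n ≤ 2000).
Averaging over many journal-years — which is exactly what the
mixed-model layer does — is where the signal lives.

A related negative finding: treating rounded reports naively as exact
point values did *not* measurably degrade π₀ recovery relative to the
interval likelihood at 50% (or even 100%) rounding to two decimals;
the ridge noise dominates both treatments. The interval likelihood is
retained as the correct model, but no test asserts a collapse that the
data do not show.

## Scraper

Abstracts are read from MEDLINE flat files (journal from TA, year from
DP, text from AB; entries without an abstract are skipped and counted).
Text is standardised before matching: unicode comparators (≤ variants),
minus/dash and multiplication signs, exotic spaces, middle-dot decimal
points, scientific-notation variants (`1.2 × 10−4`, `1.2E-4`, bare
`10-4` after a comparator) and comma decimals in p-value context are
mapped to canonical ASCII forms, and whitespace collapsed; the mapping
is idempotent. The non-case-sensitive phrases `p = `, `p < ` and
`p ≤ ` (with optional `value`, optional spacing, `p`-prefix guarded
against e.g. `snp =`) then yield candidates, which are cleaned of
trailing punctuation and parsed. Values outside (0, 1) — including a
literal `p = 0` — are dropped with a logged reason; duplicates within
an abstract are retained. Classification into exact/rounded/truncated
is a pure function of (comparator, decimal places); scientific notation
is classed exact regardless of mantissa digits, since a mantissa is not
a rounding of the probability scale to ≤ 2 decimals.

## Journal panel model

The modelling frame has one row per journal-year: response π̂₀, fixed
covariates centred year (year − 2011), Open Access indicator,
natural-log impact factor (matched per journal-year where per-year
values exist) and oncology indicator, grouped by journal. Four
sensitivity datasets are supported: all journals; journals with stable
OA status across the window; journals with no year's estimate below a
zero tolerance (default 1e−4); and the intersection.

Models are fit by REML with a random intercept per journal
(statsmodels `MixedLM`). Inference on fixed effects uses the
large-sample normal approximation; the degrees-of-freedom method is
recorded in the result metadata, and degenerate zero-variance frames
fall back to ordinary least squares (random-intercept variance reported
as 0, residual-t inference). Interaction screening starts from the
three-way subject × OA × log-JIF term plus its nested two-ways (only
OA × log-JIF in stratified models); a term is removable only when no
retained higher-order term contains it, terms with p > 0.05 are removed
one at a time (largest p first), main effects are never removed, and
every intermediate fit is logged. Covariates rendered constant or
collinear by stratification or small panels are pruned before fitting
and noted in the log.

Derived quantities:

* twofold impact-factor effect −β_logJIF · ln 2 (the FDR change when
  JIF halves; positive for negative slopes);
* adjusted group means — predicted response per level of a 0/1 group
  term with other fixed covariates at their sample means and the random
  intercept at zero, so the difference of the two means equals the
  group coefficient exactly (identity asserted at 1e−10);
* percent excess of one adjusted mean over another;
* cluster-bootstrap 95% percentile bands for predictions over a
  log-JIF grid, resampling whole journals (not rows) to respect the
  random-intercept structure; failed refits are logged and skipped.

## Synthetic data generator

The generator defines the study conditions end to end.

* **Panel.** 57 oncology + 37 general-medicine journals over
  2011–2015, ≈ 24% Open Access, impact factors log-normal
  (meanlog 1.0, sdlog 0.7 — right-skewed, median ≈ 2.7, matching
  medical-journal JIF distributions). True π₀ follows the *linear*
  model intercept 0.23 + (−0.002)·year + 0.015·OA + (−0.029)·log JIF +
  0.071·oncology + journal intercept (sd 0.06) + noise (sd 0.04),
  clamped to [0.01, 0.99] with the clamp rate reported — linear with
  clamping, not logistic, to match the linear analysis model. The
  fixed-effect sizes are the published panel-scale values; the variance
  components are chosen to give fixed-effect standard errors of the
  order seen in the published tables (≈ 0.01 for the subject effect).
  An optional switch probability creates "Open Access since year t"
  journals for filter tests.
* **Mixture.** Per journal-year, significant p values are drawn from
  the mixture at that cell's true π₀ with true-discovery shapes
  (a, b) = (0.7, 30) (mean ≈ 0.02 before truncation); uniform draws are
  labelled, so component membership is known ground truth.
* **Reporting.** Each value is reported exactly (3–4 decimals,
  scientific notation below 5·10⁻⁴) with probability 0.3, rounded to
  1–2 decimals with probability 0.4, or truncated to the smallest
  ladder threshold {0.0001, 0.001, 0.01, 0.05} above it with
  probability 0.3. Rounding a significant p value to 1 decimal always
  prints 0.0, so rounding that would print 0 (or ≥ 1) falls back to
  truncation — every emitted report parses back to a value in (0, 1).
  Rendered spans vary case, spacing, leading zeros and notation and are
  embedded in template sentences; on exact-only corpora the scraper
  recovers the embedded (value, comparator) multiset bit-exactly.
* **Determinism.** One master seed derives an independent substream per
  journal-year, so corpora are byte-identical under regeneration.

What the generator does not emulate: realistic prose beyond the
p-value-bearing spans, abstract-level clustering of p values (values
are pooled per journal-year, the estimator's unit of analysis),
selective-reporting or p-hacking distortions of the p-value
distribution, and correlation between impact factor and reporting
style. Passing tests therefore demonstrate correctness of the
machinery under the stated model, not robustness to those real-world
distortions.

## Problem sizes used in the test suite

Unit and acceptance tests run at deliberately chosen scales: mixture
recovery uses 50 journal-years of n = 2000 (plus a 60-seed median
check), oracle comparisons 200 records × 20 seeds against a 300-point
(π₀, a, b) grid, mixed-model recovery 50 panels of 94 journals × 5
years with the response taken as the generator's true rate, and the
pipeline demo 9–18 journals with 80–120 p values per cell. The
end-to-end pipeline is deterministic under a fixed seed (byte-identical
CSVs), which the suite asserts by running it twice.

## Known limitations

* Per-journal-year π̂₀ is weakly identified (see above); analyses
  should treat single-cell estimates as noisy and rely on the panel
  layer.
* Mixed-model p-values and CIs use the normal approximation rather
  than a finite-sample degrees-of-freedom correction; with ≈ 90 groups
  the difference is small (observed CI coverage 0.88–0.99 across
  recovery simulations).
* The scraper reads abstracts only and does not detect effect
  directions, one-sided tests, or p values reported outside the
  targeted phrase forms.
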