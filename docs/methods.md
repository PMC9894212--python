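# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the known limitations of `cytoclock`.

## The cohort model the generator emulates

The simulator produces a longitudinal observational cohort of healthy
aging adults. Baseline ages are truncated-normal (mean 69 y, sd 9 y) on
[47, 102]; each subject contributes 1 + Poisson(2) visits (capped at 13)
separated by 1 + Exponential(0.3) years, so consecutive visits are at
least a year apart. Sex is coded female = 1, male = 0 (the field has no
universal convention; this one is fixed here and used consistently), with
a female fraction of 308/554.

**Cytokine panel.** Marker j at visit i is generated on the natural-log
pg/mL scale as

    y_ij = mu_j + gamma_j * (age_i - 69) + s_j * sex_i + b_batch(i)
           + phi_j * latent_i + eps_ij

* `gamma_j` — age slopes; nine "true" markers (TNF-α, IL-6, MCP-1, IP-10,
  eotaxin, VEGF, VEGF-D, PLGF, Vcam-1) carry slopes of 0.012–0.016
  log-units/yr, giving per-marker age correlations of ≈0.30–0.45,
  realistic for inflammaging markers. The slopes are deliberately all in
  a detectable band: the generator's purpose is recovery testing, so
  every configured true marker must carry enough signal to be
  recoverable at cohort scale — a slope below the selection floor would
  make "true support" vacuous.
* `latent_i` — a per-visit standard-normal *latent inflammation score*,
  the shared, noise-free component of the true markers' deviations
  (loading phi = 0.1 log-units on each true marker). It is what couples
  the panel to the brain volumes beyond calendar age, and it makes the
  markers mutually correlated — the property that chained-equation
  imputation exploits.
* `eps_ij` — idiosyncratic noise, sd 0.33 for every marker, so a true
  marker's total non-age dispersion (shared + idiosyncratic) is ≈ 0.34.
* `b` — per-(batch, marker) offsets, N(0, 0.2), four batches assigned at
  random per visit.
* Missingness: 11 markers at ≈3 %, 13 at ≈45 % (the two bands of a real
  multiplex assay), injected missing-at-random with a mild age tilt
  (probability ∝ 1 + 0.3·tanh((age−69)/15)), i.e. dependent only on
  observed covariates, never on the hidden value. Duplicate wells are
  emulated by multiplicative log-normal noise (sd 0.08), so ≈1 % of
  entries legitimately fail the CV ≤ 20 filter.

**Brain volumes.** Network fraction k of TIV is

    f_ik = base_k + alpha_k * (age_i - 69) + s_k * sex_i + c_k * latent_i
           + shared_visit_i + shared_subject + noise

with all alpha_k negative (somatomotor steepest, −3.0e−4/yr), latent
loadings c_k concentrated on the default-mode, limbic and
dorsal-attention networks (−1.0e−3 to −1.5e−3 per latent unit), and two
common factors (visit-level sd 0.003, subject-level sd 0.002) that drive
the high pairwise correlations (mean ≈ 0.85–0.9) observed among real
network volumes. GMV is the sum of the seven networks plus a non-network
gray fraction (0.05). TIV is constant within subject,
N(1500 − 160·female, 100) mL. The generative *physiological age*
age + 8·latent (8 years per latent unit) is stored in the truth record;
it is the idealized quantity a perfect clock would recover.

**What the generator does not emulate**: limit-of-detection censoring,
plate-level drift, non-Gaussian marker distributions, missing-not-at-
random mechanisms, visit attrition correlated with health, or spatial
structure within networks. Passing tests therefore demonstrate the
statistical machinery is correct under the declared data-generating
process, not that the pipeline is robust to every pathology of real
assay data.

## Preprocessing

* **CV filter**: CV = 100 · sd / mean of the replicate pair, with the
  two-replicate sample sd (divisor n−1, i.e. |r1−r2|/√2), computed on
  the raw concentration scale (assays report concentrations; the choice
  of scale is stated because it is not forced). CV exactly at the
  threshold is retained. Entries with nonpositive replicate means are
  set missing and logged.
* **Batch correction**: per marker, observed values are regressed on
  [intercept | age, sex | sum-to-zero batch indicators] and only the
  fitted batch component is subtracted. Sum-to-zero coding makes the
  correction mean-neutral and leaves covariate-attributable variation
  untouched; the operation is exactly idempotent on a fixed observed
  set. A batch level entirely unobserved for a marker contributes a zero
  correction (logged).
* **Balancing weights**: ages are binned at 5-year width (configurable)
  spanning [min, max]; w_i = 1 / (visits in the bin of age_i). Weights
  are normalized to mean 1 before any fit so the penalty scale is
  comparable across cohorts.

## Imputation

Chained equations with weighted predictive mean matching. Defaults:
M = 500 ensemble size in the emulated design (desk-scale runs use
M = 50), 5 sweeps per chain, k = 5 donors — the conventional
chained-equation choices. The balancing weights enter as observation
weights in every conditional regression. The coefficient perturbation is
a normal draw with the estimated weighted-least-squares covariance;
donor ties are broken uniformly at random from the seeded stream. A
singular conditional system falls back to a tiny ridge penalty (1e−8,
logged) rather than aborting the chain. Predictors are all other
markers plus sex; age is deliberately *not* a predictor (the clock must
not be fed its own outcome through the imputation), which attenuates
the age signal of heavily missing markers — a real property of this
design, visible in their lower selection frequencies.

## The clock

* **Solver**: cyclic coordinate descent with soft-thresholding on the
  Gram form of the weighted problem; the intercept is profiled out
  exactly by weighted centering. Convergence when the largest
  coefficient change in a sweep is below 1e−7 (1e−10 in oracle
  comparisons); hard failure after 1e5 sweeps. The solution satisfies
  the KKT conditions to the same tolerance and matches an independent
  convex solver (split-variable L-BFGS-B) to 1e−6 in objective.
* **Penalty grid**: 100 log-spaced values from lambda_max (the smallest
  penalty with an all-zero solution, computed in closed form) down to
  1e−3 · lambda_max, warm-started.
* **Cross-validation**: K = 10 subject-grouped folds; per-fold weighted
  MSE, SE = sd across folds / √K. Default rule "1se" (largest penalty
  within one SE of the minimum); "min" available.
* **Pooling**: median of the M per-visit predictions by default; the
  mean is available because both statistics have precedent and the
  choice is not decisive for any conclusion. Selection frequency is the
  fraction of models with a nonzero coefficient. Sex is not a predictor
  of the LASSO by default (configurable) — the clock is defined on the
  protein panel.
* **Propagation**: a visit lacking a prediction borrows from the same
  subject's nearest measured visit within ±3 years, *shifted by the
  elapsed time* (a 2020 value carried to 2019 becomes value − 1); ties
  are broken toward the earlier source. Visits with no donor stay
  unassigned.

## Mixed models

The ladder fits y = Xβ + Zu + ε with a subject random intercept by
**maximum likelihood** (not REML): AIC/BIC and likelihood-ratio tests
across fixed-effect structures are only valid under ML, and the four
models differ exactly in their fixed effects. Given the variance ratio
θ = σ_u²/σ², β and σ² have closed-form profiled estimates; the
per-subject block structure of (I + θZZ′)⁻¹ makes each likelihood
evaluation linear in the number of observations. θ is located by a
coarse log-spaced grid (0 and 1e−6…1e6) followed by bounded scalar
minimization (golden-section/parabolic) to 1e−9. k counts fixed
coefficients plus both variance parameters. The profiled likelihood
matches a brute-force full-covariance multivariate-normal evaluation to
1e−8 and statsmodels' MixedLM (ML) to 1e−5. Exactly duplicated
within-subject responses make the likelihood unbounded (σ² → 0); the
optimizer then reports the boundary fit, which is the correct degenerate
answer. Wald z-tests provide the per-coefficient significance stars.

## Canonical correlation analysis

Weights come from the SVD of Rxx^{−1/2} Rxy Ryy^{−1/2}; inverse square
roots use a symmetric eigendecomposition with an eigenvalue floor of
1e−10 — sets nearly collinear above that floor are rejected with the
offending set named. Variates are rescaled to unit sample variance
(ddof 1 throughout), and each function's sign is fixed so its
largest-magnitude X-side loading is positive, making weights and
loadings platform-reproducible. The n entering the test statistics is
the number of complete rows in the fit. Bartlett:
χ²_k = −(n − 1 − (p+q+1)/2) · ln Λ_k with Λ_k = Π_{i≥k}(1 − ρ_i²) on
(p−k+1)(q−k+1) df. Rao: the standard F approximation, with t set to 1
when p_k² + q_k² − 5 ≤ 0 and a hard error when the denominator df is
nonpositive. Redundancy: Rd(Y|X)_k = mean_j loading(y_j, V_k)² · ρ_k²,
totals summed over dimensions. Plain (unregularized) CCA is
implemented; the sets here (3 and 7 variables, n in the hundreds) do not
need shrinkage.

## Pipeline and reproducibility

One master seed spawns fixed, named substreams per stage (simulate,
duplicates, missingness, impute, clock), so changing M does not perturb
the simulated cohort. Every artifact is plain text (TSV with `NA`
tokens, JSON with sorted keys and 10-decimal rounding); a manifest
records SHA-256 hashes; identical config + seed reproduce byte-identical
summaries. Stage failures abort with the stage name after persisting
partial artifacts.

## Problem sizes

The recovery experiments run at 300 subjects (~900 visits) with M = 50
imputations; ladder power/specificity at 500 subjects over 20 seeds;
oracle comparisons on toys of n ≤ 60. These sizes make the full suite
and the acceptance script complete in minutes on one core while keeping
every statistical conclusion at realistic effect sizes.

## Known limitations

* **Balancing weights at small cohorts.** The 1/bin-count weights give
  the one or two visits in the oldest age bins normalized weights of
  ~40, collapsing the effective sample size (Kish n_eff ≈ 110 at 900
  visits). At that effective n, a null marker's whole-cohort chance
  correlation can exceed the cross-validated penalty's entry threshold;
  because it lives in the *observed* data it persists across every
  imputation, so occasional null markers reach high selection
  frequencies, and perfect true/null separation is a cohort-level
  coin-flip rather than a guarantee. R's `cv.glmnet` (lambda.1se)
  reproduces the same behavior on identical data. Larger cohorts,
  coarser bins, or weight capping would mitigate this; the last two are
  deliberate departures from the 1/bin definition and are not applied.
* The LASSO's selection is representative, not exhaustive, under strong
  mutual correlation: raising the shared-factor loading merges true
  markers into interchangeable groups of which only representatives are
  selected.
* ML variance components are mildly biased downward relative to REML;
  this is the price of valid fixed-effect model comparison.
* No MNAR mechanisms, no limit-of-detection model, no random slopes or
  crossed random effects, no permutation-based CCA significance.
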