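# Methods

## The model

`methodcompare` addresses the agreement problem for two measurement
methods evaluated without a gold standard, when each subject is
measured repeatedly by both methods and the number of replicates may
differ across subjects and across methods within a subject.  The
motivating setting is image-guided radiotherapy positional
verification, where two imaging systems each suggest a couch shift (in
cm, per axis) at every treatment session, but nothing in the machinery
is specific to that application.

Let y_it = (y_it1, y_it2)′ be the paired measurements of subject i at
session t, i = 1..N, t = 1..p_i.  The model is a doubly-multivariate
linear mixed effects model:

    y_it = μ + b_i + e_it,
    b_i  ~ N₂(0, D)       (method-level subject random effects),
    e_it ~ N₂(0, Σ)       (session-level errors, independent across sessions),

with μ = (μ₁, μ₂)′ the method means, D the 2×2 **between-subject** and
Σ the 2×2 **within-subject** covariance of the two methods.  Stacking
a subject's observed cells session-major (method 1 before method 2
within a session) gives the marginal distribution

    y_i ~ N(X_i μ, Ω_i),    Ω_i = Z_i D Z_i′ + I_{p_i} ⊗ Σ,

restricted to observed cells: 2×2 session-diagonal blocks D + Σ,
session-off-diagonal blocks D.  Across-session correlation is carried
entirely by the method-level random effects; residuals are independent
across sessions.  (An equivalent formulation writes the residual
covariance as an equicorrelated-by-session Kronecker structure; the
decomposition here is the one actually identified by the likelihood
and matches what standard mixed-model software fits with a
by-session residual grouping.)  The per-method **overall** variance is
the sum of the between- and within-subject variances, diag(D + Σ),
and the overall between-method correlation is

    r = (d₁₂ + σ₁₂) / √((d₁₁ + σ₁₁)(d₂₂ + σ₂₂)).

A session recorded for only one method is a missing cell; the
likelihood simply drops the corresponding row/column of Ω_i, which is
valid under missing-completely-at-random missingness.

## Covariance structures and the four hypothesis tests

Each 2×2 block may be **unstructured** (UN — two variances and a
covariance, 3 parameters) or **compound-symmetric** (CS — one common
variance and a covariance, 2 parameters).  CS on a block states that
the two methods share that block's variance, so nested structure pairs
encode the agreement hypotheses.  All fits use maximum likelihood (not
REML), which makes deviance differences between nested structures
valid likelihood-ratio statistics:

| question | full model | null (constrained) | df |
|---|---|---|---|
| equal between-subject variances? | (UN, UN) | (CS, UN) | 6 − 5 = 1 |
| equal within-subject variances (repeatability)? | (UN, UN) | (UN, CS) | 6 − 5 = 1 |
| equal overall variabilities? | (UN, UN) | (CS, CS) | 6 − 4 = 2 |

The statistic is the difference of maximized −2 log-likelihoods,
referred to a chi-square with df equal to the covariance-parameter
count difference.  We follow standard usage and call the constrained
model the null.  The equality constraints are interior points of the
parameter space (a CS variance stays positive), so no
boundary-corrected mixture null is required.  `null_model_lrt_df`
(parameters − 1) is exposed to mirror the null-model LRT df line
printed by common mixed-model software.

**Bias** is the fixed-effect contrast μ₁ − μ₂ (reference method minus
new method — our convention, stated in all output), tested with a
t statistic using a Satterthwaite approximation to the denominator df
by default: df = 2g²/(∇g′A∇g) with g(θ) the contrast variance and A
the asymptotic covariance of the covariance parameters (2× inverse
numeric Hessian of the profiled deviance).  `residual`
(n_total − 2) and `subjects` (N − 1) are selectable alternatives; a
Kenward-Roger correction is not implemented.  With ~100 observations
the three choices rarely change a decision; the Satterthwaite df is
clipped to [1, n_total − 2].

## The interchangeability decision

With bias threshold δ (default 0.1, in data units — 0.1 cm = 1 mm in
the motivating setting) and level α (default 0.05), the two methods
are declared **interchangeable** iff

1. |bias| < δ, and
2. the bias t test is non-significant (p ≥ α), and
3. the between-subject LRT is non-significant, and
4. the within-subject LRT is non-significant.

Otherwise the **preferred method** is the one with the smaller
within-subject variance, i.e. the better repeatability.  When only the
bias criterion fails the same tie-break is applied (bias is in
principle correctable by calibration, but the rule must still name a
method); exact within-variance ties go to the smaller overall
variance, then to the reference method.  An optional Bonferroni factor
(default off) adjusts p-values when several axes/variables are
analysed in parallel.

## Estimation

The method means are profiled out by GLS for any covariance value
(μ̂ = (ΣX′Ω⁻¹X)⁻¹ΣX′Ω⁻¹y), so the optimizer works on the 4–6
covariance parameters only; profiling is exact, so this is full ML.

* **Parameterization.**  UN blocks via log-Cholesky (two log-diagonal
  entries plus one free off-diagonal), CS blocks via log common
  variance plus atanh-scaled correlation.  Both map unconstrained
  parameters onto valid blocks, so no explicit PD constraints are
  needed.  D may approach the PSD boundary; box bounds floor the
  log-scale parameters about 14 log-units below the data scale.
* **Optimizer.**  L-BFGS-B (finite-difference gradients) from 5 starts
  — one moment-based (between/within decomposition of method-wise
  sample variances) and four seeded jitters — followed by a
  Nelder-Mead polish of the best point.  Deterministic given the seed.
  Deviance tolerance ~1e-8; degenerate evaluations return +inf and are
  skipped by the line search.
* **Pattern grouping.**  Subjects sharing an observed-cell pattern
  share one Ω factorization per deviance evaluation, so complete
  balanced datasets cost one 2p×2p Cholesky per evaluation regardless
  of N.
* **LRT clamping.**  Optimization noise can make the constrained
  deviance fall microscopically below the full one; differences within
  −1e-4 are clamped to 0 with a logged warning, larger violations are
  an error (refit).

Validation: the structured likelihood is tested against a brute-force
multivariate-normal density on explicitly assembled covariances
(agreement to 1e-10 over randomized instances), the fitted optimum
against a derivative-free grid-refinement search, and whole fits
against R's `nlme::lme` expressing the identical model (agreement in
deviance and estimates on a frozen fixture).

## Synthetic data

`simulate` draws exactly from the generative model above; it is the
basis of every distribution-level test.  Defaults emulate a modest
agreement study on the scale of the motivating application (values in
cm): N = 100 subjects, 3 sessions each, D = [[0.05, 0.02], [0.02, 0.05]],
Σ = [[0.15, 0.05], [0.05, 0.15]] (a compound-symmetric truth, i.e. two
methods with identical variability), zero bias, no missingness.
Missingness, when enabled, is independent per cell (MCAR) with
per-method probability ≤ 0.5; degenerate draws are re-drawn with a
bounded retry.  `igrt_fixture` is a deterministic 28-subject demo
with ~100 paired sessions and a ~3:1 within-subject variance ratio —
qualitatively the situation where one method is clearly more
repeatable — intended for examples and smoke tests, not as a
reproduction of any clinical dataset.

What the generator does *not* emulate about real data: non-Gaussian
(heavy-tailed, skewed, or truncated) shifts, session-order effects or
drift, informative missingness, and heterogeneous Σ across sessions.
Passing calibration tests therefore demonstrate correctness of the
estimator and tests *under the model's own assumptions*, not
robustness to their violation.

## Problem sizes used in the validation studies

Parameter recovery uses 100 replicates at N = 500 subjects × 3
sessions; type-I calibration uses 500 replicates at N = 100 × 3 under
the compound-symmetric truth above; consistency checks use
N ∈ {50, 200, 800} with 40 replicates each.  These sizes give
Monte-Carlo error comfortably below the margins being asserted
(e.g. the 99% exact binomial interval around α = 0.05 at 500
replicates spans roughly 0.028–0.078) while keeping the whole suite
runnable on a laptop in minutes.

## Known limitations

* Exactly two methods; no covariates beyond the method effect.
* ML variances are finite-sample biased downward (no REML option, by
  design, to keep LRTs valid).
* The Satterthwaite df is an approximation; with very small N and
  heavy unbalance its p-values can differ from Kenward-Roger-corrected
  ones in the third decimal.
* The decision rule inherits the arbitrariness of its threshold and α;
  they are inputs, not estimates.
* With fewer than ~2 replicated subjects per method the between/within
  decomposition is weakly identified and the input validator rejects
  tables where it is not identified at all.
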