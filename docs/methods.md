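# Methods

`wordingsim` is a Monte Carlo laboratory for a single question: when
respondents answer positively worded (PW) and negatively worded (NW) items of
a balanced questionnaire inconsistently, can a wording-method factor recover
the *uncontaminated* person scores, or does it only repair the model fit?
The package generates ordinal data from a known one-factor population,
injects three kinds of wording effects, fits two categorical structural
models, and measures what each one recovers.

## Generating model

Each replicate draws a unidimensional common-factor population for a balanced
scale of k items (k/2 PW, k/2 NW) plus one continuous criterion:

* signed substantive loadings λ_i with |λ_i| ~ U(0.60, 0.80) (mean 0.70), a
  random half negated; drawn fresh for every replicate so items have variable
  loadings,
* a criterion variable loading 1.0 on its own factor, with substantive-
  criterion factor correlation φ = 0.50,
* population correlation matrix R = ΛΦΛ′ with unities on the diagonal;
  continuous data X = ZU from its Cholesky factor U (Z standard normal),
* item columns cut at thresholds τ = (−1.5, 0, 1.5) into four categories,
  giving symmetric marginals (≈ 6.7 / 43.3 / 43.3 / 6.7%); the criterion
  stays continuous.

A value exactly on a threshold goes to the lower category; the event has
probability zero, the convention only pins down unit-test determinism.
40% of respondents are pre-flagged as "inconsistent"; `round(0.40·N)` uses
round-half-up (irrelevant at the design's N levels, defined for custom ones).

Seeding is counter-based: every (master seed, effect, N, k, replicate, stage)
tuple hashes to its own `SeedSequence`, so any cell reruns bit-identically in
isolation and results cannot depend on execution order.

## Wording effects

Each inconsistent respondent misresponds to `round(perc/100 · k)` items
(minimum 1 when perc > 0); consistent respondents are never touched.

* **Carelessness** — a random subset of NW items is reversed
  (1↔4, 2↔3), as if the respondent read them as positively worded.
  NW items are the (conventional) target; reversing PW items instead would be
  symmetric.
* **Item verification difficulty (IVD)** — reversal conditioned on the
  respondent's uncontaminated trait estimate (one-factor EAP score on the
  clean matrix): PW items are reversed for below-zero scorers, NW items
  otherwise; a score of exactly 0 takes the high-trait branch.
* **Acquiescence** — upward category switching: items are drawn without
  replacement with weights 0.50 / 0.33 / 0.17 for current categories 1 / 2 /
  3 (4s are ineligible), and a selected item maps 1→3, 2→3 or 4 (fair coin),
  3→4, until the target count or exhaustion (logged). Since a changed item
  becomes ineligible and unchanged items keep their original category, the
  weights are static, and the successive draws are realized exactly by
  exponential sort keys (Efraimidis–Spirakis), vectorized over respondents.
  Whether the original probabilistic description meant per-draw weights or
  independent selection gates is ambiguous; weighted sampling without
  replacement is the documented choice here.

## Estimation

**Correlations.** Item thresholds are estimated from marginal cumulative
proportions (Φ⁻¹); latent correlations are two-step maximum likelihood:
polychoric for item pairs (bivariate-normal cell probabilities, thresholds
fixed), polyserial for item–criterion. All item pairs are estimated
simultaneously by a safeguarded Newton iteration on the score function, with
the derivative of each cell probability obtained from the bivariate normal
density at the cell corners (Plackett's identity); pairs the Newton solver
cannot settle fall back to a bounded 1-D likelihood search (tolerance 1e-8,
ρ ∈ [−0.999, 0.999]; likelihood maxima at the bracket ends are accepted as
boundary estimates). The bivariate normal CDF is a vectorized port of Genz's
BVND algorithm, unit-tested against an independent oracle to ~1e-14.
Per-correlation asymptotic variances come from the inverse of the
per-pair information (model-implied cell probabilities at the estimate); a
Monte Carlo check shows they match the empirical sampling variance within a
few percent at this design's thresholds. The assembled matrix is repaired by
eigenvalue clipping (floor 1e-6, then re-normalization to unit diagonal) in
the rare non-positive-definite case, and the repair is flagged.

**Models.** Two structural models are fitted to the correlation matrix by
diagonally weighted least squares, minimizing Σ_p (s_p − σ_p(θ))²/w_p over
the non-redundant correlations with w_p the asymptotic variances:

* **1F** ("do nothing"): σ_ij = λ_iλ_j, criterion column σ_ic = λ_iβ_sf.
* **RIIFA**: an orthogonal wording factor with all item loadings fixed to 1
  and variance ω free — σ_ij = λ_iλ_j + ω — and the criterion regressed on
  both factors: σ_ic = λ_iβ_sf + √ω·β_wf (β_wf reported on the standardized,
  unit-variance wording-factor metric). Internally ω is parameterized as
  s = √ω ≥ 0 to keep the gradient smooth at the boundary.

The substantive factor variance is fixed at 1; uniquenesses are remainders to
the unit diagonal (delta parameterization) and do not enter the fit.
Optimization is a bounded trust-region least-squares with analytic Jacobian
from three deterministic starts (eigenvector sign pattern at scales 0.5/0.7,
ω starting at 0.05 or 0.2); the best solution is kept. The factor is oriented
so β̂_sf ≥ 0 (the criterion correlates +0.50·λ with the trait by
construction, so this aligns the factor with the generating trait).
A fit counts as converged only if the optimizer succeeded, all uniquenesses
are nonnegative, and (RIIFA) ω̂ ≥ 1e-6: boundary-ω solutions are reported as
non-converged, which is exactly the low-wording-effect non-convergence
pattern the RIIFA shows in practice, and aggregation excludes them.

**Degrees of freedom.** Moments are the k(k−1)/2 + k non-redundant
correlations. 1F frees k loadings + β_sf; RIIFA additionally frees ω and
β_wf, so with the criterion included df(RIIFA) = df(1F) − 2 (for a 10-item
scale: 44 vs 42), and df(RIIFA) = df(1F) − 1 for measurement-only models.

**Test statistic.** The raw DWLS statistic T = (n−1)·F̂ is not chi-square
calibrated (diagonal weights ignore the correlation among residuals). The
reported statistic is therefore the scaled-and-shifted robust form used by
WLSMV software: with Γ the asymptotic covariance of the correlation vector —
estimated from per-observation influence functions of the two-step
estimates — and U the weighted residual operator at θ̂,

    T* = (T − tr(UΓ))·√(df / tr((UΓ)²)) + df,

which has mean df and variance 2df to first order under a correct model. The
zero-correlation baseline statistic for CFI/TLI is adjusted the same way.
The trace terms are computed from the n×P influence matrix in single
precision (only traces are needed; no full-weight WLS fit is performed).
A row-bootstrap cross-check of Γ (which also carries threshold-estimation
noise) moved CFI by < 0.005, so the influence-function approximation is not
the binding error. CFI, TLI and RMSEA use the standard formulas with
perfect-fit clamps; when the baseline itself fits (χ²_base ≤ df_base) the
incremental indices are clamped to 1 and the event logged.

**Person scores.** EAP under the normal-ogive graded-response
reparameterization of the fitted model: item discrimination λ_i/√θ_ii with
uniqueness θ_ii = 1 − λ_i² − ω (floored at 5e-3 for scoring), category
boundaries at the estimated thresholds. Gauss–Hermite quadrature with 41
nodes (1-D, agreeing with a dense-grid oracle to ~2e-6) and 31 nodes per
dimension for the RIIFA substantive × wording double integral (the wording
dimension is scaled by √ω̂, so its integrand is smoother and fewer nodes
suffice). Only the items enter scoring; the criterion does not. Whether the
original scores were EAP or MAP is not documented anywhere we could follow;
EAP is the stated choice here.

## Assessment

* **Loading recovery**: MBE = Σ(λ̂−λ)/k and MAE = Σ|λ̂−λ|/k per polarity
  group (PW, NW).
* **Score recovery**: Pearson correlation between the clean-matrix 1F EAP
  scores (the reference) and the contaminated-matrix scores of each model —
  over all respondents, consistent only, and inconsistent only. Wording-score
  diagnostics correlate the RIIFA wording scores with the clean substantive
  scores by subgroup.
* **Structural validity**: β̂_sf, β̂_wf and R² = β̂_sf² (+ β̂_wf²).
* **Model comparison**: split-plot ANOVA on total recovery with model as the
  repeated factor and PERC.WE (20–50% only), N, k between factors. With two
  within levels the within stratum is an OLS on the per-replicate model
  difference (Type-III, sum coding, so non-converged replicates drop
  pairwise and unbalanced cells are handled): the intercept is the model
  main effect, factor terms are model × between interactions, the residual is
  the within error; η²p = SS_effect/(SS_effect + SS_error-for-that-stratum).
  Replicates where the RIIFA failed stay in 1F-only summaries.

## Orchestration and problem sizes

One replicate of a study = one uncontaminated matrix per (N, k) cell, fitted
once by the reference 1F model, then contaminated at every PERC.WE level
(same clean matrix, same flags; misresponded item subsets drawn independently
per level) and refitted by both models. The full factorial design is 6 × 3 ×
3 cells × 100 replicates; `scripts/acceptance.py` and the default
`simulate-study` CLI run the package's desk-scale configuration — PERC.WE
{20, 30, 40, 50} × N {200, 500, 1000} × k {12, 24, 60} with 10 replicates
per cell per study (the 0/10% levels are excluded from effect-size analyses
anyway) — and the acceptance tests use 2 replicates per cell. Monte Carlo
standard errors of the grid means at these sizes are well below the
comparison tolerances.

## What the generator does and does not emulate

The synthetic data reproduce the design's stated conditions: balanced scales,
normal latent traits, symmetric thresholds, a single wording effect per
dataset, equal PW/NW loading magnitudes, and exactly 40% inconsistent
respondents. Real questionnaires violate most of these — mixed and
within-person wording effects, asymmetric category use, unbalanced keying,
non-normal traits. Passing tests therefore validate the estimation machinery
and the simulation's internal claims, not robustness of the RIIFA to
conditions outside this design (the original authors flag the same
limitations).

## Known limitations

* The robust statistic approximates the mean-and-variance adjustment of
  commercial WLSMV software; under gross misfit, absolute CFI levels from
  different implementations of that adjustment can differ by ~0.1 even when
  RMSEA and every recovery quantity agree. Incremental-fit comparisons
  between the two models are unaffected.
* η²p from the split-plot ANOVA is a ratio of a stable mean difference to
  between-replicate noise; its value is sensitive to implementation-specific
  estimation noise, so effect-size magnitudes are best compared
  qualitatively (large vs small), not to two decimals.
* Missing data, >4 categories, asymmetric thresholds, unbalanced scales and
  multidimensional substantive structures are out of scope.
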