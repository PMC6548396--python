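# Methods

## Model

The Actor–Partner Interdependence Mediation Model (APIMeM) for
distinguishable dyads is an observed-variable path model on six variables
per dyad, `(x1, x2, m1, m2, y1, y2)` — predictor, mediator and outcome for
member 1 (patient) and member 2 (nearest relative). Twelve directed paths
connect them (see README); the exogenous pair covaries freely, mediator
errors covary (C2), outcome errors covary (C3), and mediator errors are
assumed independent of outcome errors. All variables are treated as
continuous and the errors as homoskedastic multivariate normal. The unit of
analysis is the dyad everywhere — estimation, resampling, fit indices —
which is what encodes the non-independence of the two members.

## Estimation

**Saturated model.** The two mediator equations share the regressor set
`(1, x1, x2)` and the two outcome equations share `(1, x1, x2, m1, m2)`.
For seemingly-unrelated regressions with identical regressors, GLS collapses
to per-equation OLS; and because the model is saturated (21 free covariance
parameters for 21 sample moments) the implied covariance reproduces the
sample covariance exactly, so the OLS estimates *are* the SEM
maximum-likelihood solution with χ² = 0 on 0 df. `fit_saturated` therefore
uses closed-form normal equations — exact, and fast enough that bootstrap
and simulation studies are cheap. Standard errors are normal-theory
per-equation OLS errors (denominator n − p). They can differ at O(1/n)
from the ML errors printed by common SEM software; this is documented
rather than reconciled. The joint covariance of the twelve path estimates
(used by the Monte-Carlo interval) is assembled blockwise:
`Cov(β_g, β_h) = σ_gh (X'X)⁻¹` within the mediator pair and within the
outcome pair; cross-pair blocks are zero because, in sample, outcome
residuals are orthogonal to the mediators.

**Constrained model.** Path-equality constraints (the empirical
distinguishability test equates the six actor/partner path pairs across
roles) are fitted by minimizing the multivariate-normal discrepancy

    F(θ) = ln|Σ(θ)| + tr(S Σ(θ)⁻¹) − ln|S| − 6,

with S the (n − 1)-denominator sample covariance and
Σ(θ) = (I − A)⁻¹ Ψ (I − A)⁻ᵀ. The problem is concentrated analytically:
writing T = I − A (unit lower-triangular under the causal ordering, so
ln|Σ| = ln|Ψ|), the discrepancy separates over the three blocks of the
block-diagonal Ψ, and for fixed paths the ML residual blocks are the
corresponding blocks of G = T S Tᵀ. The optimizer (BFGS, gradient tolerance
1e−9, up to three jittered restarts, start at the constraint-averaged
saturated estimates) therefore searches only the free path parameters —
six under role equality — and χ² = (n − 1)·F_min with df equal to the
number of independent constraints. Constrained-fit standard errors come
from the finite-difference Hessian of (n − 1)/2·F at the optimum and are
asymptotic approximations. An empty constraint list recovers the saturated
solution with F_min = 0 to machine precision, which the tests verify.

**Fit indices.** RMSEA = sqrt(max(χ² − df, 0) / (df·(n − 1))), undefined at
df = 0; the n − 1 denominator follows the common SEM convention (at n = 312
the printed value 0.066 is reproduced under either n or n − 1). Per-equation
R² is the usual residual/total variance ratio; the overall R² is the
determinant-based generalization 1 − |Ψ_endog| / |Σ_endog| over the four
endogenous variables, which reduces to the per-equation value when the
block is univariate.

## Effects and inference

The decomposition computes, per role × pathway (actor / partner), the direct
effect, the two mediator-routed simple indirect effects, the total indirect
effect and the total effect. The additive identity total = direct + ΣIE
holds to 1e−12 (it is not forced; each quantity is computed from its own
product-sum). A brute-force oracle multiplies edge weights along every
directed route of the six-node diagram (networkx path enumeration) and must
agree exactly; this guards the index bookkeeping, which is where APIM
implementations typically go wrong. Proportion mediated = 100 × (selected
simple IE) / (pathway total effect); the numerator is selectable
(actor–actor simple IE by default, or the total IE), and values outside
[0, 100] — inconsistent mediation — are flagged, never clamped.

Interval estimation:

* **BC bootstrap (default).** Dyads (whole rows) are resampled with
  replacement; each replicate refits the saturated model via the closed-form
  kernel and recomputes all twenty effects. Bias correction uses
  z0 = Φ⁻¹(fraction of replicate estimates below the full-sample estimate),
  clipped to (1/(B+1), B/(B+1)) to keep z0 finite, with bounds at the
  bootstrap quantiles Φ(2z0 ± z_{.975}). No acceleration constant (BC, not
  BCa). Default 5000 replicates; replicates whose refit fails are skipped
  (warn above 1%, error above 10%).
* **Monte-Carlo.** Path vectors are drawn from a normal centred at the
  estimates with the blockwise coefficient covariance above and pushed
  through the decomposition; percentile bounds. This is the parametric
  analogue sometimes labelled "Monte-Carlo bootstrap" in SEM software; both
  are provided because the two names are used interchangeably in applied
  reports, and the nonparametric BC interval is the default because the
  bias-corrected variant is the conventionally reported one.

Measured at the default generator regime (n = 312), the BC interval's true
coverage for the relative actor total IE is ≈95% (the acceptance test
measures it over 1000 replicate datasets × 1000 resamples), and the
role-equality χ²(6) test holds its 5% size (4–5% over 500 null replicates).

## Power

The power module reproduces the regression approximation used to power
dyadic path models without latent variables: an omnibus F-test with
df1 = p predictors, df2 = n − p − 1, and Cohen's f² = R²/(1 − R²) driving
the noncentrality. Two noncentrality conventions circulate in software;
both are exposed. The default is λ = f²·(df2 + 1) = f²·(n − p), which
reproduces the conventional reporting of the worked example (n = 312,
p = 12, α = .05, f² = .09 → 95% power to the nearest percent); the
alternative λ = f²·n gives 96.0% for the same inputs and is what the
simulation oracle in the test-suite matches when the realised noncentrality
is fixed at f²·n by construction. `solve_f2` inverts the power function by
monotone root-finding (tolerance 1e−6); both conventions return f² ≈ 0.09
at two decimals for 95% target power.

## Synthetic-data generator

`simulate_scores` draws (x1, x2) from a bivariate normal and propagates
through the structural equations with correlated mediator and outcome
errors; identical seed + config gives bit-identical data. The default
configuration places the generator at the published study regime:

| quantity | default | source |
|---|---|---|
| paths | the twelve published estimates | printed model results |
| exogenous means/SDs | 83.1 ± 22 (patient), 78.7 ± 22.2 (relative) | printed descriptives |
| endogenous means | 108.7 / 106.9 (health), 90.6 / 89.6 (functioning) | printed descriptives, hit via intercepts |
| corr(x1, x2) | 0.3 | unprinted; plausible dyadic dependence |
| residual correlations (C2, C3) | 0.3 | unprinted; plausible dyadic dependence |
| residual variances | solved so each equation has R² = 0.17 | the study's overall equation-level fit |

The residual calibration fixes every equation's R² at 0.17 given the paths
and exogenous moments; the implied determinant-based overall R² is then
≈0.33 (correlated equations), and the implied SDs of the endogenous scores
are smaller than the printed sample SDs — given the printed paths, the
printed R² and the printed SDs cannot hold simultaneously, and the R²
calibration was chosen. All of these are config fields and overridable.

What the generator does **not** emulate: bounded/discrete sum scores
(unless `discretize=True`), non-normal or heteroskedastic errors, outliers,
missingness mechanisms beyond whole-score deletion, and any covariate
structure (age, NYHA class...). Passing tests therefore demonstrate
correctness of the estimator and intervals under the model's own
assumptions at a realistic effect-size regime — not robustness to the
violations real questionnaire data exhibit.

`simulate_items` converts discretized scale targets into 62 Likert items by
integer spreading (each item within ±1 of the scale mean, the remainder
assigned to random items), emitting the five ill-being items reverse-coded
so that default scoring recovers the targets exactly.
`simulate_null_roles` symmetrizes the configuration (six path pairs
averaged, symmetric exogenous and residual structure) and is the null for
the distinguishability test's size simulations.

## Scoring and dyad construction

FAFHES scores are raw sums (ranges 19–114, 23–138, 20–120); no
standardization, matching the printed score ranges. The instrument's
published description fixes subscale sizes but not item order, so the
package adopts a positional convention (functioning items 1–19, health
20–42, support 43–62, subscales consecutive) with a column map for files
that differ. Whether the ill-being subscale ("feelings of discomfort and
bad feelings") is reverse-keyed before summation is not stated alongside
"higher is better"; the package defaults to reverse-coding
(`reverse_illbeing=True`) for score-direction consistency and exposes the
flag so either convention is reproducible. Missing items are never imputed:
a respondent failing validation is dropped, and the dyad builder then
excludes any dyad lacking a member, carrying a duplicate or extra member,
or missing any score — each exclusion logged with exactly one reason code.
This mirrors complete-case dyadic analysis practice (e.g. 320 eligible
dyads → 8 excluded for incompleteness → 312 analysed).

## Numerical choices and limitations

* Covariance denominators: n − 1 throughout (S, residual blocks, RMSEA).
* Rank checks name the offending constant column; n ≤ 6 dyads is refused.
* χ² is clamped at 0; p = 1 and RMSEA = 0 are reported for df = 0 fits.
* "Zero-noise" identifiability is a limiting statement: with mediator
  residual variance exactly zero the mediators are collinear with the
  predictors and the b and c′ paths are unidentified, so the noiseless
  recovery tests use a noise hierarchy (tiny mediator noise dominating a
  far smaller outcome noise).
* Test-suite problem sizes are chosen for precision per CPU-second: 500
  replicate datasets for parameter recovery and test size, 1000 × 1000 for
  bootstrap coverage (a 200-replicate coverage estimate has ~1.5% binomial
  SE, large relative to the assessed band), 10⁵ simulated F-tests for the
  power oracle.
* Out of scope: latent measurement models, ordinal estimators (WLSMV),
  missing-data ML (FIML), k > 2 family groups, indistinguishable-dyad APIM
  variants beyond the role-equality test, and reliability estimation for
  the questionnaire.
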