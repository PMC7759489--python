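# Methods

## Model

An individual's probability (or fraction) of drug effect at effect-site
concentration C follows the sigmoid Emax model
P = C^γ / (C50^γ + C^γ), equivalently expit(γ·(ln C − ln C50)).
The cumulative log-normal alternative is P = Φ((ln C − ln C50)/σ).
Through the logistic approximation of the normal CDF, expit(a·z) ≈ Φ(z),
the two families coincide to better than 0.01 in P when γ·σ = a. The
minimax-optimal constant (minimizing the worst absolute deviation over z)
is a ≈ 1.702; the package uses a = 1.7 in all conversions, recomputing the
calibrated value only in `calibrate_logistic_constant` (coarse grid over
[1.5, 1.9] on a 20,001-point z-grid spanning ±10, then bounded scalar
refinement; the optimum is insensitive to widening the z-range because the
deviation decays far from 0).

Inter-individual variability (IIV) is multiplicative and log-normal:
C50_i = C50·exp(η₁), γ_i = γ·exp(η₂), with η₁ ~ N(0, ω_C50) and
η₂ ~ N(0, ω_γ). The ω symbols are **variances**, not SDs — that convention
is what lets σ*² be written as a sum of variance terms.

## Population steepness

Averaging P over individuals yields a shallower curve than any
individual's. Its steepness in the log-normal parameterization is
approximated by the variance-summation formula

σ*² = p₁·σ²/γ^p₅ + p₂·ω_C50/γ^p₆ + p₃·ω_γ/γ^p₇ + p₄·ω_C50·ω_γ/γ^p₈,
γ* = 1.7/σ*,

with calibrated, rounded constants (p₁…p₈) = (1, 1, 1.25, 2.5, 0, 0, 2, 1).
With zero IIV, σ* = σ and γ* = γ exactly. The formula predicts the Monte
Carlo population fits with ≈1.2% RMSE over the full calibration grid
(range roughly −4% to +5%); the acceptance script recomputes this number.

## Monte Carlo calibration

For each cell of a factorial grid (γ ∈ {0.5, 1, 2, 3, 5, 10, 20, 30, 50},
each ω ∈ {0, 0.05, 0.1, 0.2, 0.3, 0.5}; 324 cells), 10,000 individuals are
drawn and their Emax curves averaged on a 101-point concentration grid
C_i = C50·exp(i·ln(1/p − 1)/(n·γ*)), i = −50…50, p = 0.01, n = 50. With
n equal to the half-width the edge points sit exactly at population
probabilities p and 1 − p; the grid depends on γ*, i.e. on the constants
being calibrated, so calibration regenerates the grid with the updated
constants each outer iteration until all constants move by < 0.1 %
relative. Averaging the exact individual probabilities rather than
Bernoulli draws is the default (`dichotomize=False`): both estimate the
same curve, the latter with added binomial noise (a test asserts agreement
within that noise at n = 100,000).

Each population average is fitted by unweighted least squares over all 101
grid points, in (ln C50, ln steepness) coordinates for positivity, with a
3-point multistart (0.5×, 1×, 2× the grid-implied logit slope) guarding
the high-γ local minima. A noiseless single-individual curve is recovered
to machine precision.

The eight constants are estimated by minimizing the equal-weight sum of
squared differences between ln γ* (formula) and ln γ_mc (Monte Carlo fit)
over all cells, initialized by the stepwise scheme: (p₁, p₅) from the
no-IIV cells, (p₂, p₆) from the ω_γ = 0 cells, (p₃, p₇) from the
ω_C50 = 0 cells, (p₄, p₈) from the cells with both ω nonzero — each by
log-linear regression of the residual variance on ln γ — then a joint
bound-constrained (p ≥ 0) quasi-Newton refit.

**Identifiability caveat.** The objective is nearly flat along a ridge
trading the interaction constants against small adjustments of p₂ and p₃.
The strongly identified constants reproduce the reported values
(p₁ ≈ 1.00, p₅ = 0, p₆ ≈ 0.03, p₇ ≈ 1.97), but the free-fit optimum puts
p₄ near 1.5 and p₈ near 0.84 rather than the reported rounded 2.5 and 1 —
stably so even at 100,000 individuals per cell, so this is a property of
the objective, not Monte Carlo noise. Both constant sets predict γ* to
within ≈1.2% RMSE; the package keeps the reported rounded constants as
`PiConstants` defaults and exposes the refit via `fit_pi_constants`. The
corresponding acceptance test documents the discrepancy by failing on p₃/p₄.

## Trial simulation

The validation design emulates a typical anesthesia-depth study: 40
subjects, each observed at 4 fixed concentrations placed where the
*population* probability of effect (from γ*) equals 0.10, 0.25, 0.75 and
0.90, by inverting the Emax model at γ*: C = C50·(P/(1−P))^{1/γ*}. Each
subject's (C50_i, γ_i) is drawn once and shared across their observations.
Binary responses are Bernoulli draws at the individual probability;
continuous responses add N(0, 0.1²) error (10% of the 0–1 effect scale) to
the individual probability and are deliberately not truncated to [0, 1],
keeping the error model exactly Gaussian for the least-squares estimator.
Per-subject random substreams are derived from (seed, subject index), so a
dataset is invariant to subject ordering; study replications use
substreams keyed by (master seed, combination index, replication index).

The default study covers 48 (γ, ω_C50, ω_γ) combinations: for each
γ ∈ {1, 5, 30}, all six ω_C50 levels {0, 0.02, 0.05, 0.1, 0.2, 0.5} with
ω_γ = 0, plus the five nonzero ω_γ levels crossed with ω_C50 ∈ {0, 0.1}.

## Estimation

**Naive pooling.** All observations are treated as one individual. For
binary data the Bernoulli likelihood of the Emax probability is maximized
over (ln C50, ln γ) with L-BFGS-B and analytic gradients; this is exactly
logistic regression of the response on ln C (slope γ, intercept
−γ·ln C50), which the tests exploit as an independent oracle via a GLM
fit. Probabilities are clamped to [1e−12, 1 − 1e−12] so perfectly
separated data stay finite; separation drives γ̂ to the upper bound, where
it is reported with a boundary flag. For continuous data the Gaussian
likelihood with the residual SD profiled out (ordinary least squares) is
used. γ is bounded in [0.01, 50]; the upper bound matches the behavior of
steep binary datasets pinning near 50, and estimates within 0.5% of a
bound are flagged "near boundary". A 3-point multistart over initial γ
(1, 5, 25) guards against local minima.

**Mixed effects (Laplace).** With random effects active on ln C50 and/or
ln γ, each subject's marginal likelihood is approximated by a second-order
expansion of the joint log-density around the empirical-Bayes mode:
log m_j ≈ ℓ_j(η̂) + (d/2)·ln 2π − ½·ln det(−H(η̂)), where ℓ_j includes the
N(0, ω) prior. The inner mode search is a Newton iteration, vectorized
across subjects, using the expected-information (Fisher) Hessian — negative
definite by construction, so the step is always an ascent direction — with
per-subject backtracking, a step-norm trust region of 3 (random-effect
modes live within a few prior SDs) and convergence at |gradient| < 1e−8.
The Laplace determinant uses the observed Hessian at the mode, falling
back to the expected information where the observed one is not negative
definite. Active variances are floored at 1e−10; in the ω → 0 limit the
prior and curvature terms cancel analytically and the marginal equals the
pooled likelihood (asserted at 1e−6).

The outer problem optimizes (ln C50, ln γ bounded, √ω per active term)
with L-BFGS-B; √ω keeps variances nonnegative without hard constraints,
and ω̂ < 1e−6 is flagged "near lower boundary". The "successful covariance
step" analog requires a positive-definite central-difference Hessian of
the objective at the optimum with condition number < 1e10 and no active
boundary flag. Mixed-effects estimation is implemented for binary data
(the continuous-data validation uses naive pooling only, matching the
study design it emulates); diagonal ω only — no covariance between the two
random effects.

Laplace accuracy: against adaptive Gauss–Hermite quadrature the
approximation error is ~1e−4 log-likelihood units per subject at γ = 1 and
grows with steepness (it can reach ~1e−2 at γ = 5 with 4 binary
observations). Tests therefore check *agreement with quadrature* on
shallow toys and *implementation correctness* (against an independent
brute-force Laplace evaluation) at steep γ.

## Replication summaries

Per combination, medians and empirical 2.5/97.5 percentiles (linear
interpolation) of each estimate are computed over runs with successful
minimization — non-minimized runs are excluded by default and counted
separately (`include_failed` toggles the convention). The percent
difference reported is 100·(γ* − median γ̂)/median γ̂, and the study-level
precision is the RMSE of that quantity across combinations.

## Problem sizes and tolerances

The packaged test suite runs the full 324-cell calibration grid at 10,000
individuals per cell, the binary pooled validation at 1000 replications,
and the mixed-effects and 48-combination continuous studies at 200
replications per combination — sizes at which the medians and RMSEs are
stable to well within the tolerances asserted (e.g. ±0.15 on median γ̂,
±0.02 on median ω̂). The acceptance script uses the same sizes.

## What the simulations do and do not show

The generator reproduces the generative model exactly as analyzed:
log-normal IIV, fixed 4-level designs placed with knowledge of the true
γ*, no residual error on binary data, Gaussian error on continuous data.
Real studies add model misspecification (non-log-normal IIV, correlated
random effects, within-subject correlation from repeated stimuli, PK
uncertainty in the effect-site concentration) and designs not centered on
the true C50; passing tests validate the formula and estimators under the
stated model, not robustness to those violations. Other known limitations:
γ* is an approximation (≈1.2% RMSE, ΔP < 0.01); the Laplace approximation
degrades for very steep individual curves; and the 40×4 binary design is
demonstrably too small to estimate ω_C50 and ω_γ precisely — that negative
result is itself one of the reproduced findings.
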