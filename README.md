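# popemax

Population steepness of the sigmoid Emax concentration–effect model under
inter-individual variability (IIV): a closed-form prediction formula, the
Monte Carlo procedure that calibrates it, and a trial simulator with
naive-pooled and mixed-effects (Laplace) maximum-likelihood estimators that
validate it.

## The problem

Binary drug effects — say, response to a standardized stimulus under
anesthesia — are commonly modeled with the sigmoid Emax (Hill) model,

    P(C) = C^γ / (C50^γ + C^γ),

where C50 is the effect-site concentration giving P = 0.5 and γ the
steepness. Reported γ values for the same endpoint vary wildly between
studies, depending on whether IIV was included in the analysis. The reason:
when C50 and γ vary log-normally between individuals (variances ω_C50 and
ω_γ), the *population-averaged* curve is much shallower than any
individual's. Its steepness γ\* is what a naive pooled analysis estimates,
and what a bedside probability-of-response display actually needs.

Exploiting the near-identity of the Emax curve and the cumulative
log-normal curve (γ = 1.7/σ, via the logistic approximation of the normal
CDF with minimax constant a ≈ 1.702), the population steepness is predicted
by summing variances:

    σ*² = σ² + ω_C50 + 1.25·ω_γ/γ² + 2.5·ω_C50·ω_γ/γ,      γ* = 1.7/σ*

with σ = 1.7/γ. The package implements this formula, the Monte Carlo
calibration of its constants on a 324-cell (γ, ω_C50, ω_γ) factorial grid
of 10,000-individual simulated populations, and the validation pipeline:
simulated 40-subject trials with 4 binary (or continuous) observations per
subject, analyzed by naive pooling or by nonlinear mixed-effects estimation
with a Laplace-approximated marginal likelihood.

## Worked example

```python
from popemax import (IIVSpec, PDParams, StudySpec, gamma_star,
                     run_replications)

star = gamma_star(30.0, IIVSpec(omega_c50=0.1, omega_gamma=0.1))
print(f"gamma* = {star.gamma_star:.3g}, sigma* = {star.sigma_star:.3g}")

spec = StudySpec(combos=((30.0, 0.1, 0.0),), n_reps=1000, master_seed=3)
row = run_replications(spec).iloc[0]
print(f"median pooled gamma-hat = {row.gamma_median:.3g} "
      f"(formula gamma* = {row.gamma_star:.3g})")
```

prints

```
gamma* = 5.27, sigma* = 0.323
median pooled gamma-hat = 5.33 (formula gamma* = 5.29)
```

An individual steepness of γ = 30 with 0.1 variance on both log-parameters
collapses to a population steepness of 5.27; and the median of 1000
naive-pooled fits to simulated 40×4 binary trials (5.33) lands on the
formula's prediction (5.29), not on the individual γ = 30 — pooled analyses
estimate γ\*, not γ.

The same functionality is exposed on the command line:

```sh
popemax gamma-star 30 0.1 0.1
popemax simulate-trial --gamma 5 --omega-c50 0.1 --seed 3 --out trial.csv
popemax fit trial.csv --mode c50_iiv
popemax mc-calibrate --out-dir results/
popemax replicate --n-reps 1000 --mode pooled --out-dir results/
```

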