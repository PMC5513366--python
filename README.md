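# psajoint

Nonlinear joint modelling of PSA kinetics and survival in metastatic
castration-resistant prostate cancer (mCRPC), with Bayesian **individual
dynamic prediction** of the risk of death and time-dependent accuracy
metrics (IPCW AUC, Brier score, scaled Brier score, band coverage).

The package is for biostatisticians and pharmacometricians who want to
(i) simulate realistic mCRPC cohorts from a nonlinear joint model,
(ii) update a patient's death-risk prediction as PSA measurements
accumulate, and (iii) quantify how discriminating and well calibrated
those dynamic predictions are at different landmark and horizon times.

## Model

**Longitudinal submodel.** The observed biomarker is
y<sub>ij</sub> = log(PSA(t<sub>ij</sub>, ψ<sub>i</sub>) + 1) + e<sub>ij</sub>,
e<sub>ij</sub> ~ N(0, σ²). PSA follows a piecewise-biexponential
kinetic law: prostatic cells proliferate at rate *r* (day⁻¹) and die at
rate *d*; chemotherapy suppresses a fraction ε of proliferation until
the escape time T<sub>esc</sub>, after which growth resumes; PSA is
cleared from blood at rate δ. *d* = 0.046 day⁻¹ and δ = 0.23 day⁻¹ are
fixed (tumor-cell half-life ≈ 15 days, blood PSA half-life ≈ 3 days),
leaving ψ = (r, PSA₀, ε, T<sub>esc</sub>) per subject. Individual
parameters arise from population values through log-normal (r, PSA₀,
T<sub>esc</sub>) and logit-normal (ε) transforms of Gaussian random
effects η<sub>i</sub> ~ N(0, Ω), Ω diagonal.

**Survival submodel.** The hazard of death is a Weibull baseline scaled
by a feature f of the *true* (noise-free) PSA trajectory:

    h_i(t) = (k/λ) (t/λ)^(k-1) · exp(β · f(t, ψ_i)),

with f the current log(PSA+1) (default), its slope, its running
integral, or absent. Default parameters are the reference fit on a
400-patient mCRPC training cohort (λ = 3800 days, k = 1.19, β = 0.32
for the current-PSA link).

**Dynamic prediction.** For a subject alive at landmark *s* with PSA
history 𝒴(s), the posterior of the random effects is

    p(η | X > s, 𝒴(s)) ∝ ∏_j p(y_j | η) · S(s | g(μ, η)) · p(η),

sampled by ensemble MCMC (population parameters treated as known).
L = 200 retained draws yield the conditional death probability
π(s+t | s) = [S(s) − S(s+t)] / S(s) per draw; the reported prediction is
the median, with a 95% interval from the 2.5/97.5 Monte Carlo
percentiles. Cumulative hazards use order-8 Gauss–Legendre quadrature
in the Weibull-transformed time variable.

**Accuracy metrics.** Cumulative/dynamic AUC(s,t) and Brier score
BS(s,t) with inverse-probability-of-censoring weights; the scaled Brier
score sBS = (BS_KM − BS)/BS_KM compares against a marginal Kaplan–Meier
prediction. On simulated cohorts the package also evaluates the
coverage of the 95% prediction bands against the generating truth.

## Worked example

```python
import numpy as np
from psajoint import (PopulationParameters, DesignSpec, simulate_cohort,
                      LandmarkDataset, dynamic_prediction, DAYS_PER_MONTH,
                      predict_landmark, evaluate_predictions)

pop = PopulationParameters()              # reference joint model (current-PSA link)
cohort = simulate_cohort(pop, DesignSpec(n_subjects=50, seed=7))

s = 12 * DAYS_PER_MONTH                   # landmark: 12 months
horizons = np.array([6.0, 12.0]) * DAYS_PER_MONTH

subj = next(x for x in cohort.subjects if x.survival.T > s)
obs = [r for r in subj.records if r.t <= s]
data = LandmarkDataset(subject_id=subj.subject_id, s=s,
                       times=np.array([r.t for r in obs]),
                       y=np.array([r.y for r in obs]))
pred, draws = dynamic_prediction(data, pop, horizons, L=200, seed=1)
for t, med, lo, hi in zip((6, 12), pred.pi_median, pred.pi_lo, pred.pi_hi):
    print(f"P(death by {t:2d} months | alive at 12 months, PSA history): "
          f"{med:.3f}  [95% PI {lo:.3f}-{hi:.3f}]")

preds = predict_landmark(cohort, pop, s, horizons, L=200, seed=7)
for row in evaluate_predictions(preds, cohort, s, horizons):
    print(f"s=12, t={row['t_months']:.0f} months: AUC={row['auc']:.3f}  "
          f"BS={row['bs']:.3f}  sBS={row['sbs']:.3f}  (n at risk {row['n_at_risk']})")
```

Output:

```
P(death by  6 months | alive at 12 months, PSA history): 0.148  [95% PI 0.112-0.222]
P(death by 12 months | alive at 12 months, PSA history): 0.298  [95% PI 0.198-0.655]
s=12, t=6 months: AUC=0.789  BS=0.097  sBS=0.071  (n at risk 42)
s=12, t=12 months: AUC=0.822  BS=0.158  sBS=0.128  (n at risk 42)
```

The first two lines are one patient's updated risk of dying within 6
and 12 months of the one-year landmark, given their PSA trajectory so
far, with the Monte Carlo 95% prediction interval. The next lines score
all at-risk patients at once: an AUC near 0.8 means the model ranks
who will die in the window well; a Brier score well below the 0.25 of
an uninformative constant prediction, and a positive sBS, mean the
individualized predictions beat the marginal Kaplan–Meier forecast.

A command-line interface mirrors the library
(`psajoint simulate|predict|evaluate|coverage|run-experiment`); see
`psajoint --help`.

## Documentation

See `docs/methods.md` for the modelling assumptions, numerical choices
(quadrature, root finding, sampler settings) and known limitations.
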