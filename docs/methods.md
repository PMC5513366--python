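# Methods

## The joint model

The package couples a nonlinear mixed-effects model for PSA with a
parametric survival model through shared individual parameters.

**PSA kinetics.** A two-population view — treatment-sensitive
production decaying at rate r(1−ε)−d until the escape time
T<sub>esc</sub>, unrestrained growth at r−d afterwards, with first-order
elimination of PSA from blood at δ — admits the closed-form
piecewise-biexponential solution used everywhere in the package. We
evaluate it in the algebraically rearranged form

    PSA(t) = PSA₀ e^{−δt} (1 + δ·φ(a₁, t)),         t ≤ T_esc,
    PSA(t) = PSA(T_esc) e^{−δu} + δ PSA₀ E e^{−δu} φ(a₂, u),   u = t − T_esc,

with φ(a, t) = (e^{at} − 1)/a, a₁ = r(1−ε) − d + δ, a₂ = r − d + δ and
E = e^{(r(1−ε)−d)T_esc}. This form is manifestly positive and
continuous at T<sub>esc</sub>, and φ's removable singularity at a = 0
is evaluated by its quadratic series whenever |a| < 10⁻¹⁰ day⁻¹ —
random-effect draws can land arbitrarily close to that manifold. When
the growth exponent exceeds ~700 (event-time root searches probe very
large t), log(PSA+1) switches to its exact log-space asymptote
log(δ PSA₀/a₂) + g(t) instead of overflowing.

The slope of log(PSA+1) uses the production/elimination identity
PSA′(t) = δ·(PSA₀ e^{g(t)} − PSA(t)) with g piecewise linear, rather
than differentiating the biexponential termwise; at the T<sub>esc</sub>
kink the left derivative is returned (the hazard integrand is defined
almost everywhere, so the convention only needs to be fixed).

**Random effects and transforms.** η ~ N(0, Ω), Ω =
diag(ω²) on the transformed scale; r, PSA₀, T<sub>esc</sub> are
log-normal and ε logit-normal, so every η maps to a valid ψ and the map
is exactly invertible (round-trip tested to 10⁻¹⁰).

**Survival.** Weibull baseline hazard (k/λ)(t/λ)^{k−1} times
exp(β·f(t, ψ)) with f ∈ {0, current log(PSA+1), its slope, its running
integral}. The default parameters are the reference current-PSA fit
(λ = 3800 d, k = 1.19, β = +0.32). β's sign is an ordinary configurable
input; the positive default is the only reading consistent with the
clinical direction of the association (higher PSA, higher hazard).
No baseline covariates enter the hazard (γ = 0 in the reference model).

## Numerical choices

**Cumulative hazard.** H(t) is computed with Gauss–Legendre quadrature
of order 8 (configurable) after the substitution z = (u/λ)^k, i.e.
H(t) = ∫₀^{(t/λ)^k} e^{β f(λ z^{1/k})} dz. Plain Gauss–Legendre on
(0, t) converges only algebraically here because of the t^{k−1}
endpoint singularity of a non-integer Weibull shape (measured plateau
≈ 6·10⁻⁴ relative error at 8 nodes); in the transformed variable the
baseline integrates exactly at any order, nodes remain strictly inside
(0, t) (so k < 1 never touches the t = 0 divergence), and the 8-node
current-link error versus an adaptive oracle is ≈ 6·10⁻⁶ at the
reference parameters (worst case 3·10⁻⁴ over random ψ). The range is
additionally split at T<sub>esc</sub> by default, since the trajectory
kink degrades polynomial quadrature when spanned. The link exponent
β·f is clipped at ±700 with a logged warning so extreme posterior draws
cannot overflow the Monte Carlo loop.

**Event-time simulation.** Death times are drawn by exact inversion:
S(X) = u solved by bracketing + Brent root finding on the
high-accuracy cumulative hazard (64 nodes, kink split; |S(X) − u| <
10⁻⁶ enforced, observed ~10⁻¹⁵). The truth-generation path is
deliberately more accurate than the order-8 inference path being
evaluated. Events beyond 10⁵ days are returned as an infinity marker
and censored downstream.

**Posterior sampling.** The per-subject target over η is the product of
the Gaussian observation likelihood, the survival-to-s factor S(s|ψ)
(order-8 quadrature), and the N(0, Ω) prior; population parameters are
treated as known throughout (their uncertainty is neglected, which the
reference fit's small standard errors justify). Sampling uses the
affine-invariant ensemble algorithm (emcee): 24 walkers started in a
small ball around the posterior mode (found by a short Powell search —
without mode-centering the ensemble's migration from the prior mean
biases short-run bands), 200 warmup steps discarded, then thinning by
15 until exactly L = 200 draws are retained. All settings are
configurable. The sampler is treated as a contract, not an
implementation choice: the test suite enforces exact prior recovery
with no data, agreement of posterior means with 10⁶-particle
importance sampling on a toy subject, and recovery of dense-data truth
within 1%; any sampler passing those checks is admissible. Convergence
is flagged (never silent) through the mean acceptance fraction.
Determinism: every draw matrix is a pure function of (data, parameters,
L, seed, settings).

**Prediction summaries.** Per retained draw, the biomarker curve and
π(s+t|s) over the horizon grid; the point prediction is the pointwise
median and the 95% band the 2.5/97.5 percentiles. Draws whose survival
at s underflows to zero are dropped with a logged count. Per-draw π is
forced nondecreasing in t (guards quadrature round-off at nearby grid
points).

## The simulator

The generator reproduces the simulation design the default parameters
were built for: N = 200 subjects, PSA sampled every 21 days from day 0
(the baseline visit is always included) for 30 months (913 days) or
until death, additive N(0, σ²) noise on log(PSA+1), and death times
drawn from the subject's own PSA-dependent hazard. Death is the only
dropout mechanism: death times are fully observed by default, while PSA
collection stops at 913 days. An administrative censoring time for the
survival outcome itself is available (`admin_censor`) but off by
default — censoring the outcome at exactly 30 months would make every
landmark/horizon pair with s + t ≥ 30 months undefined (no subject
could be a control), contradicting the evaluation grid the package
targets. A measurement never postdates death: the visit schedule stops
at the last visit at or before min(death, 913).

Hidden truth (ψ, η, uncensored death time) is carried on a separate
table and file (`truth.csv`) so prediction code cannot read it by
accident; only the coverage evaluator consumes it.

What the simulator does *not* emulate about real mCRPC trials: visit
irregularity (in trials PSA is measured less often after treatment
stops), non-death dropout, accrual structure, and covariate effects.
Passing metrics on simulated cohorts therefore demonstrate correctness
of the machinery under the model's own assumptions, not transportability
to trial data, where discrimination is known to be flatter over
landmark times.

## Metrics

Cumulative/dynamic AUC and Brier score at landmark s and horizon t use
IPCW estimators with weights 1{T>s+t}/G(s+t|s) + D δ/G(T⁻|s), G the
Kaplan–Meier estimator of the censoring distribution (via lifelines)
and G(·|s) = G(·)/G(s). Conventions fixed here: G is evaluated
left-continuously at observed times, so a subject's own censoring never
deflates its weight; tied predictions contribute 1/2 to the AUC kernel
(under a strict inequality a constant predictor would score 0 rather
than the 0.5 that "no information" must yield); the Brier denominator
is the count at risk at s, not the weight sum; subjects whose required
G value is 0 are excluded with a logged count rather than given
infinite weight. With no censoring the estimators reduce exactly to
the empirical pair-ranking AUC and mean squared error (tested by
exhaustive enumeration, and against scikit-survival at landmark 0).
sBS = (BS_KM − BS)/BS_KM plugs the Kaplan–Meier conditional death
probability 1 − S_KM(s+t)/S_KM(s) of a reference cohort into the same
Brier estimator; for simulation experiments the reference is the
simulated cohort itself.

Coverage evaluation compares, per at-risk subject and horizon, the
noise-free curve b(s+t, ψ_true) and the true π(s+t|s) from ψ_true
against the subject's 95% bands; the envelope is the exact central 95%
binomial interval around the nominal level for the number at risk. The
noise-free curve (not the noisy observation) is the quantity checked —
the band describes the latent trajectory, not a future measurement.

## Evaluation grid and problem sizes

Landmarks are 0, 6, 12, 18 months and horizons 2 to 18 months in
0.5-month steps (1 month = 365.25/12 days; files store days, months
appear only at interfaces). The packaged acceptance run uses the full
design (200 subjects, L = 200); the test suite runs a 100-subject
replicate with correspondingly widened Monte Carlo tolerances, chosen
as ~3 standard errors of each metric at that size.

## Known limitations

- The kinetic model has no mechanism for acquired resistance other than
  the escape time, and PSA alone drives the hazard.
- Population-parameter uncertainty is ignored in predictions; with a
  small training cohort a fully Bayesian treatment would be needed.
- With L = 200 the 2.5/97.5 percentile bands are themselves noisy;
  empirical coverage runs ~1–2 points below nominal (visible mostly at
  information-rich landmarks), and materially smaller L under-covers.
- The IPCW estimators assume censoring independent of the biomarker
  process.
- Ω is diagonal by design; correlated random effects are out of scope.
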