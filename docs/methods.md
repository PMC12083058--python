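# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the design decisions behind `jmsched`, in the spirit of a
statistical package's model documentation.  Nothing below states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## 1. The joint model

Two log-transformed biomarkers (troponin T in ng/L, NT-proBNP in pmol/L)
follow Gaussian linear mixed models with random intercepts and slopes; the
stacked random effects `b = (b_tn0, b_tn1, b_nt0, b_nt1)` are multivariate
normal with covariance `D` (this ordering is fixed everywhere, including
serialization).  Two competing endpoints — HF hospitalization (cause 1) and
all-cause mortality (cause 2) — have cause-specific proportional hazards
with Weibull baselines, a baseline MAGGIC-score covariate, and association
terms linking each hazard to functionals of the subject-specific biomarker
trajectories.  Supported association forms are the current value, the
current slope, and the area under the trajectory; with polynomial design
bases all three are closed-form polynomials in time, so every hazard
exponent is `log h_k0(t) + P_k(t)` with `P_k` a low-degree polynomial per
subject.  Time-varying association coefficients are represented as
polynomial coefficient tuples (used only in the generative role, for the
proportional-hazards violation below).

Only the Gaussian/identity-link longitudinal case is implemented, and only
constant-coefficient current-value associations are *fitted*; slope/area
and time-varying forms exist as generative options.

### Parameter defaults and provenance

Published quantities (fixed effects, residual SDs, association and
covariate coefficients, event-count targets, cohort sizes, thresholds) are
flagged `paper` in `src/jmsched/configs/default.yaml`.  Quantities a real
fit would estimate but that are not published anywhere are flagged
`assumed`; they were chosen once, as plausible values for a stable
chronic-heart-failure cohort, and are deliberately not tuned:

* `D`: SDs 0.55 / 0.06 (troponin intercept/slope) and 0.80 / 0.10
  (NT-proBNP), correlations 0.2 within marker, 0.5 between intercepts,
  0.3 between slopes, 0.1 otherwise.  Between-subject intercept spread a
  few times the residual SD and slow, mildly correlated progression are
  typical of serial biomarker studies in this population.  The implied
  log-hazard frailty SD (through the association coefficients) is ≈ 1.
* MAGGIC score: mean 22, SD 6 — a representative HFrEF outpatient range.
  Its hazard coefficients are small (0.0112 / −0.0088), so results are
  insensitive to this choice.
* Weibull shapes are fixed at 1.0 (exponential baselines); calibration then
  has exactly as many free scales as event-fraction targets.  Shapes are
  config-exposed for sensitivity analyses.

## 2. The synthetic cohort generator

One simulated cohort contains 431 patients (381 training / 50 test).  Per
subject: draw `b ~ N(0, D)` and `maggic ~ N(μ, σ²)`; compute the overall
cumulative hazard `H(t) = Σ_k ∫_0^t h_k`; draw `U ~ Uniform(0,1)` and solve
`H(T*) = −log(1−U)` by bracketed bisection (bracket `[1e−6, 100]` years,
tolerance `1e−6`); censor administratively at 20 years; otherwise assign
the cause by a binomial trial with probabilities proportional to the
cause-specific hazards *at* `T*`.  Training subjects get quarterly
measurements from baseline until their observed time; test subjects get
warm-up measurements (0, 0.25, 0.5 years) only — their later visits are
produced by whichever scheduling strategy is being evaluated, and warm-up
records are shared across strategies within an iteration.

**Calibration.**  The Weibull scales are solved so that the expected
fraction of subjects failing from each cause by a 10-year horizon matches
the observed event fractions 90/381 (HF hospitalization) and 14/381
(death).  Per-patient follow-up durations of the source cohort are not
published, so the horizon is the main calibration lever and is
config-exposed.  The solver exploits that for fixed shapes each cause's
cumulative hazard is linear in `scale^(−shape)`: per-subject unit-scale
cumulative hazards are precomputed on a grid, each residual evaluation is
an interpolation, the event-type split is Rao-Blackwellized (expected
hazard ratio at `T*`), and the solve is a damped multiplicative fixed point
polished by a Newton-type root finder.  A self-consistency test confirms the
exact event-time sampler reproduces the targets within Monte-Carlo error.

**Misspecified scenario.**  Two violations are generated while the fitted
model is kept unchanged: NT-proBNP measurement errors become centered
exponential, `ε = σ(E−1)` with `E ~ Exp(1)` (same mean and variance,
skewness 2), and the troponin association with HF hospitalization becomes
time-varying, `α(t) = 0.5 + 0.1 t`, breaking proportional hazards.

**What the generator does not emulate:** informative dropout or missed
visits, visit-time jitter (real visits were "every 3 (±1) months"),
measurement batch effects, non-linear trajectories, and covariate-dependent
censoring.  Passing tests therefore demonstrate correctness of the method
under its own assumptions (plus the two controlled violations), not
performance on real registry data.

## 3. Posterior computation

The per-subject likelihood integrand over `b` — Gaussian prior × Gaussian
longitudinal likelihood × event-hazard term × `exp(−H)` — is log-concave,
so the random effects are integrated out by a Laplace approximation at the
per-subject mode, found by a damped, vectorized 4-dimensional Newton
iteration with analytic gradients and Hessians (warm-started across
likelihood evaluations).  With zero association the approximation is exact;
the suite asserts equality with the closed-form mixed-model likelihood to
`1e−7`.

Two posterior modes share this marginal log-posterior:

* **`laplace` (fast, default for the simulation study):** L-BFGS MAP with a
  three-stage initialization (pooled OLS → exact longitudinal-only ML →
  survival parameters with empirical-Bayes `b` plugged in), then Gaussian
  draws from the inverse of a finite-difference Hessian at the mode
  (eigenvalue-clipped; draws clamped to ±30 on the unconstrained scale so
  barely-identified directions cannot overflow the exp transforms).
* **`emcee`:** affine-invariant ensemble MCMC on the same posterior, with
  split-Rhat and bulk-ESS diagnostics via `arviz`; more than 5% of
  parameters with Rhat > 1.1 is flagged (not fatal).

Priors: `β, γ, α ~ N(0, 10²)`; `log σ`, `log shape`, `log scale
~ N(0, 5²)`; `D` through its Cholesky factor with half-`N(0, 2²)` diagonals
(via log transform, with Jacobian) and `N(0, 1)` off-diagonals.  Cause-2
covariate and association coefficients are parameterized as cause-1 values
plus stratum offsets.  All are weakly informative; the Cholesky prior is a
pragmatic stand-in for a separated SD/correlation prior and matters only
when the data barely identify `D`.

The unconstrained parameter vector (26 dimensions for the default model) is
what gets serialized: posterior files are a named-column CSV of draws plus
a JSON diagnostics sidecar.

## 4. Dynamic prediction

`π_ik(t, s)` is estimated by the posterior-predictive Monte Carlo scheme:
for each retained θ draw, draw `b` from
`p(b | history, T* > t; θ) ∝ N(b; 0, D) · Π N(y; η(b), σ²) · S(t|b)` with an
*independence* Metropolis–Hastings chain whose proposal is the exact
conjugate Gaussian conditional given the longitudinal data alone — the
acceptance ratio reduces to `S(t|b′)/S(t|b)`, and when association is zero
the proposal *is* the target (acceptance 1, asserted in tests).  Default
budgets: 200 θ draws × 5 `b` draws × 50 MH steps; the simulation study uses
smaller budgets (32 × 2 × 8) because the scheduler calls a prediction
inside a root-finder at every visit of every test patient.

The conditioning on survival to `t` is implemented by measuring the
cumulative hazard from `t` (`π(t,s) = ∫_t^s h_k(u) e^{−(H(u)−H(t))} du`),
i.e. the window CIF divided by `S(t)`.  The same convention defines the
*true* conditional window risk used for optimal interruption times, keeping
the generative truth and the estimator on the same scale.

Curves over a horizon grid share their (θ, b) draws across grid points, so
every per-draw curve is nondecreasing in `s` by construction — the
monotonicity the scheduler's bisection requires.  The 95% interval is the
2.5/97.5 percentile of the pooled per-(θ, b) draws.

## 5. Scheduling

At each decision visit both the interrupt test (`π̂(t, t+Δ) ≥ κ`, point
estimate, for both adaptive variants and all fixed schedules) and the
interval rule read one shared prediction curve.  The regular rule bisects
the point-estimate curve for `π̂ = λ`; the conservative rule bisects the
97.5%-quantile curve, hence never chooses a longer interval for the same
draws; the multi-endpoint rule takes the per-cause minimum.  Bisection
tolerance is `1e−3` years; intervals are capped at `u_max` and floored at
0.05 years (≈ 2.5 weeks) — without a floor the interval rule can request
arbitrarily short gaps when the predicted risk sits between λ and κ at tiny
`u`.  Floor hits are counted on the trace.  The warm-up protocol takes
quarterly measurements to 0.5 years with no predictions; the last warm-up
visit doubles as the first decision visit.  The text description of the
conservative rule ("upper 95% confidence limit") is followed; the displayed
equation's literal probability direction reads inverted and was not used.
By default only HF-hospitalization risk triggers interruption; the
multi-endpoint rule is available by configuration.

## 6. Evaluation

The **optimal interruption time** is the first `t` with true conditional
window risk `CIF_1(t, t+Δ)/S(t) ≥ κ`, found by a 0.25-year bracketing grid
scan plus bisection to `1e−4` years.  A patient is **in need** if that time
precedes their observed event/censoring time; **accuracy** is the
percentage of in-need patients actually interrupted before their endpoint,
computed per iteration and summarized by median/IQR across iterations
(iterations with zero in-need patients contribute a missing value).
**Measurement rates** count post-warm-up visits per patient and per
patient-year, with follow-up measured from the warm-up end to the last
realized visit so that fixed q-yearly schedules score exactly 1/q — a
fixed-rate identity the tests assert.  **RMSE** compares realized and
optimal interruption times over patients having both; interruptions without
a defined optimal time (false alarms) are counted separately rather than
entering the RMSE.

Within an iteration all strategies see the same simulated truths, the same
fitted posterior and the same warm-up records (paired design); iterations
use independent child seeds spawned from the master seed, so results are
order-independent and exactly reproducible.

## 7. Numerical choices

* All hazard integrals use fixed-panel Gauss–Legendre rules (deterministic
  node placement → bit-reproducible results).  Defaults: 15 nodes on
  ≤ 0.5-year panels for truth-level quantities; wider panels (2.5–4 years,
  7 nodes) inside likelihood and prediction, where the integrand
  `exp(polynomial)` is extremely smooth — the marginal likelihood is
  invariant to panel width across 0.5–5 years to six decimals (checked
  during development via the suite's quadrature-agreement tests).
* The first panel of any integral starting at 0 uses Gauss–Jacobi with
  weight `t^(shape−1)`, which absorbs the Weibull baseline's algebraic
  behaviour at zero; plain Gauss–Legendre loses ~3 digits there for
  non-integer shapes.  Cumulative-hazard closed forms are reproduced to
  machine precision.
* Hazard at `t = 0` is defined by continuity: 0 for shape > 1,
  `exp(covariates)/scale` for shape = 1, and an error for shape < 1.
* Exponent clipping at 700 guards `exp` overflow; `S(t)` underflow in the
  conditioning of predictions raises a declared error rather than returning
  a silent 0/0.
* Ties and degenerate inputs: an empty prediction window returns exactly 0;
  `D = 0` pins random effects at zero; zero total hazard yields guaranteed
  administrative censoring.

## 8. Problem sizes in the shipped runs

The test suite uses reduced cohorts (12–150 training subjects) and reduced
Monte-Carlo budgets chosen as the smallest sizes at which each property is
informative.  `scripts/acceptance.py` runs the study at the design cohort
size (381/50) with 4 well-specified and 3 misspecified iterations and the
reduced prediction budgets above; medians over so few iterations carry
visible Monte-Carlo spread, which is why the script reports medians rather
than individual iterations.  A full-scale run (hundreds of iterations,
default budgets) is a matter of the same configuration with larger
`n_iterations`, left to the user's hardware budget.

## 9. Known limitations

* The fast posterior is a Laplace approximation twice over (random effects
  and θ); skewness of the true posterior — most visible in the weakly
  identified cause-2 (14-event) stratum — is not captured.  The `emcee`
  mode exists for exact-posterior experiments at a much higher cost.
* Fitted baselines are Weibull, matching the generative truth; spline
  baselines of the original fitted model are not reproduced.
* `D`, `μ_maggic`, `σ_maggic` and the calibration horizon are assumed, not
  published; headline metric *levels* (accuracy, rates) shift with these
  choices even though the qualitative strategy ranking is stable across the
  settings exercised in the tests.
* Accuracy levels here are generally higher than a real cohort would give:
  with slowly drifting linear trajectories and administrative 20-year
  follow-up, most in-need patients are eventually caught by any schedule;
  discrimination between schedules shows mainly in measurement cost and
  interruption-time error.
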