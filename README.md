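# jmsched

Risk-profile based adaptive scheduling of longitudinal biomarker
measurements under competing risks.

Patients with stable chronic heart failure are monitored at regular clinic
visits where circulating markers such as NT-proBNP and troponin T are
measured; when the predicted short-term risk of disease aggravation crosses
a clinical threshold, monitoring is interrupted and therapy adjusted.  Fixed
visit intervals waste measurements on stable patients and can react too
slowly for deteriorating ones.  `jmsched` implements an adaptive
alternative — schedule the next visit where the *predicted* cumulative risk
reaches a tolerated limit — together with everything needed to evaluate it
against fixed schedules in simulation: a multivariate joint model for
longitudinal biomarkers and competing events, Monte-Carlo dynamic risk
prediction, the interval-optimizing scheduler, a calibrated synthetic-cohort
generator, and the full simulation-study driver.

It is aimed at biostatisticians studying personalized monitoring/screening
policies, and anyone needing a self-contained competing-risks joint-model
simulation bench.

## Model

Each biomarker (log scale) follows a linear mixed model

```
y_ip(t) = η_ip(t) + ε_ip,   η_ip(t) = (β_p0 + b_ip0) + (β_p1 + b_ip1) t,
ε_ip ~ N(0, σ_p²),          b_i ~ N(0, D),
```

and the cause-specific hazard of event k ∈ {1 = HF hospitalization,
2 = all-cause mortality} is

```
h_ik(t) = h_k0(t) · exp( γ_k · maggic_i + α_k1 η_i,NT-proBNP(t) + α_k2 η_i,troponin(t) ),
```

with Weibull baselines h_k0.  For a patient event-free at time t with
biomarker history Ỹ_i(t), the dynamic cumulative incidence

```
π_ik(t, s) = Pr(T*_ik < s | T* > t, Ỹ_i(t), D_n)
           = ∫ [CIF_k(t,s)/S(t)] · p(b | T* > t, Ỹ_i(t); θ) · p(θ | D_n) db dθ
```

is estimated by Monte Carlo over posterior draws of θ and conditional draws
of b.  The adaptive rule schedules the next visit after

```
u_opt(t) = { u ∈ (0, u_max] : π̂_ik(t, t+u) = λ },
```

interrupting monitoring as soon as π̂_ik(t, t+Δ) ≥ κ (defaults λ = 1%,
κ = 10%, Δ = u_max = 1 year).  A conservative variant solves the same
equation for the upper 97.5% posterior quantile of the risk, and a
multi-endpoint variant takes the minimum of per-cause intervals.

## Worked example

```python
import numpy as np
from jmsched import (McConfig, McmcConfig, ModelSpec, PatientHistory,
                     SimulationConfig, default_params, fit_joint_model,
                     generate_dataset, predict_cif)

params = default_params()                      # published generative values
sim = SimulationConfig(n_train=120, n_test=5)  # reduced cohort for the demo
rng = np.random.default_rng(7)

data = generate_dataset(params, sim, rng)
posterior = fit_joint_model(
    data.train_longitudinal, data.train_survival,
    ModelSpec.from_params(params),
    McmcConfig(method="laplace", maxiter=60, n_draws=200), rng)

alpha = {t.outcome_name: t.coefficient
         for t in posterior.map_params.causes[0].association_terms}
print(f"posterior-mode associations (HF hospitalization): "
      f"troponin {alpha['log_troponin']:.3f}, "
      f"NT-proBNP {alpha['log_ntprobnp']:.3f}")

patient = data.test_truths[0]
history = PatientHistory(
    patient.subject_id,
    data.test_warmup_longitudinal.query("subject_id == @patient.subject_id"),
    patient.baseline_covariates, t=0.5)
risk = predict_cif(posterior, history, cause=1, s=1.5, rng=rng,
                   mc_config=McConfig(n_theta=64, n_b=4))
print(f"1-year HF-hospitalization risk at t=0.5y: "
      f"{risk.point_estimate:.3f} (95% CI {risk.lower95:.3f}-{risk.upper95:.3f})")
```

Output:

```
posterior-mode associations (HF hospitalization): troponin 0.411, NT-proBNP 1.218
1-year HF-hospitalization risk at t=0.5y: 0.021 (95% CI 0.007-0.049)
```

The generative association coefficients were 0.508 (troponin) and 0.996
(NT-proBNP); a 120-patient training cohort recovers them to within the
posterior uncertainty.  The prediction says this particular warm-up history
implies about a 2% one-year hospitalization risk — far below the κ = 10%
interruption threshold, so monitoring would continue, with the next visit
scheduled where the predicted cumulative risk reaches λ = 1%.

## Command line

Every stage is also exposed as a CLI over long-format CSV files:

```bash
jmsched simulate --seed 1 --out-dir simdata --calibrate
jmsched fit --longitudinal simdata/train_longitudinal.csv \
            --survival simdata/train_survival.csv --out posterior.csv
jmsched predict --posterior posterior.csv --history patient.csv \
                --maggic 22 --t 0.5 --cause 1 --horizon 1
jmsched schedule --posterior posterior.csv --truths simdata/test_latent_truth.csv \
                 --strategy risk_based --out traces.csv
jmsched evaluate --seed 1 --out-dir results
```

`jmsched evaluate` runs the full study — simulate a cohort, refit the joint
model, run annual / semi-annual / quarterly / risk-based / conservative
strategies on the same test patients, score measurement rates, interruption
accuracy and interruption-time RMSE — and writes per-iteration metrics,
median/IQR aggregates and boxplot figures.

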