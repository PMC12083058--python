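# Default experiment configuration.
#
# Provenance of every default is flagged below under `provenance:` --
# "paper" values are the published Bio-SHiFT joint-model estimates and study
# design constants; "assumed" values are unpublished quantities chosen as
# realistic defaults for a stable heart-failure cohort (see docs/methods.md);
# "calibrated" values are outputs of the Weibull baseline calibration under
# the assumed defaults (recomputed when study.calibrate is true).

model:
  longitudinal:
    - outcome_name: log_troponin
      fixed_effects: [2.8788, 0.0537]
      residual_sd: 0.2114
      fixed_design: [0, 1]
      random_design: [0, 1]
    - outcome_name: log_ntprobnp
      fixed_effects: [4.6624, 0.0472]
      residual_sd: 0.4105
      fixed_design: [0, 1]
      random_design: [0, 1]
  # random-effect order: troponin-intercept, troponin-slope,
  # ntprobnp-intercept, ntprobnp-slope (row-major)
  re_covariance:
    - [0.302500, 0.006600, 0.220000, 0.005500]
    - [0.006600, 0.003600, 0.004800, 0.001800]
    - [0.220000, 0.004800, 0.640000, 0.016000]
    - [0.005500, 0.001800, 0.016000, 0.010000]
  causes:
    - cause_code: 1          # HF hospitalization
      weibull_shape: 1.0
      weibull_scale: 51646.6
      baseline_coefficients: [0.0112]
      association_terms:
        - {outcome_name: log_troponin, form: value, coefficient: 0.5080}
        - {outcome_name: log_ntprobnp, form: value, coefficient: 0.9957}
    - cause_code: 2          # all-cause mortality
      weibull_shape: 1.0
      weibull_scale: 39251.3
      baseline_coefficients: [-0.0088]
      association_terms:
        - {outcome_name: log_troponin, form: value, coefficient: 0.4766}
        - {outcome_name: log_ntprobnp, form: value, coefficient: 0.7170}
  baseline_covariate_names: [maggic]

simulation:
  n_train: 381
  n_test: 50
  maggic_mean: 22.0
  maggic_sd: 6.0
  censor_time: 20.0
  scenario: well_specified
  training_visit_interval: 0.25
  max_followup_train: 20.0
  test_warmup_visits: [0.0, 0.25, 0.5]
  calibration_horizon: 10.0
  calibration_n: 4000
  calibration_tol: 0.01
  misspec_residual_outcome: log_ntprobnp
  misspec_tv_outcome: log_troponin
  misspec_tv_cause: 1
  misspec_tv_coefficient: [0.5, 0.1]

strategies:
  - {kind: fixed, name: annual, fixed_interval: 1.0}
  - {kind: fixed, name: semiannual, fixed_interval: 0.5}
  - {kind: fixed, name: quarterly, fixed_interval: 0.25}
  - {kind: risk_based, name: risk_based}
  - {kind: risk_based_conservative, name: conservative}

strategy_defaults:
  lambda_: 0.01
  kappa: 0.10
  delta: 1.0
  u_max: 1.0
  warmup_visits: [0.0, 0.25, 0.5]
  interrupt_cause: 1
  min_interval: 0.05

study:
  n_iterations: 10
  target_event_fractions: [0.23622047244094488, 0.03674540682414698]  # 90/381, 14/381
  calibrate: true

mcmc:
  method: laplace
  n_draws: 200
  chains: 2
  warmup: 500
  retained: 500
  quad_panel: 4.0
  quad_nodes: 7
  maxiter: 80

mc:
  n_theta: 200
  n_b: 5
  mh_steps: 50
  quad_width: 0.5
  quad_nodes: 7
  cif_nodes: 8

master_seed: 20230381
output_dir: results

provenance:
  model.longitudinal.fixed_effects: paper
  model.longitudinal.residual_sd: paper
  model.re_covariance: assumed
  model.causes.weibull_shape: assumed
  model.causes.weibull_scale: calibrated
  model.causes.baseline_coefficients: paper
  model.causes.association_terms: paper
  simulation.n_train: paper
  simulation.n_test: paper
  simulation.maggic_mean: assumed
  simulation.maggic_sd: assumed
  simulation.censor_time: paper
  simulation.training_visit_interval: paper
  simulation.calibration_horizon: assumed
  simulation.misspec_tv_coefficient: paper
  simulation.misspec_residual_outcome: paper
  strategy_defaults.lambda_: paper
  strategy_defaults.kappa: paper
  strategy_defaults.delta: paper
  strategy_defaults.u_max: paper
  strategy_defaults.warmup_visits: paper
  strategy_defaults.min_interval: assumed
  study.target_event_fractions: paper
  mcmc: assumed
  mc: assumed
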