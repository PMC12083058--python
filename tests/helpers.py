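"""Shared constructors for toy model configurations used across the suite."""

from __future__ import annotations

import numpy as np

from jmsched import (AssociationTerm, CauseSpec, JointModelParams,
                     LongitudinalSpec, SubjectTruth)

TROPONIN = LongitudinalSpec("log_troponin", (2.8788, 0.0537), 0.2114)
NTPROBNP = LongitudinalSpec("log_ntprobnp", (4.6624, 0.0472), 0.4105)

D_DIAG = np.diag([0.55, 0.06, 0.80, 0.10]) ** 2


def toy_params(causes, re_covariance=None, covariates=()):
    """Two standard biomarker submodels with arbitrary cause specs."""
    D = D_DIAG if re_covariance is None else np.asarray(re_covariance)
    return JointModelParams(longitudinal=(TROPONIN, NTPROBNP),
                            re_covariance=D, causes=tuple(causes),
                            baseline_covariate_names=tuple(covariates))


def constant_hazard_params(rates, re_covariance=None):
    """K causes with constant hazards (Weibull shape 1, no covariates or
    association); rate_k = 1/scale_k."""
    causes = [CauseSpec(k + 1, 1.0, 1.0 / r) for k, r in enumerate(rates)]
    return toy_params(causes, re_covariance=re_covariance)


def zero_effect_subject(n_cov: int = 0) -> SubjectTruth:
    return SubjectTruth("s0", np.zeros(4), np.zeros(n_cov))


def value_assoc_cause(code, shape, scale, alpha_tn=0.0, alpha_nt=0.0,
                      gamma=()):
    terms = []
    if alpha_tn:
        terms.append(AssociationTerm("log_troponin", "value", alpha_tn))
    if alpha_nt:
        terms.append(AssociationTerm("log_ntprobnp", "value", alpha_nt))
    return CauseSpec(code, shape, scale, tuple(gamma), tuple(terms))
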