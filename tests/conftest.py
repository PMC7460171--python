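"""Shared fixtures.

The heavyweight fixture is ``replicate_fits``: one hundred seeded synthetic
studies at the default size (n = 555), each fitted with the full joint
t-copula regression and with the independence-assuming per-outcome GLMs.
Several tests (Wald coverage, 3-SE recovery, AIC dominance) consume the same
replicates, so they are computed once per session.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import copulareg as cr
from copulareg.simulate import (
    DEFAULT_CONFIG,
    DEFAULT_IAT_COVARIATES,
    DEFAULT_SAS_COVARIATES,
)

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")


FULL_SPEC = cr.RegressionSpec(
    "lognormal", "gamma",
    DEFAULT_IAT_COVARIATES, DEFAULT_SAS_COVARIATES,
    "student_t", 3.0, "fixed",
)


def truth_vector(config=DEFAULT_CONFIG) -> np.ndarray:
    """Generative truth ordered like the fitted parameter vector."""
    t = config.truth()
    return np.array(
        list(t["beta1"].values()) + list(t["beta2"].values())
        + [t["sigma1"], t["sigma2"], t["rho"]]
    )


@pytest.fixture(scope="session")
def replicate_fits():
    """100 seeded default-study replicates: joint fit + independent GLM AICs."""
    truth = truth_vector()
    out = []
    for rep in range(100):
        study = cr.generate_study(DEFAULT_CONFIG, seed=10_000 + rep)
        fit = cr.fit_copula_regression(FULL_SPEC, study.data)
        glm = cr.fit_independent_margins(
            cr.IndependentSpec("GLM", "lognormal", "gamma",
                               DEFAULT_IAT_COVARIATES, DEFAULT_SAS_COVARIATES),
            study.data,
        )
        out.append(
            {
                "params": fit.params,
                "se": fit.se,
                "se_available": fit.se_available,
                "copula_aic": fit.aic,
                "independent_aic": glm.total_aic,
                "loglik": fit.loglik,
                "init_loglik": fit.init_loglik,
            }
        )
    return {"truth": truth, "fits": out}
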