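"""Joint copula regression: likelihood identities, fitting, Wald inference."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import special

import copulareg as cr
from copulareg.errors import DomainError, InferenceError, PredictionError
from copulareg.regression import CopulaRegressionFit, _JointModel, _margin_logpdf
from copulareg.simulate import GenerativeConfig


def small_study(n=800, seed=21, rho=0.364):
    cfg = GenerativeConfig(
        n=n,
        beta1={"BAI": 0.0089, "GENDER": -0.0929},
        beta2={"AQ": 0.0049, "WESH": 0.0251},
        rho=rho,
    )
    return cfg, cr.generate_study(cfg, seed=seed)


SMALL_SPEC = cr.RegressionSpec(
    "lognormal", "gamma", ("BAI", "GENDER"), ("AQ", "WESH"), "student_t", 3.0, "fixed"
)


def dummy_fit(rho=0.0, se_rho_z=0.1, estimate=0.0089, se_est=0.0019):
    """Hand-assembled fit object for pure-inference unit tests."""
    spec = cr.RegressionSpec("lognormal", "gamma", ("BAI",), ("AQ",),
                             "student_t", 3.0, "fixed")
    se_rho = se_rho_z * (1.0 - rho * rho)
    return CopulaRegressionFit(
        spec=spec,
        beta1=np.array([3.4, estimate]),
        beta2=np.array([4.3, 0.0]),
        sigma1=0.35, sigma2=8.0, rho=rho, df=3.0,
        loglik=-100.0, aic=214.0, n=500,
        se=np.array([0.1, se_est, 0.1, 0.001, 0.01, 0.5, se_rho]),
        param_names=["margin1:Intercept", "margin1:BAI", "margin2:Intercept",
                     "margin2:AQ", "margin1:dispersion", "margin2:dispersion",
                     "copula:rho"],
        year_center=None, init_loglik=-101.0, n_clamped=0, converged=True,
    )


class TestJointLoglik:
    def test_single_observation_hand_computed(self):
        """One subject, intercept-only normal margins, Gaussian copula:
        two normal log-densities plus the closed-form copula log-density."""
        data = pd.DataFrame({"y1": [31.0], "y2": [75.0]})
        spec = cr.RegressionSpec("normal", "normal", (), (), "gaussian", None, "fixed")
        mu1, s1, mu2, s2, rho = 33.0, 12.0, 80.0, 25.0, 0.4
        # layout: beta1, beta2, dispersion1, dispersion2, rho
        got = cr.joint_loglik(spec, [mu1, mu2, s1, s2, rho], data)

        def norm_logpdf(y, m, s):
            return -0.5 * math.log(2 * math.pi * s * s) - (y - m) ** 2 / (2 * s * s)

        z1 = (31.0 - mu1) / s1
        z2 = (75.0 - mu2) / s2
        lc = -0.5 * math.log(1 - rho**2) - (
            rho**2 * (z1**2 + z2**2) - 2 * rho * z1 * z2
        ) / (2 * (1 - rho**2))
        expected = norm_logpdf(31.0, mu1, s1) + norm_logpdf(75.0, mu2, s2) + lc
        assert got == pytest.approx(expected, abs=1e-12)

    def test_independence_factorization_exact(self):
        """Gaussian copula at rho = 0 reduces to the sum of the two marginal
        regression log-likelihoods at machine precision."""
        _, study = small_study(n=300)
        data = study.data
        spec = cr.RegressionSpec("lognormal", "gamma", ("BAI",), ("AQ",),
                                 "gaussian", None, "fixed")
        params = np.array([3.4, 0.01, 4.2, 0.005, 0.35, 8.0, 0.0])
        got = cr.joint_loglik(spec, params, data)
        m = _JointModel(spec, data)
        margins = float(
            np.sum(_margin_logpdf("lognormal", m.y1, m.X1 @ params[:2], 0.35))
            + np.sum(_margin_logpdf("gamma", m.y2, m.X2 @ params[2:4], 8.0))
        )
        assert got == margins  # exact equality: the copula term is skipped

    def test_location_equivariance_normal_margin(self):
        _, study = small_study(n=200)
        data = study.data.copy()
        spec = cr.RegressionSpec("normal", "gamma", ("BAI",), ("AQ",),
                                 "gaussian", None, "fixed")
        params = np.array([33.0, 0.1, 4.2, 0.005, 12.0, 8.0, 0.3])
        base = cr.joint_loglik(spec, params, data)
        shifted = data.copy()
        shifted["y1"] = shifted["y1"] + 7.0
        params2 = params.copy()
        params2[0] += 7.0
        assert cr.joint_loglik(spec, params2, shifted) == pytest.approx(base, abs=1e-9)

    def test_wrong_length_raises(self):
        _, study = small_study(n=100)
        with pytest.raises(Exception):
            cr.joint_loglik(SMALL_SPEC, np.zeros(3), study.data)


class TestFit:
    def test_likelihood_ascent_and_determinism(self):
        _, study = small_study()
        fit1 = cr.fit_copula_regression(SMALL_SPEC, study.data)
        fit2 = cr.fit_copula_regression(SMALL_SPEC, study.data)
        assert fit1.loglik >= fit1.init_loglik
        assert fit1.loglik == fit2.loglik
        np.testing.assert_array_equal(fit1.params, fit2.params)
        assert fit1.aic == pytest.approx(-2 * fit1.loglik + 2 * SMALL_SPEC.n_params)

    def test_null_dependence_rho_near_zero_and_aic_gap(self):
        """Data generated under independence: rho estimate small and the
        copula model cannot beat the independent fit by more than chance."""
        cfg, study = small_study(n=1500, seed=33, rho=0.0)
        spec = cr.RegressionSpec("lognormal", "gamma", ("BAI", "GENDER"),
                                 ("AQ", "WESH"), "gaussian", None, "fixed")
        fit = cr.fit_copula_regression(spec, study.data)
        glm = cr.fit_independent_margins(
            cr.IndependentSpec("GLM", "lognormal", "gamma",
                               ("BAI", "GENDER"), ("AQ", "WESH")),
            study.data,
        )
        assert abs(fit.rho) < 3.0 / math.sqrt(1500) * 1.5
        gap = fit.aic - glm.total_aic
        assert -4.0 < gap <= 2.0 + 1e-9

    def test_standardization_invariance(self):
        """Standardizing covariates and back-transforming the coefficients
        reproduces the raw-scale estimates."""
        _, study = small_study(n=600, seed=40)
        data = study.data
        fit_raw = cr.fit_copula_regression(SMALL_SPEC, data)

        std = data.copy()
        stats1 = {}
        for c in ("BAI", "GENDER", "AQ", "WESH"):
            m, s = float(data[c].mean()), float(data[c].std())
            std[c] = (data[c] - m) / s
            stats1[c] = (m, s)
        fit_std = cr.fit_copula_regression(SMALL_SPEC, std)

        def back(beta, covs):
            slopes = np.array([beta[1 + i] / stats1[c][1] for i, c in enumerate(covs)])
            intercept = beta[0] - sum(
                beta[1 + i] * stats1[c][0] / stats1[c][1] for i, c in enumerate(covs)
            )
            return np.concatenate([[intercept], slopes])

        np.testing.assert_allclose(
            back(fit_std.beta1, ("BAI", "GENDER")), fit_raw.beta1, atol=1e-6
        )
        np.testing.assert_allclose(
            back(fit_std.beta2, ("AQ", "WESH")), fit_raw.beta2, atol=1e-6
        )
        assert fit_std.rho == pytest.approx(fit_raw.rho, abs=1e-6)

    def test_collinear_design_flags_se_unavailable(self):
        _, study = small_study(n=300, seed=50)
        data = study.data.copy()
        data["BAI2"] = data["BAI"] * 1.0  # exact duplicate column
        spec = cr.RegressionSpec("lognormal", "gamma", ("BAI", "BAI2"), ("AQ",),
                                 "student_t", 3.0, "fixed")
        fit = cr.fit_copula_regression(spec, data)
        assert not fit.se_available
        with pytest.raises(InferenceError):
            cr.wald_inference(fit)
        with pytest.raises(InferenceError):
            cr.correlation_ci(fit)

    def test_wald_coverage_on_default_model(self, replicate_fits):
        """Aggregated over 100 default-study replicates, the per-parameter
        95% Wald intervals cover the generative truth at nominal rate."""
        truth = replicate_fits["truth"]
        covered = total = 0
        for rep in replicate_fits["fits"]:
            if not rep["se_available"]:
                continue
            lo = rep["params"] - 1.96 * rep["se"]
            hi = rep["params"] + 1.96 * rep["se"]
            covered += int(np.sum((truth >= lo) & (truth <= hi)))
            total += truth.size
        assert total >= 90 * truth.size
        assert covered / total >= 0.94

    def test_ascent_across_replicates(self, replicate_fits):
        for rep in replicate_fits["fits"]:
            assert rep["loglik"] >= rep["init_loglik"] - 1e-9


class TestInference:
    def test_wald_example_values(self):
        tab = cr.wald_inference(dummy_fit())
        row = tab[tab.parameter == "margin1:BAI"].iloc[0]
        assert row.z == pytest.approx(0.0089 / 0.0019, rel=1e-12)
        assert row.p_value < 1e-4
        zero = tab[tab.parameter == "margin2:AQ"].iloc[0]
        assert zero.p_value == 1.0

    def test_p_values_match_erfc_oracle(self):
        tab = cr.wald_inference(dummy_fit())
        for _, row in tab.iterrows():
            ref = math.erfc(abs(row.z) / math.sqrt(2.0))
            assert row.p_value == pytest.approx(ref, abs=1e-10)

    def test_correlation_ci_example(self):
        lo, hi = cr.correlation_ci(dummy_fit(rho=0.0, se_rho_z=0.1), 0.95)
        zcrit = float(special.ndtri(0.975))
        assert lo == pytest.approx(-math.tanh(zcrit * 0.1), abs=1e-9)
        assert hi == pytest.approx(math.tanh(zcrit * 0.1), abs=1e-9)
        assert lo == pytest.approx(-0.194, abs=1e-3)

    def test_correlation_ci_bounded_near_one(self):
        lo, hi = cr.correlation_ci(dummy_fit(rho=0.99, se_rho_z=0.2))
        assert lo < 0.99 < hi < 1.0

    def test_ci_width_shrinks_with_n(self):
        widths = []
        for n in (300, 1200, 4800):
            _, study = small_study(n=n, seed=60)
            fit = cr.fit_copula_regression(SMALL_SPEC, study.data)
            lo, hi = fit.rho_ci
            assert lo < fit.rho < hi
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]

    def test_invalid_level_raises(self):
        with pytest.raises(DomainError):
            cr.correlation_ci(dummy_fit(), 1.5)


class TestConditionalMean:
    def test_lognormal_intercept_only(self):
        fit = dummy_fit()
        fit.spec = cr.RegressionSpec("lognormal", "gamma", (), (),
                                     "student_t", 3.0, "fixed")
        fit.beta1 = np.array([3.464])
        fit.beta2 = np.array([math.log(80.0)])
        fit.sigma1 = 0.346
        m1, m2 = cr.conditional_mean(fit, {})
        assert m1 == pytest.approx(math.exp(3.464 + 0.346**2 / 2))
        assert m2 == pytest.approx(80.0)

    def test_normal_margin_linear_predictor(self):
        fit = dummy_fit()
        fit.spec = cr.RegressionSpec("normal", "gamma", ("X",), (),
                                     "student_t", 3.0, "fixed")
        fit.beta1 = np.array([1.0, 2.0])
        fit.beta2 = np.array([math.log(80.0)])
        m1, _ = cr.conditional_mean(fit, {"X": 0.5})
        assert m1 == pytest.approx(2.0)

    def test_missing_covariate_raises(self):
        fit = dummy_fit()
        with pytest.raises(PredictionError):
            cr.conditional_mean(fit, {"BAI": 3.0})  # AQ missing
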