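"""Joint maximum-likelihood copula regression for two outcomes.

The model couples two marginal regressions through a bivariate copula. For
subject i with covariate rows x_i1, x_i2 and outcomes (y_i1, y_i2):

* normal margin:     y_ij ~ N(x_ij' beta_j, sigma_j)
* lognormal margin:  log y_ij ~ N(x_ij' beta_j, sigma_j)
* gamma margin:      y_ij ~ Gamma(mean = exp(x_ij' beta_j), shape alpha_j)

and the joint log-likelihood per Sklar's construction is

    sum_i [ log c(F1(y_i1), F2(y_i2); theta) + log f1(y_i1) + log f2(y_i2) ]

where c is the Gaussian or t copula density and theta = (rho[, nu]). The
lognormal and gamma margins use the canonical log link, so coefficients are
multiplicative effects on the outcome scale.

Estimation maximizes the joint likelihood by BFGS on unconstrained
transforms (log dispersions, atanh rho, log(nu-2)) with analytic gradients
(margin scores and copula density derivatives in closed form; the two
partials without closed forms -- the gamma-shape and t-df derivatives of the
probability integral transform -- by central differences). The optimizer is
warm-started by the two-stage inference-functions-for-margins route: fit
each margin independently, map the outcomes through the fitted marginal CDFs,
and fit the copula to those transforms. Standard errors come from the
inverse observed information (Jacobian of the analytic score at the optimum,
on the original parameter scale); Wald p-values use the normal reference.
A column named YEAR is centered at its sample mean before fitting for
numerical conditioning; the center is stored on the fit for prediction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

from .copulas import COPULA_FAMILIES, DEFAULT_DF_GRID, _logdensity_raw, fit_copula_pseudo_mle
from .errors import ConfigurationError, DomainError, FitError, InferenceError, PredictionError

logger = logging.getLogger(__name__)

REGRESSION_FAMILIES = ("normal", "lognormal", "gamma")

#: probability-integral transforms are clamped to this band before the copula
PIT_CLAMP = 1e-10

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


@dataclass(frozen=True)
class RegressionSpec:
    """Declaration of a bivariate copula regression model.

    ``covariates1``/``covariates2`` name the dataset columns entering each
    margin's design matrix (an intercept is always included; empty lists give
    intercept-only margins). ``df_mode`` is ``"fixed"`` (degrees of freedom
    held at ``df``) or ``"estimated"``.
    """

    margin1_family: str
    margin2_family: str
    covariates1: tuple[str, ...]
    covariates2: tuple[str, ...]
    copula_family: str = "student_t"
    df: float | None = 3.0
    df_mode: str = "fixed"

    def __post_init__(self):
        for fam in (self.margin1_family, self.margin2_family):
            if fam not in REGRESSION_FAMILIES:
                raise ConfigurationError(
                    f"margin family {fam!r} unsupported; expected one of {REGRESSION_FAMILIES}"
                )
        if self.copula_family not in COPULA_FAMILIES:
            raise ConfigurationError(f"unknown copula family {self.copula_family!r}")
        if self.df_mode not in ("fixed", "estimated"):
            raise ConfigurationError("df_mode must be 'fixed' or 'estimated'")
        if self.copula_family == "student_t" and self.df_mode == "fixed":
            if self.df is None or self.df <= 2:
                raise ConfigurationError("fixed t-copula degrees of freedom must exceed 2")
        object.__setattr__(self, "covariates1", tuple(self.covariates1))
        object.__setattr__(self, "covariates2", tuple(self.covariates2))

    @property
    def n_params(self) -> int:
        k = (1 + len(self.covariates1)) + (1 + len(self.covariates2)) + 2 + 1
        if self.copula_family == "student_t" and self.df_mode == "estimated":
            k += 1
        return k

    def drop(self, margin: int, covariate: str) -> "RegressionSpec":
        """Spec with one covariate removed from one margin (1 or 2)."""
        if margin == 1:
            if covariate not in self.covariates1:
                raise ConfigurationError(f"{covariate!r} not in margin-1 covariates")
            return replace(self, covariates1=tuple(c for c in self.covariates1 if c != covariate))
        if margin == 2:
            if covariate not in self.covariates2:
                raise ConfigurationError(f"{covariate!r} not in margin-2 covariates")
            return replace(self, covariates2=tuple(c for c in self.covariates2 if c != covariate))
        raise ConfigurationError("margin must be 1 or 2")


@dataclass
class CopulaRegressionFit:
    """Joint MLE result: coefficients, dispersions, copula parameter, inference."""

    spec: RegressionSpec
    beta1: np.ndarray
    beta2: np.ndarray
    sigma1: float
    sigma2: float
    rho: float
    df: float | None
    loglik: float
    aic: float
    n: int
    se: np.ndarray | None
    param_names: list[str]
    year_center: float | None
    init_loglik: float
    n_clamped: int
    converged: bool
    se_available: bool = field(init=False)

    def __post_init__(self):
        self.se_available = self.se is not None

    @property
    def params(self) -> np.ndarray:
        """Full original-scale parameter vector (matches ``param_names``)."""
        out = np.concatenate([self.beta1, self.beta2, [self.sigma1, self.sigma2, self.rho]])
        if self.spec.copula_family == "student_t" and self.spec.df_mode == "estimated":
            out = np.append(out, self.df)
        return out

    @property
    def rho_ci(self) -> tuple[float, float]:
        return correlation_ci(self, 0.95)


def design_matrix(data: pd.DataFrame, covariates: Sequence[str], year_center: float | None):
    """Intercept-first design matrix; YEAR centered at ``year_center``."""
    n = len(data)
    cols = [np.ones(n)]
    for c in covariates:
        if c not in data.columns:
            raise ConfigurationError(f"covariate {c!r} missing from data")
        v = np.asarray(data[c], dtype=float)
        if c == "YEAR" and year_center is not None:
            v = v - year_center
        cols.append(v)
    return np.column_stack(cols)


def _year_center(data: pd.DataFrame, spec: RegressionSpec) -> float | None:
    if "YEAR" in spec.covariates1 or "YEAR" in spec.covariates2:
        return float(np.mean(np.asarray(data["YEAR"], dtype=float)))
    return None


# ---------------------------------------------------------------------------
# margin likelihood pieces and scores
# ---------------------------------------------------------------------------

def _margin_logpdf(family: str, y, eta, disp):
    if family == "normal":
        return -math.log(disp) - _LOG_SQRT_2PI - (y - eta) ** 2 / (2.0 * disp * disp)
    if family == "lognormal":
        ly = np.log(y)
        return -math.log(disp) - _LOG_SQRT_2PI - (ly - eta) ** 2 / (2.0 * disp * disp) - ly
    # gamma with log link: mean exp(eta), shape alpha = disp, rate = alpha/mean
    return (
        disp * (math.log(disp) - eta)
        - special.gammaln(disp)
        + (disp - 1.0) * np.log(y)
        - disp * y * np.exp(-eta)
    )


def _margin_cdf(family: str, y, eta, disp):
    if family == "normal":
        return special.ndtr((y - eta) / disp)
    if family == "lognormal":
        return special.ndtr((np.log(y) - eta) / disp)
    return special.gammainc(disp, disp * y * np.exp(-eta))


def _margin_pieces(family: str, y, eta, disp):
    """Log-density, its scores, the PIT and the PIT's parameter derivatives.

    Returns (lf, dlf_deta, dlf_ddisp, u, du_deta, du_ddisp), all per
    observation. The gamma-shape derivative of the regularized incomplete
    gamma has no closed form and is taken by central differences.
    """
    if family in ("normal", "lognormal"):
        v = y if family == "normal" else np.log(y)
        z = (v - eta) / disp
        phi = np.exp(-0.5 * z * z) / math.sqrt(2.0 * math.pi)
        lf = -math.log(disp) - _LOG_SQRT_2PI - 0.5 * z * z
        if family == "lognormal":
            lf = lf - v
        dlf_deta = z / disp
        dlf_ddisp = (z * z - 1.0) / disp
        u = special.ndtr(z)
        du_deta = -phi / disp
        du_ddisp = -z * phi / disp
        return lf, dlf_deta, dlf_ddisp, u, du_deta, du_ddisp
    # gamma
    alpha = disp
    t = alpha * y * np.exp(-eta)
    lf = (
        alpha * (math.log(alpha) - eta)
        - special.gammaln(alpha)
        + (alpha - 1.0) * np.log(y)
        - t
    )
    dlf_deta = t - alpha
    dlf_ddisp = math.log(alpha) + 1.0 - special.digamma(alpha) + np.log(y) - eta - t / alpha
    u = special.gammainc(alpha, t)
    # d/dt P(alpha, t) = t^(alpha-1) e^-t / Gamma(alpha); dt/deta = -t
    log_g = (alpha - 1.0) * np.log(t) - t - special.gammaln(alpha)
    du_deta = -np.exp(log_g + np.log(t))
    h = 1e-6 * (1.0 + alpha)
    du_ddisp = (
        special.gammainc(alpha + h, (alpha + h) * y * np.exp(-eta))
        - special.gammainc(alpha - h, (alpha - h) * y * np.exp(-eta))
    ) / (2.0 * h)
    return lf, dlf_deta, dlf_ddisp, u, du_deta, du_ddisp


# ---------------------------------------------------------------------------
# copula log-density derivatives (closed form in u and rho)
# ---------------------------------------------------------------------------

def _copula_pieces(family: str, rho: float, df, u1, u2):
    """(lc, dlc_du1, dlc_du2, dlc_drho) per observation."""
    om = 1.0 - rho * rho
    if family == "gaussian":
        z1 = special.ndtri(u1)
        z2 = special.ndtri(u2)
        lc = -0.5 * math.log(om) - (
            rho * rho * (z1 * z1 + z2 * z2) - 2.0 * rho * z1 * z2
        ) / (2.0 * om)
        dlc_dz1 = -(rho * rho * z1 - rho * z2) / om
        dlc_dz2 = -(rho * rho * z2 - rho * z1) / om
        phi1 = np.exp(-0.5 * z1 * z1) / math.sqrt(2.0 * math.pi)
        phi2 = np.exp(-0.5 * z2 * z2) / math.sqrt(2.0 * math.pi)
        A = z1 * z1 + z2 * z2
        B = z1 * z2
        N = rho * rho * A - 2.0 * rho * B
        dlc_drho = rho / om - ((2.0 * rho * A - 2.0 * B) * om + 2.0 * rho * N) / (2.0 * om * om)
        return lc, dlc_dz1 / phi1, dlc_dz2 / phi2, dlc_drho
    # student t
    x1 = special.stdtrit(df, u1)
    x2 = special.stdtrit(df, u2)
    qnum = x1 * x1 - 2.0 * rho * x1 * x2 + x2 * x2
    Q = qnum / om
    wq = 1.0 + Q / df
    lc = (
        special.gammaln((df + 2.0) / 2.0)
        + special.gammaln(df / 2.0)
        - 2.0 * special.gammaln((df + 1.0) / 2.0)
        - 0.5 * math.log(om)
        - 0.5 * (df + 2.0) * np.log(wq)
        + 0.5 * (df + 1.0) * (np.log1p(x1 * x1 / df) + np.log1p(x2 * x2 / df))
    )
    dlc_dx1 = (
        -(df + 2.0) / (2.0 * df * wq) * (2.0 * x1 - 2.0 * rho * x2) / om
        + (df + 1.0) * x1 / (df + x1 * x1)
    )
    dlc_dx2 = (
        -(df + 2.0) / (2.0 * df * wq) * (2.0 * x2 - 2.0 * rho * x1) / om
        + (df + 1.0) * x2 / (df + x2 * x2)
    )
    log_ft = (
        special.gammaln((df + 1.0) / 2.0)
        - special.gammaln(df / 2.0)
        - 0.5 * math.log(df * math.pi)
    )
    f1 = np.exp(log_ft - 0.5 * (df + 1.0) * np.log1p(x1 * x1 / df))
    f2 = np.exp(log_ft - 0.5 * (df + 1.0) * np.log1p(x2 * x2 / df))
    dQ_drho = (-2.0 * x1 * x2 + 2.0 * rho * Q) / om
    dlc_drho = rho / om - (df + 2.0) / (2.0 * df * wq) * dQ_drho
    return lc, dlc_dx1 / f1, dlc_dx2 / f2, dlc_drho


class _JointModel:
    """Precomputed designs + fast evaluation of the joint log-likelihood."""

    def __init__(self, spec: RegressionSpec, data: pd.DataFrame):
        self.spec = spec
        for col in ("y1", "y2"):
            if col not in data.columns:
                raise ConfigurationError(f"data must contain outcome column {col!r}")
        y1 = np.asarray(data["y1"], dtype=float)
        y2 = np.asarray(data["y2"], dtype=float)
        if np.any(~np.isfinite(y1)) or np.any(~np.isfinite(y2)):
            raise DomainError("outcomes contain missing values; apply complete-case filtering")
        if np.any(y1 <= 0) or np.any(y2 <= 0):
            raise DomainError("outcomes must be strictly positive")
        self.y1, self.y2 = y1, y2
        self.year_center = _year_center(data, spec)
        self.X1 = design_matrix(data, spec.covariates1, self.year_center)
        self.X2 = design_matrix(data, spec.covariates2, self.year_center)
        self.p1 = self.X1.shape[1]
        self.p2 = self.X2.shape[1]
        self.n = len(y1)
        self.estimate_df = spec.copula_family == "student_t" and spec.df_mode == "estimated"
        self.n_clamped = 0

    # -- parameter packing: original scale ------------------------------
    def unpack(self, params: np.ndarray):
        p1, p2 = self.p1, self.p2
        beta1 = params[:p1]
        beta2 = params[p1 : p1 + p2]
        sigma1, sigma2, rho = params[p1 + p2 : p1 + p2 + 3]
        df = params[p1 + p2 + 3] if self.estimate_df else self.spec.df
        return beta1, beta2, float(sigma1), float(sigma2), float(rho), df

    def param_names(self) -> list[str]:
        names = ["margin1:Intercept"] + [f"margin1:{c}" for c in self.spec.covariates1]
        names += ["margin2:Intercept"] + [f"margin2:{c}" for c in self.spec.covariates2]
        names += ["margin1:dispersion", "margin2:dispersion", "copula:rho"]
        if self.estimate_df:
            names.append("copula:df")
        return names

    def _invalid(self, sigma1, sigma2, rho, df) -> bool:
        if sigma1 <= 0 or sigma2 <= 0 or abs(rho) >= 1:
            return True
        return self.spec.copula_family == "student_t" and (df is None or df <= 2)

    def loglik(self, params: np.ndarray, count_clamped: bool = False) -> float:
        beta1, beta2, sigma1, sigma2, rho, df = self.unpack(np.asarray(params, dtype=float))
        if self._invalid(sigma1, sigma2, rho, df):
            return -np.inf
        eta1 = self.X1 @ beta1
        eta2 = self.X2 @ beta2
        ll = float(
            np.sum(_margin_logpdf(self.spec.margin1_family, self.y1, eta1, sigma1))
            + np.sum(_margin_logpdf(self.spec.margin2_family, self.y2, eta2, sigma2))
        )
        if not np.isfinite(ll):
            return -np.inf
        if rho != 0.0 or self.spec.copula_family == "student_t":
            u1 = _margin_cdf(self.spec.margin1_family, self.y1, eta1, sigma1)
            u2 = _margin_cdf(self.spec.margin2_family, self.y2, eta2, sigma2)
            if count_clamped:
                self.n_clamped = int(
                    np.sum((u1 < PIT_CLAMP) | (u1 > 1 - PIT_CLAMP))
                    + np.sum((u2 < PIT_CLAMP) | (u2 > 1 - PIT_CLAMP))
                )
            u1 = np.clip(u1, PIT_CLAMP, 1.0 - PIT_CLAMP)
            u2 = np.clip(u2, PIT_CLAMP, 1.0 - PIT_CLAMP)
            ll += float(np.sum(_logdensity_raw(self.spec.copula_family, rho, df, u1, u2)))
        return ll if np.isfinite(ll) else -np.inf

    def loglik_grad(self, params: np.ndarray):
        """(loglik, gradient) on the original parameter scale."""
        params = np.asarray(params, dtype=float)
        beta1, beta2, sigma1, sigma2, rho, df = self.unpack(params)
        if self._invalid(sigma1, sigma2, rho, df):
            return -np.inf, np.zeros(params.size)
        eta1 = self.X1 @ beta1
        eta2 = self.X2 @ beta2
        lf1, d1_eta, d1_disp, u1, du1_eta, du1_disp = _margin_pieces(
            self.spec.margin1_family, self.y1, eta1, sigma1
        )
        lf2, d2_eta, d2_disp, u2, du2_eta, du2_disp = _margin_pieces(
            self.spec.margin2_family, self.y2, eta2, sigma2
        )
        u1c = np.clip(u1, PIT_CLAMP, 1.0 - PIT_CLAMP)
        u2c = np.clip(u2, PIT_CLAMP, 1.0 - PIT_CLAMP)
        lc, dlc_du1, dlc_du2, dlc_drho = _copula_pieces(
            self.spec.copula_family, rho, df, u1c, u2c
        )
        ll = float(np.sum(lf1) + np.sum(lf2) + np.sum(lc))
        if not np.isfinite(ll):
            return -np.inf, np.zeros(params.size)
        g_eta1 = d1_eta + dlc_du1 * du1_eta
        g_eta2 = d2_eta + dlc_du2 * du2_eta
        grad = np.concatenate([
            self.X1.T @ g_eta1,
            self.X2.T @ g_eta2,
            [
                float(np.sum(d1_disp + dlc_du1 * du1_disp)),
                float(np.sum(d2_disp + dlc_du2 * du2_disp)),
                float(np.sum(dlc_drho)),
            ],
        ])
        if self.estimate_df:
            h = 1e-5 * (df - 2.0)
            lp = np.sum(_logdensity_raw("student_t", rho, df + h, u1c, u2c))
            lm = np.sum(_logdensity_raw("student_t", rho, df - h, u1c, u2c))
            grad = np.append(grad, float((lp - lm) / (2.0 * h)))
        return ll, grad

    def observed_information(self, params: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
        """Negative Jacobian of the analytic score (central differences)."""
        params = np.asarray(params, dtype=float)
        k = params.size
        J = np.empty((k, k))
        for i in range(k):
            h = rel_step * (1.0 + abs(params[i]))
            e = np.zeros(k)
            e[i] = h
            _, gp = self.loglik_grad(params + e)
            _, gm = self.loglik_grad(params - e)
            J[i] = (gp - gm) / (2.0 * h)
        return -0.5 * (J + J.T)

    # -- transformed (unconstrained) scale for the optimizer ------------
    def to_internal(self, params: np.ndarray) -> np.ndarray:
        beta1, beta2, sigma1, sigma2, rho, df = self.unpack(np.asarray(params, dtype=float))
        out = np.concatenate(
            [beta1, beta2, [math.log(sigma1), math.log(sigma2), math.atanh(rho)]]
        )
        if self.estimate_df:
            out = np.append(out, math.log(df - 2.0))
        return out

    def from_internal(self, theta: np.ndarray) -> np.ndarray:
        k = self.p1 + self.p2
        out = np.array(theta, dtype=float)
        out[k] = math.exp(theta[k])
        out[k + 1] = math.exp(theta[k + 1])
        out[k + 2] = math.tanh(theta[k + 2])
        if self.estimate_df:
            out[k + 3] = 2.0 + math.exp(theta[k + 3])
        return out

    def neg_internal(self, theta: np.ndarray):
        """(negative loglik, negative gradient) on the internal scale."""
        params = self.from_internal(theta)
        ll, grad = self.loglik_grad(params)
        if not np.isfinite(ll):
            return 1e12, np.zeros(theta.size)
        k = self.p1 + self.p2
        jac = np.ones(theta.size)
        jac[k] = params[k]  # d sigma / d log sigma
        jac[k + 1] = params[k + 1]
        jac[k + 2] = 1.0 - params[k + 2] ** 2  # d rho / d atanh rho
        if self.estimate_df:
            jac[k + 3] = params[k + 3] - 2.0
        return -ll, -grad * jac


def joint_loglik(spec: RegressionSpec, params, data: pd.DataFrame) -> float:
    """Joint log-likelihood at an original-scale parameter vector.

    Layout: beta1 (intercept first), beta2, dispersion1, dispersion2, rho,
    then nu when the spec estimates the t-copula degrees of freedom.
    """
    model = _JointModel(spec, data)
    params = np.asarray(params, dtype=float)
    expected = model.p1 + model.p2 + 3 + (1 if model.estimate_df else 0)
    if params.size != expected:
        raise ConfigurationError(f"expected {expected} parameters, got {params.size}")
    return model.loglik(params)


def _fit_margin_regression(family: str, X: np.ndarray, y: np.ndarray):
    """Single-margin MLE: (beta, dispersion, loglik, aic). Least squares is
    exact for the normal and lognormal margins; the gamma margin is maximized
    numerically (analytic score) from a log-scale least-squares start."""
    n, p = X.shape
    if family in ("normal", "lognormal"):
        v = y if family == "normal" else np.log(y)
        beta, *_ = np.linalg.lstsq(X, v, rcond=None)
        resid = v - X @ beta
        sigma = float(np.sqrt(np.mean(resid**2)))
        if sigma < 1e-12:
            raise FitError(f"degenerate margin: zero residual variance under {family}")
        ll = -0.5 * n * math.log(2 * math.pi * sigma * sigma) - n / 2.0
        if family == "lognormal":
            ll -= float(np.sum(np.log(y)))
        k = p + 1
        return beta, sigma, float(ll), float(-2 * ll + 2 * k)

    # gamma, log link
    beta0, *_ = np.linalg.lstsq(X, np.log(y), rcond=None)
    mu0 = np.exp(X @ beta0)
    cv2 = float(np.mean((y / mu0 - 1.0) ** 2))
    alpha0 = max(1.0 / max(cv2, 1e-6), 1e-3)

    def neg(theta):
        beta = theta[:p]
        alpha = math.exp(theta[p])
        eta = X @ beta
        lf, dlf_deta, dlf_ddisp, *_ = _margin_pieces("gamma", y, eta, alpha)
        ll = float(np.sum(lf))
        if not np.isfinite(ll):
            return 1e12, np.zeros(p + 1)
        grad = np.append(X.T @ dlf_deta, np.sum(dlf_ddisp) * alpha)
        return -ll, -grad

    theta0 = np.append(beta0, math.log(alpha0))
    res = optimize.minimize(neg, theta0, jac=True, method="BFGS",
                            options={"gtol": 1e-9, "maxiter": 500})
    beta = res.x[:p]
    alpha = math.exp(res.x[p])
    ll = -res.fun
    k = p + 1
    return beta, float(alpha), float(ll), float(-2 * ll + 2 * k)


def fit_copula_regression(
    spec: RegressionSpec,
    data: pd.DataFrame,
    init: np.ndarray | None = None,
    seed=None,
) -> CopulaRegressionFit:
    """Fit the joint copula regression by maximum likelihood.

    Deterministic given (spec, data, init): the optimizer is warm-started
    from independent margin fits plus a copula fit to the margin PITs, then
    jointly refined with BFGS using the analytic score. ``seed`` is accepted
    for interface symmetry but unused (the procedure involves no
    randomness).
    """
    model = _JointModel(spec, data)
    if model.n < 10 * spec.n_params:
        logger.warning(
            "n = %d below the recommended 10 observations per parameter (k = %d)",
            model.n,
            spec.n_params,
        )

    if init is None:
        b1, s1, _, _ = _fit_margin_regression(spec.margin1_family, model.X1, model.y1)
        b2, s2, _, _ = _fit_margin_regression(spec.margin2_family, model.X2, model.y2)
        u1 = np.clip(
            _margin_cdf(spec.margin1_family, model.y1, model.X1 @ b1, s1),
            PIT_CLAMP, 1 - PIT_CLAMP,
        )
        u2 = np.clip(
            _margin_cdf(spec.margin2_family, model.y2, model.X2 @ b2, s2),
            PIT_CLAMP, 1 - PIT_CLAMP,
        )
        pits = np.column_stack([u1, u2])
        if spec.copula_family == "gaussian":
            cop = fit_copula_pseudo_mle("gaussian", pits)
            init = np.concatenate([b1, b2, [s1, s2, cop.rho]])
        elif spec.df_mode == "fixed":
            cop = fit_copula_pseudo_mle("student_t", pits, df=spec.df)
            init = np.concatenate([b1, b2, [s1, s2, cop.rho]])
        else:
            cop = fit_copula_pseudo_mle("student_t", pits, df_grid=DEFAULT_DF_GRID)
            init = np.concatenate([b1, b2, [s1, s2, cop.rho, cop.df]])
    init = np.asarray(init, dtype=float)
    init_ll = model.loglik(init)
    if not np.isfinite(init_ll):
        raise FitError("initialization point has non-finite joint log-likelihood")

    res = optimize.minimize(
        model.neg_internal,
        model.to_internal(init),
        jac=True,
        method="BFGS",
        options={"gtol": 1e-8, "maxiter": 2000},
    )
    if not np.all(np.isfinite(res.x)):
        raise FitError("joint optimization diverged", trace=res)
    # keep the better of warm start and refined point (ascent guarantee)
    params = model.from_internal(res.x)
    final_ll = model.loglik(params, count_clamped=True)
    if final_ll < init_ll:
        params, final_ll = init, model.loglik(init, count_clamped=True)

    se = None
    try:
        info = model.observed_information(params)
        eig = np.linalg.eigvalsh(info)
        if eig[0] <= 0 or eig[-1] / eig[0] > 1e12:
            raise np.linalg.LinAlgError("information singular or indefinite")
        cov = np.linalg.inv(info)
        d = np.diag(cov)
        if np.any(~np.isfinite(d)) or np.any(d <= 0):
            raise np.linalg.LinAlgError("information not positive definite")
        se = np.sqrt(d)
    except np.linalg.LinAlgError:
        logger.warning("singular observed information: standard errors unavailable")

    if model.n_clamped:
        logger.warning(
            "probability-integral transforms clamped for %d observation(s) at the optimum",
            model.n_clamped,
        )

    beta1, beta2, sigma1, sigma2, rho, df = model.unpack(params)
    k = spec.n_params
    return CopulaRegressionFit(
        spec=spec,
        beta1=np.array(beta1),
        beta2=np.array(beta2),
        sigma1=sigma1,
        sigma2=sigma2,
        rho=rho,
        df=None if spec.copula_family == "gaussian" else float(df),
        loglik=float(final_ll),
        aic=float(-2 * final_ll + 2 * k),
        n=model.n,
        se=se,
        param_names=model.param_names(),
        year_center=model.year_center,
        init_loglik=float(init_ll),
        n_clamped=model.n_clamped,
        converged=bool(res.success or final_ll >= init_ll),
    )


def wald_inference(fit: CopulaRegressionFit) -> pd.DataFrame:
    """Per-parameter Wald table: estimate, SE, z, two-sided normal p-value."""
    if not fit.se_available:
        raise InferenceError("standard errors unavailable (singular observed information)")
    est = fit.params
    se = fit.se
    z = np.where(est == 0.0, 0.0, est / se)
    p = 2.0 * special.ndtr(-np.abs(z))
    return pd.DataFrame(
        {"parameter": fit.param_names, "estimate": est, "se": se, "z": z, "p_value": p}
    )


def correlation_ci(fit: CopulaRegressionFit, level: float = 0.95) -> tuple[float, float]:
    """Fisher-z Wald interval for the copula correlation.

    The SE of atanh(rho) follows from the delta method, SE_z = SE_rho /
    (1 - rho^2); the interval is tanh(atanh(rho) +/- z * SE_z), guaranteed
    inside (-1, 1) and containing the point estimate.
    """
    if not 0 < level < 1:
        raise DomainError("confidence level must lie in (0, 1)")
    if not fit.se_available:
        raise InferenceError("standard errors unavailable (singular observed information)")
    idx = fit.param_names.index("copula:rho")
    rho = fit.rho
    se_z = fit.se[idx] / (1.0 - rho * rho)
    zcrit = special.ndtri(0.5 + level / 2.0)
    lo = math.tanh(math.atanh(rho) - zcrit * se_z)
    hi = math.tanh(math.atanh(rho) + zcrit * se_z)
    return lo, hi


def conditional_mean(fit: CopulaRegressionFit, covariates: Mapping[str, float]):
    """Predicted marginal means for one covariate row.

    lognormal margin: exp(x'beta + sigma^2/2); gamma (log link): exp(x'beta);
    normal: x'beta.
    """

    def one(family, covs, beta, disp):
        x = [1.0]
        for c in covs:
            if c not in covariates or covariates[c] is None:
                raise PredictionError(f"missing covariate value {c!r}")
            v = float(covariates[c])
            if c == "YEAR" and fit.year_center is not None:
                v -= fit.year_center
            x.append(v)
        eta = float(np.dot(x, beta))
        if family == "lognormal":
            return math.exp(eta + 0.5 * disp * disp)
        if family == "gamma":
            return math.exp(eta)
        return eta

    return (
        one(fit.spec.margin1_family, fit.spec.covariates1, fit.beta1, fit.sigma1),
        one(fit.spec.margin2_family, fit.spec.covariates2, fit.beta2, fit.sigma2),
    )


def fit_report(fit: CopulaRegressionFit) -> pd.DataFrame:
    """Final-model report: Wald table plus forest-plot-ready 95% bounds."""
    tab = wald_inference(fit)
    tab["ci_low"] = tab["estimate"] - 1.96 * tab["se"]
    tab["ci_high"] = tab["estimate"] + 1.96 * tab["se"]
    return tab
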