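"""Two-parameter marginal distribution families for questionnaire totals.

Addiction questionnaire totals (Y-IAT in 20-100, SAS in 33-198) are positive
and right-skewed, so the candidate marginal families are the normal,
log-normal, gamma and Weibull distributions, each with exactly two parameters:

==========  ======================  =========================
family      parameter 1             parameter 2
==========  ======================  =========================
normal      location (mean)         scale (SD), > 0
lognormal   log-scale location mu   log-scale SD sigma, > 0
gamma       shape, > 0              rate, > 0
weibull     shape, > 0              scale, > 0
==========  ======================  =========================

The gamma is parameterized by (shape, rate) and the Weibull by (shape, scale)
so that fitted estimates are directly comparable with the conventional
``fitdistrplus``-style reporting. IID maximum-likelihood fitting returns the
estimates together with standard errors from the inverse observed information
(numerical Hessian at the optimum) and AIC/BIC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats

from .errors import DomainError, FitError

FAMILIES = ("normal", "lognormal", "gamma", "weibull")

#: families whose support is the positive half-line
POSITIVE_FAMILIES = ("lognormal", "gamma", "weibull")

_PARAM_NAMES = {
    "normal": ("location", "scale"),
    "lognormal": ("meanlog", "sdlog"),
    "gamma": ("shape", "rate"),
    "weibull": ("shape", "scale"),
}


def param_names(family: str) -> tuple[str, str]:
    """Conventional names of the two parameters of ``family``."""
    _check_family(family)
    return _PARAM_NAMES[family]


@dataclass(frozen=True)
class MarginalFit:
    """Result of an iid maximum-likelihood marginal fit.

    ``aic = -2 loglik + 2k`` and ``bic = -2 loglik + k ln(n)`` with ``k = 2``
    free parameters for every supported family.
    """

    family: str
    params: tuple[float, float]
    se: tuple[float, float]
    loglik: float
    aic: float
    bic: float
    n: int


def _check_family(family: str) -> None:
    if family not in FAMILIES:
        raise DomainError(f"unknown marginal family {family!r}; expected one of {FAMILIES}")


def _check_params(family: str, params: Sequence[float]) -> tuple[float, float]:
    _check_family(family)
    if len(params) != 2:
        raise DomainError(f"{family} takes exactly two parameters, got {len(params)}")
    a, b = float(params[0]), float(params[1])
    if not (np.isfinite(a) and np.isfinite(b)):
        raise DomainError(f"non-finite parameters {params!r}")
    if family in ("normal", "lognormal"):
        if b <= 0:
            raise DomainError(f"{family} scale must be positive, got {b}")
    else:
        if a <= 0 or b <= 0:
            raise DomainError(f"{family} parameters must be positive, got {params!r}")
    return a, b


def _dist(family: str, params: Sequence[float]):
    """Frozen scipy distribution in the package's parameterization."""
    a, b = _check_params(family, params)
    if family == "normal":
        return stats.norm(loc=a, scale=b)
    if family == "lognormal":
        return stats.lognorm(s=b, scale=math.exp(a))
    if family == "gamma":
        return stats.gamma(a=a, scale=1.0 / b)
    return stats.weibull_min(c=a, scale=b)


def marginal_pdf(family: str, params: Sequence[float], y):
    """Density of ``family`` at ``y``.

    Negative ``y`` under a positive-support family is a domain error (the
    questionnaire totals are bounded well away from zero, so a negative value
    indicates malformed input rather than a tail observation).
    """
    y_arr = np.asarray(y, dtype=float)
    if family in POSITIVE_FAMILIES and np.any(y_arr < 0):
        raise DomainError(f"negative observation under positive-support family {family}")
    out = _dist(family, params).pdf(y_arr)
    return out if out.shape else float(out)


def marginal_cdf(family: str, params: Sequence[float], y):
    out = _dist(family, params).cdf(np.asarray(y, dtype=float))
    return out if out.shape else float(out)


def marginal_quantile(family: str, params: Sequence[float], p):
    """Quantile function; inverse of :func:`marginal_cdf` on (0, 1)."""
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr <= 0) or np.any(p_arr >= 1):
        raise DomainError("quantile probability must lie strictly in (0, 1)")
    out = _dist(family, params).ppf(p_arr)
    return out if out.shape else float(out)


def marginal_mean(family: str, params: Sequence[float]) -> float:
    """Closed-form expectation of the family.

    normal: location; lognormal: exp(mu + sigma^2/2); gamma: shape/rate;
    weibull: scale * Gamma(1 + 1/shape).
    """
    a, b = _check_params(family, params)
    if family == "normal":
        return a
    if family == "lognormal":
        return math.exp(a + 0.5 * b * b)
    if family == "gamma":
        return a / b
    return b * math.gamma(1.0 + 1.0 / a)


def _loglik(family: str, params: Sequence[float], y: np.ndarray) -> float:
    """IID log-likelihood via stable explicit formulas (hot path of fitting)."""
    a, b = params
    n = y.size
    if family == "normal":
        if b <= 0:
            return -np.inf
        return -0.5 * n * math.log(2 * math.pi * b * b) - float(np.sum((y - a) ** 2)) / (2 * b * b)
    if family == "lognormal":
        if b <= 0:
            return -np.inf
        ly = np.log(y)
        return (
            -0.5 * n * math.log(2 * math.pi * b * b)
            - float(np.sum((ly - a) ** 2)) / (2 * b * b)
            - float(np.sum(ly))
        )
    if family == "gamma":
        if a <= 0 or b <= 0:
            return -np.inf
        return float(
            n * (a * math.log(b) - special.gammaln(a))
            + (a - 1.0) * np.sum(np.log(y))
            - b * np.sum(y)
        )
    # weibull
    if a <= 0 or b <= 0:
        return -np.inf
    z = y / b
    return float(n * (math.log(a) - math.log(b)) + (a - 1.0) * np.sum(np.log(z)) - np.sum(z**a))


def _init_params(family: str, y: np.ndarray) -> tuple[float, float]:
    """Method-of-moments style starting values."""
    m, s = float(np.mean(y)), float(np.std(y))
    if family == "normal":
        return m, s
    if family == "lognormal":
        ly = np.log(y)
        return float(np.mean(ly)), max(float(np.std(ly)), 1e-8)
    if family == "gamma":
        s = max(s, 1e-8)
        return max(m * m / (s * s), 1e-6), max(m / (s * s), 1e-8)
    # weibull: standard CV-based approximation for the shape
    cv = max(s / m, 1e-6)
    shape = cv**-1.086
    scale = m / math.gamma(1.0 + 1.0 / shape)
    return shape, scale


def _hessian(f, x: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian of scalar ``f`` at ``x``."""
    k = x.size
    h = rel_step * (np.abs(x) + 1.0)
    H = np.empty((k, k))
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        f0 = f(x)
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / (h[i] * h[i])
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def observed_information_se(negloglik, params: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    """SEs as sqrt of the diagonal of the inverse numerical Hessian.

    Raises :class:`FitError` when the observed information is singular or not
    positive definite (e.g. a degenerate sample).
    """
    H = _hessian(negloglik, np.asarray(params, dtype=float), rel_step)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - rare
        raise FitError("singular observed information", trace=H) from exc
    d = np.diag(cov)
    if np.any(~np.isfinite(d)) or np.any(d <= 0):
        raise FitError("observed information not positive definite", trace=H)
    return np.sqrt(d)


def fit_marginal_iid(family: str, sample: Sequence[float], max_iter: int = 500) -> MarginalFit:
    """Fit ``family`` to an iid sample by maximum likelihood.

    Normal and log-normal MLEs are closed form; gamma and Weibull are
    maximized by quasi-Newton iteration on log-transformed (hence
    unconstrained) parameters from method-of-moments starts. Standard errors
    come from the inverse observed information evaluated on the original
    parameter scale.
    """
    _check_family(family)
    y = np.asarray(sample, dtype=float)
    if y.ndim != 1 or y.size < 10:
        raise DomainError(f"need a 1-D sample of at least 10 values, got shape {y.shape}")
    if not np.all(np.isfinite(y)):
        raise DomainError("sample contains non-finite values")
    if family in POSITIVE_FAMILIES and np.any(y <= 0):
        raise DomainError(f"non-positive observations invalid under {family} family")

    n = y.size
    if family in ("normal", "lognormal"):
        v = y if family == "normal" else np.log(y)
        a = float(np.mean(v))
        b = float(np.sqrt(np.mean((v - a) ** 2)))  # MLE uses 1/n
        if b < 1e-12 * max(1.0, abs(a)):
            raise FitError(f"degenerate sample: zero variance under {family} family")
        params = np.array([a, b])
    else:
        x0 = np.log(_init_params(family, y))

        def neg(logp):
            return -_loglik(family, tuple(np.exp(logp)), y)

        res = optimize.minimize(neg, x0, method="BFGS", options={"maxiter": max_iter, "gtol": 1e-10})
        if not np.all(np.isfinite(res.x)) or not np.isfinite(res.fun):
            raise FitError(f"{family} fit did not converge", trace=res)
        params = np.exp(res.x)

    ll = _loglik(family, tuple(params), y)
    se = observed_information_se(lambda p: -_loglik(family, tuple(p), y), params)
    k = 2
    return MarginalFit(
        family=family,
        params=(float(params[0]), float(params[1])),
        se=(float(se[0]), float(se[1])),
        loglik=float(ll),
        aic=float(-2.0 * ll + 2.0 * k),
        bic=float(-2.0 * ll + k * math.log(n)),
        n=int(n),
    )


def fit_report(fits: Sequence[MarginalFit]):
    """Tabulate marginal fits: one row per parameter with SE, AIC and BIC."""
    import pandas as pd

    rows = []
    for fit in fits:
        names = param_names(fit.family)
        for i in range(2):
            rows.append(
                {
                    "family": fit.family,
                    "parameter": names[i],
                    "estimate": fit.params[i],
                    "se": fit.se[i],
                    "aic": fit.aic,
                    "bic": fit.bic,
                }
            )
    return pd.DataFrame(rows)
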