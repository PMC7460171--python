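"""Bivariate Gaussian and Student-t copulas.

A copula couples two uniform margins into a joint law on the unit square; by
Sklar's theorem any continuous bivariate distribution factors into its margins
plus a unique copula. Both families here are elliptical:

* Gaussian: ``C(u1, u2; rho) = Phi2(Phi^-1(u1), Phi^-1(u2); rho)`` with one
  correlation parameter ``rho`` in (-1, 1) and no tail dependence.
* Student-t: the copula of a bivariate t with correlation ``rho`` and degrees
  of freedom ``nu > 2``; symmetric upper/lower tail dependence that grows as
  ``nu`` decreases, converging to the Gaussian copula as ``nu`` grows.

For both families Kendall's tau equals ``(2/pi) arcsin(rho)``, which the
sampler tests exploit.

Copula CDF values are computed by one-dimensional Gauss-Legendre quadrature of
the conditional CDF, ``C(u1, u2) = int_0^{u1} P(U2 <= u2 | U1 = p) dp``; the
conditional distribution of an elliptical pair is available in closed form
(normal, and scaled t with nu+1 degrees of freedom respectively). This is
vectorized over evaluation points, which the bootstrap goodness-of-fit test
relies on. Densities are closed form.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats

from .errors import ConfigurationError, DomainError, FitError

logger = logging.getLogger(__name__)

COPULA_FAMILIES = ("gaussian", "student_t")

#: default profile grid for the t-copula degrees of freedom
DEFAULT_DF_GRID = (2.1, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0, 15.0, 20.0, 30.0)

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(128)

_RHO_CAP = 0.99999


@dataclass(frozen=True)
class CopulaFit:
    """A fitted bivariate copula.

    ``aic = -2 loglik + 2k`` where ``k = 1`` for the Gaussian, ``k = 2`` for
    the t-copula with estimated degrees of freedom, and ``k = 1`` when the
    degrees of freedom were held fixed. ``df_gridpoint`` records the grid
    value selected during profile likelihood (t-copula only), before local
    refinement. ``boundary`` flags fits pinned at |rho| ~ 1.
    """

    family: str
    rho: float
    df: float | None
    loglik: float
    aic: float
    n: int
    boundary: bool = False
    df_gridpoint: float | None = None


def _check_copula_params(family: str, rho: float, df: float | None) -> None:
    if family not in COPULA_FAMILIES:
        raise DomainError(f"unknown copula family {family!r}; expected one of {COPULA_FAMILIES}")
    if not np.isfinite(rho) or abs(rho) >= 1:
        raise DomainError(f"copula correlation must lie in (-1, 1), got {rho}")
    if family == "student_t":
        if df is None or not np.isfinite(df) or df <= 2:
            raise DomainError(f"t-copula degrees of freedom must exceed 2, got {df}")


def copula_cdf(family: str, rho: float, df: float | None, u):
    """Copula CDF C(u1, u2), vectorized over an (n, 2) array of points.

    Grounded (C(u, 0) = 0) with uniform margins (C(u, 1) = u); boundary
    points are handled exactly, interior points by conditional quadrature.
    """
    _check_copula_params(family, rho, df)
    u_arr = np.atleast_2d(np.asarray(u, dtype=float))
    if u_arr.shape[-1] != 2:
        raise DomainError("u must be a pair or an (n, 2) array")
    if np.any(u_arr < 0) or np.any(u_arr > 1):
        raise DomainError("copula arguments must lie in [0, 1]")
    u1, u2 = u_arr[:, 0], u_arr[:, 1]
    out = np.empty(u_arr.shape[0])

    lo = (u1 <= 0) | (u2 <= 0)
    out[lo] = 0.0
    hi1 = (~lo) & (u1 >= 1)
    out[hi1] = u2[hi1]
    hi2 = (~lo) & (~hi1) & (u2 >= 1)
    out[hi2] = u1[hi2]
    interior = ~(lo | hi1 | hi2)
    if np.any(interior):
        out[interior] = _cdf_interior(family, rho, df, u1[interior], u2[interior])
    if np.asarray(u, dtype=float).ndim == 1:
        return float(out[0])
    return out


def _cdf_interior(family: str, rho: float, df: float | None, u1, u2):
    if rho == 0.0 and family == "gaussian":
        return u1 * u2
    s = math.sqrt(1.0 - rho * rho)
    # nodes p in (0, u1), shape (n, m)
    p = 0.5 * u1[:, None] * (_GL_NODES[None, :] + 1.0)
    w = 0.5 * u1[:, None] * _GL_WEIGHTS[None, :]
    if family == "gaussian":
        q = special.ndtri(p)
        b = special.ndtri(u2)[:, None]
        g = special.ndtr((b - rho * q) / s)
    else:
        q = special.stdtrit(df, p)
        b = special.stdtrit(df, u2)[:, None]
        scale = np.sqrt((df + q * q) / (df + 1.0))
        g = special.stdtr(df + 1.0, (b - rho * q) / (s * scale))
    return np.sum(w * g, axis=1)


def copula_logdensity(family: str, rho: float, df: float | None, u):
    """Log copula density at interior points; closed form for both families."""
    _check_copula_params(family, rho, df)
    u_arr = np.atleast_2d(np.asarray(u, dtype=float))
    if np.any(u_arr <= 0) or np.any(u_arr >= 1):
        raise DomainError("copula density requires arguments strictly inside (0, 1)")
    u1, u2 = u_arr[:, 0], u_arr[:, 1]
    out = _logdensity_raw(family, rho, df, u1, u2)
    if np.asarray(u, dtype=float).ndim == 1:
        return float(out[0])
    return out


def _t_logdensity_from_x(rho, df, x1, x2):
    """t-copula log density in terms of precomputed t quantiles x = T^-1(u)."""
    one_m = 1.0 - rho * rho
    quad = (x1 * x1 - 2.0 * rho * x1 * x2 + x2 * x2) / one_m
    log_joint = (
        special.gammaln((df + 2.0) / 2.0)
        - special.gammaln(df / 2.0)
        - math.log(df * math.pi)
        - 0.5 * math.log(one_m)
        - 0.5 * (df + 2.0) * np.log1p(quad / df)
    )
    log_marg = (
        special.gammaln((df + 1.0) / 2.0)
        - special.gammaln(df / 2.0)
        - 0.5 * math.log(df * math.pi)
    )
    log_f1 = log_marg - 0.5 * (df + 1.0) * np.log1p(x1 * x1 / df)
    log_f2 = log_marg - 0.5 * (df + 1.0) * np.log1p(x2 * x2 / df)
    return log_joint - log_f1 - log_f2


def _logdensity_raw(family, rho, df, u1, u2):
    """Closed-form log density; inputs assumed clamped inside (0, 1)."""
    one_m = 1.0 - rho * rho
    if family == "gaussian":
        z1 = special.ndtri(u1)
        z2 = special.ndtri(u2)
        return -0.5 * math.log(one_m) - (
            rho * rho * (z1 * z1 + z2 * z2) - 2.0 * rho * z1 * z2
        ) / (2.0 * one_m)
    return _t_logdensity_from_x(rho, df, special.stdtrit(df, u1), special.stdtrit(df, u2))


def copula_density(family: str, rho: float, df: float | None, u):
    return np.exp(copula_logdensity(family, rho, df, u))


def sample_copula(family: str, rho: float, df: float | None, n: int, seed) -> np.ndarray:
    """Draw ``n`` pairs with uniform margins from the copula.

    ``seed`` may be an int or a ``numpy.random.Generator``. The t-copula uses
    the normal/chi-square mixture representation.
    """
    _check_copula_params(family, rho, df)
    if n < 1:
        raise DomainError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    z = rng.standard_normal((n, 2))
    z2 = rho * z[:, 0] + math.sqrt(1.0 - rho * rho) * z[:, 1]
    if family == "gaussian":
        return np.column_stack([special.ndtr(z[:, 0]), special.ndtr(z2)])
    w = rng.chisquare(df, size=n)
    scale = np.sqrt(df / w)
    x1 = z[:, 0] * scale
    x2 = z2 * scale
    return np.column_stack([special.stdtr(df, x1), special.stdtr(df, x2)])


def pseudo_observations(pairs) -> np.ndarray:
    """Rank-based pseudo-observations rank/(n+1), with average ranks on ties.

    Invariant to strictly increasing transforms of either component; outputs
    lie strictly inside (0, 1).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise DomainError("need at least two (y1, y2) pairs")
    n = arr.shape[0]
    r1 = stats.rankdata(arr[:, 0], method="average")
    r2 = stats.rankdata(arr[:, 1], method="average")
    return np.column_stack([r1, r2]) / (n + 1.0)


def _check_pobs(pobs) -> np.ndarray:
    arr = np.asarray(pobs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise DomainError("pseudo-observations must form an (n, 2) array")
    if np.any(arr <= 0) or np.any(arr >= 1):
        raise DomainError("pseudo-observations must lie strictly inside (0, 1)")
    return arr


def _profile_rho(loglik_of_rho) -> tuple[float, float]:
    """Maximize a copula log-likelihood over rho via its atanh transform."""
    res = optimize.minimize_scalar(
        lambda a: -loglik_of_rho(math.tanh(a)),
        bounds=(-7.0, 7.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    rho = math.tanh(res.x)
    rho = max(min(rho, _RHO_CAP), -_RHO_CAP)
    return rho, loglik_of_rho(rho)


def fit_copula_pseudo_mle(
    family: str,
    pobs,
    df_grid: Sequence[float] | None = None,
    df: float | None = None,
) -> CopulaFit:
    """Maximum pseudo-likelihood copula fit.

    Gaussian: one-dimensional maximization over ``rho``. Student-t with free
    degrees of freedom: profile likelihood of ``rho`` over ``df_grid``
    (default :data:`DEFAULT_DF_GRID`) followed by joint Nelder-Mead
    refinement of (atanh rho, log(nu - 2)). Passing ``df`` fixes the degrees
    of freedom (one free parameter, as in the two-stage regression flow).
    """
    arr = _check_pobs(pobs)
    n = arr.shape[0]
    u1, u2 = arr[:, 0], arr[:, 1]

    if family == "gaussian":
        z1, z2 = special.ndtri(u1), special.ndtri(u2)
        s11 = float(z1 @ z1 + z2 @ z2)
        s12 = float(z1 @ z2)

        def ll(rho):
            om = 1.0 - rho * rho
            return -0.5 * n * math.log(om) - (rho * rho * s11 - 2.0 * rho * s12) / (2.0 * om)

        rho, loglik = _profile_rho(ll)
        k = 1
        return CopulaFit(
            family="gaussian",
            rho=rho,
            df=None,
            loglik=loglik,
            aic=-2.0 * loglik + 2.0 * k,
            n=n,
            boundary=abs(rho) >= 0.9999,
        )

    if family != "student_t":
        raise DomainError(f"unknown copula family {family!r}")

    # the t quantiles of the pseudo-observations are fixed per nu; cache them
    # so profiling rho costs one ppf evaluation per grid point
    ppf_cache: dict[float, tuple[np.ndarray, np.ndarray]] = {}

    def ll_t(rho, nu):
        key = round(float(nu), 12)
        if key not in ppf_cache:
            ppf_cache[key] = (special.stdtrit(nu, u1), special.stdtrit(nu, u2))
            if len(ppf_cache) > 64:
                ppf_cache.pop(next(iter(ppf_cache)))
        x1, x2 = ppf_cache[key]
        return float(np.sum(_t_logdensity_from_x(rho, nu, x1, x2)))

    if df is not None:
        if df <= 2:
            raise DomainError("t-copula degrees of freedom must exceed 2")
        rho, loglik = _profile_rho(lambda r: ll_t(r, df))
        k = 1
        return CopulaFit(
            family="student_t",
            rho=rho,
            df=float(df),
            loglik=loglik,
            aic=-2.0 * loglik + 2.0 * k,
            n=n,
            boundary=abs(rho) >= 0.9999,
        )

    grid = tuple(df_grid) if df_grid is not None else DEFAULT_DF_GRID
    best = None
    for nu in grid:
        rho, loglik = _profile_rho(lambda r: ll_t(r, nu))
        if best is None or loglik > best[2]:
            best = (nu, rho, loglik)
    nu0, rho0, _ = best

    def neg(theta):
        rho = math.tanh(theta[0])
        nu = 2.0 + math.exp(theta[1])
        if abs(rho) >= 1 or not np.isfinite(nu):
            return np.inf
        return -ll_t(rho, nu)

    res = optimize.minimize(
        neg,
        np.array([math.atanh(rho0), math.log(max(nu0 - 2.0, 1e-6))]),
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 500},
    )
    if not np.isfinite(res.fun):
        raise FitError("t-copula pseudo-MLE did not converge", trace=res)
    rho = max(min(math.tanh(res.x[0]), _RHO_CAP), -_RHO_CAP)
    nu = 2.0 + math.exp(res.x[1])
    loglik = ll_t(rho, nu)
    k = 2
    return CopulaFit(
        family="student_t",
        rho=rho,
        df=nu,
        loglik=loglik,
        aic=-2.0 * loglik + 2.0 * k,
        n=n,
        boundary=abs(rho) >= 0.9999,
        df_gridpoint=float(nu0),
    )


def select_copula_family(pobs, df_grid: Sequence[float] | None = None) -> CopulaFit:
    """Fit both families and return the lower-AIC one (ties go Gaussian)."""
    gauss = fit_copula_pseudo_mle("gaussian", pobs)
    t = fit_copula_pseudo_mle("student_t", pobs, df_grid=df_grid)
    return gauss if gauss.aic <= t.aic else t


def empirical_copula(pobs, points) -> np.ndarray:
    """Empirical copula C_n of ``pobs`` evaluated at ``points`` (m, 2)."""
    arr = np.asarray(pobs, dtype=float)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    ind = (arr[None, :, 0] <= pts[:, 0, None]) & (arr[None, :, 1] <= pts[:, 1, None])
    return ind.mean(axis=1)


def cvm_statistic(pobs, model_cdf) -> float:
    """Cramer-von Mises distance sum_i (C_n(u_i) - C(u_i))^2.

    ``model_cdf`` maps an (m, 2) array of points to model CDF values; passing
    the empirical copula itself yields exactly zero.
    """
    arr = _check_pobs(pobs)
    cn = empirical_copula(arr, arr)
    cm = np.asarray(model_cdf(arr), dtype=float)
    return float(np.sum((cn - cm) ** 2))


def gof_copula_cvm(fit: CopulaFit, pobs, n_boot: int = 500, seed=0) -> tuple[float, float]:
    """Parametric-bootstrap goodness-of-fit test for a fitted copula.

    The statistic is the Cramer-von Mises distance between the empirical
    copula of ``pobs`` and the fitted parametric copula, both evaluated at
    the observed pseudo-observations. The p-value resamples ``n_boot``
    datasets from the fitted copula, refits the same family (degrees of
    freedom held at the fitted value for the t-copula, to keep the bootstrap
    tractable), and recomputes the statistic; ``p = (1 + #{S* >= S}) /
    (n_boot + 1)``.
    """
    if n_boot < 1:
        raise ConfigurationError("n_boot must be >= 1")
    if n_boot < 50:
        warnings.warn("n_boot < 50 gives an unstable bootstrap p-value", stacklevel=2)
    arr = _check_pobs(pobs)
    n = arr.shape[0]
    rng = np.random.default_rng(seed)

    def model_cdf_of(f: CopulaFit):
        return lambda pts: copula_cdf(f.family, f.rho, f.df, pts)

    def refit(sample):
        if fit.family == "gaussian":
            return fit_copula_pseudo_mle("gaussian", sample)
        return fit_copula_pseudo_mle("student_t", sample, df=fit.df)

    stat = cvm_statistic(arr, model_cdf_of(fit))
    exceed = 0
    for _ in range(n_boot):
        u_star = sample_copula(fit.family, fit.rho, fit.df, n, rng)
        p_star = pseudo_observations(u_star)
        fit_star = refit(p_star)
        s_star = cvm_statistic(p_star, model_cdf_of(fit_star))
        if s_star >= stat:
            exceed += 1
    p_value = (1.0 + exceed) / (n_boot + 1.0)
    return stat, p_value
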