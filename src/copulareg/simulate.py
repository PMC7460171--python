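"""Seeded generator of study-like datasets with known generative truth.

The study data (555 Korean middle-school students, internet- and
smartphone-addiction totals plus psychosocial and usage covariates) are not
deposited, so this module fabricates datasets that reproduce the published
summary statistics and outcome-generating model:

* Psychosocial scores (BDI, BAI, BIS, CASS, AQ, STAXI_E) are drawn from a
  Gaussian copula with gamma margins matched to the published means and SDs
  (a NORTA construction); the latent correlations are solved numerically so
  the realized Pearson correlations hit the published targets, then the
  scores are rounded to integers as questionnaire totals are.
* GENDER (1 = female), ALC and SMK are independent Bernoulli draws; usage
  hours are right-skewed log-normal; YEAR is a two-level birth year.
* Outcomes are drawn from the copula regression model itself: a t-copula
  (rho = 0.364, nu = 3 by default) couples a log-normal IAT margin
  (log-scale SD 0.346) with a gamma SAS margin whose shape reproduces the
  published SAS mean/SD, with published final-model coefficients as the
  generative truth. Intercepts are solved so the expected outcome means hit
  the published sample means, including a -beta' Sigma beta / 2 correction
  for the covariate-averaged mean of a log-linear model.

Regeneration with the same (config, seed) is byte-identical.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special

from .copulas import sample_copula
from .errors import ConfigurationError, PipelineError
from .regression import design_matrix

PSYCH_SCORES = ("BDI", "BAI", "BIS", "CASS", "AQ", "STAXI_E")

#: published means and SDs of the psychosocial scores
PSYCH_MEANS = {"BDI": 7.46, "BAI": 6.46, "BIS": 63.55, "CASS": 17.91, "AQ": 63.42,
               "STAXI_E": 53.28}
PSYCH_SDS = {"BDI": 7.82, "BAI": 8.56, "BIS": 8.34, "CASS": 12.59, "AQ": 20.06,
             "STAXI_E": 11.39}

#: published correlation block of the psychosocial scores (order PSYCH_SCORES)
PSYCH_CORR = np.array([
    [1.00, 0.65, 0.31, 0.52, 0.50, 0.33],
    [0.65, 1.00, 0.30, 0.55, 0.52, 0.30],
    [0.31, 0.30, 1.00, 0.44, 0.33, 0.14],
    [0.52, 0.55, 0.44, 1.00, 0.60, 0.44],
    [0.50, 0.52, 0.33, 0.60, 1.00, 0.53],
    [0.33, 0.30, 0.14, 0.44, 0.53, 1.00],
])

USAGE_HOURS = ("WDGH", "WEGH", "WDIH", "WDSH", "WESH")

#: log-normal log-means/log-SDs of daily usage hours (chosen as realistic
#: right-skewed patterns; the study prints no usage-hour summaries)
USAGE_LOGMEANS = {"WDGH": 0.0, "WEGH": 0.6, "WDIH": 0.4, "WDSH": 0.9, "WESH": 1.2}
USAGE_LOGSDS = {"WDGH": 0.7, "WEGH": 0.7, "WDIH": 0.6, "WDSH": 0.6, "WESH": 0.6}

#: published final-model coefficients (generative truth; intercepts derived)
IAT_COEFFS = {
    "GENDER": -0.0929, "BDI": -0.0044, "BAI": 0.0089, "BIS": 0.0052,
    "CASS": 0.0029, "AQ": 0.0037, "WDGH": 0.0375, "WEGH": 0.0264,
    "WDIH": 0.0376, "YEAR": -0.0332, "ALC": -0.1677, "SMK": 0.0969,
}
SAS_COEFFS = {
    "GENDER": 0.0484, "BDI": -0.0019, "BAI": 0.0079, "BIS": 0.0082,
    "CASS": -0.0007, "AQ": 0.0049, "WDSH": 0.0057, "WESH": 0.0251,
    "YEAR": -0.051, "ALC": 0.0341, "SMK": 0.0497,
}

DEFAULT_IAT_COVARIATES = tuple(IAT_COEFFS)
DEFAULT_SAS_COVARIATES = tuple(SAS_COEFFS)


def _nearest_psd_corr(corr: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix to the nearest correlation-like PSD matrix
    by eigenvalue clipping and diagonal renormalization."""
    sym = 0.5 * (corr + corr.T)
    vals, vecs = np.linalg.eigh(sym)
    if np.min(vals) >= 0:
        return sym
    vals = np.clip(vals, eps, None)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    if np.min(np.linalg.eigvalsh(fixed)) < -eps:
        raise ConfigurationError("correlation matrix not positive semidefinite after projection")
    return fixed


# ---------------------------------------------------------------------------
# NORTA: latent Gaussian correlations that yield target Pearson correlations
# after the gamma-quantile transform. Uses the Hermite expansion of the
# transform g(Z) = F^-1(Phi(Z)): for orthonormal Hermite coefficients c_k,
# E[g_i(Z1) g_j(Z2)] = sum_k c_ik c_jk rho^k.
# ---------------------------------------------------------------------------

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(96)
_HERMITE_ORDER = 40


def _hermite_coeffs(shape: float, scale: float) -> np.ndarray:
    z = math.sqrt(2.0) * _GH_NODES
    # extreme nodes round ndtr to exactly 0/1; clip (their weights are ~e^-150)
    u = np.clip(special.ndtr(z), 1e-300, 1.0 - 1e-16)
    g = special.gammaincinv(shape, u) * scale
    w = _GH_WEIGHTS / math.sqrt(math.pi)
    # orthonormal probabilists' Hermite via recurrence
    h_prev = np.ones_like(z)
    h = z.copy()
    coeffs = [float(np.sum(w * g))]
    coeffs.append(float(np.sum(w * g * h)))
    for k in range(2, _HERMITE_ORDER + 1):
        h_next = (z * h - math.sqrt(k - 1.0) * h_prev) / math.sqrt(k)
        coeffs.append(float(np.sum(w * g * h_next)))
        h_prev, h = h, h_next
    return np.array(coeffs)


@lru_cache(maxsize=32)
def _latent_corr_cached(shapes: tuple, scales: tuple, target: tuple) -> np.ndarray:
    m = len(shapes)
    coeffs = [_hermite_coeffs(shapes[i], scales[i]) for i in range(m)]
    sds = [math.sqrt(float(np.sum(c[1:] ** 2))) for c in coeffs]
    target_mat = np.array(target).reshape(m, m)
    latent = np.eye(m)
    powers = np.arange(1, _HERMITE_ORDER + 1)
    for i in range(m):
        for j in range(i + 1, m):
            a = coeffs[i][1:] * coeffs[j][1:]
            tgt = target_mat[i, j] * sds[i] * sds[j]

            def pearson_gap(r):
                return float(np.sum(a * r**powers)) - tgt

            from scipy.optimize import brentq

            latent[i, j] = latent[j, i] = brentq(pearson_gap, -0.999, 0.999, xtol=1e-10)
    return _nearest_psd_corr(latent)


@dataclass(frozen=True)
class GenerativeConfig:
    """Everything needed to simulate one study-like dataset.

    Defaults reproduce the published study conditions: n = 555 complete
    cases, Table-style psychosocial moments/correlations, the final-model
    coefficients as generative truth, log-normal IAT margin (log-scale SD
    0.346), gamma SAS margin matched to mean 80.25 / SD 27.94, and a
    t-copula with rho = 0.364 and nu = 3. ``missing_rate`` (159/714) is the
    outcome-missingness rate applied by :func:`inject_missingness`.
    """

    n: int = 555
    psych_means: dict = field(default_factory=lambda: dict(PSYCH_MEANS))
    psych_sds: dict = field(default_factory=lambda: dict(PSYCH_SDS))
    psych_corr: tuple = tuple(map(tuple, PSYCH_CORR))
    female_rate: float = 260.0 / 555.0
    alc_rate: float = 0.12
    smk_rate: float = 0.06
    usage_logmeans: dict = field(default_factory=lambda: dict(USAGE_LOGMEANS))
    usage_logsds: dict = field(default_factory=lambda: dict(USAGE_LOGSDS))
    year_levels: tuple = (1998, 1999)
    beta1: dict = field(default_factory=lambda: dict(IAT_COEFFS))
    beta2: dict = field(default_factory=lambda: dict(SAS_COEFFS))
    mean_y1: float = 33.88
    mean_y2: float = 80.25
    sd_y2: float = 27.94
    sigma1: float = 0.346
    copula_family: str = "student_t"
    rho: float = 0.364
    df: float = 3.0
    missing_rate: float = 159.0 / 714.0

    def __post_init__(self):
        for rate in (self.female_rate, self.alc_rate, self.smk_rate):
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"rate {rate} outside [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must lie in [0, 1)")

    # -- derived generative quantities ----------------------------------
    @property
    def shape2(self) -> float:
        """Gamma shape reproducing the published SAS mean/SD at the covariate means."""
        return (self.mean_y2 / self.sd_y2) ** 2

    def covariate_expectation(self, name: str) -> float:
        if name == "GENDER":
            return self.female_rate
        if name == "ALC":
            return self.alc_rate
        if name == "SMK":
            return self.smk_rate
        if name == "YEAR":
            return 0.0  # entered centered
        if name in self.psych_means:
            return self.psych_means[name]
        if name in self.usage_logmeans:
            m, s = self.usage_logmeans[name], self.usage_logsds[name]
            return math.exp(m + 0.5 * s * s)
        raise ConfigurationError(f"unknown covariate {name!r}")

    def covariate_variance(self, name: str) -> float:
        if name in ("GENDER", "ALC", "SMK"):
            p = self.covariate_expectation(name)
            return p * (1.0 - p)
        if name == "YEAR":
            k = len(self.year_levels)
            lv = np.asarray(self.year_levels, dtype=float)
            return float(np.mean((lv - lv.mean()) ** 2)) if k > 1 else 0.0
        if name in self.psych_sds:
            return self.psych_sds[name] ** 2
        if name in self.usage_logmeans:
            m, s = self.usage_logmeans[name], self.usage_logsds[name]
            return (math.exp(s * s) - 1.0) * math.exp(2 * m + s * s)
        raise ConfigurationError(f"unknown covariate {name!r}")

    def _linear_predictor_var(self, beta: dict) -> float:
        """Var(beta' x) under the config; psychosocial covariances from the
        target Pearson correlations, other blocks independent."""
        var = 0.0
        names = list(beta)
        for i, a in enumerate(names):
            var += beta[a] ** 2 * self.covariate_variance(a)
            for b in names[i + 1:]:
                if a in PSYCH_SCORES and b in PSYCH_SCORES:
                    ia, ib = PSYCH_SCORES.index(a), PSYCH_SCORES.index(b)
                    cov = self.psych_corr[ia][ib] * self.psych_sds[a] * self.psych_sds[b]
                    var += 2.0 * beta[a] * beta[b] * cov
        return var

    @property
    def intercept1(self) -> float:
        """Log-scale IAT intercept hitting the published mean on average."""
        shift = sum(b * self.covariate_expectation(c) for c, b in self.beta1.items())
        return (math.log(self.mean_y1) - 0.5 * self.sigma1**2 - shift
                - 0.5 * self._linear_predictor_var(self.beta1))

    @property
    def intercept2(self) -> float:
        shift = sum(b * self.covariate_expectation(c) for c, b in self.beta2.items())
        return (math.log(self.mean_y2) - shift
                - 0.5 * self._linear_predictor_var(self.beta2))

    def truth(self) -> dict:
        """Generative truth in the layout of the fitted parameter vector."""
        return {
            "beta1": {"Intercept": self.intercept1, **self.beta1},
            "beta2": {"Intercept": self.intercept2, **self.beta2},
            "sigma1": self.sigma1,
            "sigma2": self.shape2,
            "rho": self.rho,
            "df": self.df,
            "copula_family": self.copula_family,
        }


DEFAULT_CONFIG = GenerativeConfig()


@dataclass(frozen=True)
class SyntheticStudy:
    """A generated dataset plus the configuration (truth) that produced it."""

    data: pd.DataFrame
    config: GenerativeConfig
    seed: int

    def write(self, csv_path, truth_path=None) -> None:
        """Write the dataset as CSV with an optional JSON truth sidecar."""
        Path(csv_path).parent.mkdir(parents=True, exist_ok=True)
        self.data.to_csv(csv_path, index=False)
        if truth_path is not None:
            payload = {"seed": self.seed, "n": len(self.data), "truth": self.config.truth()}
            Path(truth_path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def generate_covariates(config: GenerativeConfig, seed) -> pd.DataFrame:
    """Draw a covariate table: NORTA psychosocial block, Bernoulli binaries,
    log-normal usage hours, two-level birth year."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = config.n
    shapes = tuple((config.psych_means[c] / config.psych_sds[c]) ** 2 for c in PSYCH_SCORES)
    scales = tuple(config.psych_sds[c] ** 2 / config.psych_means[c] for c in PSYCH_SCORES)
    latent = _latent_corr_cached(shapes, scales,
                                 tuple(np.asarray(config.psych_corr).ravel()))
    chol = np.linalg.cholesky(latent + 1e-12 * np.eye(len(shapes)))
    z = rng.standard_normal((n, len(shapes))) @ chol.T
    u = special.ndtr(z)
    cols = {}
    for j, name in enumerate(PSYCH_SCORES):
        cols[name] = np.round(special.gammaincinv(shapes[j], u[:, j]) * scales[j])
    cols["GENDER"] = rng.binomial(1, config.female_rate, size=n)
    cols["ALC"] = rng.binomial(1, config.alc_rate, size=n)
    cols["SMK"] = rng.binomial(1, config.smk_rate, size=n)
    for name in USAGE_HOURS:
        m, s = config.usage_logmeans[name], config.usage_logsds[name]
        cols[name] = np.round(np.exp(rng.normal(m, s, size=n)), 1)
    cols["YEAR"] = rng.choice(np.asarray(config.year_levels, dtype=float), size=n)
    order = ["GENDER", *PSYCH_SCORES, *USAGE_HOURS, "YEAR", "ALC", "SMK"]
    return pd.DataFrame({k: cols[k] for k in order})


def generate_outcomes(covariates: pd.DataFrame, config: GenerativeConfig, seed) -> pd.DataFrame:
    """Draw (y1, y2) from the generative copula regression given covariates.

    A copula pair (u1, u2) is sampled, then pushed through the row-specific
    marginal quantile functions (log-normal IAT margin, gamma SAS margin
    with log link). YEAR enters centered at the table's sample mean.
    """
    for c in list(config.beta1) + list(config.beta2):
        if c not in covariates.columns:
            raise ConfigurationError(f"covariate {c!r} required by coefficients but absent")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    yc = float(covariates["YEAR"].mean()) if "YEAR" in covariates.columns else None
    X1 = design_matrix(covariates, tuple(config.beta1), yc)
    X2 = design_matrix(covariates, tuple(config.beta2), yc)
    b1 = np.array([config.intercept1, *config.beta1.values()])
    b2 = np.array([config.intercept2, *config.beta2.values()])
    eta1, eta2 = X1 @ b1, X2 @ b2
    u = sample_copula(config.copula_family, config.rho,
                      config.df if config.copula_family == "student_t" else None,
                      len(covariates), rng)
    y1 = np.exp(eta1 + config.sigma1 * special.ndtri(u[:, 0]))
    alpha = config.shape2
    y2 = special.gammaincinv(alpha, u[:, 1]) * np.exp(eta2) / alpha
    return pd.DataFrame({"y1": y1, "y2": y2})


def generate_study(config: GenerativeConfig = DEFAULT_CONFIG, seed: int = 0,
                   missing: bool = False) -> SyntheticStudy:
    """Covariates + outcomes in one table; complete by default.

    With ``missing=True`` outcome pairs are deleted completely at random at
    ``config.missing_rate``, mimicking subjects who skipped the addiction
    questionnaires.
    """
    rng = np.random.default_rng(seed)
    cov = generate_covariates(config, rng)
    out = generate_outcomes(cov, config, rng)
    study = SyntheticStudy(pd.concat([out, cov], axis=1), config, int(seed))
    if missing:
        study = inject_missingness(study, config.missing_rate, rng)
    return study


def inject_missingness(study: SyntheticStudy, rate: float, seed) -> SyntheticStudy:
    """Delete outcome pairs completely at random at the given rate."""
    if not 0.0 <= rate < 1.0:
        raise ConfigurationError("missingness rate must lie in [0, 1)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    data = study.data.copy()
    drop = rng.random(len(data)) < rate
    data.loc[drop, ["y1", "y2"]] = np.nan
    return SyntheticStudy(data, study.config, study.seed)


def complete_cases(study: SyntheticStudy) -> SyntheticStudy:
    """Rows with both outcomes present; covariate missingness is untouched."""
    keep = study.data[["y1", "y2"]].notna().all(axis=1)
    if not keep.any():
        raise PipelineError("complete-case filter removed every row")
    return SyntheticStudy(study.data.loc[keep].reset_index(drop=True), study.config, study.seed)
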