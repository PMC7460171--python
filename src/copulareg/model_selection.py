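"""AIC model comparison and backward covariate elimination.

The copula regression is benchmarked against models that treat the two
outcomes as independent: a linear-regression mode (LM: least squares, i.e.
normal MLE, on the raw or log scale) and a GLM mode (lognormal or gamma
margins fit per outcome by MLE). For independent models the total AIC is the
sum of the two single-outcome AICs, which makes it directly comparable with
the joint copula model's AIC because all likelihoods are on the outcome
scale.

Backward elimination removes, at each step, the single covariate (from either
margin) whose deletion most decreases the joint model's AIC, refitting the
full joint model for every candidate removal, and stops when no deletion
decreases AIC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FitError
from .regression import (
    RegressionSpec,
    _fit_margin_regression,
    _year_center,
    design_matrix,
    fit_copula_regression,
)

logger = logging.getLogger(__name__)

_LM_FAMILIES = ("normal", "lognormal")
_GLM_FAMILIES = ("lognormal", "gamma")

_FAMILY_ABBREV = {"normal": "Norm.", "lognormal": "Log.", "gamma": "Gam."}
_COPULA_ABBREV = {"gaussian": "Norm.", "student_t": "t"}


@dataclass(frozen=True)
class IndependentSpec:
    """Two single-outcome regressions with no dependence term.

    ``mode`` is "LM" (least-squares margins: normal on the raw scale,
    lognormal via least squares on the log scale) or "GLM" (lognormal or
    gamma margins by MLE).
    """

    mode: str
    margin1_family: str
    margin2_family: str
    covariates1: tuple[str, ...]
    covariates2: tuple[str, ...]

    def __post_init__(self):
        if self.mode not in ("LM", "GLM"):
            raise ConfigurationError("mode must be 'LM' or 'GLM'")
        allowed = _LM_FAMILIES if self.mode == "LM" else _GLM_FAMILIES
        for fam in (self.margin1_family, self.margin2_family):
            if fam not in allowed:
                raise ConfigurationError(
                    f"{fam!r} margin unsupported in {self.mode} mode (allowed: {allowed})"
                )
        object.__setattr__(self, "covariates1", tuple(self.covariates1))
        object.__setattr__(self, "covariates2", tuple(self.covariates2))

    @property
    def n_params(self) -> int:
        return (len(self.covariates1) + 2) + (len(self.covariates2) + 2)


@dataclass(frozen=True)
class IndependentFit:
    spec: IndependentSpec
    beta1: np.ndarray
    beta2: np.ndarray
    sigma1: float
    sigma2: float
    aic1: float
    aic2: float
    loglik: float

    @property
    def total_aic(self) -> float:
        return self.aic1 + self.aic2


@dataclass(frozen=True)
class ModelComparisonRow:
    label: str
    margin1_family: str
    margin2_family: str
    dependence: str
    total_aic: float
    n_params: int
    error: str | None = None


@dataclass(frozen=True)
class EliminationStep:
    step: int
    margin: int
    covariate: str
    aic_before: float
    aic_after: float


def fit_independent_margins(spec: IndependentSpec, data: pd.DataFrame) -> IndependentFit:
    """Fit the two margins separately; total AIC = AIC1 + AIC2 exactly."""
    yc = _year_center(data, RegressionSpec(
        "normal", "normal", spec.covariates1, spec.covariates2, "gaussian", None, "fixed",
    ))
    X1 = design_matrix(data, spec.covariates1, yc)
    X2 = design_matrix(data, spec.covariates2, yc)
    y1 = np.asarray(data["y1"], dtype=float)
    y2 = np.asarray(data["y2"], dtype=float)
    b1, s1, ll1, aic1 = _fit_margin_regression(spec.margin1_family, X1, y1)
    b2, s2, ll2, aic2 = _fit_margin_regression(spec.margin2_family, X2, y2)
    return IndependentFit(
        spec=spec, beta1=b1, beta2=b2, sigma1=s1, sigma2=s2,
        aic1=aic1, aic2=aic2, loglik=ll1 + ll2,
    )


def _row_label(cand) -> str:
    if isinstance(cand, IndependentSpec):
        return (
            f"{cand.mode} {_FAMILY_ABBREV[cand.margin1_family]}/"
            f"{_FAMILY_ABBREV[cand.margin2_family]}"
        )
    return (
        f"Copula {_FAMILY_ABBREV[cand.margin1_family]}/"
        f"{_FAMILY_ABBREV[cand.margin2_family]} {_COPULA_ABBREV[cand.copula_family]}"
    )


def compare_models(data: pd.DataFrame, candidates: Sequence) -> list[ModelComparisonRow]:
    """Fit every candidate (IndependentSpec or RegressionSpec) and rank by AIC.

    Failed fits are flagged with their error and placed after all ranked
    rows. Ties break toward fewer parameters, then lexicographic label, so
    the ordering is a pure function of (data, candidates).
    """
    if len(candidates) < 2:
        raise ConfigurationError("need at least two candidate models to compare")
    rows = []
    for cand in candidates:
        label = _row_label(cand)
        try:
            if isinstance(cand, IndependentSpec):
                fit = fit_independent_margins(cand, data)
                total, k, dep = fit.total_aic, cand.n_params, f"independent-{cand.mode}"
            else:
                fit = fit_copula_regression(cand, data)
                total, k, dep = fit.aic, cand.n_params, cand.copula_family
            rows.append(ModelComparisonRow(label, cand.margin1_family, cand.margin2_family,
                                           dep, total, k))
        except (FitError, np.linalg.LinAlgError) as exc:
            logger.warning("candidate %s failed to fit: %s", label, exc)
            rows.append(ModelComparisonRow(label, cand.margin1_family, cand.margin2_family,
                                           "failed", float("nan"), 0, error=str(exc)))
    ok = sorted((r for r in rows if r.error is None),
                key=lambda r: (r.total_aic, r.n_params, r.label))
    failed = sorted((r for r in rows if r.error is not None), key=lambda r: r.label)
    return ok + failed


def comparison_table(rows: Sequence[ModelComparisonRow]) -> pd.DataFrame:
    return pd.DataFrame([
        {"model": r.label, "margin_IAT": r.margin1_family, "margin_SAS": r.margin2_family,
         "dependence": r.dependence, "total_aic": r.total_aic, "k": r.n_params,
         "error": r.error}
        for r in rows
    ])


def default_candidates(covariates1: Sequence[str], covariates2: Sequence[str],
                       df: float = 3.0) -> list:
    """The canonical 12-model comparison grid.

    Four least-squares rows, four per-outcome GLM rows, and four copula rows
    (one Gaussian and three t-copula margin combinations).
    """
    c1, c2 = tuple(covariates1), tuple(covariates2)
    lm = [IndependentSpec("LM", f1, f2, c1, c2)
          for f1, f2 in [("normal", "normal"), ("lognormal", "lognormal"),
                         ("normal", "lognormal"), ("lognormal", "normal")]]
    glm = [IndependentSpec("GLM", f1, f2, c1, c2)
           for f1, f2 in [("lognormal", "lognormal"), ("gamma", "gamma"),
                          ("lognormal", "gamma"), ("gamma", "lognormal")]]
    cop = [
        RegressionSpec("lognormal", "gamma", c1, c2, "gaussian", None, "fixed"),
        RegressionSpec("lognormal", "lognormal", c1, c2, "student_t", df, "fixed"),
        RegressionSpec("lognormal", "gamma", c1, c2, "student_t", df, "fixed"),
        RegressionSpec("gamma", "lognormal", c1, c2, "student_t", df, "fixed"),
    ]
    return lm + glm + cop


def backward_eliminate(
    spec: RegressionSpec,
    data: pd.DataFrame,
    scope: Sequence[str] | None = None,
) -> tuple[RegressionSpec, list[EliminationStep]]:
    """Backward elimination on the joint copula model's AIC.

    ``scope`` restricts which covariates may be removed (default: all;
    intercepts are never eliminable). One covariate leaves one margin per
    step — the removal with the greatest AIC decrease — and the search stops
    when no removal decreases AIC, so the trace AIC is non-increasing.
    Candidate removals whose refit fails are skipped with a warning.
    """
    scope_set = set(scope) if scope is not None else set(spec.covariates1) | set(spec.covariates2)
    current = spec
    current_aic = fit_copula_regression(current, data).aic
    trace: list[EliminationStep] = []
    step = 0
    while True:
        step += 1
        candidates = [(1, c) for c in current.covariates1 if c in scope_set]
        candidates += [(2, c) for c in current.covariates2 if c in scope_set]
        if not candidates:
            break
        best = None
        for margin, cov in candidates:
            trial = current.drop(margin, cov)
            try:
                aic = fit_copula_regression(trial, data).aic
            except (FitError, np.linalg.LinAlgError) as exc:
                logger.warning("skipping removal of %s from margin %d: %s", cov, margin, exc)
                continue
            if best is None or aic < best[0]:
                best = (aic, margin, cov, trial)
        if best is None or best[0] >= current_aic:
            break
        aic, margin, cov, trial = best
        trace.append(EliminationStep(step, margin, cov, current_aic, aic))
        current, current_aic = trial, aic
    return current, trace


def elimination_table(trace: Sequence[EliminationStep]) -> pd.DataFrame:
    return pd.DataFrame([
        {"step": s.step, "margin": s.margin, "removed": s.covariate,
         "aic_before": s.aic_before, "aic_after": s.aic_after}
        for s in trace
    ])
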