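"""All-subsets construction of limited-sampling equations.

A limited-sampling strategy (LSS) predicts the full-interval trapezoidal
AUC(0-24) from a handful of early concentrations. This module enumerates every
non-empty subset of the candidate time-points (C0, C1, C2, C4 by default; the
late points are deliberately excluded so sampling fits an outpatient morning
visit), fits ordinary least squares for each subset, and compares the fits by
adjusted r-squared, in-sample median absolute prediction error, and AIC/BIC
weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, MissingSampleError, SingularDesignError, ValidationError
from .pk_exposure import ConcentrationProfile

DEFAULT_CANDIDATES = ("C0", "C1", "C2", "C4")
DEFAULT_ADJ_R2_THRESHOLD = 0.799


@dataclass(frozen=True)
class RegressionModel:
    """One fitted LSS candidate: a predictor subset with its OLS fit."""

    predictors: tuple[str, ...]
    intercept: float
    coefficients: dict[str, float]  # ng*h/mL per ng/mL
    n: int
    rss: float
    r2: float
    adj_r2: float
    aic: float
    bic: float
    mape: float  # in-sample median APE, %

    @property
    def equation(self) -> str:
        terms = "".join(f" + {p}*{self.coefficients[p]:.4g}" for p in self.predictors)
        return f"AUC = {self.intercept:.4g}{terms}"


@dataclass
class ModelComparison:
    """Retention flags and information-criterion weights over a model set."""

    models: list[RegressionModel]
    retained: list[bool]
    aic_weights: np.ndarray
    bic_weights: np.ndarray
    weights_over_all: bool  # True when nothing passed the threshold (fallback)


def enumerate_predictor_subsets(
    candidates: Sequence[str] = DEFAULT_CANDIDATES,
) -> list[tuple[str, ...]]:
    """All 2^k - 1 non-empty predictor subsets, by size then label order.

    With the four canonical candidates this ordering yields the conventional
    model numbering 1-15 (singles first, then pairs, triples, the full set).
    """
    if not 1 <= len(candidates) <= 16:
        raise ConfigError("need between 1 and 16 candidate time-points")
    if len(set(candidates)) != len(candidates):
        raise ConfigError("candidate labels must be unique")
    ordered = sorted(candidates)
    return [s for size in range(1, len(ordered) + 1) for s in combinations(ordered, size)]


def fit_ols(design: pd.DataFrame, response: Sequence[float]) -> RegressionModel:
    """Least squares with intercept of AUC on the given concentration columns.

    Raises SingularDesignError (naming the offending columns) when the design
    with intercept is rank-deficient.
    """
    y = np.asarray(response, dtype=float)
    cols = list(design.columns)
    x = np.column_stack([np.ones(len(design)), design.to_numpy(dtype=float)])
    n, p_plus_1 = x.shape
    if n <= p_plus_1:
        raise ValidationError(f"need more than {p_plus_1} observations to fit {cols}")
    if y.shape != (n,):
        raise ValidationError("response length must match design rows")
    rank = np.linalg.matrix_rank(x)
    if rank < p_plus_1:
        bad = _collinear_columns(x, cols)
        raise SingularDesignError(f"rank-deficient design; collinear columns: {bad}", columns=bad)
    beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    fitted = x @ beta
    resid = y - fitted
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if tss == 0.0 else 1.0 - rss / tss
    p = len(cols)
    adj = adjusted_r2(r2, n, p)
    aic, bic = information_criteria(n, rss, p)
    with np.errstate(divide="ignore", invalid="ignore"):
        apes = 100.0 * np.abs(fitted - y) / y
    mape = float(np.median(apes))
    return RegressionModel(
        predictors=tuple(cols),
        intercept=float(beta[0]),
        coefficients={c: float(b) for c, b in zip(cols, beta[1:])},
        n=n,
        rss=rss,
        r2=float(r2),
        adj_r2=float(adj),
        aic=aic,
        bic=bic,
        mape=mape,
    )


def _collinear_columns(x: np.ndarray, cols: list[str]) -> list[str]:
    """Columns whose removal restores full rank (greedy, for error messages)."""
    bad = []
    keep = list(range(x.shape[1]))
    for j in range(1, x.shape[1]):  # never drop the intercept
        trial = [i for i in keep if i != j]
        if np.linalg.matrix_rank(x[:, trial]) == np.linalg.matrix_rank(x[:, keep]):
            bad.append(cols[j - 1])
            keep = trial
    return bad


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """1 - (1 - r2)(n - 1)/(n - p - 1); penalizes predictor count."""
    if n <= p + 1:
        raise ValidationError(f"adjusted r2 undefined for n={n}, p={p}")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def information_criteria(n: int, rss: float, p: int) -> tuple[float, float]:
    """Gaussian profile-likelihood AIC and BIC (up to a shared constant).

    k = p + 2 counts the intercept and the residual variance. Only differences
    across models fitted to the same response are meaningful. A perfect fit
    (rss = 0) maps to -inf for both criteria.
    """
    k = p + 2
    if rss <= 0.0:
        return float("-inf"), float("-inf")
    base = n * np.log(rss / n)
    return float(base + 2 * k), float(base + k * np.log(n))


def akaike_weights(values: Sequence[float]) -> np.ndarray:
    """exp(-delta/2) weights, normalized to sum to 1; same form for AIC and BIC.

    Models with -inf criterion (perfect fits) absorb all the weight, shared
    equally among themselves.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0 or np.all(np.isnan(v)):
        raise ValidationError("need at least one finite criterion value")
    if np.any(np.isneginf(v)):
        w = np.where(np.isneginf(v), 1.0, 0.0)
        return w / w.sum()
    delta = v - np.min(v)
    w = np.exp(-0.5 * delta)
    return w / w.sum()


def retain_models(
    models: Sequence[RegressionModel], threshold: float = DEFAULT_ADJ_R2_THRESHOLD
) -> ModelComparison:
    """Flag models with adjusted r2 strictly above the threshold; weight the rest.

    AIC/BIC weights are computed over the retained set only. If nothing passes,
    a warning is issued and the weights fall back to the full model set (the
    ``weights_over_all`` flag records this).
    """
    if not 0.0 < threshold < 1.0:
        raise ConfigError(f"retention threshold must lie in (0, 1), got {threshold}")
    models = list(models)
    retained = [m.adj_r2 > threshold for m in models]
    pool = [i for i, keep in enumerate(retained) if keep]
    fallback = not pool
    if fallback:
        warnings.warn(
            f"no model exceeds adjusted r2 threshold {threshold}; weights span all models",
            stacklevel=2,
        )
        pool = list(range(len(models)))
    aic_w = np.zeros(len(models))
    bic_w = np.zeros(len(models))
    aic_w[pool] = akaike_weights([models[i].aic for i in pool])
    bic_w[pool] = akaike_weights([models[i].bic for i in pool])
    return ModelComparison(models, retained, aic_w, bic_w, fallback)


def predict_auc(model: RegressionModel, profile: ConcentrationProfile | Mapping[str, float]) -> float:
    """Evaluate an LSS equation on one profile: intercept + sum(coef * conc)."""
    conc = profile.as_mapping() if isinstance(profile, ConcentrationProfile) else dict(profile)
    total = model.intercept
    for label, coef in model.coefficients.items():
        if label not in conc:
            raise MissingSampleError(f"profile lacks required time-point {label}")
        total += coef * float(conc[label])
    return float(total)


def wide_concentrations(concentrations: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long concentration table to one row per patient, label columns."""
    return concentrations.pivot(index="patient_id", columns="label", values="conc_ng_ml")


def fit_all_subsets(
    concentrations_wide: pd.DataFrame,
    auc: pd.Series,
    candidates: Sequence[str] = DEFAULT_CANDIDATES,
    threshold: float = DEFAULT_ADJ_R2_THRESHOLD,
) -> tuple[ModelComparison, pd.DataFrame]:
    """Fit every candidate subset against trapezoidal AUC and tabulate the results.

    ``concentrations_wide`` is indexed by patient with one column per time-point
    label; ``auc`` is aligned on the same index. Returns the ModelComparison and
    a tidy table (one row per subset, conventional model numbering).
    """
    missing = [c for c in candidates if c not in concentrations_wide.columns]
    if missing:
        raise ValidationError(f"concentration table lacks candidate columns {missing}")
    x_all, y = concentrations_wide.align(auc, join="inner", axis=0)
    models = [fit_ols(x_all[list(subset)], y) for subset in enumerate_predictor_subsets(candidates)]
    comparison = retain_models(models, threshold)
    rows = []
    for i, (m, keep) in enumerate(zip(models, comparison.retained), start=1):
        rows.append(
            {
                "model": i,
                "predictors": "-".join(m.predictors),
                "equation": m.equation,
                "intercept": m.intercept,
                **{f"coef_{p}": m.coefficients.get(p, np.nan) for p in candidates},
                "n": m.n,
                "r2": m.r2,
                "adj_r2": m.adj_r2,
                "aic": m.aic,
                "bic": m.bic,
                "mape_pct": m.mape,
                "retained": keep,
                "aic_weight": comparison.aic_weights[i - 1],
                "bic_weight": comparison.bic_weights[i - 1],
            }
        )
    return comparison, pd.DataFrame(rows)
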