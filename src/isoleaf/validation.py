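"""Cross-validation, factor selection, model statistics, outlier screening.

Validation follows the small-n chemometrics playbook: 10-fold cross-
validation with random segments, the factor count chosen at the first local
minimum of the cross-validated RMSE curve, and an influential-outlier screen
combining leverage with studentized residuals.  The per-segment coefficient
vectors retained in :class:`CVResult` are the raw material of the jackknife
(Martens) significance test in :mod:`isoleaf.selection`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .pls import PLSModel, fit_pls1_nipals, predict

__all__ = [
    "CVResult",
    "ModelReport",
    "kfold_split",
    "cross_validate",
    "select_n_factors",
    "model_statistics",
    "detect_influential_outliers",
]


def kfold_split(n: int, k: int = 10, seed: int | None = None) -> np.ndarray:
    """Random partition of ``n`` samples into ``k`` segments of near-equal size.

    Returns an integer array of segment labels in ``0..k-1``; sizes differ by
    at most one.  Deterministic under ``seed``.
    """
    if k > n:
        raise ValueError(f"cannot split n={n} samples into k={k} segments")
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    labels = np.arange(n) % k
    return labels[rng.permutation(n)]


@dataclass
class CVResult:
    """Everything a k-fold cross-validation produced.

    ``predictions`` holds the held-out prediction of every sample for every
    candidate factor count (n x A_max, raw response units); each sample is
    predicted exactly once per factor count, by the submodel that did not see
    it.  ``submodel_coefficients`` are the per-segment regression vectors on
    the raw metric, resolved per factor count (k x A_max x p).
    """

    k: int
    assignments: np.ndarray
    predictions: np.ndarray
    rmse_cv_per_A: np.ndarray
    submodel_coefficients: np.ndarray
    submodel_intercepts: np.ndarray
    seed: Optional[int]
    y: np.ndarray

    @property
    def a_max(self) -> int:
        return self.predictions.shape[1]

    def predictions_at(self, n_factors: int) -> np.ndarray:
        return self.predictions[:, n_factors - 1]

    def coefficients_at(self, n_factors: int) -> np.ndarray:
        """k x p submodel coefficient matrix at the given factor count."""
        return self.submodel_coefficients[:, n_factors - 1, :]


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    a_max: int,
    k: int = 10,
    seed: int | None = None,
    var_names: Sequence | None = None,
) -> CVResult:
    """k-fold cross-validation of autoscaled PLS1 over factor counts 1..a_max.

    Every fold re-estimates the autoscaling on its training remainder, fits
    once with ``a_max`` factors and predicts its held-out segment for every
    truncated factor count, so the RMSE-vs-factors curve comes from a single
    pass.  ``a_max`` is clamped (with a warning) when a training fold is too
    small to support it.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    assignments = kfold_split(n, k, seed)
    min_train = n - int(np.bincount(assignments, minlength=k).max())
    limit = min(min_train - 1, p)
    if a_max > limit:
        warnings.warn(f"a_max={a_max} exceeds fold capacity; clamped to {limit}")
        a_max = limit
    if a_max < 1:
        raise ValueError("training folds too small for even one factor")

    predictions = np.full((n, a_max), np.nan)
    coefs = np.zeros((k, a_max, p))
    intercepts = np.zeros((k, a_max))
    for seg in range(k):
        held = assignments == seg
        model = fit_pls1_nipals(X[~held], y[~held], a_max, var_names=var_names)
        a_fit = model.n_factors  # may be truncated by rank
        for a in range(1, a_max + 1):
            a_eff = min(a, a_fit)
            predictions[held, a - 1] = predict(model, X[held], n_factors=a_eff)
            b, b0 = model.coefficients_raw(a_eff)
            coefs[seg, a - 1] = b
            intercepts[seg, a - 1] = b0
    rmse = np.sqrt(np.mean((predictions - y[:, None]) ** 2, axis=0))
    return CVResult(
        k=k,
        assignments=assignments,
        predictions=predictions,
        rmse_cv_per_A=rmse,
        submodel_coefficients=coefs,
        submodel_intercepts=intercepts,
        seed=seed,
        y=y.copy(),
    )


def select_n_factors(rmse_cv_per_A: Sequence[float]) -> int:
    """First local minimum of the cross-validated RMSE curve.

    Returns the smallest factor count whose RMSE is lower than the next
    one's; a monotonically decreasing curve returns the last count with a
    warning (more factors might still help).
    """
    rmse = np.asarray(rmse_cv_per_A, dtype=float)
    if rmse.size == 0:
        raise ValueError("empty RMSE sequence")
    for a in range(rmse.size - 1):
        if rmse[a] < rmse[a + 1]:
            return a + 1
    if rmse.size > 1:
        warnings.warn(
            "RMSE_cv monotonically non-increasing; returning the maximum "
            "factor count tried"
        )
    return int(rmse.size)


@dataclass
class ModelReport:
    """One row of the standard calibration-report table.

    Slopes and offsets come from regressing predicted on measured values;
    R2_cal is 1 - SSres/SStot on the calibration fit, R2_cv is 1 - PRESS/SStot
    on the held-out predictions, and ``rmse_cv_pct_range`` expresses RMSE_cv
    as a percentage of the measured response range.
    """

    n: int
    n_factors: int
    n_x_variables: int
    n_mut_iterations: int
    offset_cal: float
    offset_cv: float
    slope_cal: float
    slope_cv: float
    r2_cal: float
    r2_cv: float
    rmse_cal: float
    rmse_cv: float
    rmse_cv_pct_range: float
    r2_cv_corr: float = float("nan")  # squared-correlation variant, logged only
    species: str = ""
    seed: Optional[int] = None

    _TABLE_COLUMNS = [
        "species",
        "n",
        "No. factors",
        "No. X-variables",
        "No. iterations (MUT)",
        "Offset_cal",
        "Offset_cv",
        "Slope_cal",
        "Slope_cv",
        "R2_cal",
        "R2_cv",
        "RMSE_cal",
        "RMSE_cv",
        "RMSE_cv_pct_range",
        "seed",
    ]

    def to_row(self) -> dict:
        return {
            "species": self.species,
            "n": self.n,
            "No. factors": self.n_factors,
            "No. X-variables": self.n_x_variables,
            "No. iterations (MUT)": self.n_mut_iterations,
            "Offset_cal": self.offset_cal,
            "Offset_cv": self.offset_cv,
            "Slope_cal": self.slope_cal,
            "Slope_cv": self.slope_cv,
            "R2_cal": self.r2_cal,
            "R2_cv": self.r2_cv,
            "RMSE_cal": self.rmse_cal,
            "RMSE_cv": self.rmse_cv,
            "RMSE_cv_pct_range": self.rmse_cv_pct_range,
            "seed": self.seed,
        }


def _slope_offset(measured: np.ndarray, predicted: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of predicted = slope * measured + offset."""
    sxx = float(np.sum((measured - measured.mean()) ** 2))
    if sxx == 0:
        raise ValueError("measured values have zero variance")
    slope = float(np.sum((measured - measured.mean()) * (predicted - predicted.mean())) / sxx)
    offset = float(predicted.mean() - slope * measured.mean())
    return slope, offset


def model_statistics(
    y: np.ndarray, y_cal_hat: np.ndarray, y_cv_hat: np.ndarray
) -> dict[str, float]:
    """Calibration/validation statistics of one model (report-table fragment)."""
    y = np.asarray(y, dtype=float)
    y_cal_hat = np.asarray(y_cal_hat, dtype=float)
    y_cv_hat = np.asarray(y_cv_hat, dtype=float)
    if not (y.shape == y_cal_hat.shape == y_cv_hat.shape):
        raise ValueError("y, calibration and CV predictions must share a length")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("response has zero variance")
    slope_cal, offset_cal = _slope_offset(y, y_cal_hat)
    slope_cv, offset_cv = _slope_offset(y, y_cv_hat)
    ss_res = float(np.sum((y - y_cal_hat) ** 2))
    press = float(np.sum((y - y_cv_hat) ** 2))
    rmse_cal = float(np.sqrt(ss_res / y.size))
    rmse_cv = float(np.sqrt(press / y.size))
    y_range = float(y.max() - y.min())
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(y, y_cv_hat)[0, 1]
    return {
        "offset_cal": offset_cal,
        "offset_cv": offset_cv,
        "slope_cal": slope_cal,
        "slope_cv": slope_cv,
        "r2_cal": 1.0 - ss_res / ss_tot,
        "r2_cv": 1.0 - press / ss_tot,
        "r2_cv_corr": float(corr**2) if np.isfinite(corr) else 0.0,
        "rmse_cal": rmse_cal,
        "rmse_cv": rmse_cv,
        "rmse_cv_pct_range": 100.0 * rmse_cv / y_range if y_range > 0 else float("nan"),
    }


def detect_influential_outliers(
    X: np.ndarray,
    y: np.ndarray,
    n_factors: int,
    leverage_factor: float = 3.0,
    residual_threshold: float = 2.5,
    max_fraction: float = 0.05,
    sample_ids: Sequence | None = None,
) -> list:
    """Flag samples that pull the model strongly yet are poorly described.

    A sample is influential when its leverage in the factor-score space
    exceeds ``leverage_factor * (A + 1) / n`` AND its studentized calibration
    residual exceeds ``residual_threshold`` in magnitude.  At most
    ``max_fraction`` of the samples are flagged per pass (largest residuals
    first); removal is the caller's decision and should be logged, never
    silent.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    model = fit_pls1_nipals(X, y, n_factors)
    a = model.n_factors
    T = model.scores
    G = T.T @ T
    leverage = 1.0 / n + np.einsum("ia,ab,ib->i", T, np.linalg.inv(G), T)
    resid = y - predict(model, X)
    dof = max(n - a - 1, 1)
    s = np.sqrt(float(resid @ resid) / dof)
    if s == 0:
        return []
    stud = resid / (s * np.sqrt(np.clip(1.0 - leverage, 1e-12, None)))
    lev_cut = leverage_factor * (a + 1) / n
    flagged = np.flatnonzero((leverage > lev_cut) & (np.abs(stud) > residual_threshold))
    cap = max(int(np.floor(max_fraction * n)), 1) if flagged.size else 0
    if flagged.size > cap:
        order = np.argsort(-np.abs(stud[flagged]))
        flagged = flagged[order[:cap]]
    if sample_ids is not None:
        ids = list(sample_ids)
        return [ids[i] for i in flagged]
    return [int(i) for i in flagged]
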