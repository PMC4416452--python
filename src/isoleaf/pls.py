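"""PLS1 regression by NIPALS with autoscaling, plus VIP interpretation scores.

Partial least squares projects the (autoscaled) predictor matrix X onto a
small number of latent factors chosen to maximize, factor by factor, the
covariance between X-scores and the single response y.  For one response the
NIPALS weight vector has the closed form ``w = X'y / ||X'y||`` per deflation
step, which is algebraically identical to the converged iterative NIPALS
inner loop; factors are extracted by deflating X (and y) after each step.

All scaling parameters (per-variable means and SDs of X, mean and SD of y,
sample-SD convention n-1) are model state estimated on the fitting partition
only, so cross-validated predictions stay honest.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = ["PLSModel", "fit_pls1_nipals", "predict", "explained_variance", "vip"]

_RANK_TOL = 1e-12


@dataclass
class PLSModel:
    """Fitted PLS1 model: factor basis, scaling state and coefficients.

    weights ``W`` (p x A, unit-norm columns), x_loadings ``P`` (p x A),
    y_loadings ``q`` (A,), training scores ``T`` (n x A, mutually
    orthogonal) and ``R = W (P'W)^{-1}`` so that the coefficient vector on
    the autoscaled metric for the first ``a`` factors is ``R[:, :a] @ q[:a]``.
    ``ss_y_per_factor`` is the per-factor explained sum of squares of the
    autoscaled response (the SS_a weights of the VIP formula).
    """

    n_factors: int
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    scores: np.ndarray
    rotation: np.ndarray  # R = W (P'W)^{-1}
    ss_y_per_factor: np.ndarray
    total_y_ss: float
    total_x_ss: float
    ss_x_per_factor: np.ndarray
    var_names: Optional[np.ndarray] = None

    @property
    def n_variables(self) -> int:
        return self.weights.shape[0]

    def coefficients_scaled(self, n_factors: int | None = None) -> np.ndarray:
        """Regression vector on the autoscaled X/y metric."""
        a = self.n_factors if n_factors is None else n_factors
        if not 1 <= a <= self.n_factors:
            raise ValueError(f"n_factors must be in [1, {self.n_factors}]")
        return self.rotation[:, :a] @ self.y_loadings[:a]

    def coefficients_raw(self, n_factors: int | None = None) -> tuple[np.ndarray, float]:
        """(slope vector, intercept) on the original units of X and y."""
        b_s = self.coefficients_scaled(n_factors)
        b = self.y_sd * b_s / self.x_sd
        intercept = self.y_mean - float(b @ self.x_mean)
        return b, intercept

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "n_factors": self.n_factors,
            "x_mean": self.x_mean.tolist(),
            "x_sd": self.x_sd.tolist(),
            "y_mean": self.y_mean,
            "y_sd": self.y_sd,
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "scores": self.scores.tolist(),
            "rotation": self.rotation.tolist(),
            "ss_y_per_factor": self.ss_y_per_factor.tolist(),
            "total_y_ss": self.total_y_ss,
            "total_x_ss": self.total_x_ss,
            "ss_x_per_factor": self.ss_x_per_factor.tolist(),
            "var_names": None if self.var_names is None else np.asarray(self.var_names).tolist(),
        }
        text = json.dumps(doc)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @staticmethod
    def from_json(source: str | Path) -> "PLSModel":
        text = Path(source).read_text(encoding="utf-8") if Path(str(source)).exists() else str(source)
        doc = json.loads(text)
        return PLSModel(
            n_factors=doc["n_factors"],
            x_mean=np.array(doc["x_mean"]),
            x_sd=np.array(doc["x_sd"]),
            y_mean=doc["y_mean"],
            y_sd=doc["y_sd"],
            weights=np.array(doc["weights"]),
            x_loadings=np.array(doc["x_loadings"]),
            y_loadings=np.array(doc["y_loadings"]),
            scores=np.array(doc["scores"]),
            rotation=np.array(doc["rotation"]),
            ss_y_per_factor=np.array(doc["ss_y_per_factor"]),
            total_y_ss=doc["total_y_ss"],
            total_x_ss=doc["total_x_ss"],
            ss_x_per_factor=np.array(doc["ss_x_per_factor"]),
            var_names=None if doc["var_names"] is None else np.array(doc["var_names"]),
        )


def _autoscale(X: np.ndarray, y: np.ndarray):
    x_mean = X.mean(axis=0)
    x_sd = X.std(axis=0, ddof=1)
    zero = x_sd == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-variance X column(s); they receive zero "
            "weight and zero coefficient"
        )
        x_sd = np.where(zero, 1.0, x_sd)
    y_mean = float(y.mean())
    y_sd = float(y.std(ddof=1))
    if y_sd == 0:
        raise ValueError("response has zero variance")
    return x_mean, x_sd, y_mean, y_sd


def fit_pls1_nipals(
    X: np.ndarray,
    y: np.ndarray,
    n_factors: int,
    var_names: Sequence | None = None,
) -> PLSModel:
    """Fit autoscaled PLS1 by NIPALS deflation.

    Per factor a: ``w_a = X'y/||X'y||``, ``t_a = X w_a``,
    ``p_a = X't_a/(t_a't_a)``, ``q_a = y't_a/(t_a't_a)``, then X and y are
    deflated by the rank-one factor contribution.  Factors whose score
    energy falls below ``1e-12`` of the initial X sum of squares are
    truncated with a warning (rank exhausted).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y disagree on the number of samples")
    if not 1 <= n_factors <= min(n - 1, p):
        raise ValueError(f"n_factors must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}]")

    x_mean, x_sd, y_mean, y_sd = _autoscale(X, y)
    Xd = (X - x_mean) / x_sd
    yd = (y - y_mean) / y_sd
    total_x_ss = float(np.sum(Xd**2))
    total_y_ss = float(np.sum(yd**2))

    W = np.zeros((p, n_factors))
    P = np.zeros((p, n_factors))
    q = np.zeros(n_factors)
    T = np.zeros((n, n_factors))
    ss_y = np.zeros(n_factors)
    ss_x = np.zeros(n_factors)

    a_used = n_factors
    for a in range(n_factors):
        w = Xd.T @ yd
        norm = np.linalg.norm(w)
        if norm == 0:
            a_used = a
            warnings.warn(f"y residual orthogonal to X after {a} factor(s); truncating")
            break
        w /= norm
        t = Xd @ w
        tt = float(t @ t)
        if tt <= _RANK_TOL * total_x_ss:
            a_used = a
            warnings.warn(f"X rank exhausted after {a} factor(s); truncating")
            break
        p_a = Xd.T @ t / tt
        q_a = float(yd @ t) / tt
        W[:, a], P[:, a], q[a], T[:, a] = w, p_a, q_a, t
        ss_y[a] = q_a**2 * tt
        ss_x[a] = tt * float(p_a @ p_a)
        Xd -= np.outer(t, p_a)
        yd -= q_a * t

    if a_used == 0:
        raise ValueError("no PLS factor could be extracted (X'y = 0)")
    W, P, q, T = W[:, :a_used], P[:, :a_used], q[:a_used], T[:, :a_used]
    ss_y, ss_x = ss_y[:a_used], ss_x[:a_used]

    # R = W (P'W)^{-1}, built by the standard recursion (P'W is unit upper
    # triangular for NIPALS PLS1).
    R = np.zeros_like(W)
    for a in range(a_used):
        r = W[:, a].copy()
        for i in range(a):
            r -= float(P[:, i] @ W[:, a]) * R[:, i]
        R[:, a] = r

    return PLSModel(
        n_factors=a_used,
        x_mean=x_mean,
        x_sd=x_sd,
        y_mean=y_mean,
        y_sd=y_sd,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        scores=T,
        rotation=R,
        ss_y_per_factor=ss_y,
        total_y_ss=total_y_ss,
        total_x_ss=total_x_ss,
        ss_x_per_factor=ss_x,
        var_names=None if var_names is None else np.asarray(var_names),
    )


def _check_axis(model: PLSModel, X_new: np.ndarray, var_names) -> None:
    if X_new.shape[1] != model.n_variables:
        raise ValueError(
            f"X has {X_new.shape[1]} variables, model expects {model.n_variables}"
        )
    if var_names is not None and model.var_names is not None:
        given = np.asarray(var_names)
        if not np.array_equal(given, model.var_names):
            off = [str(v) for v in given[given != model.var_names][:5]]
            raise ValueError(f"variable axis mismatch; offending entries: {off}")


def predict(
    model: PLSModel,
    X_new: np.ndarray,
    n_factors: int | None = None,
    var_names: Sequence | None = None,
) -> np.ndarray:
    """Predict the response on its raw metric for new rows of X."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    _check_axis(model, X_new, var_names)
    b_s = model.coefficients_scaled(n_factors)
    Xs = (X_new - model.x_mean) / model.x_sd
    return model.y_mean + model.y_sd * (Xs @ b_s)


def transform(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Project new rows of X onto the model's factor scores."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    _check_axis(model, X_new, None)
    Xs = (X_new - model.x_mean) / model.x_sd
    return Xs @ model.rotation


def explained_variance(model: PLSModel) -> dict[str, np.ndarray]:
    """Per-factor % of the response (and predictor) variance captured."""
    return {
        "y_pct": 100.0 * model.ss_y_per_factor / model.total_y_ss,
        "x_pct": 100.0 * model.ss_x_per_factor / model.total_x_ss,
    }


def vip(model: PLSModel) -> np.ndarray:
    """Variable importance in projection.

    VIP_j = sqrt( p * sum_a SS_a (w_aj/||w_a||)^2 / sum_a SS_a ), where SS_a
    is the response sum of squares explained by factor a.  The mean of the
    squared VIPs over all p variables is exactly 1, which is why 1 (and the
    softer 0.8) serve as conventional importance cutoffs.
    """
    ss = model.ss_y_per_factor
    total = float(ss.sum())
    if total <= 0:
        raise ValueError("model explains no response variance; VIP undefined")
    W2 = model.weights**2  # columns already unit norm
    p = model.n_variables
    return np.sqrt(p * (W2 @ ss) / total)
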