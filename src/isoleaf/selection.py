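"""Jackknife (Martens) coefficient significance and iterated wavelength elimination.

Cross-validation yields one regression vector per submodel; the spread of a
wavelength's coefficient across submodels estimates its uncertainty, and a
coefficient indistinguishable from zero marks an uninformative wavelength.
Eliminating the non-significant wavelengths and re-validating, repeatedly,
shrinks the model to a stable subset — accepted only while the cross-
validated RMSE does not deteriorate, with parsimony breaking ties.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .pls import PLSModel, fit_pls1_nipals
from .validation import CVResult, cross_validate, select_n_factors

__all__ = [
    "martens_uncertainty_test",
    "iterative_elimination",
    "EliminationTrace",
    "EliminationResult",
]


def martens_uncertainty_test(
    cv: CVResult | np.ndarray,
    b_full: np.ndarray,
    alpha: float = 0.05,
    n_factors: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Significance of each regression coefficient from its jackknife spread.

    For variable j with full-model coefficient ``b_j`` and submodel
    coefficients ``b_j^(m)`` (m = 1..k), the jackknife standard error is
    ``s_j = sqrt((k-1)/k * sum_m (b_j^(m) - b_j)^2)`` and the statistic
    ``t_j = |b_j| / s_j`` is referred to a t distribution with k-1 degrees of
    freedom (two-sided).  Returns (significant mask, p-values).

    Degenerate spreads: ``s_j = 0`` with ``b_j = 0`` is not significant
    (dead variable); ``s_j = 0`` with ``b_j != 0`` is significant (perfectly
    stable coefficient).
    """
    if isinstance(cv, CVResult):
        if n_factors is None:
            raise ValueError("n_factors required when passing a CVResult")
        B = cv.coefficients_at(n_factors)
    else:
        B = np.asarray(cv, dtype=float)
    b_full = np.asarray(b_full, dtype=float).ravel()
    k, p = B.shape
    if b_full.size != p:
        raise ValueError("b_full length does not match submodel coefficients")
    s2 = (k - 1) / k * np.sum((B - b_full) ** 2, axis=0)
    s = np.sqrt(s2)
    pvals = np.ones(p)
    live = s > 0
    with np.errstate(divide="ignore"):
        t = np.abs(b_full[live]) / s[live]
    pvals[live] = 2.0 * stats.t.sf(t, df=k - 1)
    # zero spread: significance decided by the coefficient itself
    pvals[~live] = np.where(b_full[~live] != 0, 0.0, 1.0)
    return pvals < alpha, pvals


@dataclass
class EliminationTrace:
    """Per-iteration record of the elimination loop."""

    iterations: list[dict] = field(default_factory=list)
    stop_reason: str = ""

    def add(self, n_vars: int, rmse_cv: float, n_factors: int, significant: np.ndarray) -> None:
        self.iterations.append(
            {
                "iteration": len(self.iterations),
                "n_vars": int(n_vars),
                "rmse_cv": float(rmse_cv),
                "n_factors": int(n_factors),
                "n_significant": int(np.sum(significant)) if significant is not None else None,
            }
        )

    @property
    def n_mut_iterations(self) -> int:
        """Number of uncertainty-test passes applied (trace rows after the baseline)."""
        return len(self.iterations) - 1

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.iterations)


@dataclass
class EliminationResult:
    model: PLSModel
    cv: CVResult
    n_factors: int
    retained_mask: np.ndarray
    trace: EliminationTrace

    @property
    def retained_names(self) -> np.ndarray | None:
        return None if self.model.var_names is None else self.model.var_names


def _fold_seeds(master_seed: int, count: int) -> list[int]:
    """Deterministic per-iteration CV seeds derived from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) & 0x7FFFFFFF for s in ss.generate_state(count)]


def iterative_elimination(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 10,
    seed: int = 0,
    alpha: float = 0.05,
    max_iter: int = 10,
    a_max: int = 10,
    var_names=None,
    rel_tol: float = 1e-3,
) -> EliminationResult:
    """Iterate cross-validation + uncertainty test to a stable wavelength set.

    Each pass: cross-validate the current variables, pick the factor count at
    the first RMSE_cv minimum, fit the full-data model there, test every
    coefficient against its jackknife spread, drop the non-significant
    variables and re-validate.  The reduced model is accepted iff its RMSE_cv
    is no worse than the current one (within ``rel_tol`` it counts as equal
    and the smaller model wins on parsimony); otherwise the pass is rejected
    and the loop stops.  CV segments are re-randomized each pass from a
    deterministic seed sequence, so the whole trace reproduces exactly.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    names = np.arange(p) if var_names is None else np.asarray(var_names)
    seeds = _fold_seeds(seed, max_iter + 1)

    mask = np.ones(p, dtype=bool)
    trace = EliminationTrace()

    def _validate(m: np.ndarray, it: int):
        cv = cross_validate(X[:, m], y, min(a_max, int(m.sum())), k=k, seed=seeds[it])
        a_star = select_n_factors(cv.rmse_cv_per_A)
        return cv, a_star, float(cv.rmse_cv_per_A[a_star - 1])

    cv, a_star, rmse = _validate(mask, 0)
    model = fit_pls1_nipals(X[:, mask], y, a_star, var_names=names[mask])
    trace.add(mask.sum(), rmse, a_star, None)

    for it in range(1, max_iter + 1):
        b_full, _ = model.coefficients_raw(model.n_factors)
        significant, _pvals = martens_uncertainty_test(
            cv, b_full, alpha=alpha, n_factors=model.n_factors
        )
        if significant.all():
            trace.stop_reason = "no_removals"
            trace.add(mask.sum(), rmse, a_star, significant)
            break
        if not significant.any():
            warnings.warn("uncertainty test would eliminate every variable; stopping")
            trace.stop_reason = "no_improvement"
            trace.add(mask.sum(), rmse, a_star, significant)
            break
        new_mask = mask.copy()
        new_mask[np.flatnonzero(mask)[~significant]] = False
        cv_new, a_new, rmse_new = _validate(new_mask, it)
        # strictly better, or equal within rel_tol (the reduced model always
        # has fewer variables, so equality is decided by parsimony)
        accepted = rmse_new <= rmse * (1.0 + rel_tol)
        if not accepted:
            trace.stop_reason = "no_improvement"
            trace.add(mask.sum(), rmse, a_star, significant)
            break
        mask, cv, a_star, rmse = new_mask, cv_new, a_new, rmse_new
        model = fit_pls1_nipals(X[:, mask], y, a_star, var_names=names[mask])
        trace.add(mask.sum(), rmse, a_star, significant)
        if it == max_iter:
            trace.stop_reason = "max_iterations"

    if not trace.stop_reason:
        trace.stop_reason = "max_iterations"
    return EliminationResult(
        model=model, cv=cv, n_factors=a_star, retained_mask=mask, trace=trace
    )


def selection_aware_cv(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 10,
    seed: int = 0,
    alpha: float = 0.05,
    max_iter: int = 10,
    a_max: int = 10,
    var_names=None,
) -> np.ndarray:
    """Honest held-out predictions under wavelength selection (cross-model validation).

    Re-validating a wavelength subset that was itself chosen using all the
    samples understates the prediction error: under pure noise the naive
    post-selection RMSE_cv can suggest substantial skill.  Here the *entire*
    elimination procedure is re-run inside each training fold of an outer
    k-fold split, and only then is the fold's held-out segment predicted — so
    no sample ever contributes to the selection that predicts it.  Returns
    the out-of-fold prediction for every sample (raw response units).
    """
    from .pls import predict as _predict
    from .validation import kfold_split

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    outer_seeds = _fold_seeds(seed ^ 0x5EED, k + 1)
    assignments = kfold_split(y.size, k, outer_seeds[0])
    predictions = np.full(y.size, np.nan)
    for seg in range(k):
        held = assignments == seg
        res = iterative_elimination(
            X[~held],
            y[~held],
            k=k,
            seed=outer_seeds[seg + 1],
            alpha=alpha,
            max_iter=max_iter,
            a_max=a_max,
            var_names=var_names,
        )
        predictions[held] = _predict(
            res.model, X[held][:, res.retained_mask], n_factors=res.n_factors
        )
    return predictions
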