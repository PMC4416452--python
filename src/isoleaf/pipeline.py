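"""End-to-end modeling drivers: species-specific and pooled delta15N models.

Each driver runs the full chain on a spectra set + metadata: structural
filters, preprocessing, influential-outlier screening, cross-validated PLS1
with iterated jackknife wavelength elimination, and report assembly (the
calibration-table row, the elimination trace, the VIP-by-wavelength table
and the measured-vs-predicted pairs).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .pls import PLSModel, predict, transform, vip
from .preprocess import PreprocessConfig, preprocess_pipeline
from .selection import EliminationResult, iterative_elimination, selection_aware_cv
from .spectra import (
    LeafType,
    SampleRecord,
    SpectraSet,
    exclude_unlabeled_mature,
    records_to_frame,
)
from .validation import ModelReport, detect_influential_outliers, model_statistics

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "SpeciesModelResult",
    "PooledModelResult",
    "run_species_model",
    "run_pooled_model",
    "report",
]


@dataclass
class RunConfig:
    """Knobs of one modeling run (defaults = the study's conventions)."""

    preprocessing: PreprocessConfig = field(default_factory=PreprocessConfig)
    k: int = 10
    alpha: float = 0.05
    max_iter: int = 10
    a_max: int = 10
    seed: int = 0
    train_fraction: float = 2.0 / 3.0
    min_samples: int = 20
    screen_outliers: bool = True
    exclude_mature_of: tuple[str, ...] = ()
    normalization: str = "subtract_min"  # for the enrichment illustration
    cv_strategy: str = "selection_aware"  # or "naive" (post-selection re-CV)

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.cv_strategy not in ("selection_aware", "naive"):
            raise ValueError("cv_strategy must be 'selection_aware' or 'naive'")


@dataclass
class SpeciesModelResult:
    species: str
    report: ModelReport
    elimination: EliminationResult
    vip_table: pd.DataFrame
    predictions: pd.DataFrame
    removed_outliers: list
    preprocessing_log: list[str]


@dataclass
class PooledModelResult:
    report: ModelReport
    test_statistics: dict
    scores: pd.DataFrame
    separation_ratio: float
    elimination: EliminationResult
    train_ids: list[str]
    test_ids: list[str]
    per_species_test_r2: dict[str, float]


def _prepare(
    sset: SpectraSet,
    records: Sequence[SampleRecord],
    config: RunConfig,
) -> tuple[SpectraSet, list[SampleRecord], list[str]]:
    """Structural filters + preprocessing shared by both drivers."""
    records = list(records)
    for species_label in config.exclude_mature_of:
        sset, records, n_removed = exclude_unlabeled_mature(sset, records, species_label)
        if n_removed:
            logger.info("excluded %d mature %s samples", n_removed, species_label)
    processed, log = preprocess_pipeline(sset, config.preprocessing)
    return processed, records, log


def _normalized(values: np.ndarray, reference_min: float, mode: str) -> np.ndarray:
    if mode == "subtract_min":
        return values - reference_min
    if mode == "divide_min":
        return values / reference_min
    raise ValueError(f"unknown normalization mode {mode!r}")


def run_species_model(
    sset: SpectraSet,
    records: Sequence[SampleRecord],
    species: str,
    config: RunConfig | None = None,
) -> SpeciesModelResult:
    """Full modeling chain for one species.

    Filters to the species (applying any configured mature-leaf exclusion),
    preprocesses, screens influential outliers once, runs the iterated
    jackknife wavelength elimination and assembles the calibration-table row,
    the per-wavelength VIP table and the measured-vs-predicted pairs
    (raw and min-normalized to illustrate enrichment).
    """
    config = config or RunConfig()
    processed, records, log = _prepare(sset, records, config)
    recs = [r for r in records if r.species == species]
    ids = [r.sample_id for r in recs]
    if len(ids) < config.min_samples:
        raise ValueError(
            f"{species}: only {len(ids)} samples after filters "
            f"(need >= {config.min_samples})"
        )
    subset = processed.subset_samples(ids)
    X = subset.matrix
    y = np.array([r.delta15N for r in recs])
    wl = subset.wavelengths

    removed: list = []
    if config.screen_outliers:
        a_screen = min(4, config.a_max)
        removed = detect_influential_outliers(
            X, y, n_factors=a_screen, sample_ids=ids
        )
        if removed:
            logger.info("%s: removed influential outliers %s", species, removed)
            keep = [i for i, s in enumerate(ids) if s not in set(removed)]
            X, y = X[keep], y[keep]
            ids = [ids[i] for i in keep]

    elim = iterative_elimination(
        X,
        y,
        k=config.k,
        seed=config.seed,
        alpha=config.alpha,
        max_iter=config.max_iter,
        a_max=config.a_max,
        var_names=wl,
    )
    model, cv = elim.model, elim.cv
    y_cal = predict(model, X[:, elim.retained_mask])
    if config.cv_strategy == "selection_aware":
        y_cv = selection_aware_cv(
            X,
            y,
            k=config.k,
            seed=config.seed,
            alpha=config.alpha,
            max_iter=config.max_iter,
            a_max=config.a_max,
            var_names=wl,
        )
    else:
        y_cv = cv.predictions_at(elim.n_factors)
    stats = model_statistics(y, y_cal, y_cv)
    rep = ModelReport(
        n=y.size,
        n_factors=elim.n_factors,
        n_x_variables=int(elim.retained_mask.sum()),
        n_mut_iterations=elim.trace.n_mut_iterations,
        species=species,
        seed=config.seed,
        **stats,
    )

    vip_scores = vip(model)
    vip_table = pd.DataFrame(
        {
            "wavelength": model.var_names.astype(int),
            "vip": vip_scores,
            "above_0.8": vip_scores >= 0.8,
            "above_1.0": vip_scores >= 1.0,
        }
    )
    y_min = float(y.min())
    predictions = pd.DataFrame(
        {
            "sample_id": ids,
            "measured": y,
            "predicted_cal": y_cal,
            "predicted_cv": y_cv,
            "measured_norm": _normalized(y, y_min, config.normalization),
            "predicted_cv_norm": _normalized(y_cv, y_min, config.normalization),
        }
    )
    return SpeciesModelResult(
        species=species,
        report=rep,
        elimination=elim,
        vip_table=vip_table,
        predictions=predictions,
        removed_outliers=removed,
        preprocessing_log=log,
    )


def _stratified_split(
    species_of: Sequence[str], train_fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Boolean train mask, stratified by species so no species drops out."""
    species_of = np.asarray(species_of)
    train = np.zeros(species_of.size, dtype=bool)
    for sp in np.unique(species_of):
        idx = np.flatnonzero(species_of == sp)
        n_train = int(round(train_fraction * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)
        train[rng.permutation(idx)[:n_train]] = True
    return train


def run_pooled_model(
    sset: SpectraSet,
    records: Sequence[SampleRecord],
    config: RunConfig | None = None,
) -> PooledModelResult:
    """Across-species model with a stratified 2/3 train / 1/3 test split.

    Trains the full procedure on the training partition, evaluates slope,
    R2 and RMSE on the held-back test set, and reports the factor-1/2 scores
    labeled by species together with the between- vs. within-species variance
    ratio of factor-1 scores — the diagnostic for whether the pooled model is
    separating species rather than resolving delta15N within them.
    """
    config = config or RunConfig()
    processed, records, _log = _prepare(sset, records, config)
    recs = [r for r in records if r.sample_id in set(processed.sample_ids)]
    species_of = [r.species for r in recs]
    if len(set(species_of)) < 2:
        raise ValueError("pooled model needs >= 2 species")
    ids = [r.sample_id for r in recs]
    aligned = processed.subset_samples(ids)
    y = np.array([r.delta15N for r in recs])
    rng = np.random.default_rng(config.seed)
    train_mask = _stratified_split(species_of, config.train_fraction, rng)

    X_train, y_train = aligned.matrix[train_mask], y[train_mask]
    X_test, y_test = aligned.matrix[~train_mask], y[~train_mask]
    elim = iterative_elimination(
        X_train,
        y_train,
        k=config.k,
        seed=config.seed,
        alpha=config.alpha,
        max_iter=config.max_iter,
        a_max=config.a_max,
        var_names=aligned.wavelengths,
    )
    model, cv = elim.model, elim.cv
    keep = elim.retained_mask
    y_cal = predict(model, X_train[:, keep])
    if config.cv_strategy == "selection_aware":
        y_cv = selection_aware_cv(
            X_train,
            y_train,
            k=config.k,
            seed=config.seed,
            alpha=config.alpha,
            max_iter=config.max_iter,
            a_max=config.a_max,
            var_names=aligned.wavelengths,
        )
    else:
        y_cv = cv.predictions_at(elim.n_factors)
    stats = model_statistics(y_train, y_cal, y_cv)
    rep = ModelReport(
        n=int(y_train.size),
        n_factors=elim.n_factors,
        n_x_variables=int(keep.sum()),
        n_mut_iterations=elim.trace.n_mut_iterations,
        species="pooled",
        seed=config.seed,
        **stats,
    )

    y_test_hat = predict(model, X_test[:, keep])
    ss_tot = float(np.sum((y_test - y_test.mean()) ** 2))
    ss_res = float(np.sum((y_test - y_test_hat) ** 2))
    sxx = float(np.sum((y_test - y_test.mean()) ** 2))
    slope = float(
        np.sum((y_test - y_test.mean()) * (y_test_hat - y_test_hat.mean())) / sxx
    )
    test_stats = {
        "slope_test": slope,
        "offset_test": float(y_test_hat.mean() - slope * y_test.mean()),
        "r2_test": 1.0 - ss_res / ss_tot,
        "rmse_test": float(np.sqrt(ss_res / y_test.size)),
        "rmse_test_pct_range": 100.0
        * float(np.sqrt(ss_res / y_test.size))
        / float(y_test.max() - y_test.min()),
    }

    scores_all = transform(model, aligned.matrix[:, keep])
    n_score_cols = min(2, scores_all.shape[1])
    scores = pd.DataFrame(
        {
            "sample_id": ids,
            "species": species_of,
            "partition": np.where(train_mask, "train", "test"),
        }
    )
    for j in range(n_score_cols):
        scores[f"factor_{j + 1}"] = scores_all[:, j]

    f1 = scores_all[:, 0]
    groups = [f1[np.asarray(species_of) == sp] for sp in sorted(set(species_of))]
    grand = f1.mean()
    between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups) / (len(groups) - 1)
    within = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups) / (
        f1.size - len(groups)
    )
    separation = float(between / within) if within > 0 else float("inf")

    per_species_r2: dict[str, float] = {}
    sp_test = np.asarray(species_of)[~train_mask]
    for sp in sorted(set(species_of)):
        m = sp_test == sp
        if m.sum() < 3 or np.var(y_test[m]) == 0:
            per_species_r2[sp] = float("nan")
            continue
        res = float(np.sum((y_test[m] - y_test_hat[m]) ** 2))
        tot = float(np.sum((y_test[m] - y_test[m].mean()) ** 2))
        per_species_r2[sp] = 1.0 - res / tot

    return PooledModelResult(
        report=rep,
        test_statistics=test_stats,
        scores=scores,
        separation_ratio=separation,
        elimination=elim,
        train_ids=[i for i, t in zip(ids, train_mask) if t],
        test_ids=[i for i, t in zip(ids, train_mask) if not t],
        per_species_test_r2=per_species_r2,
    )


def report(
    results: Sequence[SpeciesModelResult] | SpeciesModelResult,
    path: str | Path,
    run_config: RunConfig | None = None,
) -> dict[str, Path]:
    """Write the CSV/JSON bundle of one or more completed runs.

    Emits the calibration table (one row per model), the VIP tables, the
    elimination traces, the prediction pairs and a manifest (config, seeds,
    package version) sufficient for an exact rerun.  Figures are emitted as
    data tables; plotting is left to the caller.
    """
    if isinstance(results, SpeciesModelResult):
        results = [results]
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    table = pd.DataFrame([r.report.to_row() for r in results])
    written["table"] = outdir / "model_table.csv"
    table.to_csv(written["table"], index=False)

    vips = pd.concat(
        [r.vip_table.assign(species=r.species) for r in results], ignore_index=True
    )
    written["vip"] = outdir / "vip.csv"
    vips.to_csv(written["vip"], index=False)

    traces = pd.concat(
        [r.elimination.trace.to_frame().assign(species=r.species) for r in results],
        ignore_index=True,
    )
    written["trace"] = outdir / "elimination_trace.csv"
    traces.to_csv(written["trace"], index=False)

    preds = pd.concat(
        [r.predictions.assign(species=r.species) for r in results], ignore_index=True
    )
    written["predictions"] = outdir / "predictions.csv"
    preds.to_csv(written["predictions"], index=False)

    complete = all(r.elimination.trace.stop_reason for r in results)
    manifest = {
        "package_version": _pkg_version,
        "complete": complete,
        "species": [r.species for r in results],
        "removed_outliers": {r.species: r.removed_outliers for r in results},
        "stop_reasons": {r.species: r.elimination.trace.stop_reason for r in results},
        "run_config": None if run_config is None else _config_dict(run_config),
    }
    written["manifest"] = outdir / "manifest.json"
    written["manifest"].write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    return written


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    d["exclude_mature_of"] = list(config.exclude_mature_of)
    return d
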