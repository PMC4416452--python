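"""Spectral pre-treatments applied, in fixed order, before PLS modeling.

Order: detector-splice (jump) correction -> standard normal variate (SNV)
-> Savitzky-Golay first derivative -> restriction to the model wavelength
range.  Each operator checks the incoming processing state so the chain
cannot be applied out of order or twice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Union

import numpy as np
from scipy.signal import savgol_filter

from .spectra import ProcessingState, SpectraSet, Spectrum

__all__ = [
    "PreprocessConfig",
    "correct_sensor_jumps",
    "snv_transform",
    "savgol_first_derivative",
    "subset_model_range",
    "preprocess_pipeline",
]


@dataclass
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    The splice pairs name the last band of one detector and the first band
    of the next (VNIR|SWIR1 at 1000|1001 nm, SWIR1|SWIR2 at 1800|1801 nm);
    SWIR1 is the reference detector left untouched.  The Savitzky-Golay
    filter uses ``2*sg_half_window + 1`` points (default 9) and a local
    polynomial of order ``sg_poly_order`` (default 2).  ``model_range`` is
    the inclusive wavelength window kept for modeling; the short-wave
    infrared beyond 1800 nm is dropped by default because its noise level
    under a halogen source is too high to be useful.
    """

    vnir_splice: tuple[int, int] = (1000, 1001)
    swir2_splice: tuple[int, int] = (1800, 1801)
    sg_half_window: int = 4
    sg_poly_order: int = 2
    model_range: tuple[int, int] = (400, 1800)

    def __post_init__(self) -> None:
        if self.sg_poly_order >= 2 * self.sg_half_window + 1:
            raise ValueError("sg_poly_order must be < filter width")
        if self.model_range[0] >= self.model_range[1]:
            raise ValueError("model_range must be an increasing pair")

    @property
    def sg_window(self) -> int:
        return 2 * self.sg_half_window + 1


SpectrumLike = Union[Spectrum, SpectraSet]


def _require_state(obj: SpectrumLike, allowed: set[ProcessingState], op: str) -> None:
    if obj.state not in allowed:
        raise ValueError(
            f"{op}: expected state in {sorted(s.value for s in allowed)}, "
            f"got {obj.state.value!r}"
        )


def _as_matrix(obj: SpectrumLike) -> np.ndarray:
    return obj.values[None, :] if isinstance(obj, Spectrum) else obj.matrix


def _rebuild(obj: SpectrumLike, matrix, wavelengths, state) -> SpectrumLike:
    if isinstance(obj, Spectrum):
        return Spectrum(wavelengths, matrix[0], state, obj.sample_id)
    return SpectraSet(list(obj.sample_ids), matrix, wavelengths, state)


def correct_sensor_jumps(obj: SpectrumLike, config: PreprocessConfig | None = None) -> SpectrumLike:
    """Remove detector-splice discontinuities by multiplicative rescaling.

    The VNIR segment (wavelengths <= the first splice) is multiplied by
    ``r(1001)/r(1000)`` and the SWIR2 segment (>= the second splice's right
    band) by ``r(1800)/r(1801)``, per sample, leaving the reference SWIR1
    detector untouched and the spectrum continuous at both splices.
    """
    config = config or PreprocessConfig()
    _require_state(obj, {ProcessingState.RAW}, "correct_sensor_jumps")
    wl = obj.wavelengths
    left_v, right_v = config.vnir_splice
    left_s, right_s = config.swir2_splice
    for nm in (left_v, right_v, left_s, right_s):
        if nm not in wl:
            raise ValueError(f"grid does not span splice wavelength {nm} nm")
    X = _as_matrix(obj).copy()
    iv_l, iv_r = np.searchsorted(wl, [left_v, right_v])
    is_l, is_r = np.searchsorted(wl, [left_s, right_s])
    if np.any(X[:, iv_l] == 0) or np.any(X[:, is_r] == 0):
        raise ValueError("zero reflectance at a splice band: correction factor undefined")
    f_v = X[:, iv_r] / X[:, iv_l]
    f_s = X[:, is_l] / X[:, is_r]
    for name, f in (("VNIR", f_v), ("SWIR2", f_s)):
        bad = (f < 0.5) | (f > 2.0)
        if np.any(bad):
            warnings.warn(
                f"{name} splice factor outside [0.5, 2] for "
                f"{int(bad.sum())} spectrum(s): suspect data"
            )
    X[:, : iv_l + 1] *= f_v[:, None]
    X[:, is_r:] *= f_s[:, None]
    return _rebuild(obj, X, wl, ProcessingState.JUMP_CORRECTED)


def snv_transform(obj: SpectrumLike) -> SpectrumLike:
    """Standard normal variate: center each spectrum to 0, scale to unit SD.

    Uses the sample standard deviation (n-1 divisor).  Removes per-sample
    multiplicative scatter so that spectra of differently oriented or sized
    leaves become comparable.
    """
    _require_state(
        obj, {ProcessingState.RAW, ProcessingState.JUMP_CORRECTED}, "snv_transform"
    )
    X = _as_matrix(obj)
    sd = X.std(axis=1, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant spectrum: SNV undefined (zero SD)")
    out = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    return _rebuild(obj, out, obj.wavelengths, ProcessingState.SNV)


def savgol_first_derivative(
    obj: SpectrumLike, config: PreprocessConfig | None = None
) -> SpectrumLike:
    """Savitzky-Golay first derivative (per nm), dropping half-window edges.

    At each interior band the derivative is that of the local least-squares
    polynomial of order ``sg_poly_order`` fitted over the filter window,
    divided by the grid step; the ``sg_half_window`` bands at each end, where
    no full window exists, are removed from the axis rather than filled by
    extrapolation.
    """
    config = config or PreprocessConfig()
    if obj.state == ProcessingState.FIRST_DERIVATIVE:
        raise ValueError("spectrum is already a first derivative")
    wl = obj.wavelengths
    if wl.size < config.sg_window:
        raise ValueError("spectrum shorter than the Savitzky-Golay window")
    step = float(wl[1] - wl[0])
    X = _as_matrix(obj)
    d = savgol_filter(
        X, config.sg_window, config.sg_poly_order, deriv=1, delta=step, axis=1
    )
    h = config.sg_half_window
    return _rebuild(obj, d[:, h:-h], wl[h:-h], ProcessingState.FIRST_DERIVATIVE)


def subset_model_range(
    obj: SpectrumLike, config: PreprocessConfig | None = None
) -> SpectrumLike:
    """Keep only bands inside the inclusive model wavelength range."""
    config = config or PreprocessConfig()
    lo, hi = config.model_range
    wl = obj.wavelengths
    mask = (wl >= lo) & (wl <= hi)
    if not mask.any():
        raise ValueError(f"model range [{lo}, {hi}] does not intersect the grid")
    if isinstance(obj, Spectrum):
        return Spectrum(wl[mask], obj.values[mask], obj.state, obj.sample_id)
    return obj.subset_wavelengths(mask)


def preprocess_pipeline(
    sset: SpectraSet, config: PreprocessConfig | None = None
) -> tuple[SpectraSet, list[str]]:
    """Run the full chain on a raw set; returns the result and a stage log."""
    config = config or PreprocessConfig()
    if sset.state != ProcessingState.RAW:
        raise ValueError(
            f"pipeline expects raw spectra, got state {sset.state.value!r}"
        )
    log: list[str] = []
    out = correct_sensor_jumps(sset, config)
    log.append(f"jump correction: splices at {config.vnir_splice}/{config.swir2_splice}")
    out = snv_transform(out)
    log.append("SNV: per-spectrum mean 0, sample SD 1")
    out = savgol_first_derivative(out, config)
    log.append(
        f"Savitzky-Golay derivative: window {config.sg_window}, "
        f"order {config.sg_poly_order}, {config.sg_half_window} edge bands dropped per side"
    )
    out = subset_model_range(out, config)
    log.append(
        f"model range {config.model_range}: {out.n_wavelengths} bands retained"
    )
    return out, log
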