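"""Containers and I/O for leaf reflectance spectra and per-sample metadata.

A spectrum lives on the 1-nm export grid of a field spectroradiometer
(350-2500 nm by default) and carries a processing-state tag so that the
preprocessing operators can enforce their order.  Sample metadata couples
each spectrum to the traits the modeling chain needs: the nitrogen isotope
signature delta15N (permil vs. AIR), nitrogen content (% dry mass),
gravimetric water content (g/g dry mass) and specific leaf area.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ProcessingState",
    "Spectrum",
    "SpectraSet",
    "SampleRecord",
    "LeafType",
    "read_spectra_table",
    "write_spectra_table",
    "exclude_unlabeled_mature",
    "records_to_frame",
    "frame_to_records",
]


class ProcessingState(str, Enum):
    """Stage of a spectrum in the fixed preprocessing chain."""

    RAW = "raw"
    JUMP_CORRECTED = "jump_corrected"
    SNV = "snv"
    FIRST_DERIVATIVE = "first_derivative"


class LeafType(str, Enum):
    YOUNG = "young"
    MATURE = "mature"
    STRESSED = "stressed"


def _validate_axis(wavelengths: np.ndarray) -> np.ndarray:
    wl = np.asarray(wavelengths)
    if wl.ndim != 1 or wl.size < 2:
        raise ValueError("wavelength axis must be 1-D with at least 2 points")
    if not np.all(np.equal(np.mod(wl, 1), 0)):
        raise ValueError("wavelength axis must be integer nm (1-nm export grid)")
    wl = wl.astype(int)
    steps = np.diff(wl)
    if np.any(steps <= 0):
        raise ValueError("wavelength axis must be strictly increasing")
    if np.unique(steps).size != 1:
        raise ValueError("wavelength axis must be uniformly spaced")
    return wl


@dataclass
class Spectrum:
    """One sample's spectrum on a uniform integer-nm grid.

    ``values`` are relative reflectance for the raw / jump-corrected states,
    dimensionless standardized reflectance after SNV, and per-nm derivative
    units after Savitzky-Golay differentiation.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    state: ProcessingState = ProcessingState.RAW
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = _validate_axis(self.wavelengths)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.wavelengths.shape:
            raise ValueError(
                f"values ({self.values.shape}) and wavelengths "
                f"({self.wavelengths.shape}) differ in length"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrum contains non-finite values")
        if self.state in (ProcessingState.RAW, ProcessingState.JUMP_CORRECTED):
            if np.any(self.values < 0):
                raise ValueError("reflectance values must be >= 0")
            if np.any(self.values > 1):
                warnings.warn(
                    f"spectrum {self.sample_id!r}: reflectance > 1 "
                    "(specular glare?); admitted unclipped",
                    stacklevel=2,
                )

    def value_at(self, nm: int) -> float:
        idx = np.searchsorted(self.wavelengths, nm)
        if idx >= self.wavelengths.size or self.wavelengths[idx] != nm:
            raise KeyError(f"wavelength {nm} nm not on the grid")
        return float(self.values[idx])


@dataclass
class SpectraSet:
    """A stack of spectra sharing one wavelength axis (the PLS X matrix)."""

    sample_ids: list[str]
    matrix: np.ndarray  # n_samples x n_wavelengths
    wavelengths: np.ndarray
    state: ProcessingState = ProcessingState.RAW

    def __post_init__(self) -> None:
        self.wavelengths = _validate_axis(self.wavelengths)
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.matrix.shape != (len(self.sample_ids), self.wavelengths.size):
            raise ValueError(
                f"matrix shape {self.matrix.shape} incompatible with "
                f"{len(self.sample_ids)} ids x {self.wavelengths.size} bands"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample_id in SpectraSet")
        if self.n_samples < 1:
            raise ValueError("SpectraSet needs at least one sample")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("SpectraSet contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.matrix.shape[1]

    def spectrum(self, sample_id: str) -> Spectrum:
        i = self.sample_ids.index(sample_id)
        return Spectrum(self.wavelengths, self.matrix[i], self.state, sample_id)

    def iter_spectra(self):
        for i, sid in enumerate(self.sample_ids):
            yield Spectrum(self.wavelengths, self.matrix[i], self.state, sid)

    def subset_samples(self, keep: Sequence[str]) -> "SpectraSet":
        keep = list(keep)
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in keep if s not in index]
        if missing:
            raise KeyError(f"sample ids not in set: {missing[:5]}")
        rows = [index[s] for s in keep]
        return SpectraSet(keep, self.matrix[rows], self.wavelengths, self.state)

    def subset_wavelengths(self, mask: np.ndarray) -> "SpectraSet":
        mask = np.asarray(mask, dtype=bool)
        if mask.sum() < 2:
            raise ValueError("wavelength subset would leave fewer than 2 bands")
        return SpectraSet(
            list(self.sample_ids), self.matrix[:, mask], self.wavelengths[mask], self.state
        )

    def with_state(self, state: ProcessingState) -> "SpectraSet":
        return SpectraSet(list(self.sample_ids), self.matrix.copy(), self.wavelengths, state)

    @staticmethod
    def from_spectra(spectra: Sequence[Spectrum]) -> "SpectraSet":
        if not spectra:
            raise ValueError("no spectra given")
        wl = spectra[0].wavelengths
        states = {s.state for s in spectra}
        if len(states) != 1:
            raise ValueError("spectra in one set must share a processing state")
        for s in spectra[1:]:
            if not np.array_equal(s.wavelengths, wl):
                raise ValueError("spectra do not share one wavelength axis")
        return SpectraSet(
            [s.sample_id for s in spectra],
            np.vstack([s.values for s in spectra]),
            wl,
            spectra[0].state,
        )


@dataclass
class SampleRecord:
    """Trait and isotope metadata for one leaf sample.

    delta15N is permil vs. the atmospheric-N2 (AIR) standard; treatment is
    the nominal permil enrichment of the fertilizer label (greenhouse design
    only); distance_to_canopy is metres to the nearest N2-fixer canopy
    (field design only).
    """

    sample_id: str
    species: str
    delta15N: float
    n_content: float
    gwc: float
    sla: float
    leaf_type: Optional[LeafType] = None
    treatment: Optional[float] = None
    distance_to_canopy: Optional[float] = None

    def __post_init__(self) -> None:
        if self.leaf_type is not None and not isinstance(self.leaf_type, LeafType):
            self.leaf_type = LeafType(str(self.leaf_type))
        if self.n_content <= 0:
            raise ValueError(f"{self.sample_id}: n_content must be > 0")
        if self.gwc < 0:
            raise ValueError(f"{self.sample_id}: gwc must be >= 0")
        if self.sla <= 0:
            raise ValueError(f"{self.sample_id}: sla must be > 0")
        if self.treatment is not None and self.treatment not in (0.0, 10.0, 20.0):
            raise ValueError(
                f"{self.sample_id}: treatment must be one of 0/10/20 permil"
            )


_META_COLUMNS = [
    "sample_id",
    "species",
    "leaf_type",
    "treatment",
    "delta15N",
    "n_content",
    "gwc",
    "sla",
    "distance_to_canopy",
]


def records_to_frame(records: Sequence[SampleRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "sample_id": r.sample_id,
                "species": r.species,
                "leaf_type": r.leaf_type.value if r.leaf_type is not None else None,
                "treatment": r.treatment,
                "delta15N": r.delta15N,
                "n_content": r.n_content,
                "gwc": r.gwc,
                "sla": r.sla,
                "distance_to_canopy": r.distance_to_canopy,
            }
        )
    return pd.DataFrame(rows, columns=_META_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[SampleRecord]:
    records = []
    for _, row in frame.iterrows():
        def _opt(key):
            v = row.get(key)
            return None if v is None or (isinstance(v, float) and np.isnan(v)) or (
                isinstance(v, str) and v == ""
            ) else v

        lt = _opt("leaf_type")
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                species=str(row["species"]),
                leaf_type=LeafType(lt) if lt is not None else None,
                treatment=float(row["treatment"]) if _opt("treatment") is not None else None,
                delta15N=float(row["delta15N"]),
                n_content=float(row["n_content"]),
                gwc=float(row["gwc"]),
                sla=float(row["sla"]),
                distance_to_canopy=(
                    float(row["distance_to_canopy"])
                    if _opt("distance_to_canopy") is not None
                    else None
                ),
            )
        )
    return records


def read_spectra_table(
    path: str | Path, metadata_path: str | Path
) -> tuple[SpectraSet, list[SampleRecord]]:
    """Read a wide spectra CSV plus a metadata CSV and join them on sample_id.

    The spectra file has ``sample_id`` as its first column and one column per
    integer wavelength (nm).  An optional first line ``# state=<tag>``
    records the processing state.  Samples present in only one of the two
    files are logged and dropped.
    """
    path = Path(path)
    state = ProcessingState.RAW
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        skip = 0
        if first.startswith("#"):
            skip = 1
            tag = first.strip().lstrip("#").strip()
            if tag.startswith("state="):
                state = ProcessingState(tag.split("=", 1)[1])
    table = pd.read_csv(path, skiprows=skip, dtype={0: str}, float_precision="round_trip")
    if table.columns[0] != "sample_id":
        raise ValueError("first column of the spectra table must be 'sample_id'")
    wl_headers = list(table.columns[1:])
    try:
        wl = np.array([int(h) for h in wl_headers])
    except ValueError as exc:
        bad = [h for h in wl_headers if not h.lstrip("-").isdigit()]
        raise ValueError(
            f"non-integer wavelength headers (1-nm grid required): {bad[:5]}"
        ) from exc
    wl = _validate_axis(wl)
    ids = table["sample_id"].tolist()
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sample_id in spectra table: {dupes[:5]}")
    values = table.iloc[:, 1:]
    bad_cells = values.map(lambda v: not np.isfinite(pd.to_numeric(v, errors="coerce")))
    if bad_cells.to_numpy().any():
        r, c = np.argwhere(bad_cells.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at sample {ids[r]!r}, wavelength {wl_headers[c]} nm"
        )
    matrix = values.to_numpy(dtype=float)

    meta = pd.read_csv(metadata_path, dtype={"sample_id": str})
    meta_ids = set(meta["sample_id"])
    spec_ids = set(ids)
    orphans = sorted(spec_ids ^ meta_ids)
    if orphans:
        logger.warning(
            "%d sample(s) present in only one file were dropped: %s",
            len(orphans),
            orphans[:10],
        )
    joined = [i for i in ids if i in meta_ids]
    if not joined:
        raise ValueError("no sample ids shared between spectra and metadata")
    sset = SpectraSet(ids, matrix, wl, state).subset_samples(joined)
    meta = meta.set_index("sample_id").loc[joined].reset_index()
    return sset, frame_to_records(meta)


def write_spectra_table(
    sset: SpectraSet,
    records: Sequence[SampleRecord],
    path: str | Path,
    metadata_path: str | Path,
) -> None:
    """Write the set and metadata as CSVs; read(write(x)) is the identity.

    Values are printed with shortest round-trip float repr, so the matrix is
    reproduced bit-for-bit on re-read.  The processing state is recorded in a
    ``# state=`` header line.
    """
    if sset.n_samples == 0:
        raise ValueError("refusing to write an empty SpectraSet")
    path = Path(path)
    frame = pd.DataFrame(sset.matrix, columns=[str(w) for w in sset.wavelengths])
    frame.insert(0, "sample_id", sset.sample_ids)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# state={sset.state.value}\n")
        frame.to_csv(fh, index=False)
    records_to_frame(records).to_csv(metadata_path, index=False)


def exclude_unlabeled_mature(
    sset: SpectraSet,
    records: Sequence[SampleRecord],
    species_label: str,
    leaf_type: LeafType = LeafType.MATURE,
) -> tuple[SpectraSet, list[SampleRecord], int]:
    """Drop every sample of ``species_label`` with the given leaf type.

    Mature leaves that failed to incorporate the isotope label would couple
    leaf age to delta15N; removing them keeps the label signal orthogonal to
    leaf development.  Returns the filtered set, filtered records and the
    number of samples removed.  An absent species label is a warned no-op.
    """
    records = list(records)
    if not any(r.species == species_label for r in records):
        warnings.warn(f"species {species_label!r} not present; nothing excluded")
        return sset, records, 0
    drop = {
        r.sample_id
        for r in records
        if r.species == species_label and r.leaf_type == leaf_type
    }
    kept_records = [r for r in records if r.sample_id not in drop]
    keep_ids = [s for s in sset.sample_ids if s not in drop]
    filtered = sset.subset_samples(keep_ids) if drop else sset
    if drop:
        logger.info(
            "excluded %d %s %s-leaf samples", len(drop), species_label, leaf_type.value
        )
    return filtered, kept_records, len(drop)
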