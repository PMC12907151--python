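"""Core domain types and file IO for single-cell Raman spectra.

A :class:`Spectrum` is one measured (or simulated) Raman trace over the
fingerprint region: a shared :class:`WavenumberAxis` (Raman shift, cm^-1),
an intensity vector in arbitrary units, and provenance metadata
(:class:`SpectrumMeta`).  A :class:`SpectralDataset` is an aligned
collection of spectra with the hierarchical group structure of the study
design (cell line -> cell -> measurement point) and a binary class label
per spectrum (pediatric vs adult phenotype).

Datasets are stored as plain CSV, either *wide* (one row per spectrum,
one numeric column per wavenumber) or *long* (one row per channel).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

CLASS_LABELS = ("pediatric", "adult")

#: canonical fingerprint-region grid: 316 channels from 600.0 cm^-1 at the
#: instrument's ~3.8 cm^-1/pixel resolution (600 + 315*3.8 = 1797 <= 1800)
CANONICAL_START = 600.0
CANONICAL_STEP = 3.8
CANONICAL_N = 316

_META_COLUMNS = ["spectrum_id", "cell_line", "cell_id", "point_index", "class_label", "qc_flags"]


class SpectraIOError(ValueError):
    """Raised when a spectra file violates the format contract."""


@dataclass(frozen=True)
class WavenumberAxis:
    """Strictly increasing, uniformly spaced Raman-shift grid in cm^-1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("axis needs at least two channels")
        if not np.all(np.isfinite(v)):
            raise ValueError("axis contains non-finite values")
        d = np.diff(v)
        if np.any(d <= 0):
            raise ValueError("axis must be strictly increasing")
        if v[0] < 600.0 - 1e-9 or v[-1] > 1800.0 + 1e-9:
            raise ValueError("axis outside the fingerprint region [600, 1800] cm^-1")
        step = d.mean()
        if np.any(np.abs(d - step) > 1e-9 * max(step, 1.0)):
            raise ValueError("axis spacing is not uniform")

    @classmethod
    def canonical(cls) -> "WavenumberAxis":
        return cls(CANONICAL_START + CANONICAL_STEP * np.arange(CANONICAL_N))

    @property
    def step(self) -> float:
        return float(np.diff(self.values).mean())

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberAxis):
            return NotImplemented
        return self.values.shape == other.values.shape and np.allclose(
            self.values, other.values, rtol=1e-9, atol=1e-9
        )

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash((self.values.size, float(self.values[0]), float(self.values[-1])))

    def nearest_channel(self, wavenumber: float) -> int:
        return int(np.argmin(np.abs(self.values - wavenumber)))


@dataclass(frozen=True)
class SpectrumMeta:
    """Provenance of one spectrum within the line -> cell -> point hierarchy."""

    spectrum_id: str
    cell_line: str
    cell_id: str
    point_index: int
    class_label: str
    qc_flags: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"class_label must be one of {CLASS_LABELS}")
        if int(self.point_index) not in (1, 2, 3):
            raise ValueError("point_index must be 1, 2 or 3 (three points per cell)")
        object.__setattr__(self, "point_index", int(self.point_index))
        object.__setattr__(self, "qc_flags", frozenset(self.qc_flags))

    @property
    def group(self) -> tuple:
        """Physical-cell identity; spectra sharing it must not straddle splits."""
        return (self.cell_line, self.cell_id)


@dataclass(frozen=True)
class Spectrum:
    axis: WavenumberAxis
    intensities: np.ndarray
    meta: SpectrumMeta

    def __post_init__(self) -> None:
        y = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "intensities", y)
        if y.ndim != 1 or y.size != len(self.axis):
            raise ValueError("intensities must match axis length")
        if not np.all(np.isfinite(y)):
            raise ValueError("intensities contain non-finite values")

    def with_flags(self, *flags: str) -> "Spectrum":
        meta = replace(self.meta, qc_flags=self.meta.qc_flags | set(flags))
        return replace(self, meta=meta)

    def with_intensities(self, y: np.ndarray) -> "Spectrum":
        return replace(self, intensities=np.asarray(y, dtype=float))


@dataclass
class SpectralDataset:
    """Spectra on one shared axis, with unique ids and per-line class labels."""

    spectra: list

    def __post_init__(self) -> None:
        if self.spectra:
            axis = self.spectra[0].axis
            for s in self.spectra:
                if s.axis != axis:
                    raise ValueError("all spectra must share one wavenumber axis")
            ids = [s.meta.spectrum_id for s in self.spectra]
            if len(set(ids)) != len(ids):
                raise ValueError("spectrum_ids must be unique")
            line_label: dict = {}
            for s in self.spectra:
                prev = line_label.setdefault(s.meta.cell_line, s.meta.class_label)
                if prev != s.meta.class_label:
                    raise ValueError(
                        f"class_label not constant within cell_line {s.meta.cell_line!r}"
                    )

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    @property
    def axis(self) -> WavenumberAxis:
        if not self.spectra:
            raise ValueError("empty dataset has no axis")
        return self.spectra[0].axis

    @property
    def class_counts(self) -> dict:
        counts = {label: 0 for label in CLASS_LABELS}
        for s in self.spectra:
            counts[s.meta.class_label] += 1
        return counts

    def labels(self) -> np.ndarray:
        return np.array([s.meta.class_label for s in self.spectra])

    def groups(self) -> np.ndarray:
        """One '{line}|{cell}' key per spectrum (grouped-split unit)."""
        return np.array([f"{s.meta.cell_line}|{s.meta.cell_id}" for s in self.spectra])

    def intensity_matrix(self) -> np.ndarray:
        return np.vstack([s.intensities for s in self.spectra])

    def subset(self, ids: Iterable[str]) -> "SpectralDataset":
        wanted = set(ids)
        return SpectralDataset([s for s in self.spectra if s.meta.spectrum_id in wanted])


@dataclass(frozen=True)
class BandTable:
    """Peak-position -> biochemical-allocation lookup (literature assignments)."""

    positions: np.ndarray
    allocations: tuple
    reference_notes: tuple = ()

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if pos.size == 0:
            raise ValueError("band table is empty")
        if np.any(np.diff(pos) <= 0):
            raise ValueError("band positions must be strictly increasing")
        if pos[0] < 600 or pos[-1] > 1800:
            raise ValueError("band positions outside [600, 1800] cm^-1")
        if len(self.allocations) != pos.size:
            raise ValueError("positions/allocations length mismatch")
        if not self.reference_notes:
            object.__setattr__(self, "reference_notes", tuple("" for _ in self.allocations))

    def __len__(self) -> int:
        return self.positions.size

    def allocation_at(self, position: float) -> str:
        idx = int(np.argmin(np.abs(self.positions - position)))
        if abs(self.positions[idx] - position) > 1e-9:
            raise KeyError(f"no band at {position}")
        return self.allocations[idx]

    def nearest(self, position: float) -> tuple:
        """(table position, allocation, distance); ties resolved to the lower position."""
        d = np.abs(self.positions - position)
        best = float(d.min())
        idx = int(np.flatnonzero(np.isclose(d, best, rtol=0, atol=1e-12))[0])
        return float(self.positions[idx]), self.allocations[idx], float(d[idx])


def load_band_table(path=None) -> BandTable:
    """Load a band-assignment table; default is the packaged 35-band table."""
    if path is None:
        resource = importlib.resources.files("ramanpheno.data") / "band_table.csv"
        with importlib.resources.as_file(resource) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    if df.empty:
        raise SpectraIOError("band table file has no rows")
    if "position" not in df.columns or "allocation" not in df.columns:
        raise SpectraIOError("band table needs 'position' and 'allocation' columns")
    notes = df["reference_note"].fillna("") if "reference_note" in df.columns else ["" for _ in range(len(df))]
    return BandTable(
        positions=df["position"].to_numpy(float),
        allocations=tuple(str(a) for a in df["allocation"]),
        reference_notes=tuple(str(n) for n in notes),
    )


# ---------------------------------------------------------------------------
# dataset IO


def _meta_to_row(meta: SpectrumMeta) -> dict:
    return {
        "spectrum_id": meta.spectrum_id,
        "cell_line": meta.cell_line,
        "cell_id": meta.cell_id,
        "point_index": meta.point_index,
        "class_label": meta.class_label,
        "qc_flags": ";".join(sorted(meta.qc_flags)),
    }


def _meta_from_row(row) -> SpectrumMeta:
    label = row.get("class_label")
    if label is None or (isinstance(label, float) and np.isnan(label)) or str(label) == "":
        raise SpectraIOError(f"missing class_label for spectrum {row.get('spectrum_id')!r}")
    flags = row.get("qc_flags", "")
    if flags is None or (isinstance(flags, float) and np.isnan(flags)):
        flags = ""
    return SpectrumMeta(
        spectrum_id=str(row["spectrum_id"]),
        cell_line=str(row["cell_line"]),
        cell_id=str(row["cell_id"]),
        point_index=int(row["point_index"]),
        class_label=str(label),
        qc_flags=frozenset(f for f in str(flags).split(";") if f),
    )


def write_dataset(ds: SpectralDataset, path, format: Literal["wide_csv", "long_csv"] = "wide_csv") -> None:
    """Write a dataset as delimited text; ``read_dataset`` inverts it exactly."""
    try:
        if format == "wide_csv":
            _write_wide(ds, path)
        elif format == "long_csv":
            _write_long(ds, path)
        else:
            raise ValueError(f"unknown format {format!r}")
    except OSError as exc:
        raise SpectraIOError(f"cannot write {path}: {exc}") from exc


def _write_wide(ds: SpectralDataset, path) -> None:
    if not ds.spectra:
        pd.DataFrame(columns=_META_COLUMNS).to_csv(path, index=False)
        return
    wn_cols = [f"{v:.1f}" for v in ds.axis.values]
    rows = []
    for s in ds:
        row = _meta_to_row(s.meta)
        row.update(dict(zip(wn_cols, s.intensities)))
        rows.append(row)
    pd.DataFrame(rows, columns=_META_COLUMNS + wn_cols).to_csv(path, index=False)


def _write_long(ds: SpectralDataset, path) -> None:
    cols = _META_COLUMNS + ["wavenumber", "intensity"]
    if not ds.spectra:
        pd.DataFrame(columns=cols).to_csv(path, index=False)
        return
    frames = []
    for s in ds:
        meta = _meta_to_row(s.meta)
        df = pd.DataFrame({"wavenumber": s.axis.values, "intensity": s.intensities})
        for k, v in meta.items():
            df[k] = v
        frames.append(df[cols])
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_dataset(path, format: Literal["wide_csv", "long_csv"] = "wide_csv") -> SpectralDataset:
    """Read a dataset from CSV.

    Spectra whose axis differs from the first spectrum's are linearly
    interpolated onto it (no extrapolation: the common axis is trimmed to
    the overlap of all source ranges) and flagged ``resampled``.
    """
    try:
        df = pd.read_csv(path)
    except OSError as exc:
        raise SpectraIOError(f"cannot read {path}: {exc}") from exc
    if format == "wide_csv":
        return _read_wide(df)
    if format == "long_csv":
        return _read_long(df)
    raise ValueError(f"unknown format {format!r}")


def _read_wide(df: pd.DataFrame) -> SpectralDataset:
    if df.empty and not any(c not in _META_COLUMNS for c in df.columns):
        return SpectralDataset([])
    if df["spectrum_id"].duplicated().any():
        dup = df.loc[df["spectrum_id"].duplicated(), "spectrum_id"].iloc[0]
        raise SpectraIOError(f"duplicate spectrum_id {dup!r}")
    wn_cols = [c for c in df.columns if c not in _META_COLUMNS]
    try:
        wn = np.array([float(c) for c in wn_cols])
    except ValueError as exc:
        raise SpectraIOError(f"non-numeric wavenumber column header: {exc}") from exc
    if np.any(np.diff(wn) <= 0):
        raise SpectraIOError("wavenumber columns are not strictly increasing")
    axis = WavenumberAxis(wn)
    spectra = []
    for _, row in df.iterrows():
        meta = _meta_from_row(row)
        y = row[wn_cols].to_numpy(float)
        spectra.append(Spectrum(axis=axis, intensities=y, meta=meta))
    return SpectralDataset(spectra)


def _read_long(df: pd.DataFrame) -> SpectralDataset:
    if df.empty:
        return SpectralDataset([])
    records = []  # (meta, wn array, intensity array) in first-appearance order
    for sid, g in df.groupby("spectrum_id", sort=False):
        wn = g["wavenumber"].to_numpy(float)
        if np.any(np.diff(wn) <= 0):
            raise SpectraIOError(f"non-monotone wavenumber axis for spectrum {sid!r}")
        meta = _meta_from_row(g.iloc[0])
        records.append((meta, wn, g["intensity"].to_numpy(float)))
    ref_wn = records[0][1]
    # trim the reference axis to the common support of all source ranges
    lo = max(wn[0] for _, wn, _ in records)
    hi = min(wn[-1] for _, wn, _ in records)
    if hi <= lo:
        raise SpectraIOError("spectra have no overlapping wavenumber support")
    mask = (ref_wn >= lo - 1e-9) & (ref_wn <= hi + 1e-9)
    axis = WavenumberAxis(ref_wn[mask])
    spectra = []
    for meta, wn, y in records:
        same = wn.size == ref_wn.size and np.allclose(wn, ref_wn, rtol=1e-9, atol=1e-9)
        if same:
            yi = y[mask]
        else:
            yi = np.interp(axis.values, wn, y)
            meta = replace(meta, qc_flags=meta.qc_flags | {"resampled"})
        spectra.append(Spectrum(axis=axis, intensities=yi, meta=meta))
    return SpectralDataset(spectra)
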