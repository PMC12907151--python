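"""Spectral cleaning: despiking, rubber-band baseline, QC, normalization.

Stage order is fixed: cosmic-ray despiking first (spikes corrupt the convex
hull), then rubber-band baseline subtraction, then rejection of
fluorescence-dominated spectra, then vector normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .core import Spectrum, SpectralDataset


@dataclass(frozen=True)
class PreprocessConfig:
    spike_z_threshold: float = 6.0
    spike_window: int = 5
    fluorescence_reject_ratio: float = 0.90
    normalize_region: Optional[tuple] = None  # (lo, hi) cm^-1; None = full axis

    def __post_init__(self) -> None:
        if self.spike_z_threshold <= 0:
            raise ValueError("spike_z_threshold must be positive")
        if self.spike_window < 3 or self.spike_window % 2 == 0:
            raise ValueError("spike_window must be an odd integer >= 3")
        if not 0 < self.fluorescence_reject_ratio <= 1:
            raise ValueError("fluorescence_reject_ratio must be in (0, 1]")


@dataclass(frozen=True)
class BaselineResult:
    """Rubber-band decomposition: input = baseline + corrected."""

    baseline: np.ndarray
    corrected: np.ndarray
    hull_indices: tuple


# ---------------------------------------------------------------------------
# despiking (Whitaker-Hayes-style modified z-score on first differences)


def spike_zscores(y: np.ndarray) -> np.ndarray:
    """Modified z-scores (0.6745 (d - median)/MAD) of the first differences."""
    d = np.diff(y)
    med = np.median(d)
    mad = np.median(np.abs(d - med))
    if mad == 0:
        return np.zeros_like(d)
    return 0.6745 * (d - med) / mad


#: a spike's flanking differences must exceed the adjacent differences by
#: this factor; separates one-pixel excursions from sharp band apexes,
#: whose shoulders are comparably steep
_ISOLATION_FACTOR = 3.0


def _spike_channels(y: np.ndarray, threshold: float) -> np.ndarray:
    """Boolean mask of single-pixel cosmic-ray channels.

    A channel is a spike when the differences entering and leaving it are
    both beyond threshold with opposite signs (the up-down signature of a
    one-pixel excursion) and dominate the neighbouring differences (a band
    apex fails this: its shoulders are about as steep as its tip).  At the
    array edges a single isolated beyond-threshold difference suffices.
    """
    z = spike_zscores(y)  # z[i] belongs to the step y[i] -> y[i+1]
    d = np.abs(np.diff(y))
    n = y.size
    flagged = np.zeros(n, dtype=bool)
    hot = np.abs(z) > threshold

    def neighbour_mag(i: int) -> float:
        out = 0.0
        if i - 2 >= 0:
            out = max(out, d[i - 2])
        if i + 1 <= n - 2:
            out = max(out, d[i + 1])
        return out

    for i in range(1, n - 1):
        if (
            hot[i - 1]
            and hot[i]
            and np.sign(z[i - 1]) != np.sign(z[i])
            and min(d[i - 1], d[i]) > _ISOLATION_FACTOR * neighbour_mag(i)
        ):
            flagged[i] = True
    if hot[0] and not flagged[1] and d[0] > _ISOLATION_FACTOR * d[1]:
        flagged[0] = True
    if hot[-1] and not flagged[n - 2] and d[-1] > _ISOLATION_FACTOR * d[-2]:
        flagged[-1] = True
    return flagged


def despike(s: Spectrum, cfg: PreprocessConfig = PreprocessConfig()) -> Spectrum:
    """Replace cosmic-ray pixels by the local median of clean neighbours.

    Flagged channels are replaced by the median of the non-flagged channels
    inside a ``spike_window`` window (widened until a clean neighbour is
    found).  Gains the qc flag ``despiked`` when any channel was replaced;
    idempotent on its own output.
    """
    y = s.intensities
    if y.size < cfg.spike_window:
        raise ValueError("spectrum shorter than spike_window")
    flagged = _spike_channels(y, cfg.spike_z_threshold)
    if not flagged.any():
        return s
    out = y.copy()
    half = cfg.spike_window // 2
    for i in np.flatnonzero(flagged):
        w = half
        while True:
            lo, hi = max(0, i - w), min(y.size, i + w + 1)
            neighbours = [y[j] for j in range(lo, hi) if not flagged[j]]
            if neighbours:
                out[i] = np.median(neighbours)
                break
            w += 1
    return s.with_intensities(out).with_flags("despiked")


# ---------------------------------------------------------------------------
# rubber-band baseline


def lower_hull_indices(x: np.ndarray, y: np.ndarray) -> list:
    """Andrew monotone-chain lower convex hull of the points (x, y).

    Anchored at both endpoints; collinear interior points are dropped, which
    breaks ties toward the earlier channel.
    """
    hull: list = []
    for i in range(x.size):
        while len(hull) >= 2:
            j, k = hull[-2], hull[-1]
            cross = (x[k] - x[j]) * (y[i] - y[j]) - (y[k] - y[j]) * (x[i] - x[j])
            if cross <= 0:  # last vertex is above or on the chord j->i
                hull.pop()
            else:
                break
        hull.append(i)
    return hull


def rubberband(s: Spectrum) -> BaselineResult:
    """Subtract the lower-convex-hull ("rubber band") fluorescence baseline.

    The baseline is the piecewise-linear interpolation through the lower
    convex hull of (wavenumber, intensity), anchored at both endpoints; the
    corrected spectrum is zero at every hull vertex and non-negative
    everywhere (up to float round-off).
    """
    x, y = s.axis.values, s.intensities
    if y.size < 3:
        raise ValueError("rubberband needs at least 3 channels")
    idx = lower_hull_indices(x, y)
    baseline = np.interp(x, x[idx], y[idx])
    return BaselineResult(baseline=baseline, corrected=y - baseline, hull_indices=tuple(idx))


# ---------------------------------------------------------------------------
# QC and normalization


def reject_fluorescent(
    s: Spectrum, b: BaselineResult, cfg: PreprocessConfig = PreprocessConfig()
) -> Optional[str]:
    """QC decision for fluorescence-dominated spectra.

    Returns ``None`` to keep, or the qc flag ("fluorescence" when the
    baseline carries more than ``fluorescence_reject_ratio`` of the total
    signal, strict inequality; "degenerate" for non-positive total signal).
    """
    total = float(np.sum(s.intensities))
    if total <= 0:
        return "degenerate"
    ratio = float(np.sum(b.baseline)) / total
    return "fluorescence" if ratio > cfg.fluorescence_reject_ratio else None


def baseline_ratio(s: Spectrum, b: BaselineResult) -> float:
    total = float(np.sum(s.intensities))
    return float("nan") if total <= 0 else float(np.sum(b.baseline)) / total


def vector_normalize(s: Spectrum, region: Optional[tuple] = None) -> Spectrum:
    """Scale intensities so the Euclidean norm over ``region`` equals one."""
    if region is None:
        mask = np.ones(len(s.axis), dtype=bool)
    else:
        lo, hi = region
        mask = (s.axis.values >= lo) & (s.axis.values <= hi)
    norm = float(np.linalg.norm(s.intensities[mask]))
    if norm == 0:
        raise ValueError("degenerate spectrum: zero norm over the normalization region")
    return s.with_intensities(s.intensities / norm)


@dataclass
class PreprocessResult:
    """Surviving dataset plus the per-spectrum QC audit trail."""

    dataset: SpectralDataset
    qc: pd.DataFrame  # spectrum_id, qc_flags, baseline_ratio, kept


def preprocess_dataset(
    ds: SpectralDataset, cfg: PreprocessConfig = PreprocessConfig()
) -> PreprocessResult:
    """despike -> rubber-band baseline -> fluorescence QC -> vector normalize."""
    kept, rows = [], []
    for s in ds:
        s1 = despike(s, cfg)
        b = rubberband(s1)
        verdict = reject_fluorescent(s1, b, cfg)
        ratio = baseline_ratio(s1, b)
        if verdict is not None:
            flags = sorted(s1.meta.qc_flags | {verdict})
            rows.append((s.meta.spectrum_id, ";".join(flags), ratio, False))
            continue
        corrected = s1.with_intensities(b.corrected)
        out = vector_normalize(corrected, cfg.normalize_region)
        kept.append(out)
        rows.append((s.meta.spectrum_id, ";".join(sorted(out.meta.qc_flags)), ratio, True))
    if ds.spectra and not kept:
        raise ValueError("all spectra rejected by preprocessing QC")
    qc = pd.DataFrame(rows, columns=["spectrum_id", "qc_flags", "baseline_ratio", "kept"])
    return PreprocessResult(dataset=SpectralDataset(kept), qc=qc)
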