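"""Group profiles, subtraction spectra, Savitzky-Golay second derivatives,
peak detection and band assignment.

The negative second derivative (-d2 I / d nu2, units a.u. per cm^-2)
sharpens overlapping bands: a band maximum in the spectrum becomes a local
maximum of the negative second derivative, which is then matched against
the literature band table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .core import BandTable, SpectralDataset, WavenumberAxis


@dataclass(frozen=True)
class GroupProfile:
    """Channel-wise mean +/- SD spectrum of one class."""

    axis: WavenumberAxis
    mean: np.ndarray
    sd: np.ndarray
    n: int
    class_label: str


@dataclass(frozen=True)
class PeakCall:
    """One detected peak on the -d2 scale, optionally assigned to a band."""

    position: float
    height: float
    assignment: Optional[tuple] = None  # (table position, allocation)
    distance: float = float("nan")      # cm^-1 to the nearest table band


def group_profile(ds: SpectralDataset, class_label: str) -> GroupProfile:
    """Arithmetic mean and population SD over all spectra of one class."""
    rows = [s.intensities for s in ds if s.meta.class_label == class_label]
    if not rows:
        raise ValueError(f"no spectra with class_label {class_label!r}")
    m = np.vstack(rows)
    return GroupProfile(
        axis=ds.axis,
        mean=m.mean(axis=0),
        sd=m.std(axis=0, ddof=0),
        n=m.shape[0],
        class_label=class_label,
    )


def subtraction_spectrum(a: GroupProfile, b: GroupProfile) -> np.ndarray:
    """Channel-wise difference of class means (a - b)."""
    if a.axis != b.axis:
        raise ValueError("group profiles are on different axes")
    return a.mean - b.mean


def neg_second_derivative(
    x: np.ndarray, axis: WavenumberAxis, window: int = 9, polyorder: int = 3
) -> np.ndarray:
    """Savitzky-Golay negative second derivative in physical units (cm^-2).

    Exact for polynomials of degree <= polyorder; edge channels come from
    the polynomial fitted to the truncated boundary window.
    """
    x = np.asarray(x, dtype=float)
    if window % 2 == 0 or polyorder >= window:
        raise ValueError("window must be odd and larger than polyorder")
    if x.size < window:
        raise ValueError("input shorter than the filter window")
    d2 = savgol_filter(x, window_length=window, polyorder=polyorder, deriv=2,
                       delta=axis.step, mode="interp")
    return -d2


def detect_peaks(
    d2: np.ndarray, axis: WavenumberAxis, prominence_frac: float = 0.05
) -> list:
    """Local maxima of the negative-second-derivative signal.

    Keeps positive-valued maxima (a band apex has negative curvature, hence
    -d2 > 0) with prominence >= prominence_frac x the global maximum,
    refines positions by three-point parabolic interpolation, and returns
    the calls sorted by position.
    """
    d2 = np.asarray(d2, dtype=float)
    top = float(d2.max(initial=0.0))
    if top <= 0:
        return []
    idx, _ = find_peaks(d2, prominence=prominence_frac * top, height=0.0)
    step = axis.step
    calls = []
    for i in idx:
        denom = d2[i - 1] - 2 * d2[i] + d2[i + 1]
        delta = 0.0 if denom == 0 else 0.5 * (d2[i - 1] - d2[i + 1]) / denom
        pos = float(axis.values[i] + delta * step)
        height = float(d2[i] - 0.25 * (d2[i - 1] - d2[i + 1]) * delta)
        calls.append(PeakCall(position=pos, height=height))
    return sorted(calls, key=lambda c: c.position)


def assign_bands(peaks: list, table: BandTable, tolerance: float = 4.0) -> list:
    """Match each peak to the nearest table band within ``tolerance`` cm^-1.

    Ties between equidistant bands resolve to the lower position; one table
    band may serve several peaks.  Peaks farther than the tolerance keep
    ``assignment=None`` (their distance to the nearest band is recorded).
    """
    out = []
    for p in peaks:
        pos, allocation, dist = table.nearest(p.position)
        assignment = (pos, allocation) if dist <= tolerance else None
        out.append(PeakCall(position=p.position, height=p.height,
                            assignment=assignment, distance=dist))
    return out
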