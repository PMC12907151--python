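"""Synthetic single-cell Raman cohort generator.

Emulates the study design the analysis pipeline assumes: six glioblastoma
neurosphere lines (one pediatric, five adult), three measurement points per
cell, 1,382 spectra in total of which 364 are pediatric.  Each spectrum is a
superposition of Lorentzian bands at the literature band positions, with

* class-specific intensity factors (1 + effect_delta) on the bands reported
  enriched in the pediatric phenotype (nucleic-acid, aromatic amino-acid,
  amide and lipid-ester bands) and on the adult-enriched bands (cholesterol,
  collagen, NADH, cytochrome),
* multiplicative log-normal heterogeneity at the line, cell and point level
  applied jointly to all band amplitudes,
* a broad exponentially decaying fluorescence baseline,
* additive Gaussian detector noise, and
* rare single-pixel cosmic-ray spikes.

Every spectrum carries a :class:`GroundTruth` decomposition that rebuilds
the emitted intensities exactly, so downstream stages can be tested against
a known answer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import Spectrum, SpectrumMeta, SpectralDataset, WavenumberAxis, load_band_table

#: bands more intense in the pediatric phenotype (sign convention from the
#: pediatric-minus-adult subtraction spectrum)
PEDIATRIC_ELEVATED = frozenset({621.0, 672.0, 751.0, 781.0, 1001.0, 1125.0, 1301.0, 1445.0, 1657.0, 1745.0})
#: bands more intense in the adult lines
ADULT_ELEVATED = frozenset({719.0, 1338.0, 1512.0, 1582.0})

_STRONG = frozenset({1001.0, 1445.0, 1657.0})           # dominant bands, amplitude 1.0
_MEDIUM = frozenset({781.0, 1301.0, 1582.0, 1065.0})    # amplitude 0.6; all others 0.35
DEFAULT_FWHM = 12.0

DEFAULT_LINE_COUNTS = {
    "SF188-like": 364,
    "adult-1": 204,
    "adult-2": 204,
    "adult-3": 204,
    "adult-4": 203,
    "adult-5": 203,
}
DEFAULT_PEDIATRIC_LINES = frozenset({"SF188-like"})


@dataclass(frozen=True)
class PeakSpec:
    """One Lorentzian band: center (cm^-1), height (a.u.), FWHM (cm^-1)."""

    center: float
    base_amplitude: float
    fwhm: float = DEFAULT_FWHM
    pediatric_factor: float = 1.0
    adult_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.base_amplitude < 0:
            raise ValueError("base_amplitude must be non-negative")
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")
        if self.pediatric_factor <= 0 or self.adult_factor <= 0:
            raise ValueError("class factors must be positive")

    def class_amplitude(self, class_label: str) -> float:
        factor = self.pediatric_factor if class_label == "pediatric" else self.adult_factor
        return self.base_amplitude * factor


def default_peaks(effect_delta: float = 0.15) -> tuple:
    """Build the 35-band default peak library with tiered amplitudes.

    Class factors are (1 + effect_delta) on the pediatric-elevated bands for
    the pediatric class and on the adult-elevated bands for the adult class.
    """
    table = load_band_table()
    peaks = []
    for pos in table.positions:
        pos = float(pos)
        amp = 1.0 if pos in _STRONG else 0.6 if pos in _MEDIUM else 0.35
        peaks.append(
            PeakSpec(
                center=pos,
                base_amplitude=amp,
                fwhm=DEFAULT_FWHM,
                pediatric_factor=1.0 + effect_delta if pos in PEDIATRIC_ELEVATED else 1.0,
                adult_factor=1.0 + effect_delta if pos in ADULT_ELEVATED else 1.0,
            )
        )
    return tuple(peaks)


@dataclass(frozen=True)
class SyntheticConfig:
    """Full parameterization of the cohort simulator.

    ``noise_sigma`` and the cosmic-ray gain range are expressed relative to
    the spectrum's clean (baseline-free) maximum.  Hierarchy sigmas are the
    log-scale SDs of multiplicative log-normal effects shared by all bands
    of a line / cell / point.
    """

    axis: WavenumberAxis = field(default_factory=WavenumberAxis.canonical)
    peaks: Optional[tuple] = None
    effect_delta: float = 0.15
    baseline_amplitude: float = 2.0       # 2.0 x the strongest base amplitude
    baseline_decay_tau: float = 700.0     # cm^-1
    sigma_line: float = 0.10
    sigma_cell: float = 0.05
    sigma_point: float = 0.03
    noise_sigma: float = 0.01             # x clean-signal max
    cosmic_ray_prob: float = 0.02
    cosmic_ray_gain: tuple = (5.0, 20.0)  # x clean-signal max, single pixel
    points_per_cell: int = 3
    per_line_counts: dict = field(default_factory=lambda: dict(DEFAULT_LINE_COUNTS))
    pediatric_lines: frozenset = DEFAULT_PEDIATRIC_LINES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.peaks is None:
            object.__setattr__(self, "peaks", default_peaks(self.effect_delta))
        for name in ("effect_delta", "baseline_amplitude", "sigma_line", "sigma_cell",
                     "sigma_point", "noise_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.cosmic_ray_prob <= 1.0:
            raise ValueError("cosmic_ray_prob must be in [0, 1]")
        if any(n < 1 for n in self.per_line_counts.values()):
            raise ValueError("every line needs at least one spectrum")
        if not self.pediatric_lines & set(self.per_line_counts):
            raise ValueError("no pediatric line among per_line_counts")

    def class_of(self, line: str) -> str:
        return "pediatric" if line in self.pediatric_lines else "adult"


@dataclass(frozen=True)
class GroundTruth:
    """Exact decomposition of one emitted spectrum.

    ``clean + baseline + noise + spike`` reconstructs the intensities
    bit-for-bit; ``clean`` already includes the hierarchy multipliers.
    """

    clean: np.ndarray
    baseline: np.ndarray
    noise: np.ndarray
    spike: np.ndarray
    line_multiplier: float
    cell_multiplier: float
    point_multiplier: float

    def reconstruct(self) -> np.ndarray:
        return self.clean + self.baseline + self.noise + self.spike


def lorentzian(nu: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    """Unit-height Lorentzian line profile."""
    gamma = fwhm / 2.0
    return gamma**2 / ((nu - center) ** 2 + gamma**2)


def clean_signal(class_label: str, cfg: SyntheticConfig, multiplier: float = 1.0) -> np.ndarray:
    """Noise- and baseline-free band superposition for one class."""
    nu = cfg.axis.values
    y = np.zeros_like(nu)
    for p in cfg.peaks:
        y += p.class_amplitude(class_label) * lorentzian(nu, p.center, p.fwhm)
    return multiplier * y


def baseline_profile(cfg: SyntheticConfig) -> np.ndarray:
    nu = cfg.axis.values
    return cfg.baseline_amplitude * np.exp(-(nu - nu[0]) / cfg.baseline_decay_tau)


def generate_spectrum(
    class_label: str,
    line_effect: float,
    cell_effect: float,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    meta: Optional[SpectrumMeta] = None,
) -> tuple:
    """Draw one spectrum and its ground-truth decomposition.

    ``line_effect`` and ``cell_effect`` are the (already drawn) multipliers
    shared across the line/cell; the point-level multiplier, noise and spike
    are drawn here from ``rng``.
    """
    point_effect = math.exp(rng.normal(0.0, cfg.sigma_point)) if cfg.sigma_point > 0 else 1.0
    multiplier = line_effect * cell_effect * point_effect
    clean = clean_signal(class_label, cfg, multiplier)
    baseline = baseline_profile(cfg)
    clean_max = float(clean.max()) if clean.size else 0.0

    sigma = cfg.noise_sigma * clean_max
    noise = rng.normal(0.0, sigma, size=clean.shape) if sigma > 0 else np.zeros_like(clean)

    spike = np.zeros_like(clean)
    if cfg.cosmic_ray_prob > 0 and rng.random() < cfg.cosmic_ray_prob:
        pixel = int(rng.integers(0, clean.size))
        gain = rng.uniform(*cfg.cosmic_ray_gain)
        spike[pixel] = gain * clean_max

    truth = GroundTruth(
        clean=clean, baseline=baseline, noise=noise, spike=spike,
        line_multiplier=line_effect, cell_multiplier=cell_effect,
        point_multiplier=point_effect,
    )
    if meta is None:
        meta = SpectrumMeta(
            spectrum_id="synthetic-0", cell_line="line-0", cell_id="cell-0",
            point_index=1, class_label=class_label,
        )
    spectrum = Spectrum(axis=cfg.axis, intensities=truth.reconstruct(), meta=meta)
    return spectrum, truth


def generate_cohort(cfg: SyntheticConfig) -> tuple:
    """Simulate the full cohort; deterministic given ``cfg`` (incl. seed).

    Cells carry up to ``points_per_cell`` spectra (the last cell of a line
    may carry fewer to hit the configured count); line and cell multipliers
    are drawn once and reused across their spectra.

    Returns ``(SpectralDataset, list of GroundTruth)`` in matching order.
    """
    rng = np.random.default_rng(cfg.seed)
    spectra, truths = [], []
    for line in sorted(cfg.per_line_counts):
        count = cfg.per_line_counts[line]
        label = cfg.class_of(line)
        line_effect = math.exp(rng.normal(0.0, cfg.sigma_line)) if cfg.sigma_line > 0 else 1.0
        n_cells = math.ceil(count / cfg.points_per_cell)
        produced = 0
        for cell_idx in range(n_cells):
            cell_id = f"cell{cell_idx + 1:03d}"
            cell_effect = math.exp(rng.normal(0.0, cfg.sigma_cell)) if cfg.sigma_cell > 0 else 1.0
            n_points = min(cfg.points_per_cell, count - produced)
            for point in range(1, n_points + 1):
                meta = SpectrumMeta(
                    spectrum_id=f"{line}-{cell_id}-p{point}",
                    cell_line=line, cell_id=cell_id, point_index=point,
                    class_label=label,
                )
                s, t = generate_spectrum(label, line_effect, cell_effect, cfg, rng, meta)
                spectra.append(s)
                truths.append(t)
            produced += n_points
    return SpectralDataset(spectra), truths
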