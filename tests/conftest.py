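import numpy as np
import pytest

from ramanpheno import (
    SpectralDataset,
    Spectrum,
    SpectrumMeta,
    SyntheticConfig,
    WavenumberAxis,
    load_band_table,
)

SMALL_LINE_COUNTS = {
    "SF188-like": 45,
    "adult-1": 27,
    "adult-2": 27,
    "adult-3": 27,
    "adult-4": 27,
    "adult-5": 27,
}


@pytest.fixture(scope="session")
def axis():
    return WavenumberAxis.canonical()


@pytest.fixture(scope="session")
def band_table():
    return load_band_table()


@pytest.fixture()
def small_cfg():
    """Reduced cohort (180 spectra, 45 pediatric) for fast end-to-end tests."""
    return SyntheticConfig(per_line_counts=dict(SMALL_LINE_COUNTS), seed=0)


def make_spectrum(axis, intensities, sid="s1", line="L1", cell="c1", point=1,
                  label="pediatric", flags=()):
    meta = SpectrumMeta(spectrum_id=sid, cell_line=line, cell_id=cell,
                        point_index=point, class_label=label,
                        qc_flags=frozenset(flags))
    return Spectrum(axis=axis, intensities=np.asarray(intensities, float), meta=meta)


def make_dataset(axis, n_per_class=6, spectra_per_cell=3, seed=0, channels=None):
    """Balanced two-line toy dataset with smooth random spectra."""
    rng = np.random.default_rng(seed)
    x = axis.values if channels is None else channels
    spectra = []
    for label, line in (("pediatric", "P1"), ("adult", "A1")):
        for i in range(n_per_class):
            cell = f"c{i // spectra_per_cell + 1}"
            point = i % spectra_per_cell + 1
            y = 1.0 + 0.1 * rng.random(len(x)) + 0.001 * (x - x[0])
            spectra.append(make_spectrum(
                WavenumberAxis(x), y, sid=f"{line}-{cell}-p{point}", line=line,
                cell=cell, point=point, label=label))
    return SpectralDataset(spectra)


def brute_force_lower_hull(x, y, tol=1e-9):
    """O(n^3) rubber-band oracle: pointwise maximum over all chords through
    two data points that lie below every data point."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    best = np.full(n, -np.inf)
    scale = max(1.0, float(np.max(np.abs(y))))
    for j in range(n):
        for k in range(j + 1, n):
            slope = (y[k] - y[j]) / (x[k] - x[j])
            line = y[j] + slope * (x - x[j])
            if np.all(line <= y + tol * scale):
                best = np.maximum(best, line)
    return best
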