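"""Preprocess a cohort and attribute second-derivative peaks to bands.

Despikes, removes rubber-band baselines, vector-normalizes, then computes
class-mean spectra, the pediatric-minus-adult subtraction spectrum and the
Savitzky-Golay negative second derivative of the pediatric mean, and maps
the detected peaks onto the literature band-assignment table.
"""

from ramanpheno import (
    SyntheticConfig,
    assign_bands,
    detect_peaks,
    generate_cohort,
    group_profile,
    load_band_table,
    neg_second_derivative,
    preprocess_dataset,
    subtraction_spectrum,
)

dataset, _ = generate_cohort(SyntheticConfig(seed=42))
result = preprocess_dataset(dataset)
clean = result.dataset
print(f"{len(clean)}/{len(dataset)} spectra survived QC "
      f"({int(result.qc['qc_flags'].str.contains('despiked').sum())} despiked)")

ped = group_profile(clean, "pediatric")
adu = group_profile(clean, "adult")
diff = subtraction_spectrum(ped, adu)
axis = clean.axis
for band in (1001.0, 1445.0, 1582.0):
    ch = axis.nearest_channel(band)
    sign = "pediatric" if diff[ch] > 0 else "adult"
    print(f"subtraction spectrum at {band:.0f} cm^-1: {diff[ch]:+.5f} "
          f"(elevated in the {sign} group)")

d2 = neg_second_derivative(ped.mean, axis)
peaks = assign_bands(detect_peaks(d2, axis), load_band_table())
print(f"\n{len(peaks)} second-derivative peaks in the pediatric mean:")
for p in peaks:
    if p.assignment is not None:
        pos, allocation = p.assignment
        print(f"  {p.position:7.1f} cm^-1 -> {pos:.0f}  {allocation}")
# Positive subtraction values mark bands stronger in the pediatric class
# (phenylalanine 1001, CH2 1445); negative values mark adult-elevated bands
# (cytochrome 1582). Peak attribution recovers the simulated band library.
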