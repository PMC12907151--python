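# Methods

## Problem and data model

The package classifies single-cell Raman spectra from the fingerprint
region into two phenotypes, *pediatric* (an SF188-type glioblastoma
stem-cell model) and *adult* (a panel of adult-derived glioblastoma
lines). A spectrum is a vector of intensities I(ν) on a common wavenumber
grid ν; the canonical grid has 316 channels from 600.0 cm⁻¹ at
3.8 cm⁻¹/pixel (600 + 315·3.8 = 1797 ≤ 1800). The 3.8 cm⁻¹ step matches
the spectral resolution of a 600 l/mm CCD spectrograph; the exact channel
count is a package convention, since instruments differ session to
session. Spectra carry a three-level provenance hierarchy — cell line →
physical cell → measurement point (1–3 per cell) — which drives every
grouping decision downstream.

## Preprocessing

Stage order is fixed: **despike → rubber-band baseline → fluorescence QC →
vector normalize**. Baseline removal must precede normalization (the norm
would otherwise be dominated by the background); despiking comes first
because a single hot pixel distorts the convex hull.

**Despiking.** Modified z-scores z = 0.6745·(d − median d)/MAD are
computed on the first differences d of the spectrum. A channel is treated
as a cosmic-ray pixel when the differences entering and leaving it are
both beyond the threshold (default 6) with opposite signs *and* exceed the
adjacent differences by a factor of 3. The isolation factor is essential:
in low-noise spectra a sharp Lorentzian apex also produces two large
opposite-signed differences, but its shoulders are about as steep as its
tip, whereas a one-pixel spike towers over its neighbourhood. Flagged
pixels are replaced by the median of the non-flagged channels in a
5-channel window (widened if necessary), which makes the operation
idempotent; only excessive fluorescence leads to exclusion of a spectrum,
spikes are always corrected in place.

**Rubber-band baseline.** The fluorescence background estimate is the
lower convex hull of the points (ν, I), computed by Andrew's monotone
chain (an O(n) scan after the grid ordering; collinear vertices are
dropped, which resolves ties toward the earlier channel), anchored at both
endpoints and linearly interpolated between hull vertices. The corrected
spectrum is zero at every hull vertex and non-negative everywhere. The
test suite checks the hull against an independent O(n³) brute-force
construction (pointwise maximum over all chords lying below the data).
Note that the hull of signal + convex background is *not* the hull of the
signal plus the background, so the correction carries a smooth systematic
residual (~8% of the band intensity at the default background amplitude);
the residual is class-independent, and the class *contrast* is invariant
to the background amplitude within noise — that invariance, not raw
channel-wise equality, is the tested guarantee.

**Fluorescence QC.** A spectrum is rejected when the baseline carries more
than 90% (strict inequality) of its total summed intensity, or flagged
`degenerate` when the total is non-positive. The threshold is a
convention, exposed in `PreprocessConfig`; the default cohort loses no
spectra to it.

**Normalization.** Division by the Euclidean norm over the full
fingerprint region ("vector normalization"), removing overall intensity
scale so that only relative band patterns remain.

## Band analysis

Class profiles are channel-wise arithmetic means with *population* SD
(divide by n). The subtraction spectrum (pediatric mean − adult mean)
localizes class-enriched bands by sign. Peak positions are sharpened with
the Savitzky–Golay negative second derivative (window 9, polynomial order
3, edge channels from the polynomial fitted to the truncated boundary
window). The derivative is reported in physical units (per cm⁻²,
i.e. divided by the squared grid step) so that polynomial exactness — the
filter reproduces derivatives of cubics exactly — is a well-defined test.
Peaks are positive local maxima of −d²I/dν² with prominence ≥ 5% of the
global maximum (a band apex has negative curvature; sign-indefinite local
maxima in the tails are artefacts), refined by three-point parabolic
interpolation, and assigned to the nearest entry of the packaged 35-band
table when within 4 cm⁻¹ (≈ one pixel; ties toward the lower band). The
table's biochemical allocations are literature attributions, not
biologically verified claims.

## Classification

Features are the preprocessed intensities. The standardizer (per-feature
zero mean, unit variance; constant features dropped) and the PCA (top 20
components of the standardized training matrix) are fitted **on the
training partition only** and applied unchanged to held-out data. Class
balancing subsamples the majority class to the minority count by whole
cells (seeded, one partial cell allowed); the 80/20 split is stratified by
class and grouped by cell, assigning whole cells to one side, so the test
fraction is met to within one cell per class. The same grouping rule
extends to the 10-fold cross-validation used by the architecture search —
the conservative choice, since point spectra of one cell are strongly
correlated.

The classifier is a multilayer perceptron (ReLU activations, Adam,
learning rate 10⁻³, up to 500 epochs) as implemented in scikit-learn. The
default architecture is five hidden layers of five neurons; the search
space sweeps uniform-width nets of depth 1–10 over widths
{2, 5, 10, 20, 50, 100} (the full 99-width grid is configurable but not
the default, for runtime), selecting the best mean CV accuracy with ties
broken toward fewer parameters, then fewer layers. Stopping is loss-based
(no improvement > 10⁻⁴ for 20 epochs), matching Adam's library defaults;
holding out a validation split for early stopping is available but off by
default because on very small nets the validation criterion can terminate
training on the initial plateau before the loss starts moving. Very
narrow or very deep nets (width 2, depth 10) can land in dead-unit minima
under a single random initialization regardless of class separability;
this optimization failure mode is inherent to single-init training and is
why test guarantees about "every architecture" are scoped to nets wide and
shallow enough to train reliably.

Predictions threshold the pediatric class probability at 0.5; pediatric is
the positive class everywhere (sensitivity = pediatric recall,
specificity = adult recall). The report carries raw confusion counts,
row-normalized percentages (half-up rounding to one decimal for
presentation; raw floats retained), per-class F1, and the rank-based ROC
AUC (equivalent to trapezoidal integration over all thresholds with
midrank tie handling).

## Synthetic cohort generator

The generator emulates the study design so that every stage is
testable without measured data: six lines (one pediatric: 364 spectra;
five adult: 204/204/204/203/203 — an arbitrary partition chosen only to sum to 1,382),
three points per cell (the last cell of a line may carry fewer). Each
spectrum is

I(ν) = m · Σₖ aₖ · cₖ · L(ν; νₖ, Γ) + B·exp(−(ν−600)/τ) + ε(ν) + spike,

with Lorentzian profiles L (FWHM Γ = 12 cm⁻¹, typical for biological Raman
lines) at the 35 packaged band positions. Base amplitudes aₖ are tiered —
1.0 for the dominant bands {1001, 1445, 1657}, 0.6 for
{781, 1065, 1301, 1582}, 0.35 otherwise — so the major bands dominate as
in measured cell spectra. The class factor cₖ is 1 + δ (effect size
δ = 0.15 by default) on the pediatric-enriched band set
{621, 672, 751, 781, 1001, 1125, 1301, 1445, 1657, 1745} for pediatric
spectra and on the adult-enriched set {719, 1338, 1512, 1582} for adult
spectra, else 1; the sets encode the reported enrichment directions
(nucleic-acid, aromatic and amide/lipid-ester bands in the pediatric
phenotype; cholesterol, collagen, NADH and cytochrome bands in the adult
lines). The multiplier m is a product of log-normal effects drawn once
per line (σ = 0.10), cell (σ = 0.05) and point (σ = 0.03) and shared by
all bands. The background is exponential (amplitude B = 2.0 — twice the
strongest band — decay τ = 700 cm⁻¹); detector noise is Gaussian with
σ = 1% of the spectrum's clean (baseline-free) maximum; with probability
0.02 a single pixel receives a spike of 5–20× the clean maximum. Every
spectrum ships with its exact decomposition (clean, baseline, noise,
spike, multipliers) so oracle tests can reconstruct it bit for bit.

**What the generator does and does not emulate.** It reproduces the
hierarchy, class band-pattern differences, backgrounds and artifact types
of the study design, but its only *within-class* variation surviving
baseline removal and normalization is detector noise: the joint (shared
across bands) hierarchy multipliers are pure scale and cancel under unit
normalization. Real cell spectra vary in *composition* (semi-independent
band-amplitude variation, Mie-type background shape changes, photon-count
noise), not only in brightness. Two consequences follow. First, the
synthetic classes are far easier to separate than measured ones — the
pipeline saturates its held-out metrics at the default δ = 0.15, so
passing the benchmark shows the machinery is correct, not that measured
data would classify this well; the effect-size sweep (accuracy at chance
for δ = 0, AUC non-decreasing in δ) is the meaningful behavioral check.
Second, the standardized channel variance is dominated by iid noise
spread over all 316 channels, so the top-20 PCA components capture only
≈ 48% of training variance, far below the ≈ 89% reported for measured
spectra, where rich correlated biochemical variation concentrates in few
components. This is a recognized fidelity limit of the generator, not of
the PCA implementation (which is verified against a direct
eigendecomposition oracle).

## Problem sizes and numerics

The packaged benchmark runs the full cohort (1,382 spectra × 316
channels) for five seeds; unit and property tests use a 180-spectrum
cohort with the same structure. All randomness flows through
`numpy.random.Generator` seeds threaded explicitly (the pipeline derives
independent substreams for generation, balancing, splitting and MLP
initialization from one master seed). Tolerances: axis uniformity 10⁻⁹
relative; CSV round-trip 10⁻⁹ relative on intensities; hull/oracle
agreement 10⁻⁷ absolute; SG polynomial exactness 10⁻⁹ on unit-scale
inputs. Degenerate inputs fail loudly: zero-norm spectra, single-class CV
folds, single-row scaler fits and oversized PCA ranks raise ValueError;
single-class truth yields a missing AUC with a warning rather than a
number.

## Known limitations

* One pediatric line in the emulated design: the classifier recognizes a
  line signature as much as an age signature; nothing here addresses that
  confound, which is a property of the study design itself.
* The generator's noise model is additive Gaussian; no Poisson/EMCCD
  statistics, no wavenumber calibration drift, no Mie scattering.
* Band assignments are nearest-neighbour lookups in a literature table;
  no curve fitting, deconvolution or biological verification.
* The rubber-band baseline under-corrects convex backgrounds by a smooth
  class-independent residual (see above); analyses that need absolute
  corrected intensities rather than class contrasts should account for
  this.
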