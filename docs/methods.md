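# Methods

This note documents the models, procedures and numerical choices behind
`afspectra`, and what the synthetic phantoms do and do not show about real
light-sheet data.

## Imaging model and conventions

All volumes are `(z, y, x)` arrays with 0-based indices and voxel centers at
integer coordinates; z is the detection (slice) axis.  The five excitation
channels follow the instrument configuration they emulate: lasers at 405,
488, 561, 640 and 785 nm paired with 525/50, 535/30, 620/20, 680/30 and
845/55 emission filters; camera exposure 104 ms for the four shorter
wavelengths and 1040 ms at 785 nm.  These are the defaults of
`load_channel_config` and can be overridden per channel in YAML/JSON.
Integer pixel data are never modified in place; arithmetic operations promote
to 32-bit float.  When a file carries OME voxel-size tags that disagree with
a config, the file wins and a notice is logged (the file is closer to the
data).

## Bilateral fusion

Separately acquired left- and right-illuminated stacks are combined by
simple addition.  The sum of two 16-bit stacks can exceed 65535, so fusion is
performed in 32-bit float and never saturates; the fraction of voxels that
*would* have saturated in the input dtype is reported as a diagnostic
(`clipped_fraction`).  This preserves quantitation for the downstream
signature tables.

## Trilinear downsampling

"Trilinear averaging" is implemented as exact block averaging: each output
voxel is the arithmetic mean of its `fz × fy × fx` input block (factor 4
takes isotropic 5 µm data to 20 µm).  Trailing partial blocks are averaged
over the voxels actually present — zero padding would bias edges.  Means are
conserved exactly when the factors divide the shape.

## Histogram normalization

"Normalized by histogram" is interpreted as a percentile-clipped min–max
rescale: the 0.1th percentile maps to 0, the 99.9th to 1, values clipped to
[0, 1].  Full histogram equalization was rejected because it is non-linear
and would distort the semantics of the subtraction channels.  This
interpretation is recorded in every run's `config.yaml`.  A constant volume
returns all zeros with a warning.  Subtraction channels (`a − b`, clipped at
0, optionally normalizing both inputs first) and the inversion (`1 − v` on
[0, 1] data) follow directly.

## Edge-rise-distance (ERD)

An ERD profile is the pixel intensity sequence along a line within one
slice: nearest-voxel sampling at unit steps for axis-aligned lines, linear
interpolation for oblique ones.  Replicate profiles are summarised per
position by the mean and a 95% confidence interval
`mean ± t(n−1, 0.975)·sd/√n`; the Student t quantile (not the normal) is
used because replicate counts here are small (3–4 samples).

The protocol this mirrors plots profiles but defines no scalar.  As an
extension, the profile is scalarized as the 10–90% rise distance: the
distance between the first crossings of `low + 0.1·(high−low)` and
`low + 0.9·(high−low)` of the profile's own plateau range, with crossings
linearly interpolated between samples, fractions configurable.  For an ideal
step blurred by an isotropic Gaussian of width σ the expected value is
`(z(0.9) − z(0.1))·σ = 2·1.2816·σ`; the implementation agrees with this
closed form within ~1.3% for σ between 2 and 8 px (the residual is
discretisation of the erf profile).  Falling edges are reversed before
measurement.

## Spectral signatures

`region_signature` computes the mean intensity of every labeled region in
every channel, subtracts the background-region mean per channel (floored at
0), and normalises for display.  The default `per_channel_max` scaling — each
channel column divided by its brightest region — matches per-channel display
color bars; `global_max` and `none` are available, and the uncorrected
background row is retained in `raw_means`.  How real relative-AF color bars
were scaled is inferred, not stated, so the normalization is explicit in the
output.

## Fourier sharpness

The statistic is the spectral bandwidth of a slice: the slice is
mean-subtracted, Hann-windowed, and transformed with a 2D DFT; the squared
magnitude with the DC bin removed is normalised to unit total energy and
treated as a probability distribution over radial spatial frequency
(cycles/pixel); the reported value is the power-weighted standard deviation
of that frequency.  Volumes are processed slice-wise and averaged.

This is one consistent reading of "standard deviation of the power spectrum":
it is monotone in actual image sharpness (Gaussian blur narrows the spectrum
and strictly lowers the statistic), invariant to affine intensity rescaling
`a·I + b` (so channels with different exposure do not trivially dominate),
and 0 on constant slices.  The naive standard deviation of the normalised
power *values* has the opposite monotonicity — blurring concentrates energy
into few low-frequency bins and increases the spread of values — and was
therefore not used.  The variant is recorded in run metadata.

## Trainable pixel classification

The classifier follows the WEKA trainable-segmentation design with four
classes: background, lumen (the entire vessel network), and the low- and
high-AF parenchymal zones.  Features are computed per 2D slice — training
happens on individual annotated images, and slice-wise streaming bounds
memory to a few feature planes.

**Feature bank.**  Sigmas are powers of two from 1 up to `max_sigma`
(default 16), plus sigma 0 — the unfiltered image — when `min_sigma` is 0.
Default families: Gaussian smoothing (6), Sobel gradient magnitude (6),
Hessian eigenvalues, ordered (12), differences of Gaussians over all sigma
pairs (15), and membrane projections (6): a 1-px-thick line kernel in a
19×19 patch rotated over the half circle in 6° steps, with the 30 responses
aggregated by sum/mean/max/min/median/std.  All filters use reflective
boundary handling.  That is 45 attributes per channel, pinned by a
regression test; the count is a deterministic function of the configuration
and is reported.  (The reference tool reports 228 attributes for its own —
unlisted — feature composition; the composition here is the documented one
above, and the count is not forced to match.)

**Forest.**  scikit-learn random forest, 200 trees, √(n_features) candidate
features per split, recorded seed, single-threaded for reproducibility.
Sparse annotations (0 = unlabeled) on selected slices provide the training
rows; every declared class must contribute at least one labeled pixel.
Training provenance (slices, volumes, pixels per class, training accuracy)
is stored with the model.  Default training channel: 785 nm at 20 µm, where
liver AF contrast is strongest.

**Probability maps and postprocessing.**  Vote fractions give per-class maps
summing to 1 per voxel.  Postprocessing subtracts the background probability
from each tissue class, clipping into [0, 1] (whether the original protocol
clipped negatives is unstated; clipping is adopted), and replaces the
background map by its inversion `1 − P(background)` — the organ's
gross-structure map.  Masks come from thresholding one map (default 0.5) or
from an argmax over all classes; evaluation reports per-class DICE (both
masks empty scores 1.0, flagged) and the macro average.

## Synthetic phantoms

The generator emulates the study conditions the pipeline targets; it is a
first-class, tested module, not a fixture.

- **Geometry.**  An ellipsoidal organ (or, for the biopsy preset, a tissue
  cylinder along z with 1 mm default diameter, the maximum core size of the
  clinical extractor) inside image background.  Parenchyma is split into
  high- and low-AF zones by the sign of a smooth band-limited field of
  oblique plane waves with period `zonation_period_um` (default 500 µm, a
  lobule-scale choice; no quantitative zonation geometry is published, only
  the visual analogy to GS/E-Cadherin zonation).  Vessels are random-walk
  tubes (default 12, radius 60–120 µm) carved as lumen.
- **Intensities.**  A voxel of class k in channel c has clean intensity
  `S_true[k, c]`.  Defaults: background and lumen at detector background
  (5 counts); low AF rising from 20 (405 nm) to 80 (785 nm); high AF exactly
  twice the low zone.  The 2:1 contrast is a free choice (no published
  number exists) and is stated here and in the preset, not asserted against
  anything.  Parenchyma is brightest at 785 nm by construction.
- **Shading and noise.**  Shared exponential depth attenuation along z and
  one-sided illumination decay along x (mirrored between the left and right
  acquisitions), both with 5000 µm default length — mild enough that the
  class intensity ranking survives across the volume, as it visibly does in
  cleared tissue.  Noise is signal-proportional Gaussian (default sd = 5% of
  the local clean signal) with an optional Poisson shot-noise term
  (`poisson_scale`, off by default), applied after shading, clipped at 0.
- **Determinism.**  One seed drives named substreams (geometry, left noise,
  right noise); identical specs and seeds give bit-identical volumes, and
  class voxel counts are invariant to noise and illumination settings.

What the phantoms do **not** emulate: real AF spectra and their biological
variability, partial-volume effects at class borders, stripe artifacts from
absorbing particles, refractive-index mismatch, bleed-through from residual
staining, and the transitional zonation boundary that makes real low-AF
delineation hard.  Passing the end-to-end tests therefore shows the
machinery is correct and well-calibrated on idealised tissue — it does not
reproduce real-data difficulty.  In particular the phantom DICE scores
(≈ 0.99 high AF, ≈ 0.88–0.93 lumen at default noise) are far above the
published 0.82/0.42 against manual delineations of real livers, where the
low-AF zone suffers from an indistinct transitional zone; those animal data
are not publicly deposited, so no desk-scale reproduction is possible.

## Problem sizes and defaults in the shipped workflows

The liver demo generates three phantoms at 10 µm (48×192×192), fuses and
downsamples by 2 to 20 µm (24×96×96), trains on 5 annotated slices × 2
phantoms (1000 pixels per class per slice) and predicts the third.  The
end-to-end verification in the test suite runs the same 5×2 design directly
at 20 µm on 64×256×256 volumes.  Acceptance reporting uses 32×128×128.
These sizes keep full runs in the tens-of-seconds-to-minutes range on a
single core while leaving thousands of voxels per class for stable
statistics.

## Known limitations

- Oblique ERD lines use bilinear interpolation; sub-pixel edge localisation
  is limited accordingly.
- The sharpness statistic is windowed with a separable Hann; slices smaller
  than ~16 px give noisy bandwidth estimates.
- The membrane-projection kernels are rotated with bilinear interpolation,
  so responses at intermediate angles are approximations of ideal line
  integrals.
- Label downsampling uses majority vote with ties to the smaller label id;
  thin structures (one-voxel vessels) can vanish at coarse resolutions.
- No registration between left/right stacks: they are assumed pre-aligned,
  as produced by the instrument.
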