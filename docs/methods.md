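# Methods

## Problem and pipeline

The package grades striped stem-borer infestation of rice stalks into six
ordinal degrees (DI0 healthy; DIk = infested 2k days) from visible/NIR
hyperspectral cubes (512 bands, 380–1030 nm).  The pipeline is: flat-field
calibration → band trimming → ROI mean spectra → Savitzky–Golay smoothing →
Kennard–Stone 2:1 split → SPA wavelength selection → per-cube PCA + GLCM
texture → BPNN classification of four feature sets (full spectra, selected
wavelengths, texture, spectral+texture fusion).

## Calibration and preprocessing

Reflectance is `(raw − dark) / (white − dark)` per pixel and band; white
and dark references are single cross-track frames broadcast along the scan
axis.  Dead cells (`white == dark`) would divide by zero; they are set to 0
and logged rather than propagating NaN into ROI means.  Calibrated
reflectance is clipped to [0, 1.5] so specular highlights cannot
destabilize the min–max gray-level quantization later.

Band trimming defaults to (82, 22), taking the 512-band axis to 408 bands
covering roughly 480–1000 nm.  (The source experiment's text is internally
inconsistent about this count, quoting both "490 variables" and "408
wavebands" for the trimmed axis; 512 − 82 − 22 = 408, so 408 is used
throughout.)  Savitzky–Golay smoothing defaults to window 9, polynomial
order 3 — unstated in the source, chosen as the common mild setting for
~1.3 nm/band spectra — with edges fitted on the truncated window
(`scipy.signal.savgol_filter(mode="interp")`), not reflection padding.

## Kennard–Stone split

The deterministic max–min rule: the two most distant samples (Euclidean
distance on the smoothed, trimmed spectra) seed the calibration set; each
later pick maximizes its minimum distance to the picked set.  Ties break
toward the lowest sample index.  "2:1" is `n_cal = floor(2N/3)`, which for
365 samples gives the published 243/122 partition.

## SPA

Phase 1 grows one chain per starting band; at each step every remaining
column is deflated by its projection onto the most recently chosen
residual (accumulated Gram–Schmidt, equivalent to projecting onto the
orthogonal complement of the full chosen span) and the largest residual
norm wins, ties toward the lower index.  Columns are not mean-centered by
default (a flag exposes centering).  Chains are grown only to the largest
subset size that Phase 2 will evaluate (default 30; the classic bound
min(N−1, K) ≈ 242 would waste ~90 % of the work).

Phase 2 fits an MLR of the numeric DI index 0–5 on every chain prefix in
the size range, scores RMSE on the validation set, and keeps the global
minimizer; duplicated index sets are evaluated once; RMSE ties break toward
the smaller subset and then chain order.  The ordinal DI index is used as
the regression response because the source experiment runs SPA on the same
six-degree problem without stating an encoding, and elsewhere regresses
features on DI directly.  SPA's internal validation set reuses the
Kennard–Stone prediction set.

## Texture

PCA is fitted per cube on its own ROI pixel spectra (mirroring an
image-by-image ENVI workflow), with `svd_solver="covariance_eigh"` — exact
and deterministic; the auto solver silently switches to randomized SVD
above 500 columns, which is not reproducible.  Loading signs are fixed so
each component's largest-magnitude element is positive.  Off-mask pixels of
the PC1/PC2 score images are set to the image minimum, and GLCMs are
accumulated over the ROI bounding box with any pair touching an off-mask
pixel excluded.

GLCM defaults: distance 1, symmetric counting, 64 gray levels (min–max
quantized per image), descriptors averaged over the four directions 0°,
45°, 90°, 135° — standard Haralick practice; the source states none of
these.  Entropy uses the natural log (a flag could switch to log2; the
descriptor is used comparatively, so the base is immaterial).  Correlation
of a constant image (zero marginal variance) is defined as 1: pairs are
perfectly predictable.  Directions are (row, col) offsets
0°→(0,1), 45°→(−1,1), 90°→(−1,0), 135°→(−1,−1); under image transposition
0° and 90° swap and the two diagonals map to themselves, under 90° rotation
0↔90 and 45↔135 — both invariances are tested.

## BPNN

One hidden layer, logistic sigmoid on hidden and output layers, one-hot
targets over the six classes, squared-error loss summed over output nodes
and averaged over samples per epoch.  Defaults follow the source study: 5
hidden nodes, learning rate 0.6, target error 1e-5, at most 1000 epochs;
weights initialize uniformly in [−0.5, 0.5] from the configured seed.

Weights are updated **per sample** (sequential delta rule) in fixed row
order, not full-batch.  Full-batch descent was tried first and rejected on
measurement: at the fixed learning rate and epoch budget it leaves the
fused model at ~75–83 % calibration accuracy and is strongly seed
dependent, while sequential updates reach 100 % calibration / ≥96 %
prediction accuracy on every seed tried and remain fully deterministic.
The epoch error curve and the gradient-verification oracle use the batch
loss `E = (1/N) Σ_n ‖a₂ − y‖²`; the per-sample updates apply the same
backprop formulas to one sample at a time.  The inner sweep is JIT-compiled
with numba when available (a pure-NumPy fallback with identical semantics
is used otherwise).

Known limitation: with all 408 bands as input, the network frequently
stalls on a plateau (epoch error ≈ 0.38) at the fixed learning rate and
epoch budget — 5 saturating sigmoid units fed by hundreds of collinear
[0, 1] inputs.  Fan-in-scaled and Nguyen–Widrow initializations were tried
and do not reliably fix it.  The selected-wavelength, texture and fusion
models are unaffected, so the package's comparative claims (fusion ≥ 90 %,
texture < spectral) do not rest on the full-spectra model.

## Feature preparation

Each feature is min–max scaled to [0, 1] using calibration-set extrema;
prediction samples may legitimately fall outside [0, 1] and are not
clipped.  Constant features map to 0 and are flagged.  Fusion is column
concatenation of the normalized selected-wavelength block followed by the
normalized 16-value texture block.

## Synthetic scenes

The generator emulates the documented study conditions: 365 samples in six
classes (45, 69, 69, 69, 69, 44), 512 bands over 380–1030 nm, 64×64 images
with an elongated wavy stalk ROI (~20 % of pixels).  The healthy base
spectrum is an analytic vegetation curve (green peak at 550 nm, chlorophyll
well at 670 nm, red edge at 715 nm, NIR plateau, water dip at 970 nm); only
the *ordering* constraints between classes are treated as normative, not
absolute reflectance values.  Class effects are smooth offsets on
570–700 nm and 750–1000 nm windows encoding the severity trends and the
DI1/DI2 compensation effect.  Defaults (per-class visible offsets 0, −0.020,
−0.010, +0.020, +0.045, +0.070; NIR 0, +0.030, +0.015, −0.030, −0.065,
−0.100) give adjacent-class gaps of 0.010–0.035 reflectance.

Per-sample biological variation: multiplicative gain (sd 0.01), a scalar
severity jitter multiplying the class effect (sd 0.10), and a smooth
quadratic baseline wiggle (sd 0.003).  These keep same-class samples
distinct while leaving within-class spread a factor ~3 below adjacent-class
gaps, consistent with spectra that classify above 90 % as reported.  Pixel
noise is additive Gaussian (sd 0.01 reflectance).

Lesion texture is soft-thresholded smoothed Gaussian noise whose density
(4–32 % of pixels), contrast (±6–46 % reflectance, brighter in the red,
darker in the NIR) and patch size (smoothing σ = 1 + 3·scale: scattered
spots early, coalescing blotches late) all grow with the per-class texture
scale (defaults 0.05, 0.20, 0.35, 0.50, 0.70, 0.90, with 20 % per-sample
jitter).  Under these defaults the texture-only model lands in the 45–60 %
accuracy range — clearly informative, clearly below the spectral models,
the ordering the source reports.

Raw counts are synthesized as `dark + R·(white − dark)` under a
halogen-lamp-shaped white frame, so Eq.-1 calibration recovers R exactly
(the 99.9 %-reflectance panel is treated as unity); cubes are stored in
single precision, which bounds round-trip error at ~1e-7.

What the generator does **not** emulate: radiative transfer, plant
geometry/pose variation, specular structure, instrument striping, or the
real covariance of biological spectra.  Passing tests therefore demonstrate
that the pipeline recovers class structure of this documented form, not
field performance.

## Problem sizes used by tests and the acceptance script

Unit tests run on reduced scenes (8–48 px images, 1–15 samples per class).
The end-to-end acceptance check runs the full default study (365 cubes of
64×64×512) once per seed for five seeds, ~35–45 s per run; the acceptance
script runs it once.  The oracle suites (SPA vs explicit projector, GLCM vs
pair counting, Kennard–Stone vs enumeration, BPNN gradients vs central
differences) use matrices up to 8×6, 6×6 images and 5-sample batches.

## Reference tables

The four published confusion matrices are shipped as transcribed CSV
fixtures.  Recomputing accuracies from the counts reproduces the printed
figures exactly for the first three tables; the fusion table's printed
calibration per-class percentages contradict its own printed counts in all
six rows and its prediction total prints 95.10 where the counts give
116/122 = 95.08.  Recomputed values are treated as authoritative; the
printed ones are kept as annotations (`stemborer_hsi.reference`).
Percentages are rendered with two decimals, half-up, matching the tables.
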