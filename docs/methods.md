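# Methods

This note documents the models, parameter choices and numerical decisions
behind `cropfusion`, and what the synthetic study conditions can and cannot
show about real imagery.

## Raster model

Rasters are `[band, row, col]` grids with per-band metadata (role, centre
wavelength, native resolution). Convention: row-major, origin at the outer
corner of the top-left pixel, pixel-is-area; the map coordinate of pixel
`(r, c)` is `origin + ((c+0.5)·px, −(r+0.5)·px)`. Reflectance is stored as
float in [0, 1] after preprocessing; raw digital numbers as non-negative
values. Nodata is a sentinel (NaN by default): nodata pixels are excluded
from statistics and propagate through per-pixel operations. Band roles
`{blue, red, nir, pan}` are unique per raster. On-disk containers are
NPZ or plain multiband TIFF, both with a JSON sidecar for band metadata;
no coordinate-reference-system handling (reprojection is out of scope).

## Preprocessing

* **Radiometric calibration** is a per-band linear map `gain·DN + offset`
  (gain ≠ 0); it stands in for sensor-specific calibration workflows.
* **Dark-object subtraction** subtracts each band's exact minimum valid
  value (not a percentile), so the post-condition `min = 0` holds for every
  band and the operation is idempotent. It assumes each scene contains a
  truly dark object.
* **Cubic convolution** uses the Keys kernel with `a = −0.5` (third-order
  accurate; exact on polynomials up to degree 2) with reflect padding,
  implemented as separable dense weight matrices over the shared map
  extent. Resampling to the source pixel size is the identity; constants
  are preserved exactly. The default pipeline resamples both stacks to the
  pan grid before fusion.
* The **false-colour composite** (NIR/red/green with a 2–98% percentile
  stretch) is display-only.

## Gram-Schmidt pan-sharpening

Component 0 is the simulated pan (unweighted band mean, mean-centred);
component `k ≥ 1` is the residual of mean-centred band `k−1` after
projecting out all previous components (modified Gram-Schmidt; stored
lower-triangular coefficients give exact inversion, tested to 1e−8
relative). A zero-variance simulated pan (constant stack) is a degenerate
input and raises.

Histogram matching of the real pan is affine (match mean and standard
deviation). When the pan grid is finer than the MS grid, the matching
*gain* is estimated between the block-degraded pan and the block-degraded
simulated pan, and the *offset* anchors the matched pan to the simulated
pan's mean. Estimating the gain at the fine grid instead systematically
under-weights the simulated pan's variance (the upsampled MS has lost
sub-block detail), which leaks a radiometric bias of order 0.05 NDVI into
the fused bands on noise-free scenes; the degraded-grid estimate reduces
this to ≤ 0.02 while keeping two exact invariants: substituting the
simulated pan itself returns the upsampled stack bit-near-exactly, and
per-band global means are preserved to ≤ 1e−6. Spectral bands are taken
from the fine-resolution-like stack and the pan from the coarse stack's
pan band by default; the API accepts either assignment.

## Multi-patch GLCM texture

Defaults: window 15 (odd, ≥ 3), 32 gray levels, offset distance 1, four
orientations (0° = right, 45° = up-right, 90° = up, 135° = up-left),
stride 1, reflect padding, arithmetic-mean aggregation over orientations.
Choices the method leaves open, fixed here: 32 levels balance
discrimination against sparse-matrix noise in a 225-pixel window; distance
1 is the conventional offset; the orientation mean matches reporting
per-orientation means that are averaged into a single value per feature.

Each window is quantized *locally* (uniform binning of its own min–max
range). A relative-epsilon guard (1e−9) maps numerically constant windows
to level 0 — without it, floating-point dust is stretched across the full
gray-level range and becomes spurious texture. Co-occurrences are counted
in both directions (symmetric matrix) and normalized to sum 1; entropy
uses the natural log with `0·ln 0 := 0`. A constant window has zero
marginal variance, so correlation is undefined there; it is reported as 1
by convention (a constant patch is perfectly self-correlated),
configurable to 0. The windowed implementation is vectorised
(per-window bincount over pair codes; entropy from nonzero counts only)
and is verified against a brute-force loop over the single-patch API to
1e−10, and the single-patch matrix against scikit-image's co-occurrence
routine. Texture is computed on the fused NIR band by default
(configurable); the window interpretation is a 15×15 patch from which the
four statistics are extracted.

## Spectral indices

NDVI and EVI with the canonical EVI constants G = 2.5, C1 = 6, C2 = 7.5,
L = 1 (exposed as configuration). Reflectance is clipped to [0, 1] before
index computation because sharpening can overshoot slightly. Zero (NDVI)
or near-zero (|·| < 1e−9, EVI) denominators yield NaN, which downstream
vector assembly drops.

## Feature Weighting Method

Profiles are per-feature (mean, sd); the standardized distance is
`d = (x̄ᵢ − x̄ⱼ)/(sᵢ + sⱼ)`, taken in absolute value since the sign depends
only on argument order; both deviations zero is a degenerate input. The
group weights are derived from all 15 unordered feature pairs: each
feature is scored by its mean |d| to the other five, the spectral (m = 2)
and textural (n = 4) groups each average their members' scores, and the
two group scores are normalized to sum to 1. A pair set restricted to the
8 spectral×textural cross pairs is available for comparison but makes the
weights data-independent (every cross pair touches both groups, so any
symmetric attribution yields w₁ = w₂ = 0.5); the all-pairs form is the
package's resolution of a formulation that is not fully determined, and it
preserves the intended behaviour: weights proportional to standardized
distances, invariant under within-group permutation, equal in symmetric
constructions. Weights are computed per interval by default (recomputation
per interval vs once globally is a free choice). Note that for the
scale-sensitive backends the standardizer inside the model pipeline undoes
a uniform column rescaling; FWM weighting materially affects the
tree-based backends' feature geometry only through split ordering.

## Synthetic study conditions

The generator emulates a two-crop landscape observed at 10 m (blue, green,
red, NIR), 30 m (plus SWIR1/2) and a 10 m pan band, over five intervals.
Defaults (chosen once as the study conditions):

* extent 96×96 at the fine grid, resolution ratio 3, 24 rectangular fields
  on a jittered 5×5 grid, wheat share 0.5 (greedy area-balanced class
  assignment, realized share within 5% for ≥ 20 fields);
* NDVI trajectories (mean, sd 0.05): wheat .30/.45/.60/.75/.62,
  maize .28/.35/.40/.45/.47 for T1..T5 — wheat peaks at T4 (March), the
  wheat-maize gap is non-decreasing T1→T4, and wheat ≥ maize up to the
  peak (enforced as a configuration invariant);
* per-class texture: spatial autocorrelation length 1.5 px (wheat) vs
  5 px (maize), brightness-noise amplitude 0.012, background NDVI
  0.12 ± 0.02, sensor noise sd 0.003;
* band model with brightness a = 0.25: `red = a(1−t)`, `nir = a(1+t)`
  (so pixel NDVI equals the target `t` exactly in the noise-free limit),
  blue/green tied to red by ±0.01, SWIR decreasing in `t`; the coarse
  stack is the block mean of the fine-grid radiance plus noise; pan is the
  visible+NIR mean plus noise;
* the per-pixel NDVI spread sd is split between a per-field offset
  (sd/2) and within-field autocorrelated variation (√3/2·sd);
* 2,000 labeled vectors per interval (a desk-scale stand-in for the
  published 40,000–60,000), stratified 80:10:10 split preserved.

Everything is deterministic per seed; field geometry depends only on the
seed (fields do not move between intervals) while noise depends on seed
and interval.

**What passing tests do not show.** The generator produces rectangular
fields, Gaussian textures and an exactly linear band model; real parcels,
canopies and atmospheres are none of these, so synthetic accuracies say
nothing about accuracy on real scenes — only that the pipeline's
machinery (fusion invariants, feature formulas, weighting, splitting,
training) behaves as specified. One leakage property deserves emphasis:
with a pixel-level random split, spatially autocorrelated features let a
classifier memorize field fingerprints (per-field offsets, overlapping
texture windows, field-edge window shapes), so held-out accuracy stays
above chance even when the class distributions are identical. The honest
no-signal control is therefore label permutation, which breaks the
feature-label link including its spatial structure and scores at chance
(within 3σ binomial). Real-imagery studies face the same issue when train
and test pixels share fields.

## Classification harness

Backends and defaults: DNN = multilayer perceptron, hidden layers
[128, 256, 128], ReLU, softmax output, Adam at 5e−4, 120 epochs; Conv1D =
two valid-mode 1-D convolutions (64 and 128 filters, kernel 3, ReLU) over
the 6-feature vector treated as a length-6 single-channel sequence,
flatten + softmax, Adam at 5e−4, 120 epochs, batch 64 — written directly
in NumPy with analytic backpropagation (gradient-checked against finite
differences); RF = 200 trees, depth 10; DT = Gini, depth 8; SVM = RBF,
C = 0.5; LightGBM = 40 leaves, depth 8; XGBoost = learning rate 0.05,
depth 6; CatBoost = depth 6, learning rate 0.03, L2 = 3.5. The boosting
backends are optional plug-ins: a missing library raises a capability
error naming the backend. Scale-sensitive backends (DNN, Conv1D, SVM) are
wrapped with a standardizer; labels are encoded internally to 0..K−1.
All training is seeded (default run seed 1337).

Splits: sizes are `round(fraction·n)` for validation and test with the
remainder to train (exact 32,000/4,000/4,000 at n = 40,000 and
48,000/6,000/6,000 at n = 60,000), stratified by class to within one
sample, deterministic per seed; a class smaller than the partition count
is a validation error.

Metrics are binary with wheat as the positive class. Undefined ratios
(zero denominators) are reported as NaN with a warning rather than
raising. Reported percentages round half-up to the printed precision
(integer for summary tables, one decimal for improvement percentages).

The classification map predicts every finite-feature pixel, then scores
each connected labeled field by majority vote: green circle = majority
matches the field's class, red X = field predicted background (missed),
purple square = wrong crop class, with additional purple markers for
background blobs (≥ 9 px) predicted as crop. Field-level confusion counts
(wheat positive) are returned alongside so markers and counts reconcile.
Whether accuracy is pixel-level or field-level was an open choice:
pixel-level is the primary metric, field-level is available through the
map. The window-size sweep re-runs texture extraction, training and
evaluation per window size on the same scene and split seed.

## Problem sizes and tolerances

Test and acceptance runs use the 96×96 default scenes (2,000 vectors per
interval) and a 256×256 scene (ratio 2) for the fusion-invariant checks —
sizes at which the full suite and the acceptance script each complete in
a few minutes on one CPU. Key tolerances: GS inversion 1e−8 relative;
band-mean preservation 1e−6; windowed-vs-naive GLCM agreement 1e−10;
chance-level bands 3σ binomial on the test-set size; noise-free fused
NDVI within 0.02 of the configured target.

## Known limitations

* No reprojection, cloud masking or mosaicking; inputs must be
  co-registered grids.
* The GS variant is the classical mean-based one; regression-weighted
  simulated pans and other sharpening families (PCA, Brovey, wavelet) are
  out of scope.
* CatBoost and the Conv1D backends depend on what is installed: CatBoost
  requires its library; Conv1D is a minimal NumPy network, adequate for
  6-dimensional vectors but not a general deep-learning stack.
* FWM's exact printed formulation is under-determined; the implemented
  form is one defensible resolution (documented above).
* Synthetic results do not transfer to real imagery (see above); the
  published real-data accuracy tables are not reproduction targets.
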