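# Methods

## Problem setting

Off-axis digital holographic microscopy (DHM) records the interference
between an object wave that has passed a semi-transparent specimen (e.g. red
blood cells) and a tilted plane reference wave.  The camera image — the raw
diffraction pattern — shows carrier fringes locally distorted by each cell's
optical path delay.  The classical analysis route reconstructs a quantitative
phase image numerically (Fourier sideband filtering) and segments cells
there.  This package implements the alternative: a fully convolutional
encoder–decoder is trained to segment cells *directly* in the raw hologram,
and a morphological post-processing chain turns its per-pixel foreground
probabilities into a cell count.  Phase reconstruction is retained only as a
verification oracle for the simulator and for producing ground-truth-style
phase views.

## Hologram simulator (`sim_dhm`)

Real labeled DHM recordings are not distributed with this package; the
simulator generates physically motivated stand-ins with exact ground truth.

**Scene model.**  Each cell is a disc-like phase object with a smooth
cosine-taper profile, φ(r) = A·cos²(π·r / 2R) for r ≤ R, mimicking the
dome-shaped phase elevation of an RBC.  Peak phase A is drawn uniformly from
`phase_amplitude_range` (default 1.0–2.5 rad) and the taper radius R from
`cell_radius_range`.  The ground-truth mask is the region where the taper is
at least 5% of A, i.e. r ≤ 0.856·R; this cutoff is the documented definition
of "cell support".  With `overlap_allowed=False` (default), rejection
sampling enforces a > 2-pixel gap between mask supports so the number of
connected components equals the number of cells by construction.

**Magnification modes.**  `"40x"` is the reference geometry.  `"20x"` doubles
the field of view over the same pixel grid, so cell radii halve (areas
quarter).  `"bead"` keeps 40x sizing but draws a per-object axial defocus
uniformly from ±`defocus_range` (default ±2 mm in camera-plane units), which
produces the mix of focused and defocused objects seen in bead recordings;
the ground-truth mask remains the in-focus support.

**Forward model.**  The in-focus object wave is O = exp(i·φ).  For scenes
with per-object defocus the scattered fields are superposed to first order:
O = 1 + Σₖ P_{zₖ}[exp(i·φₖ) − 1], where P_z is angular-spectrum propagation
(evanescent components dropped); for an all-in-focus scene this reduces
exactly to exp(i·φ).  The reference is a unit-amplitude tilted plane wave R
with carrier frequency sin(θ)·pitch/λ cycles/pixel per axis, validated
against Nyquist (< 0.5).  Defaults: λ = 682 nm, pixel pitch 5.7 µm, carrier
split equally over both axes with a total fringe period of ~4 pixels.  The
hologram is |O + R|² plus additive Gaussian intensity noise (σ =
`noise_sigma` in units where the noiseless fringes span [0, 4]), clipped at
zero.  Shot noise, detector MTF and aberrations beyond the constant-tilt
carrier are deliberately not modeled.

**Reconstruction oracle.**  `reconstruct_phase` multiplies the hologram by
the reference wave (shifting the +1-order sideband to DC), applies a
circular low-pass of radius 45% of the carrier offset (configurable), and
takes the argument of the inverse transform.  The result carries an
arbitrary constant offset, so comparisons are offset-corrected.  On a smooth
2-rad object at zero noise the round-trip RMS error is ≈ 0.04 rad, and it
grows monotonically with the noise level.  A warning is raised when the
carrier is too low relative to the bandpass for the sideband to separate
from the DC term.

**What the simulator does not emulate.**  Real RBC holograms contain
speckle, illumination non-uniformity, cell shape variation (echinocytes,
overlapping/stacked cells), debris, and camera artifacts.  Tests passing on
synthetic data therefore demonstrate that the pipeline is implemented
correctly and can learn the hologram-to-mask mapping; they do not establish
clinical-grade performance on real blood smears.

**Files.**  Holograms are written as 16-bit grayscale TIFF (intensity 6.0
mapped to full scale — the detector bit depth of the original recordings is
not documented, so this is a package choice), masks as 8-bit {0, 255} PNG,
and a CSV manifest records path, mode, per-image seed and true count.  All
generation is deterministic given the config seed.

## Data pipeline (`data_pipeline`)

Images are standardized by subtracting the mean and dividing by the
population (1/N) standard deviation pooled over *training* pixels only;
validation and test images reuse the training stats.  Training-time
augmentation applies one random geometric chain identically to image and
mask: per-axis flips (p = 0.5), any multiple-of-90° rotation, an extra
small-angle rotation within ±15°, translation up to 10% of the side, and
crop-then-resize with scale in [0.8, 1.0].  The source recipe names the
transform families but not their magnitudes; these conservative ranges keep
cells intact.  Masks are warped with nearest-neighbour interpolation and
re-binarized at 0.5; exposed borders are filled with zeros, consistent with
the zero-padding convention.  Inputs larger than the network size are
resized down (bilinear/nearest); smaller inputs are zero-padded
symmetrically.  k-fold splitting is a seeded shuffle followed by round-robin
assignment, giving disjoint folds whose sizes differ by at most one.

## Network (`fcn_model`)

A UNet-style encoder–decoder: per level a (3×3 conv + ReLU)×2 block, 2×2
max-pooling between encoder levels, 2×2 stride-2 transposed convolutions
with skip concatenation in the decoder, and a 1×1 convolution plus sigmoid
head.  Channel width doubles per level; the full-scale configuration is
depth 5 with base width 64 (64/128/256/512/1024).  All convolutions are
same-padded, so the output probability map has the input's size and one
trained model accepts any input whose sides are divisible by 2^(depth−1).

The implementation is pure numpy with hand-written backpropagation: the 3×3
convolutions run as nine shifted-slice GEMMs in channels-last layout, the
adjoint as a scatter of the nine back-projected gradients.  The backward
pass is verified against central finite differences to < 1e-4 relative
error.  Arithmetic is float32 (float64 available for gradient checking).

Weights use He initialization.  The head bias starts at the logit of
`foreground_prior` (default 0.05, a typical cell-pixel fraction) so the
initial output matches the class prior rather than 0.5; with imbalanced
Dice + cross-entropy training this removes an early plateau in which the
network predicts all-background for several epochs.  An optional
`vgg_pretrained_encoder` scheme loads a locally cached encoder
initialization when present and silently falls back to He, keeping the
package download-free.

## Training (`training`)

The loss for one image is the sum of a soft-Dice term and pixel-mean binary
cross entropy:

L = (1 − (2·Σ y·p + ε_d) / (Σ y + Σ p + ε_d)) − (1/N)·Σ [y·log p + (1−y)·log(1−p)]

with Dice smoothing ε_d = 1e-6 (stability for empty foreground) and
probabilities clamped to [1e-7, 1−1e-7] inside the logarithms.  Batch loss
is the mean of per-image losses.  Optimization is SGD with momentum 0.9 over
(gradient + weight-decay·param) — the convention of mainstream deep-learning
frameworks — with batch size 4, initial learning rate 0.01 decayed tenfold
every 30 epochs, weight decay 1e-4, and 60 epochs at full scale.  Validation
Dice (threshold 0.5) is computed each epoch and the returned model is the
best-validation-Dice checkpoint, the argmax generalization of picking a
single best epoch.  Runs are deterministic for a fixed seed on a single
thread (multi-threaded BLAS reductions may reorder sums).

`grid_search` trains one model per (learning rate, weight decay) pair and
tabulates best-epoch validation Dice; the tuned pair from the first
cross-validation round is meant to be reused by the remaining rounds.
`cross_validate` trains k models on a seeded round-robin split and reports
per-fold and mean/std metrics for the full predict-and-count pipeline.

**Desk-scale profile.**  `desk_profile()` defines the scaled-down study used
by the acceptance checks: 128×128 scenes with 5–15 cells of 5–8 px taper
radius, 200 training + 30 held-out images, a depth-4 / base-16 model, and 10
epochs of the standard recipe.  Depth 4 (widths 16/32/64/128) is used
because at 128×128 a fifth resolution level adds parameters and time without
a receptive-field benefit.  The desk profile trains *without* augmentation:
train and test images come from the same simulator distribution, so the
overfitting that augmentation guards against at full scale cannot occur in
10 epochs, and the broadened input distribution only slows convergence
within the short budget.  Under these conditions the held-out mean Dice is
≈ 0.98 and counting accuracy ≈ 0.98 after roughly five minutes on one CPU.

## Counting chain (`counting`)

Exactly five pure stages, in order: (1) binarize at threshold 0.5, strictly
greater-than; (2) morphological opening with the Euclidean disk
{dx² + dy² ≤ r²}, r = 3 px, which removes speckle-sized false positives and
smooths edges; (3) connected-component labeling (8-connectivity by default,
so touching cells merge rather than split; labels assigned in raster-scan
first-encounter order); (4) removal of components that touch the frame
boundary (≥ 1 pixel in the first/last row/column) *and* have area < 40 px —
unreliable partial cells; the same rule must be applied to the ground truth
before counting — followed by contiguous relabeling; (5) the count is the
maximum label.  Opening is anti-extensive and idempotent, and the exclusion
stage never increases the component count; both properties are tested.

## Evaluation (`metrics`)

Pixel metrics come from the pixelwise confusion counts of the *thresholded*
prediction against the raw truth mask: sensitivity TP/(TP+FN), accuracy
(TP+TN)/N, Dice 2TP/(2TP+FP+FN).  Degenerate conventions: sensitivity with
empty truth and Dice with both masks empty are defined as 1.0.

Boundary metrics use the union of object boundaries per image, a boundary
pixel being a foreground pixel with at least one background 4-neighbour
(frame pixels count as boundary).  The Hausdorff distance is
max(hd(X,Y), hd(Y,X)) with hd the directed max–min Euclidean distance in
pixels; the 95th-percentile variant takes the max of the two directed 95th
percentiles and is more robust to single-pixel outliers.  If exactly one
boundary set is empty the image diagonal is returned as a sentinel with a
warning; if both are empty the distance is 0.

Cell-level counting uses a centroid matching rule between the post-processed
label maps: each predicted component's centroid (mean pixel coordinate,
rounded half-up; tested as-is even if outside a concave component) is looked
up in the truth label map.  A hit on an unclaimed truth cell counts as
*correct* and claims it; a hit on a claimed cell or on background counts as
*over-counted*; unclaimed truth cells are *missed*, so
correct + missed = ground-truth total.  Predicted components are visited in
descending area (ties: lower label), so when several predictions fall in one
truth cell the largest is the one counted correct — the rule fixes the
counts but not which duplicate wins, and this tie-break is the package's
choice.  Throughput (cells counted per second) is reported for information
only; it is hardware-dependent and never used as a pass/fail quantity.

## Known limitations

- The simulator's first-order defocus superposition ignores multiple
  scattering between objects; fine for the sparse scenes generated here.
- Merged touching cells are counted as one (no watershed splitting).
- Training is single-process CPU numpy: practical at desk scale, not a
  substitute for GPU training at full scale (depth 5, base 64, 384×384).
- Bit-exact reproducibility holds for single-threaded runs with a fixed
  seed; thread-count-dependent BLAS summation order can perturb results in
  the last float32 digit.
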