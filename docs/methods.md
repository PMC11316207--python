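# Methods

This package segments, localizes and quantifies enlarged perivascular
spaces (EPVS) in 3D T2-weighted brain MRI of ex vivo hemispheres.  EPVS
appear as thin, hyperintense, curvilinear structures of roughly 0.5-50 mm³
on a 0.6 × 0.6 × 1.5 mm acquisition grid.  The pipeline has four stages:
intensity normalization, a multi-scale curvilinear-structure feature bank
reduced by PCA, an ensemble of two-stage triple U-Nets, and downstream
instance counting, regional densities and ordinal binning.  A seeded
phantom generator supplies ground-truthed synthetic hemispheres so every
stage is testable without patient data.

## Preprocessing

Images are normalized by a robust Z-score over the hemisphere mask:

    z = (x - median) / (P97.5 - P2.5)

with the median and the 2.5-97.5 percentile spread computed over masked
voxels.  The transform is invariant to affine intensity changes, which is
what makes intensities comparable across scanners.  The centre statistic
(median) is this package's choice; any robust centre would serve.
A white top-hat transform (image minus its greyscale opening by a ball of
physical radius 1.2 mm ≈ two in-plane voxels, rasterized on the
anisotropic grid) isolates bright structures at the EPVS calibre and
feeds a second branch of the feature bank.  Denoising is a pluggable hook
(`none` by default, or an anisotropy-aware Gaussian); bias-field
correction is assumed done upstream, and the robust Z-score plus batch
normalization tolerate the mild (±10%) multiplicative fields the phantom
generator produces.

## Feature bank

Three filter families are run at multiple physical scales on the
normalized image and again on its top-hat transform:

- **Steerable filters (SF)** — per scale: the Gaussian-smoothed image,
  plus first- and second-order directional Gaussian-derivative responses
  (g·v and vᵀHv) for 9 unit orientations: the 3 grid axes and the 6 face
  diagonals reduced to one hemisphere.  19 maps per scale; default scales
  0.5, 1.0, 2.0 mm.
- **Frangi filters (FF)** — per scale, from the σ²-normalized Hessian
  (γ = 2): the three eigenvalues sorted by magnitude, the bright-tube
  vesselness (α = β = 0.5, structureness cut-off at half the volume
  maximum; zero wherever λ2 > 0 or λ3 > 0, since EPVS are bright), and
  the Frobenius norm.  5 maps per scale; 12 scales log-spaced 0.4-3.0 mm.
- **Optimally oriented flux (OOF)** — per radius, the sphere-averaged
  oriented-flux matrix computed spectrally (see `features/oof.py` for the
  closed form), then: three eigenvalues sorted ascending, the bright-tube
  measure √(max(-λ1,0)·max(-λ2,0)), and the Frobenius norm.  5 maps per
  radius; 12 radii log-spaced 0.6-3.0 mm (the lower end is one voxel —
  the filter is undefined below the grid).

With both branches this yields 2 × (19·3 + 5·12 + 5·12) = 354 maps.  The
choice of the five FF/OOF maps (eigenvalues + tubularness + norm) is this
package's reading of "five features per scale"; only the count is fixed
externally.

All derivatives are computed in physical units with separable, discrete,
moment-corrected Gaussian-derivative kernels: each 1D kernel is
renormalized so constants map to zero under differentiation, a unit ramp
to one under d/dx, and x²/2 to one under d²/dx².  At 1.5 mm slices a
sub-millimetre scale is below one voxel, where naively sampled derivative
kernels carry bias comparable to the signal; the moment correction
removes it and converges to the discrete Laplacian stencil at small σ.

Per subject, PCA is fit over hemisphere-masked voxels of the 354-map
stack (deterministic covariance eigen-solver, sign fixed so each
loading's largest entry is positive) and the first 12 components become
the "EPVS-enhanced" feature channels.  Per-subject fitting matches the
per-participant feature description; the network must therefore tolerate
component rotations across subjects, which the ensemble and the remaining
channels (raw image, masks) buffer in practice.

## Network

The segmentation model is three structurally identical U-Nets in two
stages.  Stage 1 holds U-Nets A and B in parallel on the same 19-channel
input (normalized image, 12 PCA maps, white-matter mask, five regional
masks); stage 2 holds U-Net C, whose input is the concatenation of A's
and B's full-resolution decoder features and which additionally
concatenates A/B feature maps at every encoder and decoder level.

Each U-Net has four resolution levels (three 2×2×2 max-pool
downsamplings).  Convolutional blocks are 3×3×3, stride 1, zero padding,
ReLU then batch normalization, 64 channels (two blocks per level — the
block count per level is a design choice; the parameter count lands at
the right order, ~10⁷ at width 64).  The first two level transitions are
dual-path: convolution-then-pool in parallel with pool-then-convolution,
fused by concatenation; a 4×4×4 stride-4 pool of the network input feeds
directly into the quarter-resolution encoder level.  Decoding is
nearest-neighbour 2×2×2 upsampling with same-level encoder skips.  Each
U-Net ends in a 1×1×1 convolution + sigmoid head; the head bias starts at
-2 (a sparse-foreground prior, which keeps the overlap-loss denominator
informative early in training).  Inference uses the stage-2 head only.

The whole stack — reverse-mode autodiff, im2col GEMM convolutions, batch
normalization, DropConnect, pooling — is implemented in numpy
(`epvs/nn/`), with analytic gradients verified against finite differences
in the test suite.

## Loss and training

Each head h with weight β_h minimizes

    F(β) = 1 - ((1+β) Σ y·ŷ + ε) / (β Σ y + Σ ŷ + ε),   ε = 10⁻³,

with β = 10 (recall-oriented), 0.1 (precision-oriented) and 1 (balanced)
for A, B, C; the training objective is their unweighted sum.  F(β) lies
in [0, 1) for binary labels and probabilities, and is zero exactly when
(1+β)Σyŷ = βΣy + Σŷ (both-empty included, via ε).

Training samples are patches centred on uniformly drawn white-matter
voxels (reflect-padded at borders), reference scale 64 × 64 × 24 with
1200 epochs × 40 batches × 8 samples.  Optimization is SGD with Nesterov
momentum 0.9, learning rate 10⁻³ at reference scale, L2 = 10⁻³ on
convolution kernels, DropConnect p = 0.3 (per-weight Bernoulli masking
with 1/(1-p) rescaling, disabled at inference, making prediction
deterministic).  After each epoch the held-out subject is scored — F(β)
loss on a fixed 50%-overlap patch grid (deterministically thinned to at
most 12 patches) and whole-volume Dice at probability 0.5 — and early
stopping returns the weights of the Dice-maximizing epoch (ties keep the
earliest); batch-norm running statistics are frozen with those weights.

One member is trained per held-out subject (leave-one-out
cross-validation); the ensemble averages member probability maps and
thresholds at 0.2 by default.  The threshold calibration procedure
re-trains ensembles on cohorts with one randomly erased lobe per subject
(labels zeroed and voxels excluded from patch sampling), maximizes Dice
over the erased voxels on a 0.05-step grid (ties to the lowest value) and
averages the optima over five repeats.

## Evaluation protocol

Evaluation ROIs (25 × 25 × 9 voxels) are placed around connected clusters
(≥ 2 voxels) of white-matter voxels above the 90th percentile of
normalized intensity — an automatable stand-in for "hyperintense
structures with intensities similar to EPVS" — balanced across the four
lobes and basal ganglia, at most one ROI per subject unless relaxed.  A
ground-truth instance is detected if the prediction overlaps it in at
least one voxel.  Sensitivity is reported overall and for instances
strictly larger than 3 and 12 mm³ (empty bins are undefined, not zero).
Segmentation accuracy is Dice (2TP/(2TP+FP+FN); defined as 1 when both
masks are empty) over ROI voxels, and consistency is the Pearson
correlation between manual and automatic voxel counts per ROI.

## Quantification

Instances are 26-connected components (thin oblique tubes fragment under
6-connectivity on this anisotropic grid).  Each instance takes the region
of the majority of its voxels (ties to the smallest region code).
Densities are counts per cm³ of region volume.  The cerebrum total counts
all instances in the hemisphere, which may exceed the five-region sum if
tissue is unlabeled; both are emitted.  Ordinal binning compresses
right-skewed counts: lobar counts are identity up to the cohort median
(nearest-rank percentiles), the 50th-75th percentile range splits into
three equal left-open/right-closed intervals, and counts above the 75th
percentile form one top level; cerebrum totals additionally bin [0, p50]
into four equal-width levels, eight levels in total.  Degenerate spreads
(p50 = p75) collapse the interval levels with a warning.

## Phantom generator

A phantom is a half-ellipsoid "hemisphere" split into four in-plane
quadrant pseudo-lobes plus a deep basal-ganglia ellipsoid; white matter
is the interior at ≥ 2.4 mm from the hemisphere boundary (Euclidean
distance in mm).  EPVS are tortuous tubes (radius 0.3-1.2 mm, length
2-15 mm, direction random-walk of 10°/mm) rasterized by physical
distance-to-polyline, clipped to their anchor region so requested
regional counts are exact, placed without contact so instance counts are
exact; size-guaranteed sub-3 mm³ and super-12 mm³ instances can be
requested.  Tissue intensity is uniform (mean 1.0) with tubes at 3× tissue
(EPVS are hyperintense), a few rounder distractor blobs at intermediate
intensity, a smooth ±10% multiplicative bias field, and Rician magnitude
noise (σ = 0.1 of tissue mean) by default.  Cohorts draw per-subject total
counts from a log-normal (right-skewed, as real cohort counts are) with a
fixed frontal-dominant regional mix whose density is highest in the basal
ganglia.

What phantoms do not emulate: cortical/white-matter contrast, partial
volume beyond rasterization, fixation artifacts, realistic vasculature or
anatomy.  Tests passing on phantoms demonstrate that the pipeline's
machinery — features, optimization, ensembling, counting — behaves as
specified, not that the trained weights transfer to real tissue.

## Desk-scale study conditions

CPU-scale runs (tests, `scripts/acceptance.py`) use: 4 training phantoms
of 48 × 48 × 24 voxels (~22 EPVS each, contrast 3, noise σ 0.1, SNR 10),
a reduced bank (2 SF scales, 3 FF, 3 OOF → 136 maps, still 12 PCA
channels), network width 8, patches 16 × 16 × 8, 6 epochs × 10 batches ×
4 samples at learning rate 0.25, full LOOCV, threshold 0.2.  These sizes
are the package's desk-scale defaults chosen to exercise the complete
method end to end at laptop cost; the reference-scale defaults remain the
full configuration above.  At desk scale a fresh-phantom evaluation
typically reaches held-out Dice ≈ 0.6-0.8 with > 70% detection of
instances over 12 mm³; the numbers the acceptance script prints are
computed at run time, and occasional weak ensemble members (small
validation Dice) are expected at this step count.

## Numerical notes and limitations

- Activations and parameters are float32; loss sums in float64.
- Convolution uses offset-major im2col columns + GEMM; backward re-uses
  the stored columns and computes input gradients by correlation with the
  flipped, channel-transposed kernel.
- Patch spatial dimensions must be divisible by 8 (three downsamplings);
  whole volumes that satisfy this are predicted in one window, otherwise
  by 50%-overlap sliding windows with probability averaging; volumes
  smaller than a patch are reflect-padded and cropped.
- Per-subject PCA means feature channels are not strictly comparable
  across subjects; at small cohort sizes this is the main generalization
  stressor and is deliberately retained.
- The both-empty Dice = 1 convention only arises in degenerate tests.
- The lobe-erasure calibration is computationally heavy (it trains
  n_repeats full ensembles); tests exercise it through an injectable
  prediction hook, and the CLI exposes the full procedure.
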