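# Methods

This note records the modelling choices, parameter defaults, numerical
conventions and known limitations of the package.

## Conventions

All volumes are signed 16-bit Hounsfield grids indexed `(z, y, x)` with
0-based indices; an axial slice is a fixed `z`, coronal a fixed `y`,
sagittal a fixed `x`. Spacing is mm per axis in the same order.
Computation is float32/float64; storage stays int16. The default
display window is the standard lung window (width 1500 HU, level
−600 HU); the same window, rescaled to [0, 1], is the networks' input
normalisation. Reslicing into coronal/sagittal stacks presupposes
comparable in-plane scales, so pipelines resample to isotropic voxels
(1 mm default, linear for intensities, nearest for masks) before
reslicing.

## Parenchyma network

Encoder–decoder with attention-gated skips, a dense-atrous (DAC)
bottleneck and multiscale sampling blocks.

* **Attention gate.** `α = σ₂(φᵀσ₁(W_xᵀx + W_gᵀg + b_g))`, output
  `α ⊙ x`; σ₁ = ReLU, σ₂ = logistic sigmoid; the projections are 1×1
  convolutions to `channels/2`, φ a 1×1 convolution to one channel. The
  gate is the standard additive form; a residual sigmoid path is not
  included (there is no consistent way to type such a term against the
  two-input description, and the standard form matches it exactly).
* **DAC block.** Four cascade branches fixed as
  `[(3,1)]`, `[(3,3),(1,1)]`, `[(3,1),(3,3),(1,1)]`,
  `[(3,1),(3,3),(3,5),(1,1)]` ((kernel, dilation) pairs, ReLU between
  convolutions), giving effective receptive fields 3/7/9/19 by
  `RF = 1 + Σ d(k−1)`; branch outputs and the input are summed, then
  ReLU. This is the simplest composition with 3×3 kernels and dilations
  from {1,3,5} that produces those four receptive fields. The block
  sits at the bottleneck only.
* **Sampling blocks.** Downsampling sums parallel stride-2 convolutions
  with kernels 2 and 4; upsampling sums parallel stride-2 transposed
  convolutions with kernels 2 and 4. Both change the spatial size by
  exactly 2×.
* **Depth/width.** Default 4 resolution levels, base 16 channels;
  the desk-scale experiments use 3 levels / 8 channels. (The five-level
  depth requirement applies to the nodule network; the parenchyma
  network depth is unconstrained and 4 is conventional.)

## Nodule network

Five resolution levels (configurable ≥ 3 for tests), Mish activations,
and a bidirectional feature pyramid: encoder features are projected to
a common pyramid width (1×1 convolutions, default 16 channels), a
top-down pass fuses each level with the upsampled coarser level, and a
bottom-up pass fuses the original projection, the top-down feature and
the pooled finer level. Fusion nodes use fast normalized weights
`wᵢ = relu(uᵢ)/(Σⱼ relu(uⱼ) + ε)`, so weights are nonnegative and sum
to one; the pyramid has no printed equations anywhere to follow, and
this two-way cross-scale design with learned nonnegative fusion is the
established reading of "bidirectional enhanced feature pyramid with
bottom-up path enhancement". Pyramid resizing uses nearest-neighbour
upsampling and 2×2 average pooling (non-learned, as is usual for
feature pyramids); the learned multiscale sampling blocks handle the
encoder's scale changes.

**Same-size contract.** Both networks edge-pad any input whose spatial
size is not a multiple of `2^(levels−1)` and crop the output back
(`pad_policy="auto"`), so output size always equals input size —
including 200×200, the working slice size for feature extraction.
`pad_policy="strict"` instead raises an error naming the required
padding.

## Training

Dice loss `1 − 2Σpg/(Σp² + Σg² + ε)` with ε = 1 (defined even when
both masks are empty). Optimiser Adam (lr 1e-3, β = 0.9/0.999), batch
8, shuffling driven by one seeded generator per run. The output-layer
bias is initialised to −2 (foreground prior ≈ 0.12): with small targets
the Dice loss otherwise has a stable all-background collapse mode, and
the low-prior start removes it (observed directly on sagittal nodule
training). Probability maps are thresholded at 0.5 before fusion — the
threshold is a config value; 0.5 is the neutral default.

Mask fusion across positions defaults to **majority vote** (≥2 of 3):
an OR rule is specified only for the sign decision, and majority is the
operational form of "one position alone cannot be trusted". Union and
intersection are selectable.

## Candidate screening

26-connected components; per component, the circularity `4πA/P²` of the
maximum-area slice in each position, with the perimeter measured as the
arc length of the subpixel marching-squares contour (a raw pixel-edge
count biases discs above 1). Accept iff equivalent spherical diameter
∈ [4, 12] mm and circularity ≥ 0.55 in ≥ 2 positions. The lower
diameter bound sits below the 6 mm target size to tolerate
partial-volume shrinkage; 0.55 separates rasterised discs (≈ 0.74 even
at 3 px radius) from tubes seen side-on (< 0.4) with margin on both
sides. Raising the threshold can only remove candidates.

## Sign recognition

22 features per nodule: 6 first-order intensity statistics (mean,
variance, skewness, kurtosis, energy = mean squared HU, 32-bin
histogram entropy; skewness/kurtosis/entropy defined as 0 for constant
regions so vectors never contain missing values), 4 2D shape features
per position (circularity, elongation = major/minor axis ratio,
perimeter-to-area, radial-length variance normalised by squared mean
radius), and 4 3D shape features (sphericity, surface-to-volume,
equivalent diameter in mm, compactness `36πV²/A³`) from a
marching-cubes surface in mm.

Selection and fitting: univariate screen (two-sample t-test; χ² for
categorical inputs; constants dropped with a warning) at α = 0.05; L1
logistic path over 50 log-spaced penalties, chosen by stratified CV
deviance; a plain logistic refit on the surviving features (radiomics
branch) and on the screened shape features (morphology branch);
combined score = unweighted mean of the two probabilities, threshold
0.5. "Ten times cross-validation" is implemented as stratified 10-fold;
reported SEN/SPE/FPF pool the fold confusion tables. The permutation-
null control refits after shuffling labels; because a correct null run
can legitimately leave no feature below α = 0.05 (which is an error by
design, instructing the user to relax α), the null control screens at
α = 0.5. Clinical covariates are outside the synthetic scope, so the
morphology branch uses shape features only.

Per-position judgement uses the same model API on position-specific
feature rows (first-order + 3D + that position's 2D features under
neutral names); the final call is the OR over the three positions.

## Phantoms

The generator emulates exactly the structures the pipeline reasons
about: an elliptic-cylinder soft-tissue body (+40 HU) in air
(−1000 HU), two axis-aligned ellipsoidal lung fields (−850 HU),
spherical nodules (+20 HU, 6–8 mm default) optionally spiculated with
cone-shaped radial spikes (base ≈ 1.5 voxels, seeded random
directions), axis-aligned cylindrical vessels (+30 HU), and additive
Gaussian noise (σ = 15 HU default). Wall-adherent nodules are spheres
centred on the lung boundary, clipped to the body. Default volume
96×128×128 at 1 mm isotropic; the desk-scale studies use 64³ (and 40³
mini-volumes for the sign library) so that training fits interactive
budgets. Everything is deterministic in the spec's seed at the level of
voxel sets.

What the phantoms do **not** emulate: airway trees, lobe fissures, HU
texture, grid-like increased-density patterns, breathing/motion
artefacts, or scanner reconstruction effects. Passing the phantom
studies therefore demonstrates that the implementation is correct and
the pipeline's geometry logic (multiposition disambiguation,
circularity screening, spiculation separability) works as designed —
not that clinical-data performance figures transfer.

## Desk-scale study sizes

Parenchyma recovery: 40 training slices (8 axial slices from each of 5
single-nodule 64³ phantoms), 30 epochs, 10 held-out slices from an
unseen phantom. Nodule pipeline: 8 training phantoms per position
(nodule-bearing slices plus 3 background slices each), 15 epochs,
5-level networks, evaluated end-to-end on 10 unseen single-nodule
phantoms. Sign recognition: 60 nodules (30 smooth / 30 spiculated),
stratified 10-fold CV, with a label-permutation null. These sizes are
the package's chosen desk-scale conditions; all are driven by one seed
each and are reproduced verbatim in `tests/test_acceptance.py`.

## Known limitations

* The NumPy engine is single-threaded BLAS-bound; it is sized for
  ≤ 200² slices and the channel counts used here, not for clinical-
  scale training.
* DICOM support is read-only and assumes a single-orientation axial
  series with rescale tags.
* Vd/Ud can exceed 100 % for gross mismatches (the XOR numerator is
  not bounded by its denominator); they are reported as computed, not
  clamped.
* FPF, as defined, is the overall misclassified fraction
  `(FP+FN)/total` (= 100 − accuracy), not a false-positive fraction;
  the name is kept for continuity with the metric family it belongs to.
* Per-position sign models share one feature schema; clinical
  covariates and texture families beyond first-order statistics are out
  of scope.
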