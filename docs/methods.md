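# Methods

## Problem and model

Deformable image registration (DIR) of paired chest CT at two breath-holds —
functional residual capacity (FRC, expiration) and total lung capacity (TLC,
inspiration) — yields a displacement field whose Jacobian determinant `J`
measures voxelwise volume change (`J > 1` expansion, `J < 1` contraction).
`lungjac` regresses that map directly from the images with a 3D convolutional
network, bypassing iterative registration, and supports a 2x2 factorial
design: input factor (a single image vs. the FRC+TLC pair) x output space
(FRC frame, expansion, vs. TLC frame, contraction).  Single-input arms
consume only the image matching their output space.

The training target is the signed log2 encoding `Y = log2 J`, so reciprocal
volume ratios have equal magnitude and opposite sign; predictions are decoded
as `J = 2^Y`, which guarantees positivity.  Evaluation metrics that compare
expansion and contraction on one scale use `|log2 J|`.

## Network

A multiscale residual encoder with `L` levels (default 4 at full scale,
3 in the bundled demo).  Level `l` operates at 1/2^l resolution with
`C_l = C_0 * 2^l` channels (`C_0 = 8`): a residual identity block (two 3^3
convolutions with instance normalization, residual addition before the final
activation), then a residual down block to the next level (stride-2 3^3
convolution doubling the channels on the main path, stride-2 1^3 projection
on the shortcut).  Each identity-block output is returned to full resolution
by a transposed convolution with kernel = stride = 2^l and `C_0` filters; the
`L` maps are concatenated into a `C_0 * L`-channel representation, and two
integration convolutions (3^3 with norm+ReLU, then a linear 1^3) produce the
single-channel output.  The final level has no down block, since up-branches
read from identity-block outputs; inputs must therefore be divisible by
2^(L-1), which the preprocessing pad guarantees.  Weights are He-normal
initialized.  Biases that directly feed an instance normalization are inert
(the normalization subtracts the channel mean); they are retained for
uniformity.

The layers are implemented in a compact NumPy engine (`lungjac.nn`) with
hand-derived backward passes: convolution as a sum of k^3 channel-matrix
products over shifted views, non-overlapping transposed convolution, instance
normalization, ReLU, and Adam with the AMSGrad variant.  Every backward pass
is pinned by numerical gradient-check tests; the whole-network check uses
directional derivatives in float64.

## Loss

`L_total = alpha * L_MAE + (1 - alpha) * L_SSIM` with `alpha = 0.5`.  Both
terms average over in-mask voxels only.  Per-voxel SSIM uses 7^3 patches with
Gaussian weights (sigma 1.5 voxels), dynamic range Delta = 5, `K1 = 0.01`,
`K2 = 0.03`, so `C1 = (K1*Delta)^2`, `C2 = (K2*Delta)^2`.  SSIM statistics
are filtered over the full padded volume with zero padding and then averaged
over the mask — patches near the lung boundary see background values — which
makes the filter-based map equal a brute-force zero-padded patch extraction
to machine precision and makes the Gaussian operator self-adjoint, which the
analytic SSIM gradient uses.  Optimization: Adam/AMSGrad, learning rate 1e-4
at full scale, batch size 4 via gradient accumulation, one global seed
controlling simulation, splits, initialization and batch order.  A 10%
validation split of the training set selects the checkpoint.

## Synthetic paired-inflation phantom

The simulator generates (I_FRC, I_TLC, masks, lobes, J_FRC, J_TLC) with exact
ground truth:

* **Geometry.** Two ellipsoidal lungs inside a soft-tissue body, sized as
  fractions of the grid half-extent (semi-axes 0.24/0.36/0.50 of it) so
  phantoms fit any grid; per-case anatomical jitter (about +/-12% overall
  scale, +/-5% per axis, small craniocaudal shift) emulates subject
  variability.  Default grid 32^3 at 3 mm isotropic (24^3 in the demo) —
  matching the preprocessed working resolution at a desk-friendly extent.
* **Deformation.** `h` = anisotropic affine effort inflation about the
  thorax center ∘ separable sinusoid (per-axis `|amp*freq|` budget 0.15,
  wavelengths 40–80 mm) ∘ radial compression pockets (strength 0.15, sigma
  7 mm) whose count scales with `disease_fraction`.  The effort scaling
  gives the craniocaudal axis a random 40–60% share of the volume change
  (diaphragm-dominated breathing) with the remainder split randomly between
  the transverse axes; the per-axis scales multiply exactly to the
  commanded ratio.  Besides realism, the random anisotropy matters
  methodologically: with an isotropic scaling and fixed anatomy, the
  expiratory lung's margin inside the union crop box would be a clean
  geometric readout of the volume ratio, handing the single-input arm the
  effort information it is not supposed to have.  All parts have
  closed-form Jacobians; compositions use the chain rule, inverses are
  closed-form (affine) or per-axis/per-radius fixed-point iterations
  (tolerance 1e-3 mm, max 50 iterations).  Pockets expand less than
  surrounding parenchyma, emulating gas trapping (fSAD).
* **Effort semantics.** `PhantomParams.effort` is the commanded affine
  volume ratio (sampled in [1.2, 2.2]); the achieved ratio `effort_true` is
  measured from the generated masks and is slightly lower when pockets are
  present, so at fixed commanded effort more disease means lower mean J —
  mirroring lower inflation in more severe disease.  Cohorts stratify
  disease severity and effort over independent bins: effort is a
  breath-hold depth, not a disease property, and that independence is what
  makes effort unidentifiable from a single image.
* **Intensity.** FRC HU from a tissue-fraction (sponge) model,
  `HU = -1000*airfrac + 40*(1-airfrac)`, with
  `airfrac = 0.75 - 0.5*(J_het - 1) + texture` clipped to [0.5, 0.93], where
  `J_het` is the heterogeneous (effort-free) part of the Jacobian and the
  texture is a low-amplitude sum of random 3D cosines (wavelengths
  25–60 mm).  Poorly-expanding tissue thus appears darker at FRC (trapped
  gas), giving the network a learnable structure–function signal while
  leaving I_FRC strictly independent of effort: two cases with identical
  FRC images but different efforts are constructible.
* **TLC frame.** `I_TLC` is sampled on its own grid through the analytic
  inverse using tissue-mass conservation,
  `I_TLC(h(x)) + 1000 = (I_FRC(x) + 1000) / J_FRC(x)`; `J_TLC(y) =
  1 / J_FRC(h^-1(y))`, so reciprocity is exact.  Independent Gaussian HU
  noise is added per frame after the coupling (defaults 30 HU at FRC vs.
  15 HU at TLC, emulating 50 vs. 200 mAs tube currents), so the
  conservation identity holds exactly only in the noiseless limit; tests
  use noiseless cases for the identity and noisy cases for training.

What the phantom does *not* emulate: airway/vessel trees, sliding motion at
fissures and the chest wall, scanner/reconstruction differences, and real
COPD texture phenotypes.  Passing tests on phantoms therefore demonstrate
that the pipeline recovers the generative structure it assumes (mass-
conserved intensities, effort + heterogeneity + trapping), not clinical
performance on real CT.

## Preprocessing

Gaussian anti-alias smoothing (sigma = 0.5 x downsampling ratio in input
voxels, skipped when upsampling) then linear resampling to 3 mm isotropic;
masks and label maps nearest-neighbor with no smoothing; cropping to the
union bounding box of the two lung masks; masking (background -1024 HU);
clamping to [-1024, 200] HU; affine rescaling to [-1, 1]; padding to a
multiple of 2^(L-1) with fill -1 (the normalized background).  Padding
places the cropped content on a randomly grown canvas at a random,
case-seeded offset rather than centering it: with tight symmetric padding
the distance from the expiratory lung edge to the array edge equals the
inspiratory-to-expiratory size margin, a pure-geometry readout of the
inflation magnitude that single-input models must not receive; the random
placement removes that shortcut and doubles as translation augmentation
(a minimal symmetric mode remains available).  Both
frames share one grid: phantoms share it by construction; for external data
the pair must be resampled to a common grid first, recorded in the case
provenance.  Ground-truth Y maps follow the same resample/crop/pad path with
linear interpolation and are zeroed outside the lung (the loss is
mask-restricted regardless).

## Evaluation

Local: MAE, voxelwise Spearman (average ranks; undefined on constant input
and then flagged), PSNR with peak Delta = 5 on the |log2 J| scale (capped at
300 dB for identical maps).  Regional: mean in-mask SSIM; Dice of low/high
Jacobian regions, thresholded per map at its own in-mask 25th/75th
percentiles (guaranteeing quarter-sized regions; a reference-derived
threshold was the alternative, and the per-map convention is declared in the
report metadata).  Global: whole-lung mean `J_mu` and coefficient of
variation `J_CV` (population sd).  Regional volume change:
`dV_ROI = (J_mu,ROI - 1) V_ROI`, expressed as percent of the total
(`sum over a partition = 100` exactly); cases with `|J_mu - 1| < 0.02` are
flagged and excluded from dV% summaries.  ROIs: the phantom's lobe
compartments, and parametric response mapping with thresholds -856 HU (FRC)
and -950 HU (TLC) on voxelwise-corresponding pairs (exact in phantoms via
the analytic correspondence; external data must arrive pre-aligned).
Cohort agreement: OLS slope/intercept/r^2 of predicted vs. reference, and
Bland-Altman mean difference with mean +/- 1.96 sd limits per PRM class.

## Scaled-down factorial study (demo)

The bundled demo runs the full design end-to-end on one CPU in about ten
minutes: 28 cases at 32^3 (16 train including validation, 12 held out),
L = 3, C_0 = 8, 120 epochs at learning rate 2e-3 (the short schedule
takes few optimizer steps, so the demo uses a proportionally larger rate
than the full-scale default).  Under these conditions the paired-input FRC
arm recovers local expansion ranks and the effort-dependent global mean,
while the single-input arm matches the local pattern but not the global
magnitude — the same qualitative ordering reported for full-scale training,
where the effect is driven by effort being invisible in a single image.
Absolute r^2 values are noisier than at full scale (12 held-out cases vs.
70 subjects).

## Numerical choices and limitations

* Spatial derivatives of displacement fields in physical mm; central
  differences in the interior (exact for affine fields), first-order
  one-sided on the outermost voxel layer.  Non-positive determinants inside
  the mask set a `folded` quality flag (and a warning) rather than raising;
  the stored map replaces them by 1 so the log2 encoding stays defined.
* Jacobian maps are float32 on disk; float64 is preserved in memory where
  exactness matters.
* The displacement-field contract `J = det(I + du/dx)` is one realization of
  a DIR output; B-spline coefficient parameterizations are out of scope.
* Training is single-device; batch parallelism is emulated by gradient
  accumulation.  Runtimes scale with the number of voxels; the defaults here
  are chosen for small phantom grids.
* The NumPy engine is deterministic given seeds; exact bit-reproducibility
  across BLAS builds is not guaranteed, though all checks here use
  tolerances or within-build comparisons.
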