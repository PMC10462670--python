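# Methods

## The problem and the model

Volumetric fluorescence microscopy resolves structure two- to three-fold
worse along the optical axis than in the focal plane: the point spread
function (PSF) is elongated in z, and stacks are usually also sampled more
coarsely in z than in xy. `isorestore` restores isotropic resolution from a
**single anisotropic stack**, with no registered training pairs and no
explicit PSF model, by exploiting the stack's own anisotropy: the
high-resolution (HR) lateral slices are statistically similar to what the
axial slices *would* look like at isotropic resolution, so they can serve as
learning targets for the axial views.

Training runs in two alternating stages on 2D slices:

1. **Degradation modelling (unsupervised).**  From the stack we build three
   slice sets: `X` (HR lateral slices), `Y` (each `x_i` vertically
   downsampled by the anisotropy factor `dz/dx` and re-interpolated, pixel
   aligned to `x_i`), and `Z` (axial slices, z axis interpolated to the
   lateral pixel size; unpaired with X/Y).  A CycleGAN — generators `G_A:
   Y→Z`, `G_B: Z→Y`, PatchGAN discriminators `D_A`, `D_B` — learns the
   *degradation* `G_A` that makes downsampled lateral images look like real
   axial images.  Learning the degradation rather than the restoration is
   the stabilizing design choice: in unpaired settings blur is easier to
   learn, and it lets stage 2 be fully supervised.
2. **Isotropic recovery (supervised).**  The synthetic blurred image
   `G_A(y_i)` is pixel-aligned with its sharp original `x_i`, so a
   deblurring network `H` (DeblurNet) trains on honest pairs; at inference
   `H` is applied to every axial slice of the (axially re-interpolated)
   stack.  A feedback term couples the stages: stage 1 also minimizes the
   deblurring loss with `H` frozen, pushing `G_A` toward degradations that
   `H` can actually invert.

The objectives, with batch size N and means over batch and pixels:

* least-squares adversarial losses `L_G`, `L_D` (LSGAN), e.g.
  `L_G = mean (D_A[G_A(y)] − 1)² + mean (D_B[G_B(z)] − 1)²`;
* cycle consistency with the Charbonnier penalty
  `L_cycle = C(G_B[G_A(y)], y) + C(G_A[G_B(z)], z)`,
  `C(a,b) = mean √((a−b)² + ε²)`, ε = 1e−3;
* deblurring loss `L_deblur = C(H[G_A(y)], x) + σ·(1 − SSIM(H[G_A(y)], x))`
  with σ = 0.1;
* feedback loss of the same form with `H` frozen, and the full stage-1
  objective `L_degrade = L_cycle + λ·L_GAN + ρ·L_feedback`, λ = ρ = 0.1.

Per iteration the generators are stepped twice, then the discriminators
once (guarding against mode collapse), then `H` once with `G_A`'s output
detached.  Optimization uses Adam (β₁ = 0.5, β₂ = 0.999), lr 1e−4 halved
every 20 epochs, minibatches of eight 64×64 patches, 40 epochs of 600
iterations at full scale.  An "epoch" is a fixed iteration budget over
randomly sampled patches, not a pass over a finite pool.

## Architectures

All restoration networks (`G_A`, `G_B`, `H`, and the optional DeconvNet)
share one fully convolutional residual architecture operating on single-
channel 2D slices: a three-convolution head, six residual blocks
(`y = x + LReLU(Conv₂(LReLU(Conv₁(x))))`), and a three-convolution tail;
7×7 kernels at the first and last layer, 3×3 elsewhere; 64 features except
the final 1-feature layer; LeakyReLU slope 0.2; stride 1 and zero padding
throughout, so any input size is preserved.  The discriminators are
PatchGANs: four 4×4 convolutions with strides 2,2,1,1 and widths
64,128,256,1, instance normalization after the second and third.  Each
output pixel judges a 34×34 input patch (receptive-field recursion
`r ← r + (k−1)·j, j ← j·s`); note that instance normalization adds a weak
global coupling on top of this purely convolutional footprint, which is why
the empirical gradient-footprint check runs with the normalization layers
disabled.  Convolution weights initialize from N(0, 0.02) (the CycleGAN
convention), biases at zero.

Because no GPU tensor framework is assumed, the package carries its own
reverse-mode autodiff on numpy (`isorestore.autodiff`): a tape of float32
array operations with a GEMM-backed (im2col/col2im) 2D convolution and an
Adam implementation.  Freezing a network for a loss term captures
`requires_grad` at graph-construction time, so gradients flow *through*
frozen networks without accumulating in their parameters — the mechanism
behind the feedback term and the stage-2 detachment.

## Self-Net+ (deconvolution extension)

For data with strong out-of-focus background, the restored stack can be
further deconvolved: a 2D PSF is cropped from an isolated point source in a
restored axial slice (peak recentering, border-median background
subtraction, clipping, unit-sum normalization; a 50 px request yields a
49×49 odd-sized kernel), Richardson–Lucy deconvolution (5 iterations,
reflective edges, estimate initialized at the observation so 0 iterations
is the identity) is applied to the DeblurNet output, and a DeconvNet —
architecturally identical to `H` — is trained end-to-end to map raw axial
slices directly to the deconvolved targets, folding restoration and
deconvolution into one inference pass that raises the signal-to-background
ratio (SBR = peak signal / mean surrounding background).

## Data pipeline choices

* Axis order is (z, y, x); "vertical" means the y axis of a lateral slice
  and the z axis of an axial one.
* `Z` pools both xz and yz orientations (the lateral PSF is assumed
  rotationally symmetric; doubles the training data).  Default inference
  restores xz slices; a both-average option exists.
* Downsampling uses exact area averaging (alias-free, handles non-integer
  anisotropy factors continuously); upsampling uses cubic splines on the
  cell-centre grid, clipped to the source range so interpolation cannot
  manufacture out-of-range intensities.
* Intensities are normalized to [0, 1] by percentile anchors, default
  p_low = 0.1 and p_high = 99.9 with clipping; the anchors are stored in a
  `NormRecord` inside every checkpoint so inference replays training
  normalization exactly and outputs return to the input scale.
* Augmentation applies the same random rotation/flip to an (x, y) pair,
  preserving pixel alignment.
* Tiled inference blends tiles with linear feathering over the overlap
  (default 16 px), removing seam artifacts.

## Synthetic data

The simulator generates the scene statistics the method assumes, so the
whole pipeline is testable without any acquisition:

* **Beads** — spheres at uniform random positions, radii 2–4 px and peak
  intensities 150–255 by default, rasterized by the exact sphere
  inequality; overlaps combine by per-voxel maximum (avoids intensity
  spikes above the stated range).  The full-scale phantom is 512³ voxels
  with 800 beads at 0.2 µm pixels; the desk-scale default is 128³ with 60.
* **Tubes** — seeded 3D random walks with bounded curvature, rasterized as
  constant-radius tubes (full-scale: 5000 tubes in 1024³).
* **PSF** — separable anisotropic Gaussian parameterized by physical FWHMs
  (σ = FWHM / (2√(2 ln 2))); the default widths 305 nm lateral / 1000 nm
  axial match a 1.0-NA water-immersion widefield objective.  A Gaussian is
  used rather than a diffraction integral because only the anisotropy
  magnitude matters to the method.
* **Degradation** — FFT convolution with reflective edge handling (no dark
  rims that would bias width measurements), then retention of every
  z_factor-th slice with `dz ← dz · z_factor`.
* **Semisynthetic pairs** — HR lateral slices paired with vertically
  blurred (σ = 2 px), ×4 vertically downsampled-then-reinterpolated copies;
  the supervised-baseline (CARE-style) recipe is fixed at σ = 3 px, ×5.

What the generator does **not** emulate: realistic optics (aberrations,
depth-varying PSF), camera noise, autofluorescence background, or the
texture statistics of real tissue.  Passing tests therefore demonstrate
that the machinery learns and inverts the degradation it models — not
performance on any particular instrument's data.

## Evaluation metrics

RMSE; mean windowed SSIM (11×11 Gaussian window, σ 1.5, K₁ = 0.01,
K₂ = 0.03, dynamic range 1 on normalized data — the same differentiable
kernel used in the loss); SBR; sub-pixel FWHM of 1D profiles (baseline-
subtracted, linear interpolation of the half-maximum crossings).  The
**isotropy ratio** follows the traced-fibre procedure: skeleton points
resampled to equal spacing (1 voxel), a 23³ cube per point, forward
direction from a line fit through the point and its four nearest
neighbours, profiles along the normal's projections onto the cube's lateral
and axial maximum-intensity projections, ratio of lateral to axial FWHM;
ratios deviating from the *median* by more than half of it are discarded
(the median replaces a manually measured reference to keep the rule
reproducible), and points whose fibre runs parallel to a projection axis
are skipped.  Skeleton accuracy uses equal-spacing-resampled SWC trees:
each test node's nearest-neighbour distance to the gold standard defines
true positives under a threshold (default 2 µm, sensible range 1–3 µm),
precision = TP/|test|, recall = TP/|gt|, F1 = 2PR/(P+R), and ESA is the
mean of those distances.  The Fourier-spectrum isotropy score is the ratio
of axial to lateral cutoff frequency, where the cutoff is the radius
enclosing 90 % of the non-DC spectral power of the corresponding half-axis
profile — an energy-fraction definition chosen over a noise-floor crossing
because it behaves stably on both noisy (flat) and smooth (blur-decayed)
spectra.

A diagnostic, `metrics.effective_vertical_blur`, estimates the blur an
image operator applies: it fits the operator's output on real content
against vertical Gaussian blurs of the input over a σ grid with per-σ
affine (gain/offset) calibration.  Fitting on in-distribution content is
deliberate — generators trained on microscopy-like scenes respond
unreliably to synthetic probes such as ideal thin lines.

## Test-scale study conditions

The self-learning runs exercised by the test suite are scaled to a single
CPU; all sizes below are the package's fixed choices, selected before the
properties were measured and recorded here once:

* networks: 16 features, 2 residual blocks; discriminators 16/32/64/1;
  24 px patches, batch 4; no augmentation (at a few hundred iterations,
  rotations that move the degradation axis into the horizontal direction
  slow convergence measurably); lr 1e−3 halved each "epoch" of 150
  iterations (the full-scale schedule compressed; annealing damps the
  oscillation of the learned blur width around its converged value).
* degradation recovery: 128² lateral slices of a bead scene, vertical
  Gaussian σ = 2 px on the unpaired axial set, stage 1 alone (feedback off),
  450 iterations; the learned blur must land within 25 % of the true σ on
  the median of 3 seeds.
* end-to-end recovery: 64³ scene, 150 beads of radius 1.0–1.4 voxels, PSF
  FWHM 0.3/1.1 µm at 0.2 µm voxels (≈3.7-fold anisotropy, inside the
  method's working range of up to ~4×).  The bead sizes and widths
  were chosen from the quadrature prediction
  `width ≈ √(bead² + PSF_FWHM²)` so the pre-restoration bead isotropy
  ratio lands near 0.4; the bead count compensates for the ~50× smaller
  patch-sampling budget of the short run, keeping the per-iteration signal
  exposure comparable to a full-scale scene.  After the full two-stage
  training the ratio must reach ≥ 0.7 and the axial-MIP SSIM against the
  isotropic reference must improve over the raw input (median of 3 seeds).
* normalization anchors for sparse phantoms are (0.1, 100): with foreground
  under 0.1 % of voxels the default 99.9th-percentile anchor would sit in
  the background and saturate every bead.
* the DeconvNet fit (a purely supervised regression, no adversarial terms)
  uses lr 3e−3.

## Known limitations

* CPU training at full published scale (64 features, 24 000 iterations,
  64 px patches) is possible but slow; the numpy backend is tuned for the
  desk-scale regime.
* The method inherits the self-similarity assumption: structures must look
  alike in lateral and axial views.  Strongly oriented samples violate it.
* Performance degrades beyond ~4× anisotropy and at low SNR — both
  stress the self-similarity assumption the scheme rests on.
* `restore` processes one slice at a time; TB-scale streaming and GPU
  memory management are out of scope.
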