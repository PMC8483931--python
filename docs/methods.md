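# Methods

## Noise model and simulator

Low-dose acquisitions are emulated in the projection domain, where photon
statistics actually arise. A phantom in Hounsfield units is converted to
linear attenuation with the standard calibration

    mu = mu_water * (1 + HU / 1000),   clipped at 0,

with `mu_water = 0.02 /mm`. The parallel-beam Radon transform (evenly
spaced angles over [0°, 180°), scikit-image `radon`) gives line integrals
`p`; the transmitted photon count along each ray is `I0 * exp(-p)`; a
Poisson draw replaces it; counts are floored at 1 before the log so fully
opaque rays stay finite; and the noisy integrals `-log(N / I0)` are
reconstructed with ramp-filtered back projection (`iradon`, linear
interpolation). An optional zero-mean Gaussian term on the counts models
electronic noise and is off by default. All randomness flows through
explicit `numpy.random.default_rng` seeds; equal seeds give bit-identical
outputs.

The dose parameter `I0` (incident photons per detector bin) has no
canonical value for this kind of simulation; the package default of
`1e4` produces clearly visible streak noise (held-out PSNR ≈ 34 dB
against the clean phantom at 128 px) while keeping every ray well above
the count floor. Fan-beam geometry, scatter, and beam hardening are out
of scope.

What the phantoms do not emulate: anatomical texture, organ boundaries
with partial-volume ramps, and detector cross-talk. Passing tests on
this data therefore demonstrate that the implementation is correct and
that the method behaves as designed under its own assumptions — not that
the measured PSNR gains transfer quantitatively to clinical scans.

## Network

The denoiser is a single shallow encoder-decoder applied recursively with
one shared parameter set. Architecture (defaults): 8 layers — 4 valid
3×3 convolutions then 4 mirrored 3×3 transposed convolutions, stride 1,
no zero padding — 64 kernels per hidden layer, 1 in the last; weights
initialized Gaussian(0, 0.01), biases zero. Valid convolutions shrink
each spatial dimension by 2 per layer and the mirrored transposed
convolutions restore it exactly, so output shape always equals input
shape and the smallest admissible input is 9×9.

Design points that the architecture description leaves open, and how they
are resolved here:

* **Skip topology.** "Residual" is read as the canonical residual
  encoder-decoder pattern: each encoder layer's post-ReLU feature map is
  added to the pre-activation of its mirrored decoder layer, plus one
  global input→output residual. A `residual=False` config flag removes
  both for convergence comparisons.
* **Residual output.** The last layer predicts a detail map `F` and the
  stage output is `X − F`. This reconciles treating the stage output as
  the denoised image with training the network to predict noise, and it
  makes the zero-weight network exactly the identity.
* **Recursion input.** Stage inputs are channel concatenations
  (`f_in = concat`). Since later stages receive two channels, weight
  sharing forces the first layer to accept two channels at every stage,
  so stage 1 receives `concat(X, X)`.
* **Normalization.** HU are mapped affinely from the display window
  [-1000, 2000] to [0, 1] before the network and inverted afterwards.

Forward and backward passes are explicit numpy (im2col windows +
einsum/BLAS); the transposed convolution is implemented as the exact
adjoint of the valid convolution, which makes the hand-written backprop a
mechanical mirror of the forward pass and was verified against central
finite differences (agreement to ~1e-10 away from ReLU kinks).

The complexity measure is the literal per-layer sum
`E = Σ_l n_{l-1} · f_l² · n_l`, multiplied by the recursion count `S`
because the shared network executes once per stage (default 8-layer
config: 222,912 multiply weights per pass).

## Loss

`L_joint = L_MSE + w · L_per` with `w = 1` by default. `L_MSE` is the
squared pixel error normalized by `W·H` (the squared form; some
descriptions of this objective say "root MSE" but the printed formula is
squared, and the squared form is what is implemented). `L_per` is the
squared distance between frozen-encoder feature maps, normalized by the
tapped map's `W_i·H_i` with channels summed, gradients flowing to the
prediction only.

The reference loss network would be a pretrained segmentation encoder;
to keep the package self-contained the default extractor is a 4-layer
same-padded 3×3 convolutional encoder, 16 channels, He-scaled Gaussian
weights from a fixed seed, tapped at the next-to-last layer. Random
convolutional features are an established surrogate for pretrained
perceptual losses; the extractor's provenance (`seeded-random` vs
`loaded-weights`) is recorded in every `LossReport`, and externally
trained weights load through the same checkpoint container.
`perceptual_weight` exists because an unweighted sum can be badly scaled
for some extractors; the default of 1 preserves the plain sum.

## Training

Documented defaults follow the reference protocol: learning rate 1e-5,
48×48 patches, checkpoint every 1,000 iterations, stop at 50,000.
Unstated details are filled in as: Adam (plain SGD at 1e-5 is
impractically slow at desk scale; the optimizer is a config field),
batch size 32, loss applied to the final stage output only (no deep
supervision), no data augmentation.

The minibatch at iteration `i` is drawn from `default_rng([seed, i])`,
so a resumed run reproduces the unsplit run's trajectory exactly;
checkpoints store config, S, seed, iteration, parameters, and optimizer
moments.

The test suite and worked examples use a scaled-down profile chosen when
the synthetic study was designed — 128 px phantoms, S = 2, 8 kernels,
32-px patches, batch 16, Adam at 1e-3, 300 iterations — which trains in
under a minute per seed on one CPU and lifts held-out PSNR by several dB
over the noisy input (the acceptance suite asserts ≥ 0.5 dB averaged over
5 seeds). Scaling down the width and iteration count exercises the
identical code path; only the capacity of the fitted model differs from
the documented full profile.

## Tissue optimization

Three-class 1-D k-means on HU values, converted to two thresholds
(midpoints between sorted cluster centers), with the water-bone threshold
floored at 320 HU. Cluster initialization is at the physical HU anchors
-1000 (air), 0 (water), and the image maximum (at least 320, bone):
because HU is a calibrated scale these anchors are meaningful, and they
keep one center per tissue mode regardless of class proportions —
quantile-based initialization was found to drop two centers into the air
mode on typical slices (which are mostly air), merging water and bone
into one cluster and corrupting the water mask. With the anchor
initialization the segmentation is deterministic; the `seed` argument is
kept for interface stability.

The transition weights use the exact Euclidean distance transform of the
water mask (distance to the nearest non-water pixel), clipped at L = 5
px; a mask with no non-water pixel at all is assigned D = L everywhere
(the distance is unbounded, so the clip applies). Degenerate inputs:
a constant image raises a segmentation error naming the image; an image
whose water class is empty passes through unchanged with a warning,
since this stage is a refinement. Segmentation runs on the network
output, not the original noisy image.

Known limitation, by construction: the flattening assumes the
water-equivalent class is genuinely uniform. If the middle HU cluster
contains real low-contrast structure (e.g. soft-tissue inserts at
+40 HU), that structure is partially averaged away and fidelity metrics
drop; the step should be applied only where the uniformity assumption
holds.

## Metrics and reports

PSNR hard-codes an 8-bit peak of 255, so both images are first clipped
to a shared display window (default [-1000, 2000] HU) and quantized to
integers in [0, 255]; identical images report an infinite PSNR sentinel.
SSIM is the global-statistics form — one window covering the whole image,
`c1 = (0.01·255)²`, `c2 = (0.03·255)²` (the constants are the standard
choice) — because that is the printed formula; the conventional 11×11
sliding-window mean SSIM is available behind a flag. RMSE is computed on
the quantized pair rescaled to [0, 1]. Report tables carry per-method
arithmetic means of PSNR and SSIM, rounded half-up at 3 decimals for
display (internal averages are unrounded), plus pairwise mean PSNR
differences between methods, and record the display window used.

## Numerical choices

* float64 throughout; no stochastic rounding anywhere.
* Transmission counts floored at 1 before the log (degenerate-ray rule).
* k-means runs single-init from the fixed anchors (`n_init=1`), so ties
  cannot arise from restarts.
* `prior_image` forces `D = 0` pixels to be bit-identical to the input
  rather than relying on `0 * mean` arithmetic.
* Checkpoint loading raises a single `CheckpointError` for any unreadable
  or inconsistent file; no partial state is returned.
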