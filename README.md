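# redct

Low-dose CT denoising with a weight-shared recursive residual
encoder-decoder network, a joint pixel + perceptual loss, and a
clustering-based water-equivalent tissue optimization — together with a
projection-domain noise simulator so the whole method can be trained and
evaluated on synthetic phantom data, end to end, on a single CPU.

## The problem

Lowering the X-ray tube current reduces patient dose but also the photon
count reaching the detector, so low-dose CT (LDCT) projections are noisy
and the filtered-back-projection (FBP) reconstruction carries noise and
streak artifacts that disturb diagnosis. The goal is a mapping `G: z → x`
from an LDCT image `z` to its normal-dose counterpart `x` that removes
noise without smoothing away texture and edges.

## The method

**Recursive residual encoder-decoder.** One shallow 8-layer network —
four valid 3×3 convolutions, four mirrored transposed convolutions, 64
kernels per hidden layer and 1 in the last, symmetric encoder→decoder
skip additions and a global input residual — is applied `S` times with a
single shared parameter set:

```
I_1     = concat(X, X)
O_s     = RED(I_s),          s = 1, …, S
I_{s+1} = concat(O_s, X)
```

Each stage sees both the previous estimate and the original noisy image
`X`, and the parameter count is independent of `S` (default 5). The last
layer predicts a detail map `F`, and the stage output is the residual
`X − F`, so the untrained (zero-weight) network is exactly the identity.

**Joint loss.** Training minimizes `L_joint = L_MSE + L_per`: the
per-pixel squared error normalized by `W·H`, plus the squared distance
between frozen-encoder feature maps of output and target normalized by
the tapped map's `W_i·H_i`. The feature extractor is a compact 4-layer
convolutional encoder with deterministic seeded weights (a random-feature
perceptual loss); pretrained weights can be loaded through the same
checkpoint container.

**Water-equivalent tissue optimization.** After denoising, k-means
(k = 3) splits the slice into air / water(-equivalent) / bone — the
bone-water threshold floored at 320 HU — and a Euclidean distance
transform of the water mask, clipped at `L = 5` px, gives weights `D_i`.
The water region is flattened toward its `D`-weighted mean:

```
ȳ        = Σ_i D_i·y_i / Σ_i D_i
y_prior_i = (D_i/L)·ȳ + (1 − D_i/L)·y_i
```

Deep-interior water pixels snap exactly to `ȳ`, boundary pixels are left
untouched, and the `L`-pixel ramp prevents false boundaries.

**Simulator.** Phantoms in Hounsfield units are forward-projected
(parallel-beam Radon transform of `μ = μ_water·(1 + HU/1000)`), the
transmitted counts `I₀·e^{−p}` receive Poisson noise, and the noisy line
integrals are reconstructed with ramp-filtered FBP — the standard way a
low-dose scan is emulated from a clean image.

Metrics are PSNR (`20·log10(255/RMSE)` on 8-bit quantized images under a
shared display window), global-statistics SSIM, and unit-range RMSE.

## Worked example

```python
import redct
from redct.synthetic_ct import PhantomSpec, Ellipse

# 1. simulate a paired normal-dose / low-dose acquisition of a phantom
#    whose soft tissue is genuinely water-equivalent (uniform)
spec = PhantomSpec(128, (
    Ellipse((0.5, 0.5), (0.40, 0.32), 15.0, "water"),
    Ellipse((0.62, 0.44), (0.08, 0.06), 0.0, "bone"),
    Ellipse((0.38, 0.58), (0.05, 0.07), 30.0, "bone"),
))
ndct = redct.generate_phantom(spec)
ldct = redct.simulate_low_dose(ndct, incident_photons=1e4, seed=11)
print(f"low-dose input : PSNR {redct.psnr(ndct, ldct):.2f} dB, "
      f"SSIM {redct.ssim(ndct, ldct):.3f}")

# 2. train the recursive network on patches from a different simulated pair
train_nd = redct.generate_phantom(redct.random_phantom_spec(seed=7, canvas_size=128))
train_ld = redct.simulate_low_dose(train_nd, incident_photons=1e4, seed=7)
patches = redct.extract_patches(train_ld, train_nd, patch_size=32,
                                n_patches=200, seed=0)
model = redct.build_model(redct.REDConfig(kernels_per_hidden_layer=8),
                          seed=0, S=2)
model, log = redct.train(model, patches, redct.toy_train_config(seed=0))
print(f"joint loss     : {log.joint[0]:.5f} -> {log.joint[-1]:.5f}")

# 3. denoise the held-out slice and apply the tissue optimization
denoised = redct.denoise_image(model, ldct)
optimized, seg, tw = redct.optimize(denoised, L=5, seed=0)
print(f"denoised       : PSNR {redct.psnr(ndct, denoised):.2f} dB, "
      f"SSIM {redct.ssim(ndct, denoised):.3f}")
print(f"+ tissue opt   : PSNR {redct.psnr(ndct, optimized):.2f} dB, "
      f"SSIM {redct.ssim(ndct, optimized):.3f}")
```

prints (about two minutes on one CPU):

```
low-dose input : PSNR 33.64 dB, SSIM 0.993
joint loss     : 0.00329 -> 0.00125
denoised       : PSNR 36.96 dB, SSIM 0.997
+ tissue opt   : PSNR 38.35 dB, SSIM 0.998
```

The short training run lifts the held-out slice by about 3.3 dB over the
raw low-dose input, and flattening the water-equivalent region gains a
further 1.4 dB. This uses the desk-scale profile (8-kernel network, S = 2,
300 iterations, 32-px patches); the documented defaults on `REDConfig` /
`TrainConfig` (64 kernels, S = 5, 48-px patches, learning rate 1e-5,
50,000 iterations) reproduce the reference protocol.

The same pipeline is available from a shell:

```bash
redct simulate --phantoms 10 --size 128 --photons 1e4 --seed 1 --out data/
redct train    --data data/ --out run/
redct denoise  --model run/model.npz --in data/000_ldct.npy --out out.npy
redct optimize --in out.npy --out opt.npy
redct evaluate --pairs data/ --model run/model.npz --out eval/
```

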