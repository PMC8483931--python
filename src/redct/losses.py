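"""Joint training objective: pixel MSE plus feature-space perceptual loss.

The joint loss is the plain sum

    L_joint = L_MSE + w * L_per,      w = 1 by default

with L_MSE the mean squared pixel difference between the denoised image and
the clean target, normalized by width*height, and L_per the squared distance
between frozen-network feature maps of the two images, normalized by the
tapped map's width*height (channels are summed, not averaged).

The default feature extractor is a compact 4-layer convolutional encoder
with deterministic, seeded random weights. Random-feature perceptual losses
are an established surrogate for pretrained ones, and a seeded extractor
keeps the package fully self-contained; externally trained weights can be
loaded through the same checkpoint container for runs that want a
pretrained loss network.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ._nn import conv2d, conv2d_backward, relu

__all__ = [
    "FeatureExtractor",
    "LossReport",
    "mse_loss",
    "mse_loss_grad",
    "perceptual_loss",
    "perceptual_loss_grad",
    "joint_loss",
    "joint_loss_grad",
]


@dataclass
class FeatureExtractor:
    """Frozen convolutional encoder whose tapped layer defines phi_i.

    Layers are same-padded 3x3 convolutions with ReLU, so the tapped feature
    map keeps the input's spatial size and the extractor accepts any input
    of at least kernel_size pixels. Weights are never updated; gradients
    flow through it to the *prediction* only.
    """

    layers: list = field(default_factory=list)   # [(weight, bias)]
    tap_index: int = 2
    seed: int | None = None
    provenance: str = "seeded-random"

    @classmethod
    def seeded(cls, seed: int = 0, n_layers: int = 4, channels: int = 16,
               kernel_size: int = 3, tap_index: int | None = None) -> "FeatureExtractor":
        """He-scaled Gaussian random weights from a fixed seed."""
        rng = np.random.default_rng(seed)
        layers = []
        in_c = 1
        for _ in range(n_layers):
            fan_in = in_c * kernel_size ** 2
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                           size=(channels, in_c, kernel_size, kernel_size))
            layers.append((w, np.zeros(channels)))
            in_c = channels
        if tap_index is None:
            tap_index = n_layers - 2       # next-to-last encoder layer
        return cls(layers=layers, tap_index=tap_index, seed=seed,
                   provenance="seeded-random")

    def _check_tap(self):
        if not 0 <= self.tap_index < len(self.layers):
            raise ValueError(
                f"tap_index {self.tap_index} out of range for "
                f"{len(self.layers)} layers")

    def features(self, x: np.ndarray, keep_cache: bool = False):
        """phi_i(x) for a 2-D image or (N, 1, H, W) batch."""
        self._check_tap()
        squeeze = np.asarray(x).ndim == 2
        xb = np.asarray(x, dtype=np.float64)
        if squeeze:
            xb = xb[None, None]
        pad = self.layers[0][0].shape[-1] // 2
        cache = []
        a = xb
        for li, (w, b) in enumerate(self.layers[: self.tap_index + 1]):
            z = conv2d(a, w, b, padding=pad)
            cache.append((a, z))
            a = relu(z)
        feats = a
        if squeeze:
            feats = feats[0]
        if keep_cache:
            return feats, cache
        return feats

    def backprop_to_input(self, d_feats: np.ndarray, cache: list) -> np.ndarray:
        """Gradient of a scalar w.r.t. the extractor input (weights frozen)."""
        pad = self.layers[0][0].shape[-1] // 2
        cur = d_feats
        for li in range(self.tap_index, -1, -1):
            a_in, z = cache[li]
            dz = cur * (z > 0)
            cur, _, _ = conv2d_backward(dz, a_in, self.layers[li][0], padding=pad)
        return cur

    def save(self, path) -> None:
        arrays = {}
        for i, (w, b) in enumerate(self.layers):
            arrays[f"w_{i}"] = w
            arrays[f"b_{i}"] = b
        meta = dict(n_layers=len(self.layers), tap_index=self.tap_index,
                    seed=self.seed, provenance=self.provenance)
        with open(path, "wb") as fh:
            np.savez(fh, meta=np.frombuffer(json.dumps(meta).encode(),
                                            dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "FeatureExtractor":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            layers = [(data[f"w_{i}"], data[f"b_{i}"])
                      for i in range(meta["n_layers"])]
        return cls(layers=layers, tap_index=meta["tap_index"],
                   seed=meta["seed"], provenance="loaded-weights")


@dataclass
class LossReport:
    mse_term: float
    perceptual_term: float
    joint: float
    perceptual_weight: float = 1.0
    extractor_provenance: str = "seeded-random"


def _pair(prediction, target):
    p = np.asarray(prediction, dtype=np.float64)
    t = np.asarray(target, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    return p, t


def _spatial_size(x: np.ndarray) -> int:
    # W*H normalization; for batches the leading axes average implicitly
    # through the per-image mean below.
    return x.shape[-1] * x.shape[-2]


def mse_loss(prediction, target) -> float:
    """(1 / (W*H)) * sum of squared pixel differences (batch-averaged)."""
    p, t = _pair(prediction, target)
    diff = p - t
    n_images = int(np.prod(diff.shape[:-2])) if diff.ndim > 2 else 1
    return float((diff ** 2).sum() / (_spatial_size(diff) * n_images))


def mse_loss_grad(prediction, target):
    """Returns (loss, d loss / d prediction)."""
    p, t = _pair(prediction, target)
    diff = p - t
    n_images = int(np.prod(diff.shape[:-2])) if diff.ndim > 2 else 1
    denom = _spatial_size(diff) * n_images
    return float((diff ** 2).sum() / denom), 2.0 * diff / denom


def perceptual_loss(prediction, target, extractor: FeatureExtractor) -> float:
    """(1 / (W_i*H_i)) * squared distance between tapped feature maps;
    the channel axis is summed, matching the printed normalization."""
    p, t = _pair(prediction, target)
    fp = extractor.features(p)
    ft = extractor.features(t)
    diff = fp - ft
    n_images = diff.shape[0] if diff.ndim == 4 else 1
    return float((diff ** 2).sum() / (_spatial_size(diff) * n_images))


def perceptual_loss_grad(prediction, target, extractor: FeatureExtractor):
    """Returns (loss, d loss / d prediction); the target branch is detached."""
    p, t = _pair(prediction, target)
    squeeze = p.ndim == 2
    pb = p[None, None] if squeeze else p
    tb = t[None, None] if squeeze else t
    fp, cache = extractor.features(pb, keep_cache=True)
    ft = extractor.features(tb)
    diff = fp - ft
    denom = _spatial_size(diff) * diff.shape[0]
    loss = float((diff ** 2).sum() / denom)
    d_in = extractor.backprop_to_input(2.0 * diff / denom, cache)
    if squeeze:
        d_in = d_in[0, 0]
    return loss, d_in


def joint_loss(prediction, target, extractor: FeatureExtractor,
               perceptual_weight: float = 1.0) -> LossReport:
    """Joint objective: mse + weight * perceptual (weight 1 reproduces the
    unweighted sum)."""
    if perceptual_weight < 0:
        raise ValueError("perceptual_weight must be non-negative")
    mse = mse_loss(prediction, target)
    per = perceptual_loss(prediction, target, extractor)
    return LossReport(mse_term=mse, perceptual_term=per,
                      joint=mse + perceptual_weight * per,
                      perceptual_weight=perceptual_weight,
                      extractor_provenance=extractor.provenance)


def joint_loss_grad(prediction, target, extractor: FeatureExtractor,
                    perceptual_weight: float = 1.0):
    """Returns (LossReport, d joint / d prediction)."""
    if perceptual_weight < 0:
        raise ValueError("perceptual_weight must be non-negative")
    mse, d_mse = mse_loss_grad(prediction, target)
    if perceptual_weight > 0:
        per, d_per = perceptual_loss_grad(prediction, target, extractor)
    else:
        per, d_per = perceptual_loss(prediction, target, extractor), 0.0
    report = LossReport(mse_term=mse, perceptual_term=per,
                        joint=mse + perceptual_weight * per,
                        perceptual_weight=perceptual_weight,
                        extractor_provenance=extractor.provenance)
    return report, d_mse + perceptual_weight * d_per
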