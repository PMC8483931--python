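"""Clustering-based water-equivalent tissue optimization.

Water-equivalent soft tissue dominates a CT slice and should be nearly
uniform in attenuation; residual streaks and artifact noise left after
network denoising show up as low-amplitude texture across it. The
post-processing step here flattens that region toward a single value:

1. k-means (k = 3) on the pixel HU values splits the image into air,
   water(-equivalent) and bone; the bone-water threshold is floored at
   320 HU to avoid misclassifying dense tissue as bone.
2. A Euclidean distance transform of the binary water mask, clipped at a
   transition width L (default 5 px), gives each water pixel a weight D
   that ramps from 0 at the region boundary to L in the deep interior.
3. The D-weighted mean of the network output over water pixels defines
   the common water value, and each pixel is blended linearly:

       y_prior_i = (D_i / L) * water_mean + (1 - D_i / L) * y_net_i

so interior pixels snap exactly to the mean, boundary pixels are left
untouched, and no false edges appear at the region border.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt
from sklearn.cluster import KMeans

from .synthetic_ct import CTImage

__all__ = [
    "BONE_WATER_FLOOR_HU",
    "DEFAULT_TRANSITION_WIDTH",
    "TissueSegmentation",
    "TransitionWeights",
    "DegenerateImageError",
    "NoWaterError",
    "segment_tissues",
    "transition_weights",
    "weighted_water_mean",
    "prior_image",
    "optimize",
]

BONE_WATER_FLOOR_HU = 320.0
DEFAULT_TRANSITION_WIDTH = 5.0


class DegenerateImageError(ValueError):
    """Clustering is impossible (fewer than three distinct HU values)."""


class NoWaterError(ValueError):
    """No water-class pixels: the weighted water mean is undefined."""


@dataclass
class TissueSegmentation:
    labels: np.ndarray                  # 0 = air, 1 = water, 2 = bone
    thresholds: tuple[float, float]     # (air-water HU, water-bone HU)
    cluster_centers: tuple[float, float, float]

    AIR, WATER, BONE = 0, 1, 2

    @property
    def water_mask(self) -> np.ndarray:
        return (self.labels == self.WATER).astype(np.uint8)


@dataclass
class TransitionWeights:
    D: np.ndarray      # per-pixel weight in [0, L]; 0 off water
    L: float


def segment_tissues(image: CTImage, seed: int = 0) -> TissueSegmentation:
    """Three-class k-means on HU values, converted to two thresholds.

    Cluster centers are initialized at the physical HU anchors — air at
    -1000, water at 0, bone at the image maximum (at least the 320 HU
    floor) — which pins the air/water/bone ordering regardless of how much
    of the slice each class covers and makes the result deterministic.
    (Quantile-based initialization drops two centers into the air mode on
    typical slices, which are mostly air.) Thresholds are midpoints between
    sorted cluster centers; the water-bone threshold is raised to 320 HU if
    clustering lands lower.
    """
    values = image.values
    if np.unique(values).size < 3:
        raise DegenerateImageError(
            f"image {values.shape} has fewer than 3 distinct HU values; "
            "three-class segmentation is undefined")
    hi = max(float(values.max()), BONE_WATER_FLOOR_HU)
    init = np.array([-1000.0, 0.0, hi]).reshape(-1, 1)
    km = KMeans(n_clusters=3, init=init, n_init=1, random_state=seed)
    km.fit(values.reshape(-1, 1))
    centers = np.sort(km.cluster_centers_.ravel())
    t_air_water = float((centers[0] + centers[1]) / 2.0)
    t_water_bone = float(max((centers[1] + centers[2]) / 2.0,
                             BONE_WATER_FLOOR_HU))
    labels = np.full(values.shape, TissueSegmentation.WATER, dtype=np.int8)
    labels[values < t_air_water] = TissueSegmentation.AIR
    labels[values >= t_water_bone] = TissueSegmentation.BONE
    return TissueSegmentation(labels=labels,
                              thresholds=(t_air_water, t_water_bone),
                              cluster_centers=tuple(float(c) for c in centers))


def transition_weights(segmentation: TissueSegmentation,
                       L: float = DEFAULT_TRANSITION_WIDTH) -> TransitionWeights:
    """Euclidean distance of each water pixel to the nearest non-water
    pixel, clipped at L; exactly 0 on non-water pixels."""
    if L < 1:
        raise ValueError("transition width L must be >= 1")
    mask = segmentation.water_mask
    if mask.all():
        # no non-water pixel anywhere: distance is unbounded, clip applies
        D = np.full(mask.shape, float(L))
    else:
        D = np.minimum(distance_transform_edt(mask), float(L))
    return TransitionWeights(D=D, L=float(L))


def weighted_water_mean(image_net: CTImage, weights: TransitionWeights) -> float:
    """D-weighted mean of the network output: sum(D_i y_i) / sum(D_i)."""
    D = weights.D
    total = D.sum()
    if total == 0:
        raise NoWaterError("no water pixels: weighted mean undefined")
    return float((D * image_net.values).sum() / total)


def prior_image(image_net: CTImage, weights: TransitionWeights,
                water_mean: float) -> CTImage:
    """Per-pixel convex blend toward the water mean, ramped by D_i / L."""
    if weights.D.shape != image_net.shape:
        raise ValueError("weights and image must share a shape")
    frac = weights.D / weights.L
    out = frac * water_mean + (1.0 - frac) * image_net.values
    # D_i = 0 pixels must be bit-identical, not merely close
    out[weights.D == 0] = image_net.values[weights.D == 0]
    return CTImage(out, pixel_spacing=image_net.pixel_spacing)


def optimize(image_net: CTImage, L: float = DEFAULT_TRANSITION_WIDTH,
             seed: int = 0):
    """Full pipeline: segment -> transition weights -> water mean -> blend.

    Returns (optimized image, segmentation, weights). An image with no
    water pixels is passed through unchanged with a warning, since this
    step is a refinement, not a requirement.
    """
    segmentation = segment_tissues(image_net, seed=seed)
    weights = transition_weights(segmentation, L=L)
    if weights.D.sum() == 0:
        warnings.warn("no water-class pixels found; image returned unchanged",
                      stacklevel=2)
        return (CTImage(image_net.values.copy(),
                        pixel_spacing=image_net.pixel_spacing),
                segmentation, weights)
    mean = weighted_water_mean(image_net, weights)
    return prior_image(image_net, weights, mean), segmentation, weights
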