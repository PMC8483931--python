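"""Image-quality metrics (PSNR, global SSIM, RMSE) and report aggregation.

The PSNR definition hard-codes an 8-bit peak of 255, so all metrics first
quantize both images to 8 bits under a shared Hounsfield display window
(default [-1000, 2000] HU). SSIM is the *global-statistics* form — one
window covering the whole image, c1 = (0.01*255)^2, c2 = (0.03*255)^2 —
rather than the more common 11x11 sliding-window variant, which is exposed
behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np

from .red_model import HU_WINDOW, denoise_image
from .synthetic_ct import CTImage

__all__ = [
    "MetricsRecord",
    "ReportTable",
    "quantize_to_8bit",
    "psnr",
    "ssim",
    "rmse",
    "aggregate",
    "evaluate_pipeline",
]

C1 = (0.01 * 255) ** 2
C2 = (0.03 * 255) ** 2


@dataclass
class MetricsRecord:
    image_id: str
    method: str
    psnr_db: float            # math.inf for identical images
    ssim: float
    rmse: float


@dataclass
class ReportTable:
    rows: list
    averages: dict            # method -> {"psnr_db": ..., "ssim": ...} (rounded)
    pairwise_psnr_diff: dict  # (method_a, method_b) -> mean difference (rounded)
    decimals: int = 3
    hu_window: tuple[float, float] = HU_WINDOW


def _values(img) -> np.ndarray:
    return img.values if isinstance(img, CTImage) else np.asarray(img, dtype=float)


def quantize_to_8bit(img, window=HU_WINDOW) -> np.ndarray:
    """Clip to the display window and quantize to integers in [0, 255]."""
    lo, hi = window
    x = np.clip(_values(img), lo, hi)
    return np.round((x - lo) / (hi - lo) * 255.0)


def _check_pair(a, b):
    av, bv = _values(a), _values(b)
    if av.shape != bv.shape:
        raise ValueError(f"shape mismatch: {av.shape} vs {bv.shape}")
    return av, bv


def psnr(reference, test, window=HU_WINDOW) -> float:
    """20*log10(255 / RMSE) on the 8-bit quantized pair; inf if identical."""
    _check_pair(reference, test)
    qa = quantize_to_8bit(reference, window)
    qb = quantize_to_8bit(test, window)
    mse = float(np.mean((qa - qb) ** 2))
    if mse == 0:
        return math.inf
    return 20.0 * math.log10(255.0 / math.sqrt(mse))


def ssim(a, b, window=HU_WINDOW, sliding: bool = False) -> float:
    """Structural similarity on the 8-bit quantized pair.

    Default is the single-window global form; ``sliding=True`` switches to
    the conventional 11x11 Gaussian-window mean SSIM (via scikit-image).
    """
    _check_pair(a, b)
    qa = quantize_to_8bit(a, window)
    qb = quantize_to_8bit(b, window)
    if sliding:
        from skimage.metrics import structural_similarity
        return float(structural_similarity(qa, qb, data_range=255,
                                           gaussian_weights=True))
    mu_a, mu_b = qa.mean(), qb.mean()
    var_a, var_b = qa.var(), qb.var()
    cov = ((qa - mu_a) * (qb - mu_b)).mean()
    return float((2 * mu_a * mu_b + C1) * (2 * cov + C2)
                 / ((mu_a ** 2 + mu_b ** 2 + C1) * (var_a + var_b + C2)))


def rmse(a, b, window=HU_WINDOW) -> float:
    """Root-mean-square error on the quantized pair rescaled to [0, 1]."""
    _check_pair(a, b)
    qa = quantize_to_8bit(a, window) / 255.0
    qb = quantize_to_8bit(b, window) / 255.0
    return float(np.sqrt(np.mean((qa - qb) ** 2)))


def _round_half_up(x: float, decimals: int) -> float:
    return float(Decimal(repr(x)).quantize(Decimal(1).scaleb(-decimals),
                                           rounding=ROUND_HALF_UP))


def aggregate(records: list, decimals: int = 3,
              hu_window=HU_WINDOW) -> ReportTable:
    """Per-method mean PSNR/SSIM (half-up rounded for display) plus the
    pairwise mean PSNR differences between methods."""
    if not records:
        raise ValueError("no records to aggregate")
    methods: dict[str, list] = {}
    for r in records:
        methods.setdefault(r.method, []).append(r)
    averages = {}
    raw_psnr = {}
    for method, rows in methods.items():
        mean_psnr = float(np.mean([r.psnr_db for r in rows]))
        mean_ssim = float(np.mean([r.ssim for r in rows]))
        raw_psnr[method] = mean_psnr
        averages[method] = {
            "psnr_db": _round_half_up(mean_psnr, decimals),
            "ssim": _round_half_up(mean_ssim, decimals),
        }
    names = list(methods)
    diffs = {}
    for i, ma in enumerate(names):
        for mb in names[i + 1:]:
            diffs[(ma, mb)] = _round_half_up(raw_psnr[ma] - raw_psnr[mb],
                                             decimals)
            diffs[(mb, ma)] = _round_half_up(raw_psnr[mb] - raw_psnr[ma],
                                             decimals)
    return ReportTable(rows=list(records), averages=averages,
                       pairwise_psnr_diff=diffs, decimals=decimals,
                       hu_window=hu_window)


def evaluate_pipeline(model, pairs, with_optimization: bool = False,
                      seed: int = 0, window=HU_WINDOW,
                      transition_width: float = 5.0) -> ReportTable:
    """Denoise every (ndct, ldct) pair, optionally apply the tissue
    optimization, and tabulate metrics for both the raw low-dose input and
    the method's output."""
    from . import tissue_opt

    records = []
    for i, (ndct, ldct) in enumerate(pairs):
        if ndct.shape != ldct.shape:
            raise ValueError(f"pair {i}: shape mismatch {ndct.shape} vs {ldct.shape}")
        image_id = f"img{i:03d}"
        records.append(MetricsRecord(
            image_id=image_id, method="ldct",
            psnr_db=psnr(ndct, ldct, window), ssim=ssim(ndct, ldct, window),
            rmse=rmse(ndct, ldct, window)))
        den = denoise_image(model, ldct, window=window)
        if with_optimization:
            den, _, _ = tissue_opt.optimize(den, L=transition_width, seed=seed)
        records.append(MetricsRecord(
            image_id=image_id, method="proposed",
            psnr_db=psnr(ndct, den, window), ssim=ssim(ndct, den, window),
            rmse=rmse(ndct, den, window)))
    return aggregate(records, hu_window=window)
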