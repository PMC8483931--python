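"""Convolution primitives with explicit backward passes.

Everything operates on float64 arrays in NCHW layout. Forward convolutions
are *valid* cross-correlations (no padding unless requested); transposed
convolutions are their exact adjoints and grow each spatial dimension by
``kernel_size - 1``. These two are the only building blocks the encoder
(convolution) and decoder (deconvolution) halves of the network need, and
keeping the pair adjoint makes the hand-written backprop a mechanical
mirror of the forward pass.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "conv2d",
    "conv2d_backward",
    "tconv2d",
    "tconv2d_backward",
    "relu",
]


def _windows(x: np.ndarray, k: int) -> np.ndarray:
    # (N, C, H, W) -> (N, C, H-k+1, W-k+1, k, k)
    return sliding_window_view(x, (k, k), axis=(2, 3))


def conv2d(x: np.ndarray, weight: np.ndarray, bias: np.ndarray | None = None,
           padding: int = 0) -> np.ndarray:
    """Valid cross-correlation.

    x: (N, C_in, H, W); weight: (C_out, C_in, k, k); bias: (C_out,).
    Returns (N, C_out, H - k + 1 + 2*padding, W - k + 1 + 2*padding).
    """
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    k = weight.shape[-1]
    y = np.einsum("nchwij,ocij->nohw", _windows(x, k), weight, optimize=True)
    if bias is not None:
        y += bias[None, :, None, None]
    return y


def conv2d_backward(dy: np.ndarray, x: np.ndarray, weight: np.ndarray,
                    padding: int = 0):
    """Gradients of ``conv2d``. Returns (dx, dweight, dbias)."""
    if padding:
        xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    else:
        xp = x
    k = weight.shape[-1]
    dw = np.einsum("nohw,nchwij->ocij", dy, _windows(xp, k), optimize=True)
    db = dy.sum(axis=(0, 2, 3))
    # dx = transposed conv of dy with the same kernel (the adjoint map).
    dxp = tconv2d(dy, weight)
    if padding:
        dxp = dxp[:, :, padding:-padding, padding:-padding]
    return dxp, dw, db


def tconv2d(x: np.ndarray, weight: np.ndarray, bias: np.ndarray | None = None) -> np.ndarray:
    """Transposed convolution (stride 1): each input pixel scatters the kernel.

    x: (N, C_in, H, W); weight: (C_in, C_out, k, k).
    Returns (N, C_out, H + k - 1, W + k - 1) — the adjoint of a valid conv,
    i.e. the decoder op that exactly undoes the encoder's spatial shrink.
    """
    k = weight.shape[-1]
    xp = np.pad(x, ((0, 0), (0, 0), (k - 1, k - 1), (k - 1, k - 1)))
    wf = weight[:, :, ::-1, ::-1]
    y = np.einsum("nchwij,coij->nohw", _windows(xp, k), wf, optimize=True)
    if bias is not None:
        y += bias[None, :, None, None]
    return y


def tconv2d_backward(dy: np.ndarray, x: np.ndarray, weight: np.ndarray):
    """Gradients of ``tconv2d``. Returns (dx, dweight, dbias).

    Since tconv is the adjoint of a valid conv, its input-gradient is a
    valid conv of dy with the same kernel.
    """
    k = weight.shape[-1]
    win = _windows(dy, k)                      # (N, C_out, H, W, k, k)
    dx = np.einsum("nohwij,coij->nchw", win, weight, optimize=True)
    dw = np.einsum("nchw,nohwij->coij", x, win, optimize=True)
    db = dy.sum(axis=(0, 2, 3))
    return dx, dw, db


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)
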