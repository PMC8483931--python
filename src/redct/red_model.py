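"""Weight-shared recursive shallow residual encoder-decoder network.

The denoiser is a single shallow encoder-decoder ("RED") network of
``n_layers`` layers — half valid 3x3 convolutions that shrink the feature
maps, half mirrored transposed convolutions that grow them back — applied
recursively S times with one shared parameter set:

    I_1 = concat(X, X)
    O_s = RED(I_s)                 s = 1..S
    I_{s+1} = concat(O_s, X)

where X is the noisy input. Each stage therefore sees both the previous
stage's estimate and the original image, and the parameter count does not
grow with S. Inside the shallow network, each encoder layer's (post-ReLU)
feature map is added to the pre-activation of its mirrored decoder layer,
and the final layer predicts a detail/noise map F so the stage output is
the global residual X - F. With all weights zero the network is exactly
the identity.

All arithmetic is float64 numpy; forward and backward passes are written
explicitly (see :mod:`redct._nn`) so the model is self-contained and
bit-reproducible from a seed.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from ._nn import conv2d, conv2d_backward, tconv2d, tconv2d_backward, relu

__all__ = [
    "REDConfig",
    "RecursiveREDModel",
    "RecursionTrace",
    "build_model",
    "forward_shallow",
    "forward_recursive",
    "denoise_image",
    "complexity",
    "normalize_hu",
    "denormalize_hu",
    "save_checkpoint",
    "load_checkpoint",
    "CheckpointError",
]

#: display/normalization window in HU shared across the package
HU_WINDOW = (-1000.0, 2000.0)


@dataclass(frozen=True)
class REDConfig:
    """Architecture of the shallow network.

    Defaults follow the reference setup: 8 layers (4 conv + 4 deconv),
    64 kernels in every hidden layer and 1 in the last, 3x3 kernels,
    stride 1, no zero padding, Gaussian(0, 0.01) weight initialization.
    ``input_channels`` is 2 because every recursion stage receives the
    previous output cascaded with the original image.
    """

    n_layers: int = 8
    kernels_per_hidden_layer: int = 64
    kernels_last_layer: int = 1
    kernel_size: int = 3
    input_channels: int = 2
    init_mean: float = 0.0
    init_std: float = 0.01
    residual: bool = True   # symmetric skips + global input residual

    def __post_init__(self):
        if self.n_layers % 2 != 0 or self.n_layers < 4:
            raise ValueError("n_layers must be even and >= 4")
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")

    @property
    def n_half(self) -> int:
        return self.n_layers // 2

    @property
    def min_input_size(self) -> int:
        """Smallest spatial size the valid-convolution chain accepts."""
        return self.n_half * (self.kernel_size - 1) + 1

    def channel_sequence(self) -> list[int]:
        """Per-layer output channel counts, preceded by the input count."""
        seq = [self.input_channels]
        seq += [self.kernels_per_hidden_layer] * (self.n_layers - 1)
        seq.append(self.kernels_last_layer)
        return seq


@dataclass
class RecursiveREDModel:
    """One shared parameter set plus the recursion count S."""

    config: REDConfig
    enc: list          # [(weight (out,in,k,k), bias (out,))] per encoder layer
    dec: list          # [(weight (in,out,k,k), bias (out,))] per decoder layer
    S: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.S < 1:
            raise ValueError("recursion count S must be >= 1")

    def parameter_arrays(self) -> list[np.ndarray]:
        out = []
        for w, b in self.enc + self.dec:
            out.extend((w, b))
        return out

    def n_parameters(self) -> int:
        return sum(a.size for a in self.parameter_arrays())

    def parameter_bytes(self) -> bytes:
        """Canonical serialization of the shared weights (independent of S)."""
        buf = io.BytesIO()
        for a in self.parameter_arrays():
            buf.write(np.ascontiguousarray(a, dtype=np.float64).tobytes())
        return buf.getvalue()

    def zeroed_like(self) -> "RecursiveREDModel":
        return RecursiveREDModel(
            config=self.config,
            enc=[(np.zeros_like(w), np.zeros_like(b)) for w, b in self.enc],
            dec=[(np.zeros_like(w), np.zeros_like(b)) for w, b in self.dec],
            S=self.S, seed=self.seed)


@dataclass
class RecursionTrace:
    """Per-stage inputs I_1..I_S and outputs O_1..O_S (batched NCHW)."""

    inputs: list = field(default_factory=list)
    outputs: list = field(default_factory=list)


def build_model(config: REDConfig, seed: int = 0, S: int = 5) -> RecursiveREDModel:
    """Draw all weights from Gaussian(init_mean, init_std); biases zero."""
    rng = np.random.default_rng(seed)
    k = config.kernel_size
    m = config.n_half
    hidden = config.kernels_per_hidden_layer
    enc, dec = [], []
    in_c = config.input_channels
    for _ in range(m):
        w = rng.normal(config.init_mean, config.init_std, size=(hidden, in_c, k, k))
        enc.append((w, np.zeros(hidden)))
        in_c = hidden
    for j in range(m):
        out_c = config.kernels_last_layer if j == m - 1 else hidden
        w = rng.normal(config.init_mean, config.init_std, size=(hidden, out_c, k, k))
        dec.append((w, np.zeros(out_c)))
    return RecursiveREDModel(config=config, enc=enc, dec=dec, S=S, seed=seed)


# ---------------------------------------------------------------------------
# forward / backward

def _as_batch(x: np.ndarray, channels: int) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 2:
        x = x[None, None]
    if x.ndim != 4 or x.shape[1] != channels:
        raise ValueError(f"expected (N, {channels}, H, W) input, got {x.shape}")
    return x


def _shallow_forward(model: RecursiveREDModel, x: np.ndarray) -> tuple[np.ndarray, dict]:
    """One pass of the shallow network. Returns (O, cache)."""
    cfg = model.config
    m = cfg.n_half
    h, w = x.shape[2], x.shape[3]
    if min(h, w) < cfg.min_input_size:
        raise ValueError(
            f"input {h}x{w} too small for {cfg.n_layers} valid "
            f"{cfg.kernel_size}x{cfg.kernel_size} layers "
            f"(needs >= {cfg.min_input_size})")
    acts = [x]           # a_0 .. a_m (post-ReLU encoder outputs)
    pre = []             # encoder pre-activations z_1 .. z_m
    for (wgt, b) in model.enc:
        z = conv2d(acts[-1], wgt, b)
        pre.append(z)
        acts.append(relu(z))
    d = acts[-1]
    dec_in = []          # decoder inputs d_0 .. d_{m-1}
    dec_pre = []         # decoder pre-activations (post-skip)
    for j, (wgt, b) in enumerate(model.dec):
        dec_in.append(d)
        t = tconv2d(d, wgt, b)
        if j < m - 1:
            if cfg.residual:
                t = t + acts[m - 1 - j]          # mirrored encoder skip
            dec_pre.append(t)
            d = relu(t)
        else:
            dec_pre.append(t)
            d = t                                 # last layer: linear
    detail = d
    out = x[:, :1] - detail if cfg.residual else detail
    cache = dict(x=x, acts=acts, pre=pre, dec_in=dec_in, dec_pre=dec_pre)
    return out, cache


def _shallow_backward(model: RecursiveREDModel, cache: dict, d_out: np.ndarray,
                      grads: "ModelGrads") -> np.ndarray:
    """Backprop one shallow pass; accumulates into grads, returns dI."""
    cfg = model.config
    m = cfg.n_half
    acts, pre = cache["acts"], cache["pre"]
    d_detail = -d_out if cfg.residual else d_out
    d_acts = [np.zeros_like(a) for a in acts]
    cur = d_detail
    for j in range(m - 1, -1, -1):
        if j < m - 1:
            cur = cur * (cache["dec_pre"][j] > 0)
            if cfg.residual:
                d_acts[m - 1 - j] += cur
        dd, dw, db = tconv2d_backward(cur, cache["dec_in"][j], model.dec[j][0])
        grads.dec[j][0] += dw
        grads.dec[j][1] += db
        cur = dd
    d_acts[m] += cur
    cur = d_acts[m]
    for i in range(m - 1, -1, -1):
        dz = cur * (pre[i] > 0)
        dx, dw, db = conv2d_backward(dz, acts[i], model.enc[i][0])
        grads.enc[i][0] += dw
        grads.enc[i][1] += db
        cur = dx + (d_acts[i] if i > 0 else 0.0)
    d_input = cur
    if cfg.residual:
        d_input = d_input.copy()
        d_input[:, :1] += d_out
    return d_input


class ModelGrads:
    """Mutable gradient accumulator mirroring a model's parameter layout."""

    def __init__(self, model: RecursiveREDModel):
        self.enc = [[np.zeros_like(w), np.zeros_like(b)] for w, b in model.enc]
        self.dec = [[np.zeros_like(w), np.zeros_like(b)] for w, b in model.dec]

    def arrays(self) -> list[np.ndarray]:
        out = []
        for w, b in self.enc + self.dec:
            out.extend((w, b))
        return out


def forward_recursive(model: RecursiveREDModel, x: np.ndarray,
                      keep_caches: bool = False):
    """Run all S recursion stages; returns (O_S, RecursionTrace[, caches]).

    ``x`` is a single-channel image in normalized units: a 2-D array or an
    (N, 1, H, W) batch. Stage 1 receives concat(X, X); later stages receive
    concat(O_s, X). The same shared parameters are applied at every stage.
    """
    X = _as_batch(x, 1)
    trace = RecursionTrace()
    caches = []
    current = X
    for _ in range(model.S):
        inp = np.concatenate([current, X], axis=1)
        trace.inputs.append(inp)
        out, cache = _shallow_forward(model, inp)
        trace.outputs.append(out)
        if keep_caches:
            caches.append(cache)
        current = out
    if keep_caches:
        return current, trace, caches
    return current, trace


def backward_recursive(model: RecursiveREDModel, caches: list,
                       d_final: np.ndarray) -> ModelGrads:
    """Backprop through all recursion stages (shared weights accumulate)."""
    grads = ModelGrads(model)
    d_out = d_final
    for s in range(len(caches) - 1, -1, -1):
        d_inp = _shallow_backward(model, caches[s], d_out, grads)
        # I_s = concat(O_{s-1}, X): channel 0 feeds the previous stage.
        d_out = d_inp[:, :1]
    return grads


def forward_shallow(model: RecursiveREDModel, x: np.ndarray) -> np.ndarray:
    """Single pass of the shared shallow network on an input with
    ``config.input_channels`` channels."""
    xb = _as_batch(x, model.config.input_channels)
    out, _ = _shallow_forward(model, xb)
    return out[0, 0] if np.asarray(x).ndim == 2 else out


# ---------------------------------------------------------------------------
# HU normalization

def normalize_hu(hu: np.ndarray, window: tuple[float, float] = HU_WINDOW) -> np.ndarray:
    """Affine map of the HU display window onto [0, 1] (values may exceed it)."""
    lo, hi = window
    return (np.asarray(hu, dtype=np.float64) - lo) / (hi - lo)


def denormalize_hu(x: np.ndarray, window: tuple[float, float] = HU_WINDOW) -> np.ndarray:
    lo, hi = window
    return np.asarray(x, dtype=np.float64) * (hi - lo) + lo


def denoise_image(model: RecursiveREDModel, image, window=HU_WINDOW):
    """Denoise a :class:`~redct.synthetic_ct.CTImage` end to end."""
    from .synthetic_ct import CTImage

    x = normalize_hu(image.values, window)
    out, _ = forward_recursive(model, x)
    return CTImage(denormalize_hu(out[0, 0], window),
                   pixel_spacing=image.pixel_spacing)


# ---------------------------------------------------------------------------
# complexity

def complexity(config: REDConfig, S: int = 1) -> int:
    """Operation-count measure: sum over layers of n_{l-1} * f_l^2 * n_l,
    multiplied by the recursion count (the shared network runs S times)."""
    seq = config.channel_sequence()
    f2 = config.kernel_size ** 2
    per_pass = sum(seq[l - 1] * f2 * seq[l] for l in range(1, len(seq)))
    return int(per_pass * S)


# ---------------------------------------------------------------------------
# checkpoints

class CheckpointError(RuntimeError):
    """Raised when a checkpoint file is unreadable or inconsistent."""


def save_checkpoint(path, model: RecursiveREDModel, iteration: int = 0,
                    optimizer_state: dict | None = None) -> None:
    """Write a self-describing checkpoint (config, S, seed, iteration,
    parameters, optional optimizer moments)."""
    meta = dict(config=asdict(model.config), S=model.S, seed=model.seed,
                iteration=iteration, format_version=1)
    arrays = {}
    for i, (w, b) in enumerate(model.enc):
        arrays[f"enc_w_{i}"] = w
        arrays[f"enc_b_{i}"] = b
    for i, (w, b) in enumerate(model.dec):
        arrays[f"dec_w_{i}"] = w
        arrays[f"dec_b_{i}"] = b
    if optimizer_state is not None:
        for key, arrs in optimizer_state.items():
            for i, a in enumerate(arrs):
                arrays[f"opt_{key}_{i}"] = a
        meta["optimizer_arrays"] = {k: len(v) for k, v in optimizer_state.items()}
    with open(path, "wb") as fh:
        np.savez(fh, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)


def load_checkpoint(path) -> tuple[RecursiveREDModel, int, dict | None]:
    """Read a checkpoint; returns (model, iteration, optimizer_state)."""
    try:
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            cfg = REDConfig(**meta["config"])
            m = cfg.n_half
            enc = [(data[f"enc_w_{i}"], data[f"enc_b_{i}"]) for i in range(m)]
            dec = [(data[f"dec_w_{i}"], data[f"dec_b_{i}"]) for i in range(m)]
            opt = None
            if "optimizer_arrays" in meta:
                opt = {k: [data[f"opt_{k}_{i}"] for i in range(n)]
                       for k, n in meta["optimizer_arrays"].items()}
    except CheckpointError:
        raise
    except Exception as exc:
        raise CheckpointError(f"cannot load checkpoint {path}: {exc}") from exc
    model = RecursiveREDModel(config=cfg, enc=enc, dec=dec, S=meta["S"],
                              seed=meta["seed"])
    return model, meta["iteration"], opt
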