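"""Patch-based training of the recursive network with the joint loss.

Defaults document the reference protocol — learning rate 1e-5, 48x48
patches, checkpoints every 1,000 iterations, stop at 50,000 — while the
test suite and worked examples run a scaled-down profile (smaller patches,
narrower network, a few hundred iterations) that exercises the identical
code path on a single CPU. The optimizer is Adam by default; plain SGD is
available as a config choice.

Reproducibility contract: the minibatch drawn at iteration ``i`` depends
only on (seed, i), so a run of N iterations and a run of N/2 iterations
resumed for N/2 more produce identical parameter trajectories.
"""

from __future__ import annotations

import os
import time
from dataclasses import dataclass, field

import numpy as np

from .losses import FeatureExtractor, joint_loss_grad
from .red_model import (
    RecursiveREDModel, ModelGrads, backward_recursive, forward_recursive,
    normalize_hu, save_checkpoint, load_checkpoint, HU_WINDOW,
)

__all__ = ["TrainConfig", "TrainLog", "train", "resume", "toy_train_config"]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-5
    max_iterations: int = 50_000
    checkpoint_every: int = 1_000
    batch_size: int = 32
    patch_size: int = 48
    seed: int = 0
    perceptual_weight: float = 1.0
    optimizer: str = "adam"            # "adam" | "sgd"
    extractor_seed: int = 7
    checkpoint_dir: str | None = None
    hu_window: tuple[float, float] = HU_WINDOW

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.checkpoint_every > self.max_iterations:
            raise ValueError("checkpoint_every must not exceed max_iterations")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


def toy_train_config(seed: int = 0, iterations: int = 300,
                     checkpoint_dir: str | None = None) -> TrainConfig:
    """Desk-scale profile used by the worked examples and the test suite."""
    return TrainConfig(learning_rate=1e-3, max_iterations=iterations,
                       checkpoint_every=max(1, iterations // 3),
                       batch_size=16, patch_size=32, seed=seed,
                       checkpoint_dir=checkpoint_dir)


@dataclass
class TrainLog:
    iterations: list = field(default_factory=list)
    joint: list = field(default_factory=list)
    mse: list = field(default_factory=list)
    perceptual: list = field(default_factory=list)
    timestamps: list = field(default_factory=list)
    checkpoints: list = field(default_factory=list)

    def record(self, iteration: int, report) -> None:
        self.iterations.append(iteration)
        self.joint.append(report.joint)
        self.mse.append(report.mse_term)
        self.perceptual.append(report.perceptual_term)
        self.timestamps.append(time.time())


class _Adam:
    def __init__(self, shapes, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]

    def step(self, params, grads):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def state(self):
        return {"m": self.m, "v": self.v,
                "t": [np.array([self.t], dtype=np.int64)]}

    def load_state(self, state):
        self.m = [np.asarray(a, dtype=np.float64) for a in state["m"]]
        self.v = [np.asarray(a, dtype=np.float64) for a in state["v"]]
        self.t = int(state["t"][0][0])


class _SGD:
    def __init__(self, shapes, lr):
        self.lr = lr
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for p, g in zip(params, grads):
            p -= self.lr * g

    def state(self):
        return {"t": [np.array([self.t], dtype=np.int64)]}

    def load_state(self, state):
        self.t = int(state["t"][0][0])


def _make_optimizer(config: TrainConfig, model: RecursiveREDModel):
    shapes = [a.shape for a in model.parameter_arrays()]
    if config.optimizer == "adam":
        return _Adam(shapes, config.learning_rate)
    return _SGD(shapes, config.learning_rate)


def _stack_patches(patches, config):
    noisy = np.stack([normalize_hu(p.noisy, config.hu_window) for p in patches])
    clean = np.stack([normalize_hu(p.clean, config.hu_window) for p in patches])
    return noisy[:, None], clean[:, None]


def _run(model, noisy, clean, config, extractor, optimizer, log,
         start_iteration):
    params = model.parameter_arrays()
    n = noisy.shape[0]
    for it in range(start_iteration + 1, config.max_iterations + 1):
        # batch depends only on (seed, iteration) so resumed runs line up
        rng = np.random.default_rng([config.seed, it])
        idx = rng.integers(0, n, size=min(config.batch_size, n))
        xb, yb = noisy[idx], clean[idx]
        out, _, caches = forward_recursive(model, xb, keep_caches=True)
        report, d_out = joint_loss_grad(out, yb, extractor,
                                        config.perceptual_weight)
        if not np.isfinite(report.joint):
            raise FloatingPointError(
                f"non-finite joint loss at iteration {it}: {report.joint}")
        grads = backward_recursive(model, caches, d_out)
        optimizer.step(params, grads.arrays())
        log.record(it, report)
        if config.checkpoint_dir and it % config.checkpoint_every == 0:
            path = os.path.join(config.checkpoint_dir, f"checkpoint_{it:07d}.npz")
            save_checkpoint(path, model, iteration=it,
                            optimizer_state=optimizer.state())
            log.checkpoints.append(path)
    return model, log


def train(model: RecursiveREDModel, patches, config: TrainConfig):
    """Optimize the shared parameters on noisy/clean patch pairs.

    Returns (trained model, TrainLog). The model is updated in place and
    also returned. Raises on an empty patch set, patches that do not match
    ``config.patch_size``, or a non-finite loss.
    """
    if not patches:
        raise ValueError("patch set is empty")
    for p in patches:
        if p.noisy.shape != (config.patch_size, config.patch_size):
            raise ValueError(
                f"patch shape {p.noisy.shape} does not match "
                f"config.patch_size={config.patch_size}")
    if config.checkpoint_dir:
        os.makedirs(config.checkpoint_dir, exist_ok=True)
    extractor = FeatureExtractor.seeded(config.extractor_seed)
    optimizer = _make_optimizer(config, model)
    noisy, clean = _stack_patches(patches, config)
    return _run(model, noisy, clean, config, extractor, optimizer,
                TrainLog(), start_iteration=0)


def resume(checkpoint_path, patches, config: TrainConfig):
    """Continue training from a checkpoint up to ``config.max_iterations``."""
    model, iteration, opt_state = load_checkpoint(checkpoint_path)
    if not patches:
        raise ValueError("patch set is empty")
    if config.checkpoint_dir:
        os.makedirs(config.checkpoint_dir, exist_ok=True)
    extractor = FeatureExtractor.seeded(config.extractor_seed)
    optimizer = _make_optimizer(config, model)
    if opt_state is not None:
        optimizer.load_state(opt_state)
    noisy, clean = _stack_patches(patches, config)
    return _run(model, noisy, clean, config, extractor, optimizer,
                TrainLog(), start_iteration=iteration)
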