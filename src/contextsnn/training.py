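"""Two-phase surrogate-gradient training (BPTT) with perturbation injection.

Phase 1 (*pretrain*) trains the base network on clean weights, then freezes
the batch-normalization statistics so later perturbations cannot leak into
the normalization constants.  Phase 2 (*adapt*) continues training one of
the experimental variants: per mini-batch a context level is sampled
uniformly from the discrete grid restricted to [0, c_max]; variants that
carry perturbations receive a fresh noise realization frozen for the whole
batch (the gradient flows through the perturbed weights back to the ideal
weights, never into the noise); variants that carry modulation train the
projection vectors p jointly with the weights.

The optimizer is stochastic gradient descent with momentum (lr 0.001,
momentum 0.9) and a plateau schedule that halves the learning rate after 10
epochs without improvement.  All randomness (shuffling, context sampling,
draw seeds) derives from one seeded generator, so identical seeds reproduce
training bit-exactly on one thread.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .architectures import SpikingConvNet
from .perturbation import (
    DosePerturbationSpec,
    PerturbationDraw,
    PerturbationSpec,
    default_level_grid,
)

__all__ = [
    "TrainConfig",
    "SGD",
    "PlateauSchedule",
    "trial_loss",
    "pretrain",
    "adapt_train",
    "copy_weights_from",
]


@dataclass
class TrainConfig:
    """Hyperparameters of one training phase."""

    phase: str = "pretrain"  # "pretrain" | "adapt"
    epochs: int = 100
    lr: float = 0.001
    momentum: float = 0.9
    plateau_patience: int = 10
    plateau_factor: float = 0.5
    batch_size: int = 64
    c_max: float = 1.0
    context_sampling: str = "uniform"  # "uniform" | "fixed_max"
    grad_clip: float | None = 5.0  # global gradient-norm ceiling
    level_grid: np.ndarray = field(default_factory=default_level_grid)
    perturbation_model: str = "gaussian"  # "gaussian" | "dose"
    dose_spec: DosePerturbationSpec | None = None
    seed: int = 0
    log_path: str | None = None

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        self.level_grid = np.asarray(self.level_grid, dtype=float)
        if self.phase == "adapt" and not np.any(
            np.isclose(self.level_grid, self.c_max)
        ):
            raise ValueError(f"c_max={self.c_max} is not on the level grid")
        if self.context_sampling not in ("uniform", "fixed_max"):
            raise ValueError(f"unknown context sampling {self.context_sampling!r}")


class SGD:
    """Momentum SGD over a named parameter dict, with optional global
    gradient-norm clipping (BPTT through spiking recurrence produces
    occasional spikes in gradient magnitude)."""

    def __init__(self, params: dict[str, Tensor], lr: float, momentum: float = 0.9,
                 grad_clip: float | None = None):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.grad_clip = grad_clip
        self._buffers = {k: np.zeros_like(t.data) for k, t in params.items()}

    def zero_grad(self) -> None:
        for t in self.params.values():
            t.grad = None

    def _clip(self) -> None:
        total = 0.0
        for t in self.params.values():
            if t.grad is not None:
                total += float((t.grad.astype(np.float64) ** 2).sum())
        norm = np.sqrt(total)
        if norm > self.grad_clip:
            scale = self.grad_clip / norm
            for t in self.params.values():
                if t.grad is not None:
                    t.grad = t.grad * scale

    def step(self) -> None:
        if self.grad_clip is not None:
            self._clip()
        for name, t in self.params.items():
            if t.grad is None:
                continue
            buf = self._buffers[name]
            buf *= self.momentum
            buf += t.grad
            t.data = t.data - self.lr * buf


class PlateauSchedule:
    """Halve the learning rate after ``patience`` non-improving epochs."""

    def __init__(self, optimizer: SGD, patience: int = 10, factor: float = 0.5):
        self.optimizer = optimizer
        self.patience = patience
        self.factor = factor
        self.best = np.inf
        self.stall = 0

    def step(self, metric: float) -> float:
        if metric < self.best - 1.0e-12:
            self.best = metric
            self.stall = 0
        else:
            self.stall += 1
            if self.stall > self.patience:
                self.optimizer.lr *= self.factor
                self.stall = 0
        return self.optimizer.lr


def trial_loss(network: SpikingConvNet, outputs, targets) -> Tensor:
    """Cross-entropy on final-step logits, or per-step MSE for tracking."""
    if network.config.task_head == "classification":
        return ad.cross_entropy_logits(outputs, np.asarray(targets))
    diff = outputs - np.asarray(targets, dtype=np.float32)
    return (diff * diff).mean()


def _epoch_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def _log(records: list[dict], path: str | None, entry: dict) -> None:
    records.append(entry)
    if path is not None:
        with open(path, "a") as fh:
            fh.write(json.dumps(entry) + "\n")


def _run_phase(
    network: SpikingConvNet,
    frames: np.ndarray,
    targets: np.ndarray,
    config: TrainConfig,
    batch_setup: Callable[[np.random.Generator], tuple[float, PerturbationDraw | None,
                                                       PerturbationSpec | None]],
) -> list[dict]:
    params = network.named_parameters(trainable_only=True)
    optimizer = SGD(params, config.lr, config.momentum,
                    grad_clip=config.grad_clip)
    schedule = PlateauSchedule(optimizer, config.plateau_patience,
                               config.plateau_factor)
    # independent streams: batch shuffling vs context/perturbation draws, so
    # variants that consume different amounts of draw randomness still see
    # identical batch orderings
    shuffle_rng, draw_rng = [
        np.random.default_rng(s)
        for s in np.random.SeedSequence(config.seed).spawn(2)
    ]
    history: list[dict] = []
    for epoch in range(config.epochs):
        losses = []
        for idx in _epoch_batches(len(frames), config.batch_size, shuffle_rng):
            c, draw, spec = batch_setup(draw_rng)
            optimizer.zero_grad()
            out = network.forward(frames[idx], c=c, draw=draw, perturbation=spec,
                                  reset=True)
            loss = trial_loss(network, out, targets[idx])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged (non-finite loss) at epoch {epoch}, "
                    f"seed {config.seed}"
                )
            loss.backward()
            optimizer.step()
            losses.append(float(loss.data))
        mean_loss = float(np.mean(losses))
        lr = schedule.step(mean_loss)
        _log(history, config.log_path,
             {"epoch": epoch, "loss": mean_loss, "lr": lr})
    return history


def pretrain(network: SpikingConvNet, frames: np.ndarray, targets: np.ndarray,
             config: TrainConfig) -> list[dict]:
    """Phase 1: train the base network clean, then freeze normalization."""
    if network.variant.name != "base":
        raise ValueError("pretraining runs on the base variant only")

    def batch_setup(rng):
        return 0.0, None, None

    history = _run_phase(network, frames, targets, config, batch_setup)
    network.freeze_normalization()
    return history


def adapt_train(network: SpikingConvNet, frames: np.ndarray, targets: np.ndarray,
                config: TrainConfig) -> list[dict]:
    """Phase 2: variant-specific training with context sampling.

    The network should carry pretrained weights (see
    :func:`contextsnn.architectures.load_checkpoint` /
    ``copy_weights_from``).  Per batch: sample c from the grid restricted to
    [0, c_max]; draw fresh frozen perturbation noise if the variant carries
    perturbations; pass c to the modulation if the variant carries it (sham
    receives the same sampled c as context models).
    """
    levels = config.level_grid[config.level_grid <= config.c_max + 1.0e-12]
    if levels.size == 0:
        raise ValueError("no context levels at or below c_max")
    perturbing = network.variant.perturbation

    def batch_setup(rng):
        if config.context_sampling == "fixed_max":
            c = float(config.c_max)
        else:
            c = float(levels[rng.integers(levels.size)])
        draw = spec = None
        if perturbing:
            draw = PerturbationDraw(int(rng.integers(2**31)))
            spec = PerturbationSpec(model=config.perturbation_model, level=c,
                                    dose_spec=config.dose_spec)
        return c, draw, spec

    return _run_phase(network, frames, targets, config, batch_setup)


def copy_weights_from(target: SpikingConvNet, source: SpikingConvNet) -> None:
    """Copy weights and normalization statistics between variant networks.

    Modulation projections present only in the target (sham/context) keep
    their own initialization; everything shared is copied.
    """
    src = source.named_parameters()
    for name, tensor in target.named_parameters().items():
        if name in src:
            tensor.data = src[name].data.copy()
    for tb, sb in zip(target.blocks, source.blocks):
        if tb.bn_mean is not None and sb.bn_mean is not None:
            tb.bn_mean = sb.bn_mean.copy()
            tb.bn_var = sb.bn_var.copy()
            tb.bn_frozen = sb.bn_frozen
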