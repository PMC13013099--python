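"""Synthetic desk-scale datasets: small-object tracking and toy frame classes.

The small-object-tracking (SOT) generator emulates a remote-sensing video:
a single bright pixel moves over a static cluttered background with
constant velocity plus Gaussian positional jitter, reflecting off the frame
boundaries, for T timesteps; the regression target is the continuous (x, y)
track.  The toy classification generator produces procedurally patterned
frames per class (a stand-in for natural-image classification so the
static-frame pipeline runs without downloads); a nearest-template observer
reaches ~100% at zero noise.

Every dataset carries its config and seed, and regeneration from them is
bit-exact.  Coordinates are (x, y) = (column, row), zero-based; the track is
continuous and only rounded for rendering, and tracking error is measured as
MSE in pixel units on the continuous coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import h5py
import numpy as np

__all__ = [
    "SOTConfig",
    "SOTSample",
    "ToyClassConfig",
    "generate_sot",
    "sot_to_arrays",
    "generate_toy_classification",
    "class_templates",
    "train_test_split_indices",
    "save_sot_dataset",
    "load_sot_dataset",
]


@dataclass
class SOTConfig:
    """Generator knobs for the single-pixel tracking task."""

    height: int = 16
    width: int = 16
    n_timesteps: int = 100
    contrast: float = 2.0
    background_amplitude: float = 0.3
    noise_sigma: float = 0.05
    speed: float = 0.7  # pixels per frame
    jitter_sigma: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_timesteps < 2:
            raise ValueError("n_timesteps must be at least 2")
        if self.contrast <= 0:
            raise ValueError("contrast must be positive")


@dataclass
class SOTSample:
    """One trial: frames (T, H, W) and the continuous track (T, 2) as (x, y)."""

    frames: np.ndarray
    track: np.ndarray


def _reflect(pos: float, lo: float, hi: float) -> float:
    """Reflect a coordinate into [lo, hi] (billiard boundary)."""
    span = hi - lo
    x = (pos - lo) % (2 * span)
    return lo + (x if x <= span else 2 * span - x)


def generate_sot(config: SOTConfig, n_samples: int) -> list[SOTSample]:
    """Generate ``n_samples`` independent tracking trials, seeded."""
    rng = np.random.default_rng(config.seed)
    h, w, t_steps = config.height, config.width, config.n_timesteps
    samples = []
    for _ in range(n_samples):
        background = config.background_amplitude * rng.random((h, w))
        x = rng.uniform(1.0, w - 2.0)
        y = rng.uniform(1.0, h - 2.0)
        theta = rng.uniform(0, 2 * np.pi)
        vx, vy = config.speed * np.cos(theta), config.speed * np.sin(theta)
        frames = np.empty((t_steps, h, w), dtype=np.float32)
        track = np.empty((t_steps, 2), dtype=np.float32)
        for t in range(t_steps):
            x = _reflect(x + vx + rng.normal(0, config.jitter_sigma), 0.0, w - 1.0)
            y = _reflect(y + vy + rng.normal(0, config.jitter_sigma), 0.0, h - 1.0)
            frame = background + rng.normal(0, config.noise_sigma, (h, w))
            col, row = int(round(x)), int(round(y))
            frame[row, col] = background[row, col] + config.contrast
            frames[t] = frame
            track[t] = (x, y)
        samples.append(SOTSample(frames=frames, track=track))
    return samples


def sot_to_arrays(samples: list[SOTSample]) -> tuple[np.ndarray, np.ndarray]:
    """Stack samples into network inputs (N, T, 1, H, W) and targets (N, T, 2)."""
    frames = np.stack([s.frames for s in samples])[:, :, None, :, :]
    tracks = np.stack([s.track for s in samples])
    return frames, tracks


@dataclass
class ToyClassConfig:
    """Generator knobs for the procedural frame-classification task."""

    n_classes: int = 3
    height: int = 12
    width: int = 12
    noise_sigma: float = 0.2
    n_timesteps: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")


def class_templates(config: ToyClassConfig) -> np.ndarray:
    """Pairwise-distinct procedural patterns, one (H, W) template per class."""
    h, w = config.height, config.width
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    yy, xx = yy / max(h - 1, 1), xx / max(w - 1, 1)
    templates = []
    for k in range(config.n_classes):
        freq = 1.0 + k
        phase = 2 * np.pi * k / config.n_classes
        pattern = np.sin(2 * np.pi * freq * xx + phase) * np.cos(
            2 * np.pi * (k % 3 + 1) * yy
        )
        templates.append(pattern.astype(np.float32))
    return np.stack(templates)


def generate_toy_classification(
    config: ToyClassConfig, n_samples: int
) -> tuple[np.ndarray, np.ndarray]:
    """Class-balanced noisy template frames.

    Returns frames (N, T, 1, H, W) — the static frame repeated for the
    presentation window — and integer labels (N,).  Classes are assigned
    round-robin so the label histogram is uniform up to remainder.
    """
    rng = np.random.default_rng(config.seed)
    templates = class_templates(config)
    labels = np.arange(n_samples) % config.n_classes
    labels = rng.permutation(labels)
    static = templates[labels] + rng.normal(
        0, config.noise_sigma, (n_samples, config.height, config.width)
    ).astype(np.float32)
    frames = np.repeat(
        static[:, None, None, :, :], config.n_timesteps, axis=1
    ).astype(np.float32)
    return frames, labels.astype(np.int64)


def train_test_split_indices(n: int, test_fraction: float = 0.2,
                             seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint 80/20 split by sample index, seeded."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_test = max(1, int(round(n * test_fraction)))
    return np.sort(order[n_test:]), np.sort(order[:n_test])


# -- persistence -------------------------------------------------------------


def save_sot_dataset(path, samples: list[SOTSample], config: SOTConfig) -> None:
    frames, tracks = sot_to_arrays(samples)
    with h5py.File(path, "w") as f:
        f.create_dataset("frames", data=frames[:, :, 0])
        f.create_dataset("tracks", data=tracks)
        f.attrs["config"] = json.dumps(asdict(config))


def load_sot_dataset(path) -> tuple[list[SOTSample], SOTConfig]:
    with h5py.File(path, "r") as f:
        frames = f["frames"][()]
        tracks = f["tracks"][()]
        config = SOTConfig(**json.loads(f.attrs["config"]))
    samples = [SOTSample(frames=fr, track=tr) for fr, tr in zip(frames, tracks)]
    return samples, config
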