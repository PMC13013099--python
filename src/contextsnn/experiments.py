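"""Desk-scale experiment presets tying the modules into runnable studies.

These functions reproduce, at desk scale on one CPU, the qualitative
findings of the full study: perturbation degrades task performance; a
context-modulated recurrent network trained across perturbation levels
recovers much of it; a feedforward network does not benefit the same way.
Problem sizes (frame size, sample counts, channel widths, epochs) are the
package's tiny preset — small enough that the whole pipeline, including
training every variant over several seeds, runs in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .architectures import build_network, save_checkpoint, tiny_config
from .perturbation import default_level_grid
from .sweep import checkpoint_name, evaluate
from .tasks import (
    SOTConfig,
    ToyClassConfig,
    generate_sot,
    generate_toy_classification,
    sot_to_arrays,
    train_test_split_indices,
)
from .training import TrainConfig, adapt_train, copy_weights_from, pretrain

__all__ = [
    "RecoveryConfig",
    "recovery_experiment",
    "LatentConfig",
    "latent_experiment",
    "train_grid_checkpoints",
]


@dataclass
class RecoveryConfig:
    """Tiny small-object-tracking recovery study (one topology)."""

    topology: str = "recurrent"
    height: int = 16
    width: int = 16
    n_timesteps: int = 50
    n_train: int = 24
    n_test: int = 8
    widths: tuple[int, ...] = (4, 8, 16)
    pretrain_epochs: int = 50
    adapt_epochs: int = 40
    batch_size: int = 8
    lr: float = 0.003
    level_grid: np.ndarray = field(default_factory=lambda: default_level_grid(4))
    c_max: float = 1.0
    seeds: tuple[int, ...] = (0, 1, 2)
    mod_modes: tuple[str, ...] = ("threshold", "tau")
    test_levels: tuple[float, ...] = (0.0, 1.0)
    n_eval_draws: int = 5
    base_seed: int = 0


def _sot_data(cfg: RecoveryConfig):
    sot_cfg = SOTConfig(
        height=cfg.height, width=cfg.width, n_timesteps=cfg.n_timesteps,
        seed=cfg.base_seed + 7919,
    )
    samples = generate_sot(sot_cfg, cfg.n_train + cfg.n_test)
    frames, tracks = sot_to_arrays(samples)
    train_idx, test_idx = train_test_split_indices(
        len(samples), test_fraction=cfg.n_test / (cfg.n_train + cfg.n_test),
        seed=cfg.base_seed + 13,
    )
    return (frames[train_idx], tracks[train_idx],
            frames[test_idx], tracks[test_idx])


def recovery_experiment(cfg: RecoveryConfig, checkpoint_dir=None) -> dict:
    """Pretrain + adapt the perturbed and context variants, evaluate both.

    Returns a dict with a long-format ``mse`` frame (columns: topology,
    variant, mod, seed, test_level, mse) and the learned projection vectors
    per (mod_mode, seed) for downstream parameter statistics.
    """
    tr_frames, tr_tracks, te_frames, te_tracks = _sot_data(cfg)
    net_cfg = tiny_config(cfg.topology, "tracking",
                          (1, cfg.height, cfg.width), 2, widths=cfg.widths)
    rows = []
    p_vectors: dict[tuple[str, int], np.ndarray] = {}
    for seed in cfg.seeds:
        base = build_network(net_cfg, "base", None, seed=cfg.base_seed + seed)
        pretrain(base, tr_frames, tr_tracks, TrainConfig(
            phase="pretrain", epochs=cfg.pretrain_epochs, lr=cfg.lr,
            batch_size=cfg.batch_size, seed=cfg.base_seed + seed,
        ))

        jobs = [("perturbed", None)]
        jobs += [("context", m) for m in cfg.mod_modes]
        for variant, mod in jobs:
            net = build_network(net_cfg, variant, mod, seed=cfg.base_seed + seed)
            copy_weights_from(net, base)
            history = adapt_train(net, tr_frames, tr_tracks, TrainConfig(
                phase="adapt", epochs=cfg.adapt_epochs, lr=cfg.lr,
                batch_size=cfg.batch_size, c_max=cfg.c_max,
                level_grid=cfg.level_grid, seed=cfg.base_seed + seed + 101,
            ))
            final_train_loss = history[-1]["loss"]
            if checkpoint_dir is not None:
                save_checkpoint(
                    net,
                    Path(checkpoint_dir) / checkpoint_name(variant, mod,
                                                           cfg.c_max, seed),
                    manifest={"variant": variant, "mod_mode": mod,
                              "seed": seed, "train_c_max": cfg.c_max,
                              "topology": cfg.topology},
                )
            for level in cfg.test_levels:
                mse = evaluate(net, te_frames, te_tracks, level,
                               n_draws=cfg.n_eval_draws, seed=seed)
                rows.append({"topology": cfg.topology, "variant": variant,
                             "mod": mod or "none", "seed": seed,
                             "test_level": level, "mse": mse,
                             "final_train_loss": final_train_loss})
            if variant == "context":
                p_vectors[(mod, seed)] = np.concatenate(
                    [v.ravel() for v in net.projection_vectors().values()]
                )
    return {"mse": pd.DataFrame(rows), "p_vectors": p_vectors,
            "config": cfg}


def recovery_summary(mse_frame: pd.DataFrame) -> pd.DataFrame:
    """Seed-mean MSE per (topology, variant, mod, test_level)."""
    return (mse_frame.groupby(["topology", "variant", "mod", "test_level"])
            ["mse"].mean().reset_index())


@dataclass
class LatentConfig:
    """Tiny recurrent classification study for latent trajectory analysis."""

    n_classes: int = 3
    height: int = 12
    width: int = 12
    n_timesteps: int = 32
    noise_sigma: float = 0.3
    n_train: int = 60
    n_test: int = 15
    widths: tuple[int, ...] = (4, 8)
    pretrain_epochs: int = 15
    adapt_epochs: int = 25
    batch_size: int = 8
    lr: float = 0.01
    mod_mode: str = "tau"
    n_separation_draws: int = 3
    level_grid: np.ndarray = field(default_factory=lambda: default_level_grid(4))
    c_max: float = 1.0
    seeds: tuple[int, ...] = (0, 1, 2)
    contexts: tuple[float, ...] = (0.0, 0.2, 1.0)
    base_seed: int = 0


def latent_experiment(cfg: LatentConfig) -> dict:
    """Train perturbed and context recurrent classifiers, record
    penultimate-layer potentials, and score final-position class separation.

    The separation score per (variant, seed) at the highest context level is
    averaged over ``n_separation_draws`` frozen perturbation draws.  Returns
    the per-(variant, seed, context) trajectory records, the per-variant
    hold-out accuracy at the level-grid extremes, and the separation table.
    """
    from .latent import class_separation, pca_trajectories, record_trajectories

    toy_cfg = ToyClassConfig(
        n_classes=cfg.n_classes, height=cfg.height, width=cfg.width,
        n_timesteps=cfg.n_timesteps, noise_sigma=cfg.noise_sigma,
        seed=cfg.base_seed + 7919,
    )
    frames, labels = generate_toy_classification(
        toy_cfg, cfg.n_train + cfg.n_test)
    train_idx, test_idx = train_test_split_indices(
        len(labels), test_fraction=cfg.n_test / (cfg.n_train + cfg.n_test),
        seed=cfg.base_seed + 13,
    )
    tr_f, tr_y = frames[train_idx], labels[train_idx]
    te_f, te_y = frames[test_idx], labels[test_idx]

    net_cfg = tiny_config("recurrent", "classification",
                          (1, cfg.height, cfg.width), cfg.n_classes,
                          widths=cfg.widths)
    scores = []
    accuracy_rows = []
    records = {}
    top = max(cfg.contexts)
    for seed in cfg.seeds:
        base = build_network(net_cfg, "base", None, seed=cfg.base_seed + seed)
        pretrain(base, tr_f, tr_y, TrainConfig(
            phase="pretrain", epochs=cfg.pretrain_epochs, lr=cfg.lr,
            batch_size=cfg.batch_size, seed=cfg.base_seed + seed,
        ))
        for variant, mod in [("perturbed", None), ("context", cfg.mod_mode)]:
            net = build_network(net_cfg, variant, mod, seed=cfg.base_seed + seed)
            copy_weights_from(net, base)
            adapt_train(net, tr_f, tr_y, TrainConfig(
                phase="adapt", epochs=cfg.adapt_epochs, lr=cfg.lr,
                batch_size=cfg.batch_size, c_max=cfg.c_max,
                level_grid=cfg.level_grid, seed=cfg.base_seed + seed + 101,
            ))
            for level in (0.0, top):
                accuracy_rows.append({
                    "variant": variant, "seed": seed, "test_level": level,
                    "accuracy": evaluate(net, te_f, te_y, level, n_draws=5,
                                         seed=cfg.base_seed + seed),
                })
            records[(variant, seed)] = record_trajectories(
                net, te_f, te_y, contexts=cfg.contexts,
                draw_seed=cfg.base_seed + seed,
            )
            draw_scores = []
            for d in range(cfg.n_separation_draws):
                recs = record_trajectories(
                    net, te_f, te_y, contexts=(top,),
                    draw_seed=cfg.base_seed + seed * 17 + d,
                )
                emb = pca_trajectories(recs[top])
                draw_scores.append(class_separation(emb, te_y))
            scores.append({"variant": variant, "seed": seed, "context": top,
                           "separation": float(np.mean(draw_scores))})
    return {"scores": pd.DataFrame(scores),
            "accuracy": pd.DataFrame(accuracy_rows),
            "records": records, "test_labels": te_y, "config": cfg}


def train_grid_checkpoints(
    checkpoint_dir,
    combos: list[tuple[str, str | None]],
    c_max_list: list[float],
    seeds: list[int],
    level_grid: np.ndarray | None = None,
    epochs: int = 2,
    base_seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Train ultra-tiny feedforward classifiers for sweep-machinery studies.

    One checkpoint per (variant/mod, c_max, seed); returns the hold-out
    evaluation frames and labels.
    """
    checkpoint_dir = Path(checkpoint_dir)
    checkpoint_dir.mkdir(parents=True, exist_ok=True)
    if level_grid is None:
        level_grid = default_level_grid(4)
    toy_cfg = ToyClassConfig(n_classes=2, height=8, width=8, n_timesteps=8,
                             seed=base_seed + 7919)
    frames, labels = generate_toy_classification(toy_cfg, 30)
    train_idx, test_idx = train_test_split_indices(30, seed=base_seed + 13)
    tr_f, tr_y = frames[train_idx], labels[train_idx]
    net_cfg = tiny_config("feedforward", "classification", (1, 8, 8), 2,
                          widths=(4,))
    for seed in seeds:
        base = build_network(net_cfg, "base", None, seed=base_seed + seed)
        pretrain(base, tr_f, tr_y, TrainConfig(
            phase="pretrain", epochs=epochs, batch_size=8,
            seed=base_seed + seed))
        for variant, mod in combos:
            for c_max in c_max_list:
                net = build_network(net_cfg, variant, mod,
                                    seed=base_seed + seed)
                copy_weights_from(net, base)
                adapt_train(net, tr_f, tr_y, TrainConfig(
                    phase="adapt", epochs=epochs, batch_size=8, c_max=c_max,
                    level_grid=level_grid, seed=base_seed + seed + 101))
                save_checkpoint(net, checkpoint_dir / checkpoint_name(
                    variant, mod, c_max, seed))
    return frames[test_idx], labels[test_idx]
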