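"""Train x test perturbation-level grid evaluation.

Every trained checkpoint (one per variant, modulation mode, training
maximum level c_max, and seed) is evaluated at every test perturbation
level.  Each grid cell averages a handful of independent frozen
perturbation draws; per-draw values are retained in long format
(``variant, mod, cmax, test_level, seed, draw, metric``) so cell means over
seeds can be recomputed exactly.  Cells are cached by key: re-running a
sweep against an existing cache recomputes nothing and reproduces the
result bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .architectures import SpikingConvNet, load_checkpoint
from .perturbation import DosePerturbationSpec, PerturbationDraw, PerturbationSpec

__all__ = [
    "SweepGridResult",
    "evaluate",
    "checkpoint_name",
    "run_grid",
    "plot_grid",
]

_COLUMNS = ["variant", "mod", "cmax", "test_level", "seed", "draw", "metric"]


@dataclass
class SweepGridResult:
    """Long-format metric table plus provenance metadata."""

    frame: pd.DataFrame
    metric_name: str  # "accuracy" | "mse"
    metadata: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return len(self.frame.drop_duplicates(
            ["variant", "mod", "cmax", "test_level", "seed"]
        ))

    def cell_means(self) -> pd.DataFrame:
        """Mean metric per (variant, mod, cmax, test_level), averaged over
        draws then seeds."""
        per_seed = (
            self.frame.groupby(["variant", "mod", "cmax", "test_level", "seed"])
            ["metric"].mean().reset_index()
        )
        return (
            per_seed.groupby(["variant", "mod", "cmax", "test_level"])["metric"]
            .mean().reset_index()
        )

    def save(self, csv_path, manifest_path=None) -> None:
        # %.17g round-trips float64 exactly through text
        self.frame.to_csv(csv_path, index=False, float_format="%.17g")
        if manifest_path is not None:
            with open(manifest_path, "w") as fh:
                json.dump({"metric_name": self.metric_name,
                           "metadata": self.metadata}, fh, indent=2)

    @classmethod
    def load(cls, csv_path, manifest_path=None) -> "SweepGridResult":
        frame = pd.read_csv(csv_path, float_precision="round_trip")
        metric_name, metadata = "metric", {}
        if manifest_path is not None and Path(manifest_path).exists():
            with open(manifest_path) as fh:
                m = json.load(fh)
            metric_name, metadata = m["metric_name"], m["metadata"]
        return cls(frame=frame, metric_name=metric_name, metadata=metadata)


def _metric(network: SpikingConvNet, outputs, targets) -> float:
    data = outputs.data if hasattr(outputs, "data") else np.asarray(outputs)
    if network.config.task_head == "classification":
        return float((data.argmax(axis=1) == np.asarray(targets)).mean())
    diff = data - np.asarray(targets)
    return float(np.mean(diff**2))


def evaluate(
    network: SpikingConvNet,
    frames: np.ndarray,
    targets: np.ndarray,
    test_level: float,
    n_draws: int = 5,
    seed: int = 0,
    level_grid: np.ndarray | None = None,
    perturbation_model: str = "gaussian",
    dose_spec: DosePerturbationSpec | None = None,
    return_draws: bool = False,
):
    """Metric at one test perturbation level, averaged over frozen draws.

    The context input equals the test level for modulated variants; for
    variants without perturbation the draws are irrelevant and a single
    forward pass is used.  Top-1 accuracy for classification, MSE (pixels^2)
    for tracking.
    """
    if level_grid is not None and not np.any(np.isclose(level_grid, test_level)):
        raise ValueError(f"test level {test_level} is not on the level grid")
    values = []
    effective_draws = n_draws if network.variant.perturbation and test_level > 0 else 1
    for d in range(effective_draws):
        draw = spec = None
        if network.variant.perturbation:
            draw = PerturbationDraw(seed * 1009 + d)
            spec = PerturbationSpec(model=perturbation_model, level=test_level,
                                    dose_spec=dose_spec)
        out = network.forward(frames, c=test_level, draw=draw, perturbation=spec,
                              reset=True)
        values.append(_metric(network, out, targets))
    if return_draws:
        return values
    return float(np.mean(values))


def checkpoint_name(variant: str, mod_mode: str | None, c_max: float,
                    seed: int) -> str:
    return f"{variant}_{mod_mode or 'none'}_cmax{c_max:.3f}_seed{seed}.h5"


def run_grid(
    checkpoint_dir,
    combos: list[tuple[str, str | None]],
    c_max_list: list[float],
    test_levels: list[float],
    seeds: list[int],
    frames: np.ndarray,
    targets: np.ndarray,
    n_draws: int = 5,
    cache_path=None,
    perturbation_model: str = "gaussian",
    dose_spec: DosePerturbationSpec | None = None,
    metadata: dict | None = None,
) -> SweepGridResult:
    """Evaluate all (variant/mod, c_max, test level, seed) combinations.

    ``combos`` lists (variant, mod_mode) pairs.  Checkpoints are looked up
    in ``checkpoint_dir`` by :func:`checkpoint_name`; a missing checkpoint
    marks its cells absent and the run continues.  With ``cache_path`` the
    per-draw rows are cached and re-runs recompute only missing cells.
    """
    checkpoint_dir = Path(checkpoint_dir)
    cached = pd.DataFrame(columns=_COLUMNS)
    if cache_path is not None and Path(cache_path).exists():
        cached = pd.read_csv(cache_path, float_precision="round_trip")
    have = set(
        zip(cached["variant"], cached["mod"].fillna("none"),
            np.round(cached["cmax"], 9), np.round(cached["test_level"], 9),
            cached["seed"])
    ) if len(cached) else set()

    rows = []
    metric_name = None
    n_computed = 0
    for variant, mod_mode in combos:
        for c_max in c_max_list:
            for seed in seeds:
                path = checkpoint_dir / checkpoint_name(variant, mod_mode, c_max, seed)
                network = None
                for level in test_levels:
                    key = (variant, mod_mode or "none", round(c_max, 9),
                           round(level, 9), seed)
                    if key in have:
                        continue
                    if network is None:
                        if not path.exists():
                            break  # cells absent; continue with next combo
                        network, _ = load_checkpoint(path)
                        metric_name = ("accuracy" if network.config.task_head ==
                                       "classification" else "mse")
                    vals = evaluate(network, frames, targets, level,
                                    n_draws=n_draws, seed=seed,
                                    perturbation_model=perturbation_model,
                                    dose_spec=dose_spec, return_draws=True)
                    for d, v in enumerate(vals):
                        rows.append((variant, mod_mode or "none", c_max, level,
                                     seed, d, v))
                    n_computed += 1
    new = pd.DataFrame(rows, columns=_COLUMNS)
    if len(cached) and len(new):
        frame = pd.concat([cached, new], ignore_index=True)
    else:
        frame = cached if len(cached) else new
    if cache_path is not None and n_computed:
        frame.to_csv(cache_path, index=False, float_format="%.17g")
    if metric_name is None:
        metric_name = "accuracy" if len(frame) == 0 else "metric"
    meta = dict(metadata or {})
    meta.update({"n_draws": n_draws, "n_computed_cells": n_computed,
                 "perturbation_model": perturbation_model})
    return SweepGridResult(frame=frame, metric_name=metric_name, metadata=meta)


def plot_grid(result: SweepGridResult, path) -> None:
    """Heatmap per (variant, mod): training c_max (rows) x test level (cols)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    means = result.cell_means()
    panels = means[["variant", "mod"]].drop_duplicates().itertuples(index=False)
    panels = list(panels)
    fig, axes = plt.subplots(1, max(len(panels), 1),
                             figsize=(4 * max(len(panels), 1), 3.2), squeeze=False)
    for ax, (variant, mod) in zip(axes[0], panels):
        sub = means[(means["variant"] == variant) & (means["mod"] == mod)]
        pivot = sub.pivot(index="cmax", columns="test_level", values="metric")
        im = ax.imshow(pivot.to_numpy(), origin="lower", aspect="auto")
        ax.set_xticks(range(pivot.shape[1]),
                      [f"{v:g}" for v in pivot.columns])
        ax.set_yticks(range(pivot.shape[0]), [f"{v:g}" for v in pivot.index])
        ax.set_xlabel("test level")
        ax.set_ylabel("train c_max")
        ax.set_title(f"{variant} / {mod}")
        fig.colorbar(im, ax=ax, label=result.metric_name)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
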