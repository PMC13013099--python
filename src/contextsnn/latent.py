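"""Latent-state trajectory analysis and learned-parameter statistics.

To see *how* context modulation restores network function, we record the
sub-threshold (pre-reset) membrane potentials of the last spiking layer
during inference, embed them with PCA, and follow each trial's timecourse
through component space.  One PCA is fit per condition (variant x context
level) on the pooled (trial x timestep, unit) matrix, so trajectory
locations are comparable across trials within a condition; each component's
loading vector is sign-flipped so its largest-magnitude entry is positive,
making the embedding deterministic.  A silhouette score over the
final-timestep positions quantifies how uniquely each class lands in its
own region of latent space.

Learned projection vectors p are summarized per training level with
one-sample t tests against zero and pairwise two-sample Kolmogorov-Smirnov
tests, Bonferroni-corrected within each family of comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .architectures import SpikingConvNet
from .perturbation import DosePerturbationSpec, PerturbationDraw, PerturbationSpec

__all__ = [
    "TrajectoryRecord",
    "EmbeddingResult",
    "record_trajectories",
    "pca_trajectories",
    "class_separation",
    "p_distribution_stats",
]

DEFAULT_CONTEXTS = (0.0, 0.2, 1.0)


@dataclass
class TrajectoryRecord:
    """Pre-threshold membrane potentials, (trials, timesteps, units)."""

    potentials: np.ndarray
    labels: np.ndarray
    context: float
    variant: str
    draw_seed: int | None = None

    @property
    def degenerate(self) -> bool:
        """True when the record carries no activity at all (e.g. zero input)."""
        return bool(np.allclose(self.potentials, 0.0))

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("potentials", data=self.potentials)
            f.create_dataset("labels", data=self.labels)
            f.attrs["context"] = self.context
            f.attrs["variant"] = self.variant
            f.attrs["draw_seed"] = -1 if self.draw_seed is None else self.draw_seed

    @classmethod
    def load(cls, path) -> "TrajectoryRecord":
        with h5py.File(path, "r") as f:
            seed = int(f.attrs["draw_seed"])
            return cls(
                potentials=f["potentials"][()],
                labels=f["labels"][()],
                context=float(f.attrs["context"]),
                variant=str(f.attrs["variant"]),
                draw_seed=None if seed < 0 else seed,
            )


@dataclass
class EmbeddingResult:
    """PCA loadings, per-trial 2-D trajectories, explained variance."""

    components: np.ndarray  # (n_components, units)
    trajectories: np.ndarray  # (trials, timesteps, n_components)
    explained_variance_ratio: np.ndarray
    mean: np.ndarray


def record_trajectories(
    network: SpikingConvNet,
    frames: np.ndarray,
    labels: np.ndarray,
    contexts=DEFAULT_CONTEXTS,
    draw_seed: int = 0,
    perturbation_model: str = "gaussian",
    dose_spec: DosePerturbationSpec | None = None,
) -> dict[float, TrajectoryRecord]:
    """One trajectory record per context level.

    Each level's forward pass uses one frozen perturbation draw (a trial is
    an evaluation batch); the draw seed is logged in the record.  Degenerate
    (all-zero) records are flagged with a warning but still returned.
    """
    records: dict[float, TrajectoryRecord] = {}
    for c in contexts:
        draw = spec = None
        if network.variant.perturbation:
            draw = PerturbationDraw(draw_seed)
            spec = PerturbationSpec(model=perturbation_model, level=float(c),
                                    dose_spec=dose_spec)
        _, potentials = network.forward(
            frames, c=float(c), draw=draw, perturbation=spec, reset=True,
            record_penultimate=True,
        )
        rec = TrajectoryRecord(
            potentials=potentials,
            labels=np.asarray(labels),
            context=float(c),
            variant=network.variant.name,
            draw_seed=draw_seed if draw is not None else None,
        )
        if rec.degenerate:
            warnings.warn(
                f"trajectory record at context {c} is all-zero (degenerate)",
                stacklevel=2,
            )
        records[float(c)] = rec
    return records


def pca_trajectories(record: TrajectoryRecord, n_components: int = 2) -> EmbeddingResult:
    """Fit PCA on the pooled (trial x timestep, unit) matrix of one condition
    and project each trial's timecourse into component space."""
    trials, t_steps, units = record.potentials.shape
    if trials < 2:
        raise ValueError("need at least 2 trials for a PCA embedding")
    pooled = record.potentials.reshape(trials * t_steps, units)
    rank = np.linalg.matrix_rank(pooled - pooled.mean(axis=0))
    k = min(n_components, rank) if rank > 0 else 1
    if k < n_components:
        warnings.warn(
            f"rank-deficient input: returning {k} component(s) instead of "
            f"{n_components}", stacklevel=2,
        )
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(pooled)
    # sign convention: largest-|loading| entry of each component is positive
    flips = np.sign(
        pca.components_[np.arange(k), np.abs(pca.components_).argmax(axis=1)]
    )
    flips[flips == 0] = 1.0
    components = pca.components_ * flips[:, None]
    scores = scores * flips[None, :]
    return EmbeddingResult(
        components=components,
        trajectories=scores.reshape(trials, t_steps, k),
        explained_variance_ratio=pca.explained_variance_ratio_,
        mean=pca.mean_,
    )


def class_separation(embedding: EmbeddingResult, labels: np.ndarray) -> float:
    """Silhouette score of final-timestep trajectory positions by class.

    Near 1 when every class occupies its own unique final region of latent
    space, <= 0 when classes overlap or collapse onto the same point.
    Invariant to rigid rotations of the embedding (euclidean distances).
    """
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("class_separation needs at least 2 classes")
    finals = embedding.trajectories[:, -1, :]
    if np.allclose(finals, finals[0]):
        return 0.0  # all points coincide: no separation
    score = silhouette_score(finals, labels)
    return float(score) if np.isfinite(score) else 0.0


def p_distribution_stats(
    groups: dict[float, np.ndarray], alpha: float = 0.05
) -> dict[str, object]:
    """Location and distribution tests on learned projections by training level.

    Returns ``location`` (per group: mean, one-sample t vs 0, Bonferroni
    over the group family) and ``pairwise`` (two-sample Kolmogorov-Smirnov
    per group pair, Bonferroni over the pair family), plus the corrected
    alpha for each family.
    """
    if not groups:
        raise ValueError("need at least one group of projections")
    keys = sorted(groups)
    n_loc = len(keys)
    loc_rows = []
    for k in keys:
        p = np.asarray(groups[k], dtype=float).ravel()
        if p.size > 1 and np.ptp(p) > 0:
            t, pval = stats.ttest_1samp(p, 0.0)
        else:
            t, pval = 0.0, 1.0
        loc_rows.append({
            "group": k, "n": p.size, "mean": p.mean(), "std": p.std(ddof=1) if p.size > 1 else 0.0,
            "t": float(t), "p_raw": float(pval),
            "p_bonferroni": min(float(pval) * n_loc, 1.0),
            "significant": float(pval) * n_loc < alpha,
        })
    pair_rows = []
    pairs = [(a, b) for i, a in enumerate(keys) for b in keys[i + 1:]]
    n_pairs = max(len(pairs), 1)
    for a, b in pairs:
        ks, pval = stats.ks_2samp(np.ravel(groups[a]), np.ravel(groups[b]))
        pair_rows.append({
            "group_a": a, "group_b": b, "ks": float(ks), "p_raw": float(pval),
            "p_bonferroni": min(float(pval) * n_pairs, 1.0),
            "significant": float(pval) * n_pairs < alpha,
        })
    return {
        "location": pd.DataFrame(loc_rows),
        "pairwise": pd.DataFrame(pair_rows),
        "alpha": alpha,
        "alpha_corrected_location": alpha / n_loc,
        "alpha_corrected_pairwise": alpha / n_pairs,
    }


def plot_trajectories(embedding: EmbeddingResult, labels: np.ndarray, path) -> None:
    """2-D trajectories colored by timestep, one panel per class."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = np.asarray(labels)
    classes = np.unique(labels)
    fig, axes = plt.subplots(1, classes.size, figsize=(3.2 * classes.size, 3.2),
                             squeeze=False)
    t_steps = embedding.trajectories.shape[1]
    for ax, cls in zip(axes[0], classes):
        for traj in embedding.trajectories[labels == cls]:
            ax.scatter(traj[:, 0], traj[:, 1], c=np.arange(t_steps),
                       cmap="viridis", s=6)
        ax.set_title(f"class {cls}")
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
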