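"""Synaptic-weight perturbation models.

Two models of slow analog-weight drift are provided:

* **Gaussian**: ``w' = w + c * |w| * phi`` with ``phi ~ N(0,1)`` i.i.d. per
  weight.  The level ``c`` doubles as the global context signal; the model
  widens the weight distribution around each target weight without moving
  its mean.
* **Dose-dependent**: ``w' = w + N(mu(w, dose), sigma(w, dose))`` with the
  mean shift and spread looked up (bilinear interpolation) in a rectangular
  ``(weight, dose)`` table.  This emulates charge-trap (SONOS) conductance
  drift under total ionizing dose: the mean error grows with dose toward a
  saturation weight, while the spread grows modestly on top of the intrinsic
  write-error spread present at dose zero.  A synthetic default table ships
  with the package; measured tables in the same CSV format are accepted.

Perturbations model slow drift, not fast stochasticity: a
:class:`PerturbationDraw` freezes one noise realization per weight tensor,
so every timestep of a trial (and every replay with the same draw) sees
identical perturbed weights.  Ideal weights are never modified in place.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "GaussianPerturbationSpec",
    "DosePerturbationSpec",
    "PerturbationSpec",
    "PerturbationDraw",
    "default_level_grid",
    "default_dose_grid",
    "perturb_gaussian",
    "perturb_dose",
    "weight_distribution_stats",
    "load_dose_table",
    "default_dose_spec",
]

_TABLE_COLUMNS = ["weight", "dose_krad", "mu", "sigma"]


def default_level_grid(n: int = 10) -> np.ndarray:
    """The discrete context grid: n levels evenly spaced across [0, 1]."""
    return np.linspace(0.0, 1.0, n)


def default_dose_grid() -> np.ndarray:
    """Ten dose evaluation levels in 100-krad steps starting at 0."""
    return np.arange(0.0, 1000.0, 100.0)


@dataclass
class GaussianPerturbationSpec:
    """Level and evaluation grid for the Gaussian weight-noise model."""

    c: float = 0.0
    level_grid: np.ndarray = field(default_factory=default_level_grid)

    def __post_init__(self) -> None:
        self.level_grid = np.asarray(self.level_grid, dtype=float)
        if self.c < 0:
            raise ValueError("perturbation level c must be non-negative")
        if np.any(np.diff(self.level_grid) < 0):
            raise ValueError("level_grid must be sorted ascending")
        if self.level_grid.min() < 0 or self.level_grid.max() > 1:
            raise ValueError("level_grid must lie within [0, 1]")


@dataclass
class DosePerturbationSpec:
    """Dose level plus the (weight, dose) -> (mu, sigma) lookup tables."""

    dose: float
    weight_grid: np.ndarray
    dose_table_grid: np.ndarray
    mu_table: np.ndarray
    sigma_table: np.ndarray
    dose_grid: np.ndarray = field(default_factory=default_dose_grid)

    def __post_init__(self) -> None:
        self.weight_grid = np.asarray(self.weight_grid, dtype=float)
        self.dose_table_grid = np.asarray(self.dose_table_grid, dtype=float)
        self.mu_table = np.asarray(self.mu_table, dtype=float)
        self.sigma_table = np.asarray(self.sigma_table, dtype=float)
        if self.dose < 0:
            raise ValueError("dose must be non-negative")
        expected = (self.weight_grid.size, self.dose_table_grid.size)
        if self.mu_table.shape != expected or self.sigma_table.shape != expected:
            raise ValueError("mu/sigma tables must be rectangular over (weight, dose)")
        if np.any(self.sigma_table < 0):
            raise ValueError("sigma table must be non-negative everywhere")

    @property
    def write_error_sigma(self) -> float:
        """Spread at dose 0 (intrinsic write error), from the table."""
        i = int(np.argmin(np.abs(self.dose_table_grid)))
        return float(self.sigma_table[:, i].mean())

    def lookup(self, weights: np.ndarray, dose: float) -> tuple[np.ndarray, np.ndarray]:
        """Bilinear (mu, sigma) at each weight for a given dose.

        Weights outside the table's weight range are clamped to the edge of
        the grid (tables are expected to cover the trained weight range).
        """
        if dose < self.dose_table_grid.min() or dose > self.dose_table_grid.max():
            raise ValueError(
                f"dose {dose} outside table range "
                f"[{self.dose_table_grid.min()}, {self.dose_table_grid.max()}]"
            )
        w = np.clip(weights, self.weight_grid.min(), self.weight_grid.max())
        pts = np.stack([w.ravel(), np.full(w.size, dose)], axis=1)
        mu = RegularGridInterpolator(
            (self.weight_grid, self.dose_table_grid), self.mu_table
        )(pts).reshape(weights.shape)
        sigma = RegularGridInterpolator(
            (self.weight_grid, self.dose_table_grid), self.sigma_table
        )(pts).reshape(weights.shape)
        return mu, sigma


@dataclass
class PerturbationSpec:
    """Which perturbation model applies, at what level, with what draw policy.

    ``level`` is the context scalar in [0, 1]; for the dose model it is
    mapped linearly onto the table's dose axis maximum (level 1.0 = max
    tabulated dose).  ``per_sample`` requests independent realizations per
    sample instead of one frozen realization per trial/batch.
    """

    model: str = "none"
    level: float = 0.0
    dose_spec: DosePerturbationSpec | None = None
    per_sample: bool = False

    def __post_init__(self) -> None:
        if self.model not in ("none", "gaussian", "dose"):
            raise ValueError(f"unknown perturbation model {self.model!r}")
        if self.level < 0:
            raise ValueError("perturbation level must be non-negative")
        if self.model == "dose" and self.dose_spec is None:
            raise ValueError("dose model requires a DosePerturbationSpec")

    def apply(self, weights, draw: "PerturbationDraw", key: str):
        if self.model == "none" or self.level == 0.0 and self.model == "gaussian":
            return weights
        if self.model == "gaussian":
            return perturb_gaussian(weights, self.level, draw, key=key)
        dose = self.level * float(self.dose_spec.dose_table_grid.max())
        spec = DosePerturbationSpec(
            dose=dose,
            weight_grid=self.dose_spec.weight_grid,
            dose_table_grid=self.dose_spec.dose_table_grid,
            mu_table=self.dose_spec.mu_table,
            sigma_table=self.dose_spec.sigma_table,
        )
        return perturb_dose(weights, spec, draw, key=key)


class PerturbationDraw:
    """A seeded, frozen noise realization per weight tensor.

    The first request for a key draws standard-normal noise of the given
    shape and caches it; later requests with the same key return the cached
    array bit-for-bit, so a draw applied twice yields identical perturbed
    tensors while two draws with different seeds differ almost surely.
    """

    def __init__(self, seed: int):
        self.seed = int(seed)
        self._rng = np.random.default_rng(self.seed)
        self._cache: dict[str, np.ndarray] = {}

    def standard_normal(self, key: str, shape: tuple[int, ...]) -> np.ndarray:
        if key in self._cache:
            cached = self._cache[key]
            if cached.shape != tuple(shape):
                raise ValueError(f"draw key {key!r} reused with a different shape")
            return cached
        noise = self._rng.standard_normal(shape)
        self._cache[key] = noise
        return noise


def perturb_gaussian(weights, c: float, draw: PerturbationDraw, key: str = "w",
                     n_realizations: int | None = None):
    """w' = w + c * |w| * phi with phi ~ N(0,1) frozen in ``draw``.

    Non-destructive: a new tensor is returned.  With Tensor weights the
    gradient flows through both terms (d w'/d w = 1 + c*phi*sign(w)); the
    noise itself receives no gradient.  ``n_realizations`` stacks that many
    independent per-sample realizations along a new leading axis.
    """
    if c < 0:
        raise ValueError("perturbation level c must be non-negative")
    base_shape = weights.shape if isinstance(weights, Tensor) else np.shape(weights)
    shape = base_shape if n_realizations is None else (n_realizations, *base_shape)
    phi = draw.standard_normal(key, shape)
    if isinstance(weights, Tensor):
        return weights + ad.tabs(weights) * (c * phi)
    w = np.asarray(weights)
    return w + c * np.abs(w) * phi


def perturb_dose(weights, spec: DosePerturbationSpec, draw: PerturbationDraw,
                 key: str = "w"):
    """w' = w + N(mu(w, dose), sigma(w, dose)) from the lookup tables.

    The additive error is computed from the current weight values and
    treated as a constant by the autodiff tape (drift is not a function the
    network can shape, only compensate for).
    """
    w_data = weights.data if isinstance(weights, Tensor) else np.asarray(weights)
    mu, sigma = spec.lookup(w_data, spec.dose)
    phi = draw.standard_normal(key, w_data.shape)
    additive = mu + sigma * phi
    if isinstance(weights, Tensor):
        return weights + additive
    return w_data + additive


def weight_distribution_stats(
    weights_before, weights_after, decimals: int = 6
) -> pd.DataFrame:
    """Per-target-weight mean shift and spread of the perturbed weights.

    Groups elements by their ideal (pre-perturbation) value and returns a
    frame with columns ``target_weight, n, mean_shift, spread`` — the
    summary needed for perturbed-weight histograms around each target.
    """
    before = np.asarray(
        weights_before.data if isinstance(weights_before, Tensor) else weights_before
    ).ravel()
    after = np.asarray(
        weights_after.data if isinstance(weights_after, Tensor) else weights_after
    ).ravel()
    if before.shape != after.shape:
        raise ValueError("weight tensors must have matching shapes")
    delta = after - before
    frame = pd.DataFrame(
        {"target_weight": np.round(before, decimals), "delta": delta}
    )
    grouped = frame.groupby("target_weight", sort=True)["delta"]
    out = grouped.agg(n="size", mean_shift="mean", spread=lambda d: d.std(ddof=0))
    return out.reset_index()


# -- dose lookup table I/O ---------------------------------------------------


def load_dose_table(path, dose: float = 0.0) -> DosePerturbationSpec:
    """Load a (weight, dose) -> (mu, sigma) CSV table.

    Format: header ``weight,dose_krad,mu,sigma``; one row per grid point;
    the (weight, dose_krad) combinations must form a full rectangular grid.
    """
    frame = pd.read_csv(path)
    if list(frame.columns) != _TABLE_COLUMNS:
        raise ValueError(f"dose table must have columns {_TABLE_COLUMNS}, "
                         f"got {list(frame.columns)}")
    weight_grid = np.sort(frame["weight"].unique())
    dose_grid = np.sort(frame["dose_krad"].unique())
    if len(frame) != weight_grid.size * dose_grid.size:
        raise ValueError("dose table grid is not rectangular")
    mu = frame.pivot(index="weight", columns="dose_krad", values="mu")
    sigma = frame.pivot(index="weight", columns="dose_krad", values="sigma")
    if mu.isna().any().any() or sigma.isna().any().any():
        raise ValueError("dose table grid is not rectangular (missing entries)")
    return DosePerturbationSpec(
        dose=dose,
        weight_grid=weight_grid,
        dose_table_grid=dose_grid,
        mu_table=mu.to_numpy(),
        sigma_table=sigma.to_numpy(),
    )


def default_dose_spec(dose: float = 0.0) -> DosePerturbationSpec:
    """The synthetic charge-trap drift table shipped with the package."""
    resource = importlib.resources.files("contextsnn.data").joinpath(
        "sonos_tid_synthetic.csv"
    )
    with importlib.resources.as_file(resource) as path:
        return load_dose_table(path, dose=dose)
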