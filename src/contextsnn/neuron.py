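"""Discrete-time leaky integrate-and-fire dynamics with context modulation.

The neuron integrates input current into a leaky membrane, spikes when the
membrane crosses a voltage threshold, and resets to ``v_reset``.  A global
scalar context signal ``c`` (e.g. a dosimeter reading tracking how degraded
the synaptic weights are) shifts either the firing threshold or the membrane
time constant of each unit through a learned per-unit projection ``p``:

    v_th,j  = v_th_base  + p_j * c        (threshold mode)
    tau_m,j = tau_m_base + p_j * c        (tau mode)

Integration is forward Euler with the stimulus frame as the clock tick
(``dt`` = 1 frame by default; it is exposed so fine-step simulations can be
compared against the closed-form LIF firing rate).  All step functions
accept plain numpy arrays (simulation) or autodiff Tensors (training); the
spike nonlinearity uses a hard Heaviside forward and the SuperSpike
surrogate derivative backward.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "LIFParameters",
    "LIFState",
    "LIState",
    "ContextModulation",
    "SurrogateSpec",
    "effective_threshold",
    "effective_tau",
    "lif_step",
    "li_step",
    "fi_curve",
    "init_projection",
]

_MODES = ("threshold", "tau", "none")


@dataclass
class LIFParameters:
    """LIF constants. Voltages in volts, times in stimulus frames."""

    v_leak: float = 0.0
    v_reset: float = 0.0
    v_th_base: float = 1.0
    tau_m_base: float = 4.0
    dt: float = 1.0
    tau_min: float = 0.1

    def __post_init__(self) -> None:
        if self.tau_m_base <= 0:
            raise ValueError("tau_m_base must be strictly positive")
        if self.dt <= 0:
            raise ValueError("dt must be strictly positive")
        if self.tau_min <= 0:
            raise ValueError("tau_min must be strictly positive")


@dataclass
class LIFState:
    """Membrane potential and last spike output, one entry per unit."""

    v: object
    z: object


@dataclass
class LIState:
    """Leaky-integrator (non-spiking readout) state."""

    v: object


@dataclass
class ContextModulation:
    """Learned per-unit projection of the global context scalar.

    ``p`` holds one value per modulated unit (a channel for convolutional
    layers, a neuron for dense layers).  ``mode`` selects which neuron
    parameter the product ``p * c`` shifts; ``none`` disables modulation and
    leaves ``p`` unused.  ``inverse_tau`` switches the tau parameterization
    to act additively on 1/tau instead of tau.
    """

    p: object = None
    mode: str = "none"
    c: float = 0.0
    inverse_tau: bool = False

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.c < 0:
            raise ValueError("context scalar c must be non-negative")


@dataclass
class SurrogateSpec:
    """SuperSpike surrogate slope; d z / d v ~ 1/(beta*|v - v_th| + 1)^2."""

    beta: float = 100.0

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("surrogate slope beta must be positive")


def init_projection(
    n_units: int, rng: np.random.Generator, std: float = 0.1
) -> np.ndarray:
    """Random-normal initialization of the adaptive projection vector p."""
    return rng.normal(0.0, std, size=n_units)


def effective_threshold(mod: ContextModulation, params: LIFParameters):
    """Per-unit firing threshold v_th_base + p*c (threshold mode only).

    No clamping: thresholds below baseline (or below ``v_reset``) are legal;
    such a unit simply fires on every step.
    """
    if mod.mode != "threshold":
        raise ValueError(f"effective_threshold requires mode='threshold', got {mod.mode!r}")
    return params.v_th_base + mod.p * mod.c


def effective_tau(mod: ContextModulation, params: LIFParameters):
    """Per-unit membrane time constant under tau modulation.

    Direct parameterization: max(tau_m_base + p*c, tau_min).  The lower
    clamp is an implementation guard against sign flips when p*c drives the
    time constant negative.  With ``inverse_tau`` the shift acts on 1/tau.
    """
    if mod.mode != "tau":
        raise ValueError(f"effective_tau requires mode='tau', got {mod.mode!r}")
    if mod.inverse_tau:
        inv = ad.clamp_min(1.0 / params.tau_m_base + mod.p * mod.c, 1.0e-6)
        return ad.clamp_min(1.0 / inv, params.tau_min)
    return ad.clamp_min(params.tau_m_base + mod.p * mod.c, params.tau_min)


def _check_finite(x) -> None:
    data = x.data if isinstance(x, Tensor) else np.asarray(x)
    if not np.all(np.isfinite(data)):
        raise FloatingPointError("non-finite input current")


def lif_step(
    state: LIFState,
    input_current,
    params: LIFParameters,
    mod: ContextModulation | None = None,
    surrogate: SurrogateSpec | None = None,
) -> LIFState:
    """One forward-Euler LIF update with jump condition and reset.

    v' = v + (dt/tau_eff) * (v_leak - v + I)
    z' = Heaviside(v' - v_th_eff)
    v' := v_reset  where z' = 1

    The returned spikes are binary in the forward pass; the backward pass
    (Tensor inputs) differentiates through the SuperSpike surrogate, and the
    reset multiplies the decayed membrane by (1 - z') so gradient also flows
    through the reset path.
    """
    _check_finite(input_current)
    mod = mod or ContextModulation()
    beta = (surrogate or SurrogateSpec()).beta

    if mod.mode == "tau":
        tau = effective_tau(mod, params)
    else:
        tau = params.tau_m_base
    if mod.mode == "threshold":
        v_th = effective_threshold(mod, params)
    else:
        v_th = params.v_th_base

    v_decayed = state.v + (params.dt / tau) * (params.v_leak - state.v + input_current)
    z_new = ad.heaviside(v_decayed - v_th, beta)
    v_new = v_decayed * (1.0 - z_new) + z_new * params.v_reset
    return LIFState(v=v_new, z=z_new)


def li_step(state: LIState, input_current, params: LIFParameters) -> LIState:
    """Leaky-integrator update: the same leak as the LIF but never spikes."""
    _check_finite(input_current)
    v_new = state.v + (params.dt / params.tau_m_base) * (
        params.v_leak - state.v + input_current
    )
    return LIState(v=v_new)


def fi_curve(
    params: LIFParameters,
    mod: ContextModulation | None,
    current_levels: Sequence[float],
    duration: int = 1000,
) -> np.ndarray:
    """Firing rate (spikes per frame) at each constant input current.

    Simulates ``duration`` timesteps from rest for every level at once and
    returns spike_count / (duration * dt).  Deterministic.
    """
    levels = np.asarray(current_levels, dtype=float)
    if levels.size == 0:
        raise ValueError("current_levels must be non-empty")
    if np.any(np.diff(levels) < 0):
        raise ValueError("current_levels must be sorted ascending")
    if duration < 100:
        raise ValueError("duration must be at least 100 timesteps")

    if mod is not None and mod.mode != "none":
        # broadcast each unit's modulation across all current levels
        p = np.atleast_1d(np.asarray(mod.p, dtype=float))
        if p.size != 1:
            raise ValueError("fi_curve characterizes a single unit; p must be scalar")
        mod = ContextModulation(p=float(p[0]), mode=mod.mode, c=mod.c,
                                inverse_tau=mod.inverse_tau)

    state = LIFState(v=np.zeros_like(levels), z=np.zeros_like(levels))
    counts = np.zeros_like(levels)
    for _ in range(duration):
        state = lif_step(state, levels, params, mod)
        counts += state.z
    return counts / (duration * params.dt)
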