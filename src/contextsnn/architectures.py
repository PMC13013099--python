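"""Spiking network architectures with perturbable weights and context modulation.

Two topologies are provided, both built from convolutional blocks with LIF
activations and a non-spiking leaky-integrator (LI) readout that accumulates
spike evidence over the trial:

* **feedforward**: VGG-style blocks of conv -> batch norm -> LIF -> max pool.
* **recurrent**: the same blocks plus a second convolution applied to the
  block's own previous-timestep spikes, injected as an additive current
  stream; recurrent blocks use no batch normalization so every inter-block
  tensor stays binary.

Each network is instantiated in one of four experimental variants crossing
{perturbation present?} x {context modulation present?}:

    base      = (no,  no)      perturbed = (yes, no)
    sham      = (no,  yes)     context   = (yes, yes)

Modulated variants own one trainable projection entry per channel
(convolutional layers) shifting either the firing threshold or the membrane
time constant by p*c.  Perturbations are applied to all convolution kernels
(feedforward and recurrent) and the readout linear weight — never to biases
or normalization parameters — and are frozen once per trial.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import h5py
import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .neuron import (
    ContextModulation,
    LIFParameters,
    LIFState,
    LIState,
    SurrogateSpec,
    effective_tau,
    effective_threshold,
    init_projection,
    li_step,
)
from .perturbation import PerturbationDraw, PerturbationSpec

__all__ = [
    "BlockSpec",
    "NetworkConfig",
    "ModelVariant",
    "VARIANTS",
    "SpikingConvNet",
    "build_network",
    "forward_trial",
    "tiny_config",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ModelVariant:
    """One cell of the perturbation x modulation factorial design."""

    name: str
    perturbation: bool
    modulation: bool


VARIANTS = {
    "base": ModelVariant("base", False, False),
    "perturbed": ModelVariant("perturbed", True, False),
    "sham": ModelVariant("sham", False, True),
    "context": ModelVariant("context", True, True),
}


@dataclass
class BlockSpec:
    """One conv block; ``recurrent_kernel_size`` adds the recurrent stream."""

    in_channels: int
    out_channels: int
    kernel_size: int = 3
    pool: int = 2
    normalize: bool = True
    recurrent_kernel_size: int | None = None
    init_gain: float | None = None  # None: use NetworkConfig.init_gain


@dataclass
class NetworkConfig:
    """Topology, block stack, and readout head of one network."""

    topology: str  # "feedforward" | "recurrent"
    input_shape: tuple[int, int, int]  # (C, H, W)
    blocks: list[BlockSpec]
    n_outputs: int
    task_head: str  # "classification" | "tracking"
    tau_m_base: float | None = None
    surrogate_beta: float = 100.0
    p_init_std: float = 0.1
    init_gain: float = 1.0
    bias_init: float = 0.0
    inverse_tau: bool = False
    readout_tau: float | None = None  # defaults to tau_m_base
    output_scale: float = 1.0
    output_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.topology not in ("feedforward", "recurrent"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.task_head not in ("classification", "tracking"):
            raise ValueError(f"unknown task head {self.task_head!r}")
        if self.tau_m_base is None:
            # membrane time constants tuned per topology (frames)
            self.tau_m_base = 4.0 if self.topology == "feedforward" else 16.0
        recurrent = self.topology == "recurrent"
        for b in self.blocks:
            if recurrent:
                if b.normalize:
                    raise ValueError("recurrent blocks must not use batch norm")
                if b.recurrent_kernel_size is None:
                    b.recurrent_kernel_size = b.kernel_size
            elif b.recurrent_kernel_size is not None:
                raise ValueError("feedforward blocks cannot carry recurrent kernels")

    def lif_parameters(self) -> LIFParameters:
        # tau_min = dt keeps forward Euler stable (dt/tau_eff <= 1) however
        # far the modulation drives the time constant
        return LIFParameters(tau_m_base=float(self.tau_m_base), tau_min=1.0)

    def to_json(self) -> str:
        d = asdict(self)
        d["input_shape"] = list(d["input_shape"])
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "NetworkConfig":
        d = json.loads(s)
        d["input_shape"] = tuple(d["input_shape"])
        d["blocks"] = [BlockSpec(**b) for b in d["blocks"]]
        return cls(**d)


def tiny_config(
    topology: str,
    task_head: str,
    input_shape: tuple[int, int, int],
    n_outputs: int,
    widths: Sequence[int] = (4, 8, 16),
    surrogate_beta: float = 10.0,
) -> NetworkConfig:
    """Desk-scale preset: small channel widths, one block per width.

    Uses a softer surrogate slope and a larger initialization gain than the
    full-scale defaults: at desk scale the narrow blocks start far from
    threshold, and a steep surrogate would leave them with vanishing
    gradients.
    """
    recurrent = topology == "recurrent"
    blocks = []
    c_in = input_shape[0]
    for i, w in enumerate(widths):
        # the first block sees dense frame currents; deeper blocks see sparse
        # binary spikes attenuated by dt/tau, so their kernels start larger
        blocks.append(
            BlockSpec(
                in_channels=c_in,
                out_channels=w,
                pool=1 if (task_head == "tracking" and i == len(widths) - 1)
                else 2,
                normalize=not recurrent,
                recurrent_kernel_size=3 if recurrent else None,
                init_gain=4.0 if i == 0 else 12.0,
            )
        )
        c_in = w
    h, w = input_shape[1], input_shape[2]
    return NetworkConfig(
        topology=topology,
        input_shape=input_shape,
        blocks=blocks,
        n_outputs=n_outputs,
        task_head=task_head,
        surrogate_beta=surrogate_beta,
        bias_init=0.5,
        inverse_tau=True,
        readout_tau=4.0 if task_head == "tracking" else None,
        output_scale=(w - 1) / 2.0 if task_head == "tracking" else 1.0,
        output_offset=(w - 1) / 2.0 if task_head == "tracking" else 0.0,
    )


def _conv_init(rng: np.random.Generator, out_ch: int, in_ch: int, k: int,
               gain: float = 1.0) -> np.ndarray:
    fan_in = in_ch * k * k
    return rng.normal(0.0, gain * np.sqrt(2.0 / fan_in),
                      size=(out_ch, in_ch, k, k)).astype(np.float32)


class _Block:
    """Conv (+ recurrent conv) -> optional BN -> context-modulated LIF -> pool."""

    def __init__(self, spec: BlockSpec, index: int, config: NetworkConfig,
                 modulated: bool, rng: np.random.Generator):
        self.spec = spec
        self.name = f"block{index}"
        self.modulated = modulated
        gain = spec.init_gain if spec.init_gain is not None else config.init_gain
        self.weight = Tensor(
            _conv_init(rng, spec.out_channels, spec.in_channels, spec.kernel_size,
                       gain),
            requires_grad=True,
        )
        self.bias = Tensor(
            np.full(spec.out_channels, config.bias_init, dtype=np.float32),
            requires_grad=True,
        )
        self.rec_weight = None
        if spec.recurrent_kernel_size is not None:
            self.rec_weight = Tensor(
                _conv_init(rng, spec.out_channels, spec.out_channels,
                           spec.recurrent_kernel_size, gain),
                requires_grad=True,
            )
        self.bn_gamma = self.bn_beta = None
        self.bn_mean = self.bn_var = None
        self.bn_frozen = False
        if spec.normalize:
            self.bn_gamma = Tensor(np.ones(spec.out_channels, dtype=np.float32),
                                   requires_grad=True)
            self.bn_beta = Tensor(np.zeros(spec.out_channels, dtype=np.float32),
                                  requires_grad=True)
            self.bn_mean = np.zeros(spec.out_channels, dtype=np.float32)
            self.bn_var = np.ones(spec.out_channels, dtype=np.float32)
        self.p = None
        if modulated:
            # one projection entry per output channel, shared over space
            self.p = Tensor(
                init_projection(spec.out_channels, rng, config.p_init_std).astype(
                    np.float32
                ),
                requires_grad=True,
            )

    def named_parameters(self) -> dict[str, Tensor]:
        out = {f"{self.name}/weight": self.weight, f"{self.name}/bias": self.bias}
        if self.rec_weight is not None:
            out[f"{self.name}/rec_weight"] = self.rec_weight
        if self.bn_gamma is not None:
            out[f"{self.name}/bn_gamma"] = self.bn_gamma
            out[f"{self.name}/bn_beta"] = self.bn_beta
        if self.p is not None:
            out[f"{self.name}/p"] = self.p
        return out

    def _batchnorm(self, x, bn_momentum: float = 0.1, eps: float = 1.0e-5):
        """Training-mode BN (batch statistics + running-average update)."""
        out, mu, var = ad.batchnorm2d(x, self.bn_gamma, self.bn_beta, eps=eps)
        self.bn_mean = ((1 - bn_momentum) * self.bn_mean
                        + bn_momentum * mu).astype(np.float32)
        self.bn_var = ((1 - bn_momentum) * self.bn_var
                       + bn_momentum * var).astype(np.float32)
        return out

    def _frozen_affine(self, eps: float = 1.0e-5):
        """Per-trial scale/shift equivalent to BN at the frozen statistics."""
        inv = (1.0 / np.sqrt(self.bn_var + eps)).reshape(1, -1, 1, 1)
        mu = self.bn_mean.reshape(1, -1, 1, 1)
        scale = self.bn_gamma.reshape(1, -1, 1, 1) * inv
        shift = self.bn_beta.reshape(1, -1, 1, 1) - scale * mu
        return scale, shift


class SpikingConvNet:
    """A feedforward or recurrent spiking convolutional network.

    Holds the *ideal* weights; perturbed copies are materialized per trial
    from a :class:`PerturbationDraw` and never written back.
    """

    def __init__(self, config: NetworkConfig, variant: ModelVariant,
                 mod_mode: str | None, seed: int):
        if variant.modulation:
            if mod_mode not in ("threshold", "tau"):
                raise ValueError(
                    f"variant {variant.name!r} requires mod_mode 'threshold' or "
                    f"'tau', got {mod_mode!r}"
                )
        elif mod_mode is not None:
            raise ValueError(
                f"variant {variant.name!r} has no modulation; mod_mode must be None"
            )
        self.config = config
        self.variant = variant
        self.mod_mode = mod_mode
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        self.blocks = [
            _Block(spec, i, config, variant.modulation, rng)
            for i, spec in enumerate(config.blocks)
        ]
        c, h, w = config.input_shape
        for b in config.blocks:
            h //= b.pool
            w //= b.pool
        n_flat = config.blocks[-1].out_channels * h * w
        self.readout_weight = Tensor(
            rng.normal(0.0, np.sqrt(1.0 / n_flat),
                       size=(n_flat, config.n_outputs)).astype(np.float32),
            requires_grad=True,
        )
        self.readout_bias = Tensor(np.zeros(config.n_outputs, dtype=np.float32),
                                   requires_grad=True)
        self.lif_params = config.lif_parameters()
        self.readout_params = LIFParameters(
            tau_m_base=float(config.readout_tau or config.tau_m_base))
        self.surrogate = SurrogateSpec(beta=config.surrogate_beta)
        self._last_states: list[np.ndarray] | None = None

    # -- parameter access ----------------------------------------------
    def named_parameters(self, trainable_only: bool = False) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for b in self.blocks:
            out.update(b.named_parameters())
        out["readout/weight"] = self.readout_weight
        out["readout/bias"] = self.readout_bias
        if trainable_only:
            out = {k: v for k, v in out.items() if v.requires_grad}
        return out

    def n_parameters(self) -> int:
        return sum(t.data.size for t in self.named_parameters().values())

    def perturbable_weights(self) -> dict[str, Tensor]:
        """Conv kernels (incl. recurrent) and the readout linear weight."""
        out = {}
        for b in self.blocks:
            out[f"{b.name}/weight"] = b.weight
            if b.rec_weight is not None:
                out[f"{b.name}/rec_weight"] = b.rec_weight
        out["readout/weight"] = self.readout_weight
        return out

    def projection_vectors(self) -> dict[str, np.ndarray]:
        return {f"{b.name}/p": b.p.data.copy() for b in self.blocks
                if b.p is not None}

    def freeze_normalization(self) -> None:
        """Lock batch-norm to its running statistics (post-pretraining)."""
        for b in self.blocks:
            b.bn_frozen = True

    def reset_state(self) -> None:
        self._last_states = None

    # -- forward -------------------------------------------------------
    def _modulation(self, block: _Block, c: float) -> ContextModulation | None:
        if not self.variant.modulation:
            return None
        p = block.p.reshape(1, -1, 1, 1)  # broadcast over batch and space
        return ContextModulation(p=p, mode=self.mod_mode, c=float(c),
                                 inverse_tau=self.config.inverse_tau)

    def forward(
        self,
        frames: np.ndarray,
        c: float = 0.0,
        draw: PerturbationDraw | None = None,
        perturbation: PerturbationSpec | None = None,
        reset: bool = True,
        record_penultimate: bool = False,
        debug_binary: bool = False,
    ):
        """Run one trial of T timesteps.

        ``frames``: (N, T, C, H, W) input currents injected into the first
        convolution.  The perturbation (if this variant carries one) is
        materialized once from ``draw`` and frozen across all T timesteps.
        Returns logits (N, n_outputs) at the final timestep for the
        classification head, or per-timestep outputs (N, T, n_outputs) for
        tracking.  With ``record_penultimate`` also returns the pre-reset
        membrane potentials of the last spiking layer, (N, T, units).
        """
        if frames.ndim != 5:
            raise ValueError("frames must be (N, T, C, H, W)")
        if not np.all(np.isfinite(frames)):
            raise FloatingPointError("non-finite input frames")
        n, t_steps = frames.shape[:2]

        weights = self._effective_weights(c, draw, perturbation)

        if reset or self._last_states is None:
            states, li_state = self._fresh_states(n, frames.dtype)
        else:
            states, li_state = self._last_states

        dtype = np.float32
        p_lif = self.lif_params
        # per-trial constants: effective a = dt/tau and threshold (the
        # modulation does not change within a trial), broadcast biases,
        # frozen-BN affine maps
        per_block = []
        for block in self.blocks:
            a = p_lif.dt / p_lif.tau_m_base
            v_th = p_lif.v_th_base
            if self.variant.modulation:
                mod = self._modulation(block, c)
                if self.mod_mode == "tau":
                    a = p_lif.dt / effective_tau(mod, p_lif)
                else:
                    v_th = effective_threshold(mod, p_lif)
            bias = block.bias.reshape(1, -1, 1, 1)
            affine = None
            if block.bn_gamma is not None and block.bn_frozen:
                affine = block._frozen_affine()
            per_block.append((a, v_th, bias, affine))

        outputs = []
        recorded = []
        for t in range(t_steps):
            x = frames[:, t].astype(dtype, copy=False)
            for i, block in enumerate(self.blocks):
                a, v_th, bias, affine = per_block[i]
                cur = ad.conv2d(x, weights[f"{block.name}/weight"])
                if block.rec_weight is not None:
                    cur = cur + ad.conv2d(states[i].z,
                                          weights[f"{block.name}/rec_weight"])
                cur = cur + bias
                if block.bn_gamma is not None:
                    if affine is not None:
                        cur = cur * affine[0] + affine[1]
                    else:
                        cur = block._batchnorm(cur)
                self._abort_on_nan(cur, block.name, t)
                prev = states[i]
                v_new, z_new = ad.lif_fused(
                    prev.v, cur, a, v_th, v_leak=p_lif.v_leak,
                    v_reset=p_lif.v_reset, beta=self.surrogate.beta,
                )
                if record_penultimate and i == len(self.blocks) - 1:
                    # pre-reset (sub-threshold) membrane of the last LIF layer
                    v_prev = self._data(prev.v)
                    a_d = self._data(a)
                    v_dec = v_prev + a_d * (p_lif.v_leak - v_prev
                                            + self._data(cur))
                    recorded.append(np.asarray(v_dec).reshape(n, -1).copy())
                states[i] = LIFState(v=v_new, z=z_new)
                if debug_binary:
                    zd = self._data(z_new)
                    assert np.all((zd == 0) | (zd == 1)), "non-binary spikes"
                x = ad.maxpool2d(z_new, block.spec.pool)
            flat = x.reshape(n, -1)
            drive = flat @ weights["readout/weight"] + self.readout_bias
            li_state = li_step(li_state, drive, self.readout_params)
            if self.config.task_head == "tracking":
                outputs.append(li_state.v * self.config.output_scale
                               + self.config.output_offset)
        self._last_states = (states, li_state)

        if self.config.task_head == "tracking":
            out = ad.stack(outputs, axis=1)
        else:
            out = li_state.v * self.config.output_scale + self.config.output_offset
        if record_penultimate:
            return out, np.stack(recorded, axis=1)
        return out

    # -- helpers -------------------------------------------------------
    @staticmethod
    def _data(x):
        return x.data if isinstance(x, Tensor) else np.asarray(x)

    @staticmethod
    def _abort_on_nan(cur, layer: str, t: int) -> None:
        data = cur.data if isinstance(cur, Tensor) else cur
        if not np.all(np.isfinite(data)):
            raise FloatingPointError(
                f"non-finite activation in layer {layer!r} at timestep {t}"
            )

    def _fresh_states(self, n: int, dtype):
        states = []
        c, h, w = self.config.input_shape
        for spec in self.config.blocks:
            shape = (n, spec.out_channels, h, w)
            states.append(
                LIFState(v=np.zeros(shape, np.float32), z=np.zeros(shape, np.float32))
            )
            h //= spec.pool
            w //= spec.pool
        li = LIState(v=np.zeros((n, self.config.n_outputs), np.float32))
        return states, li

    def _effective_weights(self, c, draw, perturbation):
        weights = {}
        for b in self.blocks:
            weights[f"{b.name}/weight"] = b.weight
            if b.rec_weight is not None:
                weights[f"{b.name}/rec_weight"] = b.rec_weight
        weights["readout/weight"] = self.readout_weight
        if self.variant.perturbation and perturbation is not None \
                and perturbation.model != "none":
            if draw is None:
                raise ValueError("perturbation-bearing forward needs a draw")
            weights = {
                key: perturbation.apply(w, draw, key=key)
                for key, w in weights.items()
            }
        return weights


def build_network(config: NetworkConfig, variant: ModelVariant | str,
                  mod_mode: str | None = None, seed: int = 0) -> SpikingConvNet:
    """Instantiate one of the four experimental variants of a topology."""
    if isinstance(variant, str):
        variant = VARIANTS[variant]
    return SpikingConvNet(config, variant, mod_mode, seed)


def forward_trial(network: SpikingConvNet, frames: np.ndarray, c: float,
                  draw: PerturbationDraw | None = None,
                  perturbation: PerturbationSpec | None = None, **kw):
    """One stateless trial: states reset, perturbation frozen over T steps."""
    return network.forward(frames, c=c, draw=draw, perturbation=perturbation,
                           reset=True, **kw)


# -- checkpointing -----------------------------------------------------------


def save_checkpoint(network: SpikingConvNet, path, manifest: dict | None = None) -> None:
    """HDF5 checkpoint: weights under ``weights/<name>``, batch-norm running
    statistics under ``norm_stats/<name>``, config and manifest as attrs."""
    with h5py.File(path, "w") as f:
        g = f.create_group("weights")
        for name, tensor in network.named_parameters().items():
            g.create_dataset(name, data=tensor.data)
        s = f.create_group("norm_stats")
        for b in network.blocks:
            if b.bn_mean is not None:
                s.create_dataset(f"{b.name}/mean", data=b.bn_mean)
                s.create_dataset(f"{b.name}/var", data=b.bn_var)
        f.attrs["config"] = network.config.to_json()
        f.attrs["variant"] = network.variant.name
        f.attrs["mod_mode"] = network.mod_mode or ""
        f.attrs["seed"] = network.seed
        f.attrs["bn_frozen"] = any(b.bn_frozen for b in network.blocks)
        f.attrs["manifest"] = json.dumps(manifest or {})


def load_checkpoint(path) -> tuple[SpikingConvNet, dict]:
    """Rebuild a network (weights, stats, variant) from an HDF5 checkpoint."""
    with h5py.File(path, "r") as f:
        config = NetworkConfig.from_json(f.attrs["config"])
        variant = VARIANTS[f.attrs["variant"]]
        mod_mode = f.attrs["mod_mode"] or None
        net = SpikingConvNet(config, variant, mod_mode, int(f.attrs["seed"]))
        params = net.named_parameters()
        def _visit(name, obj):
            if isinstance(obj, h5py.Dataset):
                params[name].data = obj[()].astype(np.float32)
        f["weights"].visititems(_visit)
        for b in net.blocks:
            if b.bn_mean is not None and f"norm_stats/{b.name}/mean" in f:
                b.bn_mean = f[f"norm_stats/{b.name}/mean"][()]
                b.bn_var = f[f"norm_stats/{b.name}/var"][()]
        if f.attrs.get("bn_frozen", False):
            net.freeze_normalization()
        manifest = json.loads(f.attrs["manifest"])
    return net, manifest
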