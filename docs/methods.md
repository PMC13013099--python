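# Methods

## Model

### Neuron dynamics

All activations are discrete-time leaky integrate-and-fire (LIF) neurons,
integrated with forward Euler on the stimulus-frame clock (`dt` = 1 frame;
`dt` is exposed so fine-step simulations can be compared against closed
forms):

    v[t+1] = v[t] + (dt / tau_m) * (v_leak - v[t] + I[t])
    z[t+1] = Theta(v[t+1] - v_th)
    v[t+1] <- v_reset   where z[t+1] = 1

with `v_leak = v_reset = 0` and base threshold `v_th = 1` V. The membrane
time constant is 4 frames for feedforward networks and 16 frames for
recurrent networks. The reset is reset-to-value (not reset-by-subtraction).
A membrane exactly at threshold does not fire (`Theta(0) = 0`).

The non-spiking readout is a leaky integrator (LI): the same leak equation
without the jump/reset, so spike evidence accumulates over the trial.
Classification reads the LI state at the final timestep as logits; tracking
reads it at every timestep.

### Context modulation

A global scalar context signal `c in [0, 1]` — in deployment, a dosimeter or
clock reading proportional to how perturbed the synaptic weights are — is
broadcast to every neuron. Each modulated unit owns one trainable projection
`p_j` (initialized N(0, 0.1), seeded), converting the context into a
per-unit parameter shift:

* **threshold mode**: `v_th,j = v_th_base + p_j * c`, no clamping; a
  threshold driven below the reset voltage is legal (the unit then fires
  every step).
* **tau mode**: the shift acts on the membrane time constant. Two
  parameterizations are implemented: direct (`tau_j = tau_base + p_j * c`)
  and inverse (`1/tau_j = 1/tau_base + p_j * c`), selected by the
  `inverse_tau` flag. The effective tau is clamped below at `tau_min`
  (default 0.1 frames for the bare neuron API). Inside networks the clamp is
  `tau_min = dt`: forward Euler is only stable for `dt/tau <= 1`, and an
  unconstrained modulation can otherwise push the update into an oscillating
  divergence — we observed exactly this failure before introducing the
  network-level clamp.

Granularity: one `p` per output **channel** in convolutional layers (shared
over spatial positions), one per unit in dense layers. Exactly one
modulation mode is active per network.

The tau parameterization is genuinely ambiguous in the source material
(a direct additive shift on tau versus an additive shift on the inverse time
constant); we implement both. The tiny presets use the inverse
parameterization, for a concrete reason: with `tau_base = 16`, the gradient
of the update gain `a = dt/tau` with respect to `p` is `c/tau^2 ~ c/256`
under the direct form but `c` under the inverse form — at desk scale the
direct form is effectively gradient-dead, while the inverse form trains.

### Spike gradient

The forward pass uses the hard Heaviside; the backward pass uses the
SuperSpike surrogate `1/(beta*|v - v_th| + 1)^2`. The full-scale default is
`beta = 100`; the tiny presets use `beta = 10` because narrow blocks spend
most of their time far from threshold, where a steep surrogate leaves no
usable gradient.

## Perturbation models

* **Gaussian**: `w' = w + c * |w| * phi`, `phi ~ N(0,1)` i.i.d. per weight.
  Mean-preserving; spread `c*|w|`. The evaluation grid is 10 context levels
  evenly spaced on [0, 1] (4 levels in the tiny presets).
* **Dose-dependent (charge-trap drift)**: `w' = w + N(mu(w, D), sigma(w, D))`
  with `mu`/`sigma` bilinearly interpolated from a rectangular
  `(weight, dose)` CSV table; at dose 0 only the intrinsic write-error
  spread applies. The shipped table (`data/sonos_tid_synthetic.csv`) is
  synthetic: its mean error drifts linearly with dose toward a saturation
  weight of -0.25 (drift coefficient 0.6 at 1,000 krad) and its spread grows
  from 0.02 at dose 0 to 0.08 at 1,000 krad, slightly faster for large
  |w|. It reproduces the qualitative fingerprint of measured
  total-ionizing-dose data on SONOS devices — dose-increasing mean shift,
  modest spread growth — not any measured device. Measured tables in the
  same format are accepted and validated on load. The dose evaluation grid
  is 10 levels in 100-krad steps starting at 0 (0–900 krad); the table
  itself extends to 1,000 krad.

Perturbations model slow drift: one realization is frozen per trial (trial =
one training mini-batch or one evaluation batch) and held constant across
all timesteps. Ideal weights are never modified; gradients flow through the
perturbed weights to the ideal weights and never into the noise. The
perturbed tensors are all convolution kernels (feedforward and recurrent)
and the readout linear weight; biases and normalization parameters are never
perturbed. For the dose model the additive error is treated as a constant by
the tape (the drift is not trainable, only compensable).

## Architectures and variants

Both topologies stack three (two, in the smallest presets) VGG-style blocks
with decreasing spatial resolution and increasing channel count, then
flatten into a linear readout integrated by the LI. Feedforward blocks use
batch normalization between the convolution and the LIF; recurrent blocks
add a second 3x3 convolution applied to the block's own previous-timestep
spikes (an additive current stream, zero-initialized state) and use no batch
normalization so that every inter-block tensor stays binary. Batch-norm
statistics are frozen after pretraining so perturbations cannot leak into
the normalization constants.

The four experimental variants cross perturbation x modulation:
base (-,-), perturbed (+,-), sham (-,+), context (+,+). Sham receives the
same sampled context input as context models but no perturbation; base and
perturbed ignore the context input entirely.

Full-scale channel widths default to 32/64/128. The tiny preset used by the
tests uses 4/8/16 (4/8 for the classification study): these widths keep the
complete study — pretraining plus adaptation of every variant over three
seeds — in the minutes range on one CPU core.

### Desk-scale initialization

Two initialization choices matter at these widths and are part of the tiny
preset:

* per-depth kernel gain: the first block sees dense frame currents (gain 4x
  over Kaiming), deeper blocks see sparse binary spikes attenuated by
  `dt/tau` — a single input spike changes a downstream membrane by only
  `w/tau` — so their kernels start larger (12x). Without this the deep
  blocks are silent and no gradient reaches them.
* spiking-block biases start at 0.5 V, halfway to threshold, so units are
  within surrogate-gradient range of firing from the first epoch.

For tracking, the readout uses its own LI time constant (4 frames — a
16-frame readout lags a moving target by more than half the frame) and an
affine output map fixed to the frame geometry (scale and offset
`(width-1)/2`), so the raw LI state is centered and unit-scaled while
predictions and losses are in pixel coordinates. The last tracking block
does not pool (final feature map 4x4), because pooling to 2x2 destroys the
spatial information the task asks for.

## Training protocol

Two phases, both BPTT with momentum SGD (momentum 0.9) and a plateau
schedule that halves the learning rate after 10 non-improving epochs:

1. **Pretrain** the base network on clean weights; freeze batch-norm
   statistics at the end.
2. **Adapt** each variant from the pretrained weights. Per mini-batch, a
   context level is sampled uniformly from the discrete grid restricted to
   [0, c_max] (a fixed-at-max policy is available behind
   `context_sampling="fixed_max"`); perturbation-bearing variants get a
   fresh frozen noise realization per batch; modulation-bearing variants
   train `p` jointly with the weights.

Full-scale defaults are 100 epochs per phase at learning rate 0.001 and
batch 64. The tiny presets train for 50 + 40 epochs (15 + 25 for the
classification study) at learning rate 0.003–0.01 and batch 8: with two
orders of magnitude fewer gradient steps than a full-scale run, the
full-scale rate barely moves the weights. Gradients are clipped to a global
norm of 5 — BPTT through spiking recurrence with shared per-channel
modulation parameters produces occasional large-magnitude gradient spikes
(we observed tau-modulated adaptation diverging without the clip).

Randomness is split into independent streams (batch shuffling vs
context/draw sampling) so that variants consuming different amounts of draw
randomness still see identical batch orderings; identical seeds reproduce
training bit-exactly on one thread.

## Synthetic tasks

* **Small-object tracking (SOT)**: T frames (default 100; 50 in the tiny
  preset) of a single bright pixel (contrast 2.0) moving over a static
  clutter background (amplitude 0.3) with per-frame Gaussian pixel noise
  (sigma 0.05), constant velocity 0.7 px/frame plus positional jitter
  (sigma 0.1), reflecting off the frame boundaries. Targets are the
  continuous (x, y) = (column, row) track; loss and metric are per-timestep
  MSE in pixel^2. What it emulates: a remote-sensing-style spatiotemporal
  regression. What it does not: real clutter statistics, object extent,
  occlusion — conclusions from passing tests are about the relative effect
  of perturbation and modulation, not absolute tracking quality.
* **Toy frame classification**: procedurally generated sinusoidal class
  templates plus Gaussian pixel noise, presented statically for T timesteps
  (default 32). Class-balanced, seeded; a nearest-template observer is
  perfect at zero noise. This is plumbing for the static-classification
  pipeline (a stand-in for a natural-image set that would need downloading),
  not a claim about natural images.

Splits are 80/20 by sample with disjoint seeded index sets; every dataset
carries its config and seed and regenerates bit-exactly.

## Evaluation sweep

Every trained checkpoint (variant x modulation x training maximum c_max x
seed) is evaluated at every test level; the context input equals the test
level for modulated variants. Each cell averages 5 independent frozen
draws; per-draw values are retained in long format, cells are cached by key,
and the CSV serialization uses `%.17g` with round-trip float parsing so
results reload bit-exactly. Desk-scale sweep defaults: 3 seeds, 4 grid
levels; the full 10x10x10-seed grid is a matter of passing larger lists.

## Latent analysis

Sub-threshold (pre-reset) membrane potentials of the last spiking layer are
recorded at every timestep during inference under one frozen draw per
context level. One PCA is fit per condition on the pooled
(trial x timestep, unit) matrix — the reading of "per-trial PCA" that makes
locations comparable across trials; a literal per-single-trial fit is
available by passing one trial — and each trial's timecourse is projected
into component space. Loadings are sign-fixed (largest-magnitude entry
positive) for determinism. Class separation is the silhouette score of
final-timestep positions by class, invariant to rigid rotations; learned
`p` vectors are compared across training levels with one-sample t tests
against zero and pairwise Kolmogorov–Smirnov tests, Bonferroni-corrected
within each family.

## Desk-scale findings and limitations

The tiny recovery study reproduces the central qualitative result:
perturbation at the top level roughly triples the recurrent network's
tracking error, context modulation recovers a large part of it (the tau mode
recovers substantially more than the threshold mode at this scale, where
threshold recovery is consistently present but thin), and the feedforward
topology shows no reliable benefit.

The latent separation contrast (context above perturbed at the top level)
did **not** reproduce at desk scale in our experiments: with 4–8 channels
there is little population redundancy, context modulation does not recover
static-classification accuracy at the top perturbation level, and the
recorded layer of a two-block network is dominated by direct stimulus drive,
so both variants separate classes about equally (with the context model, if
anything, slightly lower — its modulation reshapes the final-timestep state
without an accuracy payoff). The corresponding check is left in the suite
as the honest desk-scale outcome of that analysis.

Other numerical choices: spike threshold comparisons are strict (`>`); max
pooling breaks ties by first index; silhouette on coincident points is
defined as 0; rank-deficient PCA inputs truncate the component count with a
warning; dose lookups clamp weights to the table's weight range; training
aborts with seed and epoch on a non-finite loss.
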