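# Methods

## Neuron model and forward dynamics

Each layer simulates discrete-time leaky integrate-and-fire neurons. The
membrane potential accumulates weighted input spikes, decays by a
per-neuron leak factor `τ_i ∈ [0, 1]` (heterogeneous neurons), and resets
to 0 after a spike via multiplicative gating of the leak term — not by
threshold subtraction. The threshold comparison is `≥`, so a potential
exactly at `U_th` spikes. Within a timestep all neurons update
synchronously from the `t−1` state; recurrent input always uses the
previous step's spikes. Self-synapses (the diagonal of the intra-layer
weight matrix) are excluded by default because the bias already provides
self-excitation or self-suppression. The initial state is `u⁰ = s⁰ = 0`.

`U_th` defaults to 1 and is configurable (large thresholds reproduce a
known divergence mode: the firing rate saturates instead of declining; the
trainer detects a non-finite loss or FR ≥ 0.99 sustained for 3 epochs and
raises a diagnostic error rather than crashing).

## Backward pass

The spike nonlinearity is non-differentiable; its Dirac-impulse derivative
is replaced during the backward pass by a Gaussian surrogate. We use the
unit-mass normalization `g'(x) = (α/√π)·exp(−α²x²)` so the surrogate is a
proper Dirac approximation (the constant is a config field; `α/π` is one
edit away). Default `α = 0.7`.

The potential gradient is computed by a backward-in-time recursion that is
O(T) per neuron. Two conventions matter and are shared by the test
oracles:

- the reset-gate edge `s^{t−1} → u^t` carries no information (it only
  gates the leak) and is excluded from the backward graph;
- in recurrent layers, the synaptic edge through `w_rec` *is*
  differentiated, producing a transposed-weight accumulation from the next
  timestep.

Parameter gradients follow by summing over the window; the l1 term
`λ_w·sign(w)` uses `sign(0) = 0` so pruned (exactly-zero) synapses receive
no push and stay at zero under masking. Gradients are not clipped — the
*parameters* are clamped after each optimizer step (`w`, `b` to
`[−U_th, U_th]`, `τ` to `[0, 1]`). For layers flagged `tau_shared`, the τ
gradient is summed across the sharing group.

Batch convention (not fixed by the model definition, chosen here):
cross-entropy and the spike penalty are averaged over the samples of a
batch; the weight penalty does not depend on data and is added once per
batch. The output-layer spike gradient is `p − y` at every timestep (the
readout scale factor `k` is absorbed into the learning rate).

## Loss and readout

Class logits are `k·Σ_t s_c^t` with `k = 10/T`, so a fully spiking output
neuron contributes logit 10 regardless of the window length; probabilities
come from a max-subtracted softmax. The spike penalty
`(λ_s/2)·Σ‖s‖²` covers hidden layers only (spikes are boolean, so `‖s‖²`
is the spike count); the weight penalty `λ_w·Σ‖w‖₁` covers the inter- and
intra-layer weights of every layer but not the bias.

## Rewiring

Momentum `m` is the exponential moving average of the *unmasked* weight
gradient, `m := β_m·m + (1−β_m)·∇w` (the plain-accumulation variant
`m := m + (1−β_m)·∇w` is available behind `literal_update`). Pruning
removes existing synapses with `|w| < Θ_w` (strict); growth adds absent
synapses with `|m| > Θ_m·(1 + μ_m·d^p)` (strict), where `d` is the
Euclidean distance between the neuron coordinates in the unit cube and the
exponent `p` defaults to 1 (0.5 selectable — either choice preserves the
"longer range costs more" semantics). Grown synapses enter at weight
exactly 0 and are moved by subsequent optimizer steps. Defaults:
`Θ_w = 10⁻²`, `Θ_m = 10⁻⁴`, `μ_m = 5`, `β_m = 0.99`, rewiring every
update from the first step (a warm-up delay is configurable). Momentum of
masked synapses keeps updating, which is what enables regrowth; it is not
reset when a synapse grows. By default any absent position is a growth
candidate (a `pruned_only` universe is selectable). Flat layers never grow
intra-layer synapses.

Because masked weights must stay exactly zero even under optimizers with
internal state (Adam moves parameters with zero gradient), masks are
re-applied after every optimizer step.

## Initialization

`W ~ N(0, 1)` clamped to `[−U_th, U_th]`, `b ~ U(0, 1)`, `τ = 0.5`,
neuron coordinates uniform in the unit cube, masks all-true (recurrent
diagonal excluded). Runs are bit-reproducible given (spec, seed).

## Encoders

- **Rate**: each channel's value in [0, 1] is a Bernoulli probability per
  timestep, seeded.
- **Rank order**: latency `t(v) = round((1 − v/v_max)(T−1))`, zero-based;
  `v = 0` never spikes, ties share a timestep (a strict-rank variant
  assigns unique latencies by sort order). The code emits at most one
  spike per channel: information lives purely in timing.
- **Level crossing**: absolute amplitude levels `k·δ` (no reference drift);
  an UP/DOWN spike when the signal's quantized level rises/falls, at most
  one spike per channel per native sample, so signals should be sampled
  finely enough to change by less than `δ` per sample. A C-channel signal
  becomes 2C spike channels; native samples map onto the T grid by uniform
  binning with OR-reduction. The staircase reconstruction
  `(cumUP − cumDOWN)·δ` then tracks the (zero-referenced) signal within
  `δ`.

## Post-training quantization

Weights and biases round to the nearest multiple of `2^−(n−1)`
(nearest-even), saturating at `±(1 − 2^−(n−1))` — consistent with the
training-time clamp at `U_th = 1`. `τ` rounds to `2^−m` with
`m = round(−log₂ τ)`; `τ = 0` maps to an `m = ∞` sentinel (full reset).
Accumulation during quantized inference is wide fixed point with no
intermediate rounding. Energy is counted event-wise (one accumulate per
spike per existing outgoing synapse; one bias add and one leak
multiply-or-shift per neuron-timestep) and normalized with
{FL-ADD 1, FL-MUL 4, FI-ADD 0.2, BIT-OP 0}.

## Motif analysis

The topology comparison uses the 13 connected classes of the standard
directed triad census (induced subgraphs), in the conventional order
021D 021U 021C 111D 111U 030T 030C 201 120D 120U 120C 210 300. The null
model is directed-edge-swap randomization preserving every in- and
out-degree (10× edge count successful swaps per sample; rigid graphs fall
back to identity samples with a warning). The significance profile is the
unit-norm z-vector against the ensemble; zero-variance motif classes get
z = 0 to keep the profile finite, and an all-zero z-vector (no direction)
is an explicit error. Census and edge swaps are delegated to networkx;
the test suite cross-checks the census against an independent brute-force
enumerator.

## Synthetic tasks: what they emulate, and what they don't

- `rate_clusters` (default: 2 classes, 20 channels, T = 20, 400/200
  samples, template noise sd 0.1): class-specific intensity templates,
  Bernoulli-encoded — an MNIST-like intensity task.
- `temporal_order` (jitter sd 0.3/n_channels on the latent values): every
  channel carries exactly one rank-order spike, so total spike counts are
  identical across classes by construction; the label is carried purely
  by spike timing. Collapsing the time axis (`collapse_time`) yields
  all-ones inputs — a model without temporal processing is at chance,
  which is the ablation control.
- `lc_waveforms` (2 analog channels, class-specific frequencies
  2.0 + 1.5·c cycles per window, amplitude jitter U(0.7, 0.9), phase
  random, additive noise sd 0.01, 400 native samples, δ = 0.1, T = 40):
  quasi-periodic signals level-crossing-encoded into 4 bipolar channels —
  an ECG-like task.

These generators are deliberately low-dimensional and linearly or
temporally separable by construction. Passing them demonstrates that the
gradient machinery, regularizers, rewiring and quantization work as
specified; it does not demonstrate performance on high-dimensional natural
data, class imbalance, sensor drift or label noise, none of which the
generators model.

## Experiment sizes and numerical choices

Desk-scale experiment sizes were chosen so every check runs on one CPU:
oracle suites use layers with N ≤ 16, T ≤ 32; training runs use the task
defaults above with 50 epochs (80 for the rewiring study, whose
sparsification continues well past accuracy convergence; 150 with the
final quarter's firing rate averaged for the λ_s sweep, which measures
converged firing-rate levels — single-epoch values fluctuate by ~0.01).
The rewiring study uses an over-parameterized recurrent layer (r32 on a
4-channel input) so that there is redundant structure to remove, mirroring
the large-network setting in which structural pruning is meaningful.

A caveat on the λ_s sweep: at this scale the difference between λ_s = 0
and λ_s = 10⁻⁷ is comparable to seed-to-seed variation (the spiking
penalty's gradient is ~10³ times smaller than the cross-entropy gradient
floor), so the first link of the firing-rate ordering is a weak effect;
the decade steps to 10⁻⁶ and 10⁻⁵ separate robustly.

Known limitations: no convolutional or residual layers (and hence no
shared-weight gradient summation beyond the homogeneous-τ case), no
event-driven/asynchronous simulation, no GPU path, no
quantization-aware training.
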