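# bpsr

Sparsity-regularized backpropagation for spiking neural networks (SNNs),
in plain numpy.

Spiking networks promise energy-efficient inference because computation is
event-driven: a synapse only accumulates when its presynaptic neuron fires,
and fixed-point accumulation is far cheaper than floating-point multiply-add.
That promise is only realized when both the *spikes* and the *synapses* are
sparse. `bpsr` trains heterogeneous leaky integrate-and-fire (LIF) networks
— including brain-like recurrent layers — with exactly that goal:

- **O(T) surrogate-gradient backpropagation through time.** The spike
  threshold's Dirac derivative is replaced by a unit-mass Gaussian
  `g'(x) = (α/√π)·exp(−α²x²)`, and the potential gradient is computed by a
  backward-in-time recursion (one add and multiply per step) instead of
  unrolling the graph.
- **Spiking regularization** (`λ_s`, an l2 penalty on hidden spike counts)
  trades firing rate against accuracy.
- **Synaptic regularization + rewiring** (`λ_w`, l1) shrinks weights while a
  prune/grow rule removes synapses with `|w| < Θ_w` and regrows absent ones
  whose gradient momentum `m` exceeds a distance-scaled threshold
  `Θ_m·(1 + μ_m·‖c_i − c_j‖₂)` — longer-range connections need a stronger
  growth trend.
- **Spike encoders**: Bernoulli rate coding, rank-order (intensity →
  latency) coding, and bipolar level-crossing sampling for analog signals
  such as ECG.
- **Post-training quantization** to n-bit fixed-point weights and
  power-of-two leaks (`τ ≈ 2^−m`, so the leak becomes a right shift), with
  event-driven operation/energy accounting.
- **Motif analysis**: 13-class directed triad census, degree-preserving null
  ensembles, and unit-norm significance profiles for comparing a learned
  topology against reference connectomes.

The model, per layer and timestep:

```
u_i^t = u_i^{t-1} · τ_i · (1 − s_i^{t-1}) + Σ_j w_ij x_j^t + Σ_k w_ik s_k^{t-1} + b_i
s_i^t = H(u_i^t − U_th)
```

with softmax/cross-entropy loss on the scaled output spike counts
(`k = 10/T`) plus the two sparsity penalties. All learnable parameters
(`w`, `b`, and the per-neuron leak `τ`) are optimized jointly (AdamW by
default) and clamped each step.

## Worked example

```python
import bpsr

# 2-class task: per-class channel intensity templates, rate-encoded
ds = bpsr.make_synthetic_task(
    "rate_clusters", n_classes=2, n_channels=20, T=20,
    n_train=400, n_test=200, seed=1,
)

# "r20 - fc10 - fc2": a recurrent layer and two fully connected layers
spec = bpsr.NetworkSpec(
    n_inputs=20,
    layers=[("recurrent", 20), ("flat", 10), ("flat", 2)],
    T=20, epochs=10,
)
net, history, trainer = bpsr.train(spec, ds)
m = bpsr.evaluate(net, ds.x_test, ds.y_test)
print(f"accuracy {m.accuracy:.3f}  firing rate {m.fr:.3f} "
      f"synapses {m.synapse_count}")
```

prints (seeds fixed as above):

```
accuracy 1.000  firing rate 0.347 synapses 650
```

The task is solved exactly; the network fires on average 0.35 spikes per
neuron per timestep, and the default l1 + rewiring configuration has already
pruned the 962 initial synapses down to 650. Training longer continues to
remove synapses while the firing rate declines — the characteristic
sparsification dynamic of this learning rule.

There is also a small CLI (`bpsr train/eval/sweep/motifs`) driven by a YAML
config; see `bpsr --help`.

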