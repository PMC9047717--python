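"""End-to-end training loop: forward, backprop, rewiring, clamped update.

One training step on a batch runs

1. forward through every layer (sample-parallel),
2. readout + regularized loss,
3. the backward recursions layer by layer, chaining each layer's input
   gradient into the previous layer's spike gradient (plus the spiking
   regularizer on hidden spikes),
4. gradient-momentum update and (at the configured interval) rewiring,
5. an optimizer step (SGD / Adam / AdamW) followed by clamping:
   weights and bias to [-u_th, +u_th], tau to [0, 1], masked synapses
   back to exactly zero.

Initialization: W ~ N(0, 1), bias ~ U(0, 1), tau = 0.5, neuron coordinates
uniform in the unit cube, all clamped to the legal ranges; masks start
all-true (recurrent diagonals excluded).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, asdict

import numpy as np

from .backprop import (
    GradientBundle,
    SurrogateConfig,
    hidden_layer_spike_grad,
    output_layer_spike_grad,
    parameter_grads,
    potential_grad,
)
from .lif import LayerParams, LayerTrace, firing_rate, lif_forward
from .objective import LossReport, ReadoutConfig, readout_probs, total_loss
from .optim import make_optimizer
from .quantize import count_energy
from .rewiring import RewireEvent, RewireState, apply_rewire, update_momentum
from .tasks import SpikeDataset

__all__ = [
    "RewireConfig",
    "NetworkSpec",
    "Network",
    "Trainer",
    "TrainingDiverged",
    "init_network",
    "evaluate",
    "train",
    "write_metrics_csv",
]


class TrainingDiverged(RuntimeError):
    """Raised when the loss becomes non-finite or the network saturates.

    An inappropriately high threshold can drive the firing rate to
    saturation instead of the usual rate-reduction dynamic; this is
    detected (non-finite loss, or FR >= 0.99 for 3 consecutive epochs)
    and reported rather than crashing."""


@dataclass
class RewireConfig:
    enabled: bool = True
    theta_w: float = 1e-2
    theta_m: float = 1e-4
    mu_m: float = 5.0
    beta_m: float = 0.99
    interval: int = 1
    dist_exponent: float = 1.0
    candidates: str = "all_absent"
    literal_update: bool = False
    warmup_steps: int = 0


@dataclass
class NetworkSpec:
    """Architecture and hyper-parameters of one experiment.

    ``layers`` is an ordered list of ``(kind, size)`` with kind ``"flat"``
    or ``"recurrent"`` — e.g. ``[("recurrent", 20), ("flat", 10),
    ("flat", 2)]`` is the structure "r20 - fc10 - fc2".  The last layer
    size is the number of classes.
    """

    n_inputs: int
    layers: list
    T: int
    u_th: float = 1.0
    alpha: float = 0.7
    lr: float = 1e-2
    lambda_s: float = 1e-7
    lambda_w: float = 1e-2
    optimizer: str = "adamw"
    batch_size: int = 32
    epochs: int = 50
    seed: int = 0
    tau_init: float = 0.5
    rewire: RewireConfig = field(default_factory=RewireConfig)

    def readout(self) -> ReadoutConfig:
        return ReadoutConfig(T=self.T, n_classes=self.layers[-1][1])

    def surrogate(self) -> SurrogateConfig:
        return SurrogateConfig(alpha=self.alpha)


@dataclass
class Network:
    layers: list
    input_coords: np.ndarray
    spec: NetworkSpec

    def synapse_count(self) -> int:
        return sum(lp.synapse_count() for lp in self.layers)

    def pre_coords(self, i: int) -> np.ndarray:
        return self.input_coords if i == 0 else self.layers[i - 1].coords


def init_network(
    spec: NetworkSpec, rng: np.random.Generator | None = None
) -> Network:
    """Draw initial parameters; bit-identical for a given seed."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    input_coords = rng.uniform(size=(spec.n_inputs, 3))
    layers = []
    n_in = spec.n_inputs
    for kind, size in spec.layers:
        if kind not in ("flat", "recurrent"):
            raise ValueError(f"unknown layer kind {kind!r}")
        w_in = np.clip(rng.standard_normal((size, n_in)), -spec.u_th, spec.u_th)
        if kind == "recurrent":
            w_rec = np.clip(
                rng.standard_normal((size, size)), -spec.u_th, spec.u_th
            )
            np.fill_diagonal(w_rec, 0.0)
            mask_rec = ~np.eye(size, dtype=bool)
        else:
            w_rec = np.zeros((size, size))
            mask_rec = np.zeros((size, size), dtype=bool)
        bias = np.clip(rng.uniform(0.0, 1.0, size), -spec.u_th, spec.u_th)
        coords = rng.uniform(size=(size, 3))
        layers.append(
            LayerParams(
                w_in=w_in,
                w_rec=w_rec,
                bias=bias,
                tau=np.full(size, spec.tau_init),
                u_th=spec.u_th,
                mask_in=np.ones((size, n_in), dtype=bool),
                mask_rec=mask_rec,
                coords=coords,
                kind=kind,
            )
        )
        n_in = size
    return Network(layers=layers, input_coords=input_coords, spec=spec)


def forward_network(network: Network, x: np.ndarray) -> list:
    """Forward pass through all layers; spikes chain layer to layer."""
    traces = []
    inp = x
    for lp in network.layers:
        tr = lif_forward(lp, inp)
        traces.append(tr)
        inp = tr.spikes
    return traces


def backward_network(
    network: Network,
    x: np.ndarray,
    traces: list,
    probs: np.ndarray,
    labels: np.ndarray,
) -> list:
    """Backward pass; returns one GradientBundle per layer."""
    spec = network.spec
    cfg = spec.surrogate()
    grads: list = [None] * len(network.layers)
    d_s = output_layer_spike_grad(probs, labels, traces[-1].T)
    for i in range(len(network.layers) - 1, -1, -1):
        lp = network.layers[i]
        tr = traces[i]
        x_in = x if i == 0 else traces[i - 1].spikes
        d_u = potential_grad(d_s, tr, lp, cfg)
        grads[i] = parameter_grads(d_u, tr, x_in, lp, spec.lambda_w)
        if i > 0:
            d_s = hidden_layer_spike_grad(
                grads[i].d_x, traces[i - 1].spikes, spec.lambda_s
            )
    return grads


class Trainer:
    """Holds optimizer and rewiring state across steps of one run."""

    def __init__(self, network: Network):
        self.network = network
        spec = network.spec
        self.optimizer = make_optimizer(spec.optimizer, spec.lr)
        rw = spec.rewire
        self.rewire_states = [
            RewireState.for_layer(
                lp,
                theta_w=rw.theta_w,
                theta_m=rw.theta_m,
                mu_m=rw.mu_m,
                beta_m=rw.beta_m,
                interval=rw.interval,
                dist_exponent=rw.dist_exponent,
                candidates=rw.candidates,
                literal_update=rw.literal_update,
            )
            for lp in network.layers
        ]
        self.step_count = 0
        self.rewire_log: list[dict] = []

    def train_step(
        self, x: np.ndarray, labels: np.ndarray
    ) -> LossReport:
        """One forward/backward/rewire/update cycle on a batch."""
        net = self.network
        spec = net.spec
        traces = forward_network(net, x)
        report = total_loss(
            traces, net.layers, labels, spec.lambda_s, spec.lambda_w,
            spec.readout(),
        )
        if not np.isfinite(report.total):
            raise TrainingDiverged(
                f"non-finite loss at step {self.step_count}"
            )
        grads = backward_network(net, x, traces, report.probs, labels)
        self.step_count += 1
        rw = spec.rewire
        for i, (lp, g) in enumerate(zip(net.layers, grads)):
            if rw.enabled:
                update_momentum(self.rewire_states[i], g)
                if (
                    self.step_count > rw.warmup_steps
                    and self.step_count % rw.interval == 0
                ):
                    event = apply_rewire(
                        lp, g, self.rewire_states[i], net.pre_coords(i)
                    )
                    self.rewire_log.append(
                        {
                            "step": self.step_count,
                            "layer": i,
                            "pruned": event.pruned,
                            "grown": event.grown,
                            "synapses": event.synapses,
                        }
                    )
                    if event.synapses == 0:
                        self.rewire_log[-1]["disconnected"] = True
                else:
                    g.d_w_in = g.d_w_in * lp.mask_in
                    g.d_w_rec = g.d_w_rec * lp.mask_rec
            else:
                g.d_w_in = g.d_w_in * lp.mask_in
                g.d_w_rec = g.d_w_rec * lp.mask_rec
            self.optimizer.step(f"{i}.w_in", lp.w_in, g.d_w_in)
            if lp.kind == "recurrent":
                self.optimizer.step(f"{i}.w_rec", lp.w_rec, g.d_w_rec)
            self.optimizer.step(f"{i}.bias", lp.bias, g.d_bias)
            self.optimizer.step(f"{i}.tau", lp.tau, g.d_tau)
            # clamp and re-mask
            np.clip(lp.w_in, -spec.u_th, spec.u_th, out=lp.w_in)
            np.clip(lp.w_rec, -spec.u_th, spec.u_th, out=lp.w_rec)
            np.clip(lp.bias, -spec.u_th, spec.u_th, out=lp.bias)
            np.clip(lp.tau, 0.0, 1.0, out=lp.tau)
            lp.apply_masks()
        return report

    def fit(
        self,
        dataset: SpikeDataset,
        epochs: int | None = None,
        rng: np.random.Generator | None = None,
    ) -> list[dict]:
        """Train for ``epochs`` over the dataset; returns per-epoch metrics."""
        spec = self.network.spec
        epochs = spec.epochs if epochs is None else epochs
        if rng is None:
            rng = np.random.default_rng(spec.seed + 1)
        n = dataset.x_train.shape[0]
        if n == 0:
            raise ValueError("empty training set")
        history = []
        saturated = 0
        for epoch in range(epochs):
            order = rng.permutation(n)
            ce = sp = wp = tot = 0.0
            correct = 0
            frs = []
            n_batches = 0
            for start in range(0, n, spec.batch_size):
                idx = order[start : start + spec.batch_size]
                x, y = dataset.x_train[idx], dataset.y_train[idx]
                report = self.train_step(x, y)
                ce += report.cross_entropy
                sp += report.spike_penalty
                wp += report.weight_penalty
                tot += report.total
                correct += int(
                    (
                        report.probs.argmax(-1) == y.argmax(-1)
                    ).sum()
                )
                n_batches += 1
            traces = forward_network(self.network, dataset.x_train)
            fr = firing_rate(traces)
            row = {
                "epoch": epoch,
                "ce": ce / n_batches,
                "spike_pen": sp / n_batches,
                "weight_pen": wp / n_batches,
                "total": tot / n_batches,
                "fr": fr,
                "accuracy": correct / n,
                "synapse_count": self.network.synapse_count(),
            }
            history.append(row)
            saturated = saturated + 1 if fr >= 0.99 else 0
            if saturated >= 3:
                raise TrainingDiverged(
                    f"firing rate saturated (>= 0.99) for 3 epochs at "
                    f"epoch {epoch}"
                )
        return history


@dataclass
class EvalMetrics:
    accuracy: float
    fr: float
    fr_hidden: float
    synapse_count: int
    spikes_per_sample: float
    energy: float


def evaluate(
    network: Network, x: np.ndarray, labels: np.ndarray
) -> EvalMetrics:
    """Deterministic test-set metrics for a fixed checkpoint."""
    if x.shape[0] == 0:
        raise ValueError("empty evaluation set")
    traces = forward_network(network, x)
    probs = readout_probs(traces[-1].spikes, network.spec.readout())
    acc = float((probs.argmax(-1) == labels.argmax(-1)).mean())
    energy = count_energy(x, traces, network.layers)
    n_samples = x.shape[0]
    spikes = sum(int(tr.spikes.sum()) for tr in traces) / n_samples
    return EvalMetrics(
        accuracy=acc,
        fr=firing_rate(traces),
        fr_hidden=firing_rate(traces, exclude_output=True),
        synapse_count=network.synapse_count(),
        spikes_per_sample=spikes,
        energy=energy.energy,
    )


def train(
    spec: NetworkSpec, dataset: SpikeDataset, epochs: int | None = None
) -> tuple[Network, list[dict], Trainer]:
    """Convenience wrapper: init, fit, return (network, history, trainer)."""
    network = init_network(spec)
    trainer = Trainer(network)
    history = trainer.fit(dataset, epochs=epochs)
    return network, history, trainer


def write_metrics_csv(history: list[dict], path) -> None:
    """Per-epoch metric rows to CSV."""
    if not history:
        return
    keys = list(history[0])
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=keys)
        writer.writeheader()
        writer.writerows(history)
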