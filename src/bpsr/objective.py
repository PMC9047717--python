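"""Sparsity-regularized classification loss and the spike-count readout.

The loss is

    L = -sum_c y_c log p_c                       (cross-entropy)
        + (lambda_s / 2) sum_{hidden} ||s||^2    (spiking sparsity, l2)
        + lambda_w  sum_{layers} ||w||_1         (synaptic sparsity, l1)

where the class probabilities come from the scaled spike-count readout

    p_c = softmax(k * sum_t s_c^t),   k = 10 / T,

so that a fully spiking output neuron contributes logit 10 regardless of
the time window.  The spike penalty excludes the output layer (to preserve
classification accuracy); because spikes are boolean, ||s||^2 is simply the
spike count.  Batch reduction: cross-entropy and spike penalty are averaged
over samples; the weight penalty does not depend on data and is added once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lif import LayerParams, LayerTrace

__all__ = ["ReadoutConfig", "LossReport", "readout_probs", "total_loss"]


@dataclass
class ReadoutConfig:
    """Spike-count readout: ``logit_c = k * sum_t s_c^t`` with ``k*T = 10``."""

    T: int
    n_classes: int
    k: float | None = None

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.k is None:
            self.k = 10.0 / self.T


@dataclass
class LossReport:
    cross_entropy: float
    spike_penalty: float
    weight_penalty: float
    total: float
    probs: np.ndarray


def readout_probs(output_spikes: np.ndarray, cfg: ReadoutConfig) -> np.ndarray:
    """Class probabilities from an output spike train ``(..., C, T)``.

    Numerically stabilized (max-subtraction) softmax over the scaled spike
    counts.
    """
    spikes = np.asarray(output_spikes)
    if spikes.shape[-2] != cfg.n_classes:
        raise ValueError(
            f"expected {cfg.n_classes} output neurons, got {spikes.shape[-2]}"
        )
    logits = cfg.k * spikes.sum(axis=-1).astype(float)
    logits -= logits.max(axis=-1, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=-1, keepdims=True)


def total_loss(
    traces: list[LayerTrace],
    params: list[LayerParams],
    labels: np.ndarray,
    lambda_s: float,
    lambda_w: float,
    cfg: ReadoutConfig,
) -> LossReport:
    """Evaluate the full regularized loss for a forward pass.

    ``traces`` are ordered input-side to output-side; ``labels`` is one-hot
    ``(..., C)``.  Returns the component breakdown and the probabilities.
    """
    if lambda_s < 0 or lambda_w < 0:
        raise ValueError("regularization coefficients must be >= 0")
    if not traces:
        raise ValueError("no traces")
    probs = readout_probs(traces[-1].spikes, cfg)
    labels = np.asarray(labels, dtype=float)
    if labels.shape != probs.shape:
        raise ValueError("labels must be one-hot, congruent with probs")
    batch = int(probs.size // cfg.n_classes)

    ce = float(-(labels * np.log(np.clip(probs, 1e-12, 1.0))).sum() / batch)

    hidden_spikes = sum(int(tr.spikes.sum()) for tr in traces[:-1])
    spike_pen = 0.5 * lambda_s * hidden_spikes / batch

    weight_pen = lambda_w * sum(
        float(np.abs(p.w_in).sum() + np.abs(p.w_rec).sum()) for p in params
    )

    return LossReport(
        cross_entropy=ce,
        spike_penalty=float(spike_pen),
        weight_penalty=float(weight_pen),
        total=float(ce + spike_pen + weight_pen),
        probs=probs,
    )
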