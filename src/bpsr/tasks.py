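"""Seeded synthetic classification tasks in spike form.

Three task families cover the three encoders and the three kinds of
structure the learner must exploit:

rate_clusters
    Per-class channel-intensity templates in [0, 1] plus Gaussian noise,
    Bernoulli rate-encoded.  Information lives in per-channel spike
    *rates* (an MNIST-like intensity task).
temporal_order
    Each class has a characteristic ordering of the channels; every
    channel carries exactly one rank-order spike, so total spike counts
    are identical across classes by construction and the label is carried
    purely by spike *timing* — solving it requires temporal credit
    assignment.
lc_waveforms
    Class-specific quasi-periodic 2-channel waveforms (distinct
    frequencies, random phase and amplitude jitter), level-crossing
    encoded into 4 bipolar spike channels (an ECG-like task).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coding import EncoderConfig, lc_encode, rank_order_encode, rate_encode

__all__ = ["SpikeDataset", "make_synthetic_task", "collapse_time"]


@dataclass
class SpikeDataset:
    x_train: np.ndarray  # (n_train, N, T) bool
    y_train: np.ndarray  # (n_train, C) one-hot
    x_test: np.ndarray
    y_test: np.ndarray
    kind: str
    meta: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return self.x_train.shape[1]

    @property
    def T(self) -> int:
        return self.x_train.shape[2]

    @property
    def n_classes(self) -> int:
        return self.y_train.shape[1]


def _one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    return np.eye(n_classes)[labels]


def _balanced_labels(n: int, n_classes: int, rng) -> np.ndarray:
    labels = np.arange(n) % n_classes
    rng.shuffle(labels)
    return labels


def make_synthetic_task(
    kind: str,
    n_classes: int = 2,
    n_channels: int = 20,
    T: int = 20,
    n_train: int = 400,
    n_test: int = 200,
    seed: int = 0,
    noise: float | None = None,
    lc_delta: float = 0.1,
) -> SpikeDataset:
    """Generate a seeded spike-train classification dataset."""
    rng = np.random.default_rng(seed)
    if kind == "rate_clusters":
        return _rate_clusters(
            rng, n_classes, n_channels, T, n_train, n_test,
            noise if noise is not None else 0.1,
        )
    if kind == "temporal_order":
        return _temporal_order(
            rng, n_classes, n_channels, T, n_train, n_test,
            noise if noise is not None else 0.3,
        )
    if kind == "lc_waveforms":
        return _lc_waveforms(
            rng, n_classes, T, n_train, n_test, lc_delta,
            noise if noise is not None else 0.01,
        )
    raise ValueError(f"unknown task kind {kind!r}")


def _rate_clusters(rng, C, ch, T, n_train, n_test, noise_sd):
    templates = rng.uniform(0.1, 0.9, size=(C, ch))
    cfg = EncoderConfig(scheme="rate", T=T)

    def build(n):
        labels = _balanced_labels(n, C, rng)
        intensity = np.clip(
            templates[labels] + rng.normal(0, noise_sd, (n, ch)), 0.0, 1.0
        )
        return rate_encode(intensity, cfg, rng=rng), _one_hot(labels, C)

    x_tr, y_tr = build(n_train)
    x_te, y_te = build(n_test)
    return SpikeDataset(
        x_tr, y_tr, x_te, y_te, "rate_clusters",
        meta={"templates": templates, "noise_sd": noise_sd},
    )


def _temporal_order(rng, C, ch, T, n_train, n_test, jitter):
    # per-class channel permutation: rank r fires r-th
    perms = np.array([rng.permutation(ch) for _ in range(C)])
    cfg = EncoderConfig(scheme="rank_order", T=T)

    def build(n):
        labels = _balanced_labels(n, C, rng)
        rank = perms[labels]  # (n, ch)
        base = (ch - rank).astype(float) / ch  # in (0, 1]
        v = np.clip(
            base + rng.normal(0, jitter / ch, (n, ch)), 0.5 / ch, 1.0
        )
        return rank_order_encode(v, cfg), _one_hot(labels, C)

    x_tr, y_tr = build(n_train)
    x_te, y_te = build(n_test)
    return SpikeDataset(
        x_tr, y_tr, x_te, y_te, "temporal_order",
        meta={"perms": perms, "jitter": jitter},
    )


def _lc_waveforms(rng, C, T, n_train, n_test, delta, noise_sd, n_samples=400):
    freqs = 2.0 + 1.5 * np.arange(C)  # cycles per window, per class
    u = np.arange(n_samples) / n_samples
    cfg = EncoderConfig(scheme="level_crossing", T=T, lc_delta=delta)

    def build(n):
        labels = _balanced_labels(n, C, rng)
        x = np.zeros((n, 4, T), dtype=bool)
        for i, c in enumerate(labels):
            amp = rng.uniform(0.7, 0.9)
            phase = rng.uniform(0, 2 * np.pi)
            w = 2 * np.pi * freqs[c]
            sig = np.stack(
                [
                    amp * np.sin(w * u + phase),
                    amp * np.sin(w * u + phase + np.pi / 2),
                ]
            )
            sig += rng.normal(0, noise_sd, sig.shape)
            x[i] = lc_encode(sig, cfg)
        return x, _one_hot(labels, C)

    x_tr, y_tr = build(n_train)
    x_te, y_te = build(n_test)
    return SpikeDataset(
        x_tr, y_tr, x_te, y_te, "lc_waveforms",
        meta={"freqs": freqs[:C], "delta": delta, "noise_sd": noise_sd},
    )


def collapse_time(x: np.ndarray) -> np.ndarray:
    """Collapse a spike train to a single timestep (any spike -> 1).

    The time-blind ablation control: all temporal structure is destroyed
    while per-channel spike *presence* is preserved.
    """
    return np.asarray(x).any(axis=-1, keepdims=True)
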