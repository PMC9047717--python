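"""Spike encoders: rate, rank-order and level-crossing coding.

rate
    Each channel's value in [0, 1] is a Bernoulli probability sampled
    independently at every timestep — dense, timing-free coding.
rank_order
    Each channel emits at most one spike; larger values spike earlier
    (latency ``t(v) = round((1 - v / v_max) * (T - 1))``, zero-based).
    Zero values never spike, so the train carries information purely in
    spike timing with at most N spikes total.
level_crossing
    Bipolar edge coding of analog signals: an UP spike whenever the signal
    rises through an absolute amplitude level ``k * delta``, a DOWN spike
    for falls.  A C-channel signal becomes a 2C-channel spike train
    (e.g. 2-lead ECG -> 4 spike channels); native samples are mapped onto
    the T grid by uniform binning with OR-reduction.

Also provides a reader for MNIST-style IDX files for optional real-data
runs.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

import numpy as np

__all__ = [
    "EncoderConfig",
    "rate_encode",
    "rank_order_encode",
    "lc_encode",
    "lc_reconstruct",
    "read_idx",
]


@dataclass
class EncoderConfig:
    scheme: str = "rate"
    T: int = 20
    lc_delta: float = 0.1
    seed: int = 0
    strict_rank: bool = False

    def __post_init__(self) -> None:
        if self.scheme not in ("rate", "rank_order", "level_crossing"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.scheme == "level_crossing" and self.lc_delta <= 0:
            raise ValueError("lc_delta must be positive")


def rate_encode(
    values: np.ndarray,
    cfg: EncoderConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Bernoulli spike train ``(..., N, T)`` from intensities in [0, 1]."""
    values = np.asarray(values, dtype=float)
    if np.any(values < 0) or np.any(values > 1):
        raise ValueError("rate coding requires values in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    return rng.random(values.shape + (cfg.T,)) < values[..., None]


def rank_order_encode(values: np.ndarray, cfg: EncoderConfig) -> np.ndarray:
    """Single-spike latency code ``(..., N, T)``: larger value, earlier spike.

    Ties share a timestep unless ``cfg.strict_rank`` is set, in which case
    channels get unique times by sort rank (index tiebreak).
    """
    values = np.asarray(values, dtype=float)
    T = cfg.T
    spikes = np.zeros(values.shape + (T,), dtype=bool)
    flat = values.reshape(-1, values.shape[-1])
    out = spikes.reshape(-1, values.shape[-1], T)
    for b in range(flat.shape[0]):
        v = flat[b]
        active = v > 0
        if not active.any():
            continue
        vmax = v[active].max()
        if cfg.strict_rank:
            order = np.argsort(-v[active], kind="stable")
            n_act = int(active.sum())
            # unique latencies spread over the window, value rank order
            if n_act > 1:
                lat = np.round(np.linspace(0, T - 1, n_act)).astype(int)
            else:
                lat = np.zeros(1, dtype=int)
            times = np.empty(n_act, dtype=int)
            times[order] = lat
            out[b, np.flatnonzero(active), times] = True
        else:
            times = np.round((1.0 - v[active] / vmax) * (T - 1)).astype(int)
            out[b, np.flatnonzero(active), times] = True
    return spikes


def lc_encode(signal: np.ndarray, cfg: EncoderConfig) -> np.ndarray:
    """Level-crossing encode an analog signal ``(C, S)`` to ``(2C, T)``.

    Channel layout: channels ``2c`` carry UP spikes and ``2c + 1`` DOWN
    spikes of analog channel ``c``.  Levels are an absolute ``k * delta``
    grid (no drift); at most one spike per channel per native sample, so
    the signal should be sampled finely enough that it changes by less
    than ``delta`` per sample.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim == 1:
        signal = signal[None, :]
    if not np.all(np.isfinite(signal)):
        raise ValueError("signal must be finite")
    C, S = signal.shape
    delta = cfg.lc_delta
    native = np.zeros((2 * C, S), dtype=bool)
    eps = 1e-9
    for c in range(C):
        level = int(np.floor(signal[c, 0] / delta + eps))
        for i in range(1, S):
            target = int(np.floor(signal[c, i] / delta + eps))
            if target > level:
                native[2 * c, i] = True
                level += 1
            elif target < level:
                native[2 * c + 1, i] = True
                level -= 1
    T = cfg.T
    if T >= S:
        spikes = np.zeros((2 * C, T), dtype=bool)
        idx = (np.arange(S) * T) // S
        for i in range(S):
            spikes[:, idx[i]] |= native[:, i]
        return spikes
    # uniform binning with OR-reduction
    spikes = np.zeros((2 * C, T), dtype=bool)
    edges = (np.arange(T + 1) * S) // T
    for t in range(T):
        spikes[:, t] = native[:, edges[t] : edges[t + 1]].any(axis=1)
    return spikes


def lc_reconstruct(spikes: np.ndarray, delta: float) -> np.ndarray:
    """Staircase reconstruction ``(cum UP - cum DOWN) * delta`` per channel.

    Tracks the (zero-referenced) original within ``delta`` at every sample
    when the encoder's slope assumption holds.
    """
    spikes = np.asarray(spikes, dtype=float)
    up = spikes[0::2].cumsum(axis=-1)
    down = spikes[1::2].cumsum(axis=-1)
    return (up - down) * delta


def read_idx(path) -> np.ndarray:
    """Read an IDX file (MNIST format, magic 0x0801 vectors / 0x0803 images)."""
    with open(path, "rb") as fh:
        magic = struct.unpack(">I", fh.read(4))[0]
        if magic == 0x0801:
            (n,) = struct.unpack(">I", fh.read(4))
            return np.frombuffer(fh.read(n), dtype=np.uint8)
        if magic == 0x0803:
            n, rows, cols = struct.unpack(">III", fh.read(12))
            data = np.frombuffer(fh.read(n * rows * cols), dtype=np.uint8)
            return data.reshape(n, rows, cols)
        raise ValueError(f"unsupported IDX magic 0x{magic:08x}")
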