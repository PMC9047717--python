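"""Discrete-time heterogeneous leaky integrate-and-fire (LIF) layers.

The membrane potential of neuron ``i`` in a layer evolves as

    u_i^t = u_i^{t-1} * tau_i * (1 - s_i^{t-1})
            + sum_j w_in[i, j] * x_j^t
            + sum_k w_rec[i, k] * s_k^{t-1}
            + b_i

and a spike is emitted whenever the potential reaches threshold:

    s_i^t = H(u_i^t - u_th)        (H = Heaviside, H(0) = 1)

The reset is multiplicative gating: a spike at ``t-1`` zeroes the leak term,
returning the potential to the resting value 0.  ``tau_i in [0, 1]`` is a
per-neuron leak coefficient (heterogeneous neurons); a flat layer has
``w_rec == 0`` while a recurrent layer carries intra-layer synapses that use
the *previous* timestep's spikes (synchronous update).

All operations accept an optional leading batch dimension: state vectors are
``(..., N)`` and spike trains / traces ``(..., N, T)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LayerParams",
    "LayerTrace",
    "lif_step",
    "lif_forward",
    "firing_rate",
]


class ShapeError(ValueError):
    """Inputs are not congruent with the layer's parameter shapes."""


class NumericError(FloatingPointError):
    """A membrane potential became non-finite during simulation."""


@dataclass
class LayerParams:
    """All learnable and structural quantities of one LIF layer.

    Parameters
    ----------
    w_in
        Inter-layer synaptic weights, shape ``(n_out, n_in)``.
    w_rec
        Intra-layer weights, shape ``(n_out, n_out)``; all-zero for a flat
        layer.  The diagonal (self-synapses) is excluded by default — the
        bias already provides self-excitation/suppression.
    bias
        Per-neuron bias, shape ``(n_out,)``.
    tau
        Per-neuron leak coefficients in ``[0, 1]``, shape ``(n_out,)``.
    u_th
        Spiking threshold (default 1).
    mask_in, mask_rec
        Boolean existing-synapse indicators congruent with the weights.
        Masked-out entries of the weights are kept at exactly zero.
    coords
        Neuron positions in the unit cube, shape ``(n_out, 3)``; used by the
        distance-gated synaptic growth rule.
    tau_shared
        If True the layer uses a single homogeneous leak value; the tau
        gradient is then summed across the sharing group.
    kind
        ``"flat"`` or ``"recurrent"``.
    """

    w_in: np.ndarray
    w_rec: np.ndarray
    bias: np.ndarray
    tau: np.ndarray
    u_th: float = 1.0
    mask_in: np.ndarray | None = None
    mask_rec: np.ndarray | None = None
    coords: np.ndarray | None = None
    tau_shared: bool = False
    kind: str = "flat"

    def __post_init__(self) -> None:
        self.w_in = np.asarray(self.w_in, dtype=float)
        self.w_rec = np.asarray(self.w_rec, dtype=float)
        self.bias = np.asarray(self.bias, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        n_out, n_in = self.w_in.shape
        if self.w_rec.shape != (n_out, n_out):
            raise ShapeError(
                f"w_rec shape {self.w_rec.shape} != ({n_out}, {n_out})"
            )
        if self.bias.shape != (n_out,) or self.tau.shape != (n_out,):
            raise ShapeError("bias/tau must have shape (n_out,)")
        if self.mask_in is None:
            self.mask_in = self.w_in != 0
        if self.mask_rec is None:
            self.mask_rec = self.w_rec != 0
        self.mask_in = np.asarray(self.mask_in, dtype=bool)
        self.mask_rec = np.asarray(self.mask_rec, dtype=bool)
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)

    @property
    def n_out(self) -> int:
        return self.w_in.shape[0]

    @property
    def n_in(self) -> int:
        return self.w_in.shape[1]

    def apply_masks(self) -> None:
        """Zero masked-out synapses in place (mask/weight coincidence)."""
        self.w_in *= self.mask_in
        self.w_rec *= self.mask_rec

    def synapse_count(self) -> int:
        """Number of existing synapses (inter- plus intra-layer)."""
        return int(self.mask_in.sum() + self.mask_rec.sum())

    def validate(self) -> None:
        """Check the post-clamp parameter contract."""
        if np.any(self.tau < 0) or np.any(self.tau > 1):
            raise ValueError("tau must lie in [0, 1]")
        for name, w in (("w_in", self.w_in), ("w_rec", self.w_rec),
                        ("bias", self.bias)):
            if np.any(np.abs(w) > self.u_th + 1e-12):
                raise ValueError(f"|{name}| exceeds u_th={self.u_th}")
        if np.any(self.w_in[~self.mask_in] != 0):
            raise ValueError("masked w_in entries must be exactly zero")
        if np.any(self.w_rec[~self.mask_rec] != 0):
            raise ValueError("masked w_rec entries must be exactly zero")


@dataclass
class LayerTrace:
    """Per-timestep membrane potentials and spikes from one forward pass.

    ``potentials`` has shape ``(..., N, T)`` and ``spikes`` is the boolean
    train with ``spikes[..., i, t] = (potentials[..., i, t] >= u_th)``.
    """

    potentials: np.ndarray
    spikes: np.ndarray

    @property
    def T(self) -> int:
        return self.spikes.shape[-1]

    @property
    def n_neurons(self) -> int:
        return self.spikes.shape[-2]


def lif_step(
    params: LayerParams,
    u_prev: np.ndarray,
    s_prev: np.ndarray,
    x_t: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Advance a layer one timestep.

    Returns ``(u_t, s_t)`` where ``u_t`` is the new potential vector and
    ``s_t`` the boolean spike vector.  Leading batch dimensions broadcast.
    """
    u_prev = np.asarray(u_prev, dtype=float)
    s_prev = np.asarray(s_prev)
    x_t = np.asarray(x_t)
    if u_prev.shape[-1] != params.n_out or s_prev.shape[-1] != params.n_out:
        raise ShapeError("state vectors must have length n_out")
    if x_t.shape[-1] != params.n_in:
        raise ShapeError(
            f"input length {x_t.shape[-1]} != n_in {params.n_in}"
        )
    sf = s_prev.astype(float)
    u_t = (
        u_prev * params.tau * (1.0 - sf)
        + x_t.astype(float) @ params.w_in.T
        + sf @ params.w_rec.T
        + params.bias
    )
    if not np.all(np.isfinite(u_t)):
        raise NumericError("non-finite membrane potential in lif_step")
    s_t = u_t >= params.u_th
    return u_t, s_t


def lif_forward(params: LayerParams, x: np.ndarray) -> LayerTrace:
    """Simulate a layer over a full time window.

    Parameters
    ----------
    x
        Boolean input spike train of shape ``(..., n_in, T)``.  The layer is
        iterated from the initial state ``u^0 = s^0 = 0``.
    """
    x = np.asarray(x)
    if x.ndim < 2:
        raise ShapeError("input train must have shape (..., n_in, T)")
    T = x.shape[-1]
    if T < 1:
        raise ShapeError("time window must be >= 1")
    lead = x.shape[:-2]
    u = np.zeros(lead + (params.n_out,))
    s = np.zeros(lead + (params.n_out,), dtype=bool)
    potentials = np.empty(lead + (params.n_out, T))
    spikes = np.empty(lead + (params.n_out, T), dtype=bool)
    for t in range(T):
        try:
            u, s = lif_step(params, u, s, x[..., t])
        except NumericError as exc:
            raise NumericError(f"{exc} (timestep {t})") from None
        potentials[..., t] = u
        spikes[..., t] = s
    return LayerTrace(potentials=potentials, spikes=spikes)


def firing_rate(
    traces: list[LayerTrace] | tuple[LayerTrace, ...],
    exclude_output: bool = False,
) -> float:
    """Mean spikes per neuron per timestep over the included layers.

    Input encoding spikes are never part of ``traces`` and hence never
    counted.  When ``exclude_output`` is set the last trace (the readout
    layer) is dropped, mirroring the scope of the spiking regularizer.
    """
    included = list(traces[:-1]) if exclude_output else list(traces)
    if not included:
        raise ValueError("no traces to compute a firing rate over")
    total = sum(int(tr.spikes.sum()) for tr in included)
    size = sum(tr.spikes.size for tr in included)
    return total / size
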