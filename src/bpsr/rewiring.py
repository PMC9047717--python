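"""Synaptic rewiring: momentum-tracked pruning and distance-gated growth.

An existing synapse is pruned when its weight magnitude has been driven
below the pruning threshold (typically by the l1 synaptic regularizer):

    prune:  |w| < theta_w

An absent synapse grows back when the exponential moving average ``m`` of
its (unmasked) weight gradient exceeds a distance-scaled threshold —
establishing a longer-range connection requires a stronger growth trend:

    grow:   |m| > theta_m * (1 + mu_m * dist(c_i, c_j) ** p)

with ``dist`` the Euclidean distance between the neuron coordinates in the
unit cube (exponent ``p`` defaults to 1; 0.5 is selectable).  Grown
synapses enter with weight exactly 0 and are moved by subsequent updates.
Momentum is updated from the *unmasked* gradient before masking, so pruned
positions keep accumulating growth pressure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .backprop import GradientBundle
from .lif import LayerParams

__all__ = [
    "RewireState",
    "RewireEvent",
    "update_momentum",
    "prune_mask",
    "grow_mask",
    "apply_rewire",
]


@dataclass
class RewireState:
    """Per-layer rewiring state and hyper-parameters.

    Defaults: theta_w = 1e-2, theta_m = 1e-4, mu_m = 5, beta_m = 0.99.
    ``literal_update`` switches the momentum rule from the standard EMA
    ``m := beta*m + (1-beta)*grad`` to the plain accumulation
    ``m := m + (1-beta)*grad``.  ``candidates`` selects the growth universe:
    every currently absent position (``"all_absent"``) or only positions
    that were wired at some point (``"pruned_only"``).
    """

    momentum_in: np.ndarray
    momentum_rec: np.ndarray
    theta_w: float = 1e-2
    theta_m: float = 1e-4
    mu_m: float = 5.0
    beta_m: float = 0.99
    interval: int = 1
    dist_exponent: float = 1.0
    literal_update: bool = False
    candidates: str = "all_absent"
    ever_in: np.ndarray | None = None
    ever_rec: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.theta_w <= 0 or self.theta_m <= 0:
            raise ValueError("thresholds must be positive")
        if not (0.0 < self.beta_m < 1.0):
            raise ValueError("beta_m must lie in (0, 1)")
        if self.candidates not in ("all_absent", "pruned_only"):
            raise ValueError("unknown candidate universe")

    @classmethod
    def for_layer(cls, params: LayerParams, **kwargs) -> "RewireState":
        return cls(
            momentum_in=np.zeros_like(params.w_in),
            momentum_rec=np.zeros_like(params.w_rec),
            ever_in=params.mask_in.copy(),
            ever_rec=params.mask_rec.copy(),
            **kwargs,
        )


@dataclass
class RewireEvent:
    """Outcome of one rewiring call (for the event log)."""

    pruned: int
    grown: int
    synapses: int


def update_momentum(state: RewireState, grads: GradientBundle) -> RewireState:
    """EMA update of the gradient momentum from *unmasked* gradients."""
    for m, g in (
        (state.momentum_in, grads.d_w_in),
        (state.momentum_rec, grads.d_w_rec),
    ):
        if m.shape != np.shape(g):
            raise ValueError("gradient shape does not match momentum")
        if state.literal_update:
            m += (1.0 - state.beta_m) * g
        else:
            m *= state.beta_m
            m += (1.0 - state.beta_m) * g
    return state


def prune_mask(
    params: LayerParams, state: RewireState
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean matrices marking existing synapses with ``|w| < theta_w``."""
    p_in = params.mask_in & (np.abs(params.w_in) < state.theta_w)
    p_rec = params.mask_rec & (np.abs(params.w_rec) < state.theta_w)
    return p_in, p_rec


def _growth_threshold(state, coords_post, coords_pre):
    d = np.linalg.norm(
        coords_post[:, None, :] - coords_pre[None, :, :], axis=-1
    )
    return state.theta_m * (1.0 + state.mu_m * d**state.dist_exponent)


def grow_mask(
    params: LayerParams,
    state: RewireState,
    coords_pre: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean matrices marking absent synapses whose momentum clears the
    distance-scaled growth threshold (strict ``>``)."""
    if params.coords is None:
        raise ValueError("neuron coordinates required for growth")
    if coords_pre is None:
        raise ValueError("presynaptic coordinates required for growth")
    thr_in = _growth_threshold(state, params.coords, np.asarray(coords_pre))
    g_in = ~params.mask_in & (np.abs(state.momentum_in) > thr_in)
    if params.kind == "recurrent":
        thr_rec = _growth_threshold(state, params.coords, params.coords)
        g_rec = ~params.mask_rec & (np.abs(state.momentum_rec) > thr_rec)
        np.fill_diagonal(g_rec, False)  # no self-synapses
    else:
        g_rec = np.zeros_like(params.mask_rec)  # flat layer stays flat
    if state.candidates == "pruned_only":
        g_in &= state.ever_in
        g_rec &= state.ever_rec
    return g_in, g_rec


def apply_rewire(
    params: LayerParams,
    grads: GradientBundle,
    state: RewireState,
    coords_pre: np.ndarray | None = None,
) -> RewireEvent:
    """Prune and grow in place; mask weights and gradients.

    ``mask := (existing AND NOT prune) OR grow``; then ``W := mask * W``
    and ``dW := mask * dW`` so that absent synapses stay exactly zero and
    receive no update.  Returns the event counts.
    """
    p_in, p_rec = prune_mask(params, state)
    g_in, g_rec = grow_mask(params, state, coords_pre)

    params.mask_in = (params.mask_in & ~p_in) | g_in
    params.mask_rec = (params.mask_rec & ~p_rec) | g_rec
    params.apply_masks()
    grads.d_w_in = grads.d_w_in * params.mask_in
    grads.d_w_rec = grads.d_w_rec * params.mask_rec

    if state.ever_in is not None:
        state.ever_in |= params.mask_in
        state.ever_rec |= params.mask_rec

    return RewireEvent(
        pruned=int(p_in.sum() + p_rec.sum()),
        grown=int(g_in.sum() + g_rec.sum()),
        synapses=params.synapse_count(),
    )
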