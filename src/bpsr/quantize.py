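"""Post-training fixed-point quantization and event-driven energy accounting.

Weights and biases are rounded (nearest-even) to n-bit fixed point with one
sign bit and ``n - 1`` fraction bits, saturating at ``+/-(1 - 2^-(n-1))`` —
consistent with the training-time clamp |w| <= u_th = 1.  Leak coefficients
are rounded to powers of two, ``tau ~= 2^-m``, so the leak multiplication
becomes an m-bit right shift; ``tau = 0`` maps to the full-reset sentinel
``m = inf``.  Accumulation during quantized inference is wide fixed point
(no intermediate rounding), so synaptic integration is pure fixed-point
addition.

Energy is counted event-wise: one accumulate per spike per existing
outgoing synapse, one bias add and one leak multiply (or shift) per
neuron-timestep, converted to normalized units with the cost model
{FL-ADD: 1, FL-MUL: 4, FI-ADD: 0.2, BIT-OP: 0}.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .lif import LayerParams, LayerTrace

__all__ = [
    "QuantSpec",
    "EnergyReport",
    "DEFAULT_COSTS",
    "quantize_params",
    "quantize_network",
    "quantization_error",
    "count_energy",
]

DEFAULT_COSTS = {"FL_ADD": 1.0, "FL_MUL": 4.0, "FI_ADD": 0.2, "BIT_OP": 0.0}


@dataclass
class QuantSpec:
    """Fixed-point format: ``n_bits`` total width including one sign bit."""

    n_bits: int = 8
    tau_shift: np.ndarray | None = None  # filled by quantize_params

    def __post_init__(self) -> None:
        if self.n_bits < 2:
            raise ValueError("need at least a sign bit and one fraction bit")

    @property
    def frac_bits(self) -> int:
        return self.n_bits - 1

    @property
    def step(self) -> float:
        return 2.0 ** (-self.frac_bits)


def _fixed_point(x: np.ndarray, spec: QuantSpec) -> np.ndarray:
    max_int = 2**spec.frac_bits - 1
    q = np.round(x / spec.step)  # nearest-even
    return np.clip(q, -max_int, max_int) * spec.step


def quantize_params(params: LayerParams, spec: QuantSpec) -> LayerParams:
    """Quantize one layer; returns a new LayerParams, fills spec.tau_shift.

    Zero weights stay exactly zero (sparsity preserved) and the masks are
    carried over unchanged.
    """
    w_in = _fixed_point(params.w_in, spec) * params.mask_in
    w_rec = _fixed_point(params.w_rec, spec) * params.mask_rec
    bias = _fixed_point(params.bias, spec)
    tau = np.asarray(params.tau, dtype=float)
    shift = np.where(
        tau > 0, np.round(-np.log2(np.where(tau > 0, tau, 1.0))), np.inf
    )
    shift = np.maximum(shift, 0.0)  # tau = 1 -> m = 0
    tau_q = np.where(np.isinf(shift), 0.0, 2.0**-shift)
    spec.tau_shift = shift
    return replace(
        params,
        w_in=w_in,
        w_rec=w_rec,
        bias=bias,
        tau=tau_q,
        mask_in=params.mask_in.copy(),
        mask_rec=params.mask_rec.copy(),
    )


def quantize_network(layers: list[LayerParams], spec: QuantSpec
                     ) -> tuple[list[LayerParams], list[QuantSpec]]:
    """Quantize every layer with its own tau-shift record."""
    specs = [QuantSpec(n_bits=spec.n_bits) for _ in layers]
    return [quantize_params(p, s) for p, s in zip(layers, specs)], specs


@dataclass
class QuantError:
    max_abs: float
    mean_abs: float


def quantization_error(params: LayerParams, params_q: LayerParams) -> QuantError:
    """Max and mean absolute deviation over w_in, w_rec and bias."""
    diffs = [
        np.abs(params.w_in - params_q.w_in).ravel(),
        np.abs(params.w_rec - params_q.w_rec).ravel(),
        np.abs(params.bias - params_q.bias).ravel(),
    ]
    all_d = np.concatenate(diffs)
    return QuantError(max_abs=float(all_d.max()), mean_abs=float(all_d.mean()))


@dataclass
class EnergyReport:
    synaptic_ops: int
    bias_ops: int
    leak_ops: int
    energy: float


def count_energy(
    input_spikes: np.ndarray,
    traces: list[LayerTrace],
    params: list[LayerParams],
    cost_model: dict | None = None,
    quantized: bool = False,
) -> EnergyReport:
    """Event-driven operation count and normalized energy for one inference.

    Synaptic ops: each input spike triggers one accumulate per existing
    synapse leaving its source neuron; recurrent spikes likewise (shifted
    one step, s^0 = 0).  Bias adds and leak multiplies are per
    neuron-timestep.  With ``quantized`` the adds are fixed point and the
    leak is a shift (cost from ``BIT_OP``).  A leading batch dimension is
    averaged to per-sample numbers.
    """
    costs = dict(DEFAULT_COSTS)
    if cost_model:
        unknown = set(cost_model) - set(costs)
        if unknown:
            raise ValueError(f"unknown op kinds: {sorted(unknown)}")
        costs.update(cost_model)

    x = np.asarray(input_spikes)
    batch = int(x.size // (x.shape[-2] * x.shape[-1])) if x.ndim > 2 else 1

    syn = 0.0
    bias_ops = 0.0
    leak_ops = 0.0
    for lp, tr in zip(params, traces):
        fan_in = lp.mask_in.sum(axis=0)  # synapses leaving each input node
        # spikes per source channel, summed over time (and batch)
        src = x.reshape(-1, x.shape[-2], x.shape[-1]).sum(axis=(0, 2))
        syn += float(src @ fan_in) / batch
        if lp.kind == "recurrent":
            fan_rec = lp.mask_rec.sum(axis=0)
            s = tr.spikes[..., :-1]  # s^{t-1}, t = 2..T; s^0 = 0
            src_rec = s.reshape(-1, s.shape[-2], s.shape[-1]).sum(axis=(0, 2))
            syn += float(src_rec @ fan_rec) / batch
        bias_ops += lp.n_out * tr.T
        leak_ops += lp.n_out * tr.T
        x = tr.spikes

    add_cost = costs["FI_ADD"] if quantized else costs["FL_ADD"]
    leak_cost = costs["BIT_OP"] if quantized else costs["FL_MUL"]
    energy = (syn + bias_ops) * add_cost + leak_ops * leak_cost
    return EnergyReport(
        synaptic_ops=int(round(syn)),
        bias_ops=int(bias_ops),
        leak_ops=int(leak_ops),
        energy=float(energy),
    )
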