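"""Spatio-temporal gradient recursions for flat and recurrent LIF layers.

The spike nonlinearity is the Heaviside function; its derivative (a Dirac
impulse) is replaced by a unit-mass Gaussian surrogate

    g'(x) = (alpha / sqrt(pi)) * exp(-alpha^2 x^2)

during the backward pass only.  The backward-in-time recursion for the
potential gradient runs in O(T) per neuron:

flat layer
    dL/du^T = dL/ds^T * g'(u^T - u_th)
    dL/du^t = dL/ds^t * g'(u^t - u_th) + dL/du^{t+1} * tau * (1 - s^t)

recurrent layer
    dL/du^t = [dL/ds^t + W_rec^T dL/du^{t+1}] * g'(u^t - u_th)
              + dL/du^{t+1} * tau * (1 - s^t)

The gating edge s^{t-1} -> u^t (the reset) carries no information and is
deliberately excluded from the backward graph; only the synaptic edge
through ``w_rec`` is differentiated.  Parameter gradients then follow by
summing over the time window, with the l1 synaptic-regularization term
``lambda_w * sign(w)`` added once (sign(0) = 0, so pruned synapses receive
no push).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lif import LayerParams, LayerTrace, ShapeError

__all__ = [
    "SurrogateConfig",
    "GradientBundle",
    "surrogate_deriv",
    "output_layer_spike_grad",
    "hidden_layer_spike_grad",
    "potential_grad_flat",
    "potential_grad_recurrent",
    "potential_grad",
    "parameter_grads",
]


@dataclass
class SurrogateConfig:
    """Shape of the Gaussian surrogate derivative.

    ``normalization`` selects the leading constant: ``"sqrt_pi"`` gives
    alpha/sqrt(pi) (unit integral — a proper Dirac approximation, the
    default) and ``"pi"`` gives alpha/pi.
    """

    alpha: float = 0.7
    normalization: str = "sqrt_pi"

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.normalization not in ("sqrt_pi", "pi"):
            raise ValueError("normalization must be 'sqrt_pi' or 'pi'")

    @property
    def scale(self) -> float:
        if self.normalization == "sqrt_pi":
            return self.alpha / np.sqrt(np.pi)
        return self.alpha / np.pi


@dataclass
class GradientBundle:
    """Gradients of the loss w.r.t. every layer parameter and its input.

    ``d_u`` and ``d_x`` keep any leading batch dimension; the parameter
    gradients (``d_w_in``, ``d_w_rec``, ``d_bias``, ``d_tau``) are averaged
    over the batch.
    """

    d_u: np.ndarray
    d_w_in: np.ndarray
    d_w_rec: np.ndarray
    d_bias: np.ndarray
    d_tau: np.ndarray
    d_x: np.ndarray


def surrogate_deriv(x, cfg: SurrogateConfig | None = None) -> np.ndarray:
    """Gaussian surrogate for the Heaviside derivative, evaluated at ``x``."""
    if cfg is None:
        cfg = SurrogateConfig()
    x = np.asarray(x, dtype=float)
    return cfg.scale * np.exp(-(cfg.alpha**2) * x * x)


def output_layer_spike_grad(
    probs: np.ndarray, labels: np.ndarray, T: int
) -> np.ndarray:
    """Gradient of softmax cross-entropy w.r.t. the output spike train.

    Because the readout sums spikes over the window, the gradient is the
    same at every timestep: ``dL/ds_c^t = p_c - y_c``.  Shapes ``(..., C)``
    in, ``(..., C, T)`` out.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if probs.shape != labels.shape:
        raise ShapeError("probs and labels must have the same shape")
    if not np.allclose(probs.sum(axis=-1), 1.0, atol=1e-6):
        raise ValueError("probs must be normalized probability vectors")
    diff = probs - labels
    return np.repeat(diff[..., None], T, axis=-1)


def hidden_layer_spike_grad(
    d_x_next: np.ndarray, spikes: np.ndarray, lambda_s: float
) -> np.ndarray:
    """Spike gradient of a hidden layer.

    The following layer's input gradient plus the l2 spiking-regularization
    derivative ``lambda_s * s`` (zero wherever the neuron did not spike).
    """
    d_x_next = np.asarray(d_x_next, dtype=float)
    spikes = np.asarray(spikes)
    if d_x_next.shape != spikes.shape:
        raise ShapeError("d_x_next and spikes must be congruent")
    return d_x_next + lambda_s * spikes.astype(float)


def potential_grad_flat(
    d_s: np.ndarray,
    trace: LayerTrace,
    params: LayerParams,
    cfg: SurrogateConfig | None = None,
) -> np.ndarray:
    """O(T) backward recursion for the potential gradient of a flat layer."""
    return _potential_grad(d_s, trace, params, cfg, recurrent=False)


def potential_grad_recurrent(
    d_s: np.ndarray,
    trace: LayerTrace,
    params: LayerParams,
    cfg: SurrogateConfig | None = None,
) -> np.ndarray:
    """Backward recursion with the intra-layer (transposed-weight) term."""
    return _potential_grad(d_s, trace, params, cfg, recurrent=True)


def potential_grad(
    d_s: np.ndarray,
    trace: LayerTrace,
    params: LayerParams,
    cfg: SurrogateConfig | None = None,
) -> np.ndarray:
    """Dispatch on the layer kind."""
    return _potential_grad(
        d_s, trace, params, cfg, recurrent=(params.kind == "recurrent")
    )


def _potential_grad(d_s, trace, params, cfg, recurrent):
    if cfg is None:
        cfg = SurrogateConfig()
    d_s = np.asarray(d_s, dtype=float)
    if d_s.shape != trace.spikes.shape:
        raise ShapeError("d_s must be congruent with the trace")
    if not np.all(np.isfinite(d_s)):
        raise FloatingPointError("non-finite incoming spike gradient")
    T = trace.T
    gp = surrogate_deriv(trace.potentials - params.u_th, cfg)
    s = trace.spikes.astype(float)
    d_u = np.empty_like(d_s)
    d_u[..., T - 1] = d_s[..., T - 1] * gp[..., T - 1]
    for t in range(T - 2, -1, -1):
        nxt = d_u[..., t + 1]
        bracket = d_s[..., t]
        if recurrent:
            bracket = bracket + nxt @ params.w_rec
        d_u[..., t] = bracket * gp[..., t] + nxt * params.tau * (
            1.0 - s[..., t]
        )
    return d_u


def parameter_grads(
    d_u: np.ndarray,
    trace: LayerTrace,
    x: np.ndarray,
    params: LayerParams,
    lambda_w: float = 0.0,
) -> GradientBundle:
    """Gradients for every parameter and the input spikes from ``dL/du``.

    With ``u^0 = s^0 = 0``:

    - ``d_x[j, t]   = sum_i d_u[i, t] * w_in[i, j]``
    - ``d_w_in[i,j] = sum_t d_u[i, t] * x[j, t]       + lambda_w * sign(w)``
    - ``d_w_rec[i,k]= sum_t d_u[i, t] * s[k, t-1]     + lambda_w * sign(w)``
    - ``d_bias[i]   = sum_t d_u[i, t]``
    - ``d_tau[i]    = sum_t d_u[i, t] * u[i,t-1] * (1 - s[i,t-1])``

    Leading batch dimensions of ``d_u``/``x`` are averaged for parameter
    gradients (the l1 term is added once, after the mean); ``d_x`` keeps
    the batch.  The result is the raw (unmasked) gradient — masking happens
    in the rewiring step so that growth momentum can see it first.
    """
    d_u = np.asarray(d_u, dtype=float)
    x = np.asarray(x).astype(float)
    N, T = params.n_out, trace.T
    if d_u.shape[-2:] != (N, T):
        raise ShapeError("d_u shape mismatch")
    if x.shape[-2:] != (params.n_in, T):
        raise ShapeError("input train shape mismatch")
    batch = int(d_u.size // (N * T))

    d_x = np.einsum("...it,ij->...jt", d_u, params.w_in)

    # flatten leading batch dimensions for the summed parameter gradients
    du_f = d_u.reshape(batch, N, T)
    x_f = x.reshape(batch, params.n_in, T)

    d_w_in = np.einsum("bit,bjt->ij", du_f, x_f) / batch
    d_bias = du_f.sum(axis=(0, 2)) / batch

    s = trace.spikes.astype(float)
    # previous-step state with u^0 = s^0 = 0
    u_prev = np.zeros_like(trace.potentials)
    u_prev[..., 1:] = trace.potentials[..., :-1]
    s_prev = np.zeros_like(s)
    s_prev[..., 1:] = s[..., :-1]
    up_f = (u_prev * (1.0 - s_prev)).reshape(batch, N, T)
    sp_f = s_prev.reshape(batch, N, T)

    d_tau = np.einsum("bit,bit->i", du_f, up_f) / batch
    if params.tau_shared:
        d_tau = np.full_like(d_tau, d_tau.sum())
    d_w_rec = np.einsum("bit,bkt->ik", du_f, sp_f) / batch

    if lambda_w:
        d_w_in = d_w_in + lambda_w * np.sign(params.w_in)
        d_w_rec = d_w_rec + lambda_w * np.sign(params.w_rec)

    return GradientBundle(
        d_u=d_u,
        d_w_in=d_w_in,
        d_w_rec=d_w_rec,
        d_bias=d_bias,
        d_tau=d_tau,
        d_x=d_x,
    )
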