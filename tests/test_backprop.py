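"""Gradient recursions versus the fully-unrolled chain-rule oracle."""

import numpy as np
import pytest
from scipy.integrate import quad

from bpsr.backprop import (
    SurrogateConfig,
    hidden_layer_spike_grad,
    output_layer_spike_grad,
    parameter_grads,
    potential_grad_flat,
    potential_grad_recurrent,
    surrogate_deriv,
)
from bpsr.lif import lif_forward
from conftest import make_random_layer
from oracles import unrolled_gradients


class TestSurrogate:
    def test_peak_value(self):
        cfg = SurrogateConfig(alpha=0.7)
        assert surrogate_deriv(0.0, cfg) == pytest.approx(0.7 / np.sqrt(np.pi))

    def test_even_symmetry(self, rng):
        cfg = SurrogateConfig(alpha=1.3)
        x = rng.normal(size=20)
        np.testing.assert_allclose(
            surrogate_deriv(x, cfg), surrogate_deriv(-x, cfg)
        )

    @pytest.mark.parametrize("alpha", [0.3, 0.7, 2.0])
    def test_unit_mass(self, alpha):
        # the surrogate approximates a Dirac impulse: total mass 1
        cfg = SurrogateConfig(alpha=alpha)
        integral, _ = quad(lambda x: surrogate_deriv(x, cfg), -50, 50)
        assert integral == pytest.approx(1.0, abs=1e-9)

    def test_alpha_over_pi_variant(self):
        cfg = SurrogateConfig(alpha=0.7, normalization="pi")
        assert surrogate_deriv(0.0, cfg) == pytest.approx(0.7 / np.pi)


class TestSpikeGrads:
    def test_output_grad_constant_over_time(self):
        g = output_layer_spike_grad([0.7, 0.3], [1.0, 0.0], T=4)
        np.testing.assert_allclose(g[0], -0.3)
        np.testing.assert_allclose(g[1], 0.3)
        # softmax/CE identity: class-sum is zero at each t
        np.testing.assert_allclose(g.sum(axis=0), 0.0, atol=1e-12)

    def test_output_grad_zero_when_correct(self):
        g = output_layer_spike_grad([1.0, 0.0], [1.0, 0.0], T=3)
        assert not g.any()

    def test_output_grad_rejects_unnormalized(self):
        with pytest.raises(ValueError):
            output_layer_spike_grad([0.7, 0.7], [1.0, 0.0], T=2)

    def test_hidden_grad_regularizer(self):
        s = np.array([[1, 0], [0, 1]], dtype=bool)
        d0 = np.zeros((2, 2))
        g = hidden_layer_spike_grad(d0, s, lambda_s=1e-7)
        # lambda_s only acts where the neuron actually spiked
        np.testing.assert_allclose(g, 1e-7 * s)
        np.testing.assert_array_equal(
            hidden_layer_spike_grad(d0 + 2.0, s, 0.0), d0 + 2.0
        )


def _random_instance(rng, kind):
    n_in = int(rng.integers(1, 8))
    n_out = int(rng.integers(1, 9))
    T = int(rng.integers(1, 17))
    p = make_random_layer(rng, n_in, n_out, kind=kind)
    x = rng.random((n_in, T)) < 0.4
    d_s = rng.normal(size=(n_out, T))
    return p, x, d_s


def _rel_err(a, b):
    scale = max(np.abs(b).max(), 1e-30)
    return np.abs(a - b).max() / scale


class TestPotentialGrad:
    def test_base_case_T1(self, rng):
        p = make_random_layer(rng, 3, 4, kind="flat")
        x = rng.random((3, 1)) < 0.5
        tr = lif_forward(p, x)
        d_s = rng.normal(size=(4, 1))
        cfg = SurrogateConfig()
        d_u = potential_grad_flat(d_s, tr, p, cfg)
        expected = d_s * surrogate_deriv(tr.potentials - p.u_th, cfg)
        np.testing.assert_allclose(d_u, expected)

    def test_zero_error_zero_gradient(self, rng):
        p = make_random_layer(rng, 3, 4)
        x = rng.random((3, 8)) < 0.5
        tr = lif_forward(p, x)
        d_u = potential_grad_recurrent(np.zeros((4, 8)), tr, p)
        assert not d_u.any()

    def test_recurrent_degenerates_to_flat(self, rng):
        p = make_random_layer(rng, 3, 4, kind="recurrent")
        p.w_rec[:] = 0.0
        x = rng.random((3, 10)) < 0.5
        tr = lif_forward(p, x)
        d_s = rng.normal(size=(4, 10))
        np.testing.assert_allclose(
            potential_grad_recurrent(d_s, tr, p),
            potential_grad_flat(d_s, tr, p),
        )

    @pytest.mark.parametrize("kind", ["flat", "recurrent"])
    def test_matches_unrolled_oracle(self, rng, kind):
        cfg = SurrogateConfig()
        grad_fn = (
            potential_grad_flat if kind == "flat" else potential_grad_recurrent
        )
        for _ in range(40):
            p, x, d_s = _random_instance(rng, kind)
            tr = lif_forward(p, x)
            d_u = grad_fn(d_s, tr, p, cfg)
            oracle = unrolled_gradients(p, x, d_s, alpha=cfg.alpha)
            assert _rel_err(d_u, oracle["d_u"]) < 1e-10

    def test_linearity_in_ds(self, rng):
        p, x, d_s1 = _random_instance(rng, "recurrent")
        d_s2 = rng.normal(size=d_s1.shape)
        tr = lif_forward(p, x)
        lhs = potential_grad_recurrent(2.0 * d_s1 - 3.0 * d_s2, tr, p)
        rhs = 2.0 * potential_grad_recurrent(
            d_s1, tr, p
        ) - 3.0 * potential_grad_recurrent(d_s2, tr, p)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)


class TestParameterGrads:
    @pytest.mark.parametrize("kind", ["flat", "recurrent"])
    def test_matches_unrolled_oracle(self, rng, kind):
        cfg = SurrogateConfig()
        grad_fn = (
            potential_grad_flat if kind == "flat" else potential_grad_recurrent
        )
        for _ in range(30):
            p, x, d_s = _random_instance(rng, kind)
            tr = lif_forward(p, x)
            d_u = grad_fn(d_s, tr, p, cfg)
            g = parameter_grads(d_u, tr, x, p, lambda_w=0.01)
            oracle = unrolled_gradients(p, x, d_s, cfg.alpha, lambda_w=0.01)
            for name in ("d_x", "d_w_in", "d_w_rec", "d_bias", "d_tau"):
                assert _rel_err(getattr(g, name), oracle[name]) < 1e-10, name

    def test_pure_regularization_gradient(self, rng):
        # with no loss signal, d_w is exactly lambda_w * sign(w)
        p, x, _ = _random_instance(rng, "recurrent")
        tr = lif_forward(p, x)
        d_u = potential_grad_recurrent(np.zeros(tr.spikes.shape), tr, p)
        g = parameter_grads(d_u, tr, x, p, lambda_w=0.01)
        np.testing.assert_allclose(g.d_w_in, 0.01 * np.sign(p.w_in))
        np.testing.assert_allclose(g.d_w_rec, 0.01 * np.sign(p.w_rec))
        # sign(0) = 0: the zeroed diagonal receives no push
        assert not g.d_w_rec.diagonal().any()

    def test_zero_du_zero_grads(self, rng):
        p, x, _ = _random_instance(rng, "flat")
        tr = lif_forward(p, x)
        g = parameter_grads(
            np.zeros(tr.spikes.shape), tr, x, p, lambda_w=0.0
        )
        for name in ("d_x", "d_w_in", "d_w_rec", "d_bias", "d_tau"):
            assert not getattr(g, name).any()

    def test_batch_mean_equals_mean_of_samples(self, rng):
        p = make_random_layer(rng, 3, 4)
        x = rng.random((6, 3, 8)) < 0.5
        tr = lif_forward(p, x)
        d_s = rng.normal(size=(6, 4, 8))
        d_u = potential_grad_recurrent(d_s, tr, p)
        g = parameter_grads(d_u, tr, x, p)
        per_sample = []
        for b in range(6):
            tr_b = lif_forward(p, x[b])
            du_b = potential_grad_recurrent(d_s[b], tr_b, p)
            per_sample.append(parameter_grads(du_b, tr_b, x[b], p).d_w_in)
        np.testing.assert_allclose(g.d_w_in, np.mean(per_sample, axis=0))

    def test_tau_shared_sums_gradient(self, rng):
        p = make_random_layer(rng, 3, 4)
        p.tau_shared = True
        x = rng.random((3, 8)) < 0.5
        tr = lif_forward(p, x)
        d_u = potential_grad_recurrent(rng.normal(size=(4, 8)), tr, p)
        g = parameter_grads(d_u, tr, x, p)
        assert np.ptp(g.d_tau) == 0.0
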