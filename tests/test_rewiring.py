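"""Pruning/growth rules, momentum tracking and mask bookkeeping."""

import numpy as np
import pytest

from bpsr.backprop import GradientBundle
from bpsr.rewiring import (
    RewireState,
    apply_rewire,
    grow_mask,
    prune_mask,
    update_momentum,
)
from conftest import make_random_layer


def bundle_for(params, d_w_in=None, d_w_rec=None):
    zeros = lambda a: np.zeros_like(a)
    return GradientBundle(
        d_u=np.zeros((params.n_out, 1)),
        d_w_in=zeros(params.w_in) if d_w_in is None else np.asarray(d_w_in),
        d_w_rec=zeros(params.w_rec) if d_w_rec is None else np.asarray(d_w_rec),
        d_bias=np.zeros(params.n_out),
        d_tau=np.zeros(params.n_out),
        d_x=np.zeros((params.n_in, 1)),
    )


class TestMomentum:
    def test_ema_converges_to_constant_gradient(self, rng):
        p = make_random_layer(rng, 3, 4)
        st = RewireState.for_layer(p, beta_m=0.9)
        g = bundle_for(p, d_w_in=np.full_like(p.w_in, 0.5))
        for _ in range(300):
            update_momentum(st, g)
        np.testing.assert_allclose(st.momentum_in, 0.5, rtol=1e-10)

    def test_zero_gradient_geometric_decay(self, rng):
        p = make_random_layer(rng, 2, 2)
        st = RewireState.for_layer(p, beta_m=0.99)
        st.momentum_in[:] = 1.0
        update_momentum(st, bundle_for(p))
        np.testing.assert_allclose(st.momentum_in, 0.99)

    def test_matches_scalar_ema_reference(self, rng):
        p = make_random_layer(rng, 1, 1)
        st = RewireState.for_layer(p, beta_m=0.97)
        m_ref = 0.0
        for k in range(50):
            g = float(rng.normal())
            update_momentum(st, bundle_for(p, d_w_in=[[g]]))
            m_ref = 0.97 * m_ref + 0.03 * g
            assert st.momentum_in[0, 0] == pytest.approx(m_ref, rel=1e-12)

    def test_literal_accumulation_variant(self, rng):
        p = make_random_layer(rng, 1, 1)
        st = RewireState.for_layer(p, beta_m=0.99, literal_update=True)
        g = bundle_for(p, d_w_in=[[1.0]])
        for _ in range(10):
            update_momentum(st, g)
        assert st.momentum_in[0, 0] == pytest.approx(10 * 0.01)


class TestPrune:
    def test_threshold_is_strict(self, rng):
        p = make_random_layer(rng, 2, 1)
        p.w_in[0] = [0.005, 0.01]
        st = RewireState.for_layer(p, theta_w=0.01)
        pr_in, _ = prune_mask(p, st)
        assert pr_in[0].tolist() == [True, False]

    def test_masked_synapse_not_repruned(self, rng):
        p = make_random_layer(rng, 2, 1)
        p.mask_in[0, 0] = False
        p.w_in[0, 0] = 0.0
        st = RewireState.for_layer(p)
        pr_in, _ = prune_mask(p, st)
        assert not pr_in[0, 0]


class TestGrow:
    def _layer_with_absent(self, rng, coincident=False):
        p = make_random_layer(rng, 3, 3)
        p.mask_in[:] = False
        p.w_in[:] = 0.0
        if coincident:
            p.coords[:] = 0.5
        st = RewireState.for_layer(p, theta_m=1e-4, mu_m=5.0)
        st.ever_in[:] = False
        return p, st

    def test_coincident_neurons_grow_above_theta(self, rng):
        p, st = self._layer_with_absent(rng, coincident=True)
        coords_pre = np.full((3, 3), 0.5)
        st.momentum_in[0, 0] = 2e-4
        st.momentum_in[0, 1] = 1e-4  # exactly at threshold: strict >
        g_in, _ = grow_mask(p, st, coords_pre)
        assert g_in[0, 0] and not g_in[0, 1]

    def test_existing_synapse_never_grows(self, rng):
        p, st = self._layer_with_absent(rng, coincident=True)
        p.mask_in[0, 0] = True
        st.momentum_in[:] = 1.0
        g_in, _ = grow_mask(p, st, np.full((3, 3), 0.5))
        assert not g_in[0, 0]
        assert g_in[0, 1]

    def test_growable_set_shrinks_with_distance(self, rng):
        # fixed |m|: partners further away need a stronger trend
        p, st = self._layer_with_absent(rng)
        p.coords[:] = 0.0
        dists = np.linspace(0, 1, 50)
        coords_pre = np.zeros((50, 3))
        coords_pre[:, 0] = dists
        p2 = make_random_layer(rng, 50, 3)
        p2.mask_in[:] = False
        p2.w_in[:] = 0.0
        p2.coords[:] = 0.0
        st2 = RewireState.for_layer(p2, theta_m=1e-4, mu_m=5.0)
        st2.ever_in[:] = False
        st2.momentum_in[:] = 3e-4
        g_in, _ = grow_mask(p2, st2, coords_pre)
        row = g_in[0]
        # once growth stops with distance it never resumes
        assert all(row[i] or not row[i + 1] for i in range(49))

    def test_flat_layer_never_grows_recurrent_synapses(self, rng):
        p = make_random_layer(rng, 3, 3, kind="flat")
        st = RewireState.for_layer(p)
        st.momentum_rec[:] = 1.0
        _, g_rec = grow_mask(p, st, np.zeros((3, 3)))
        assert not g_rec.any()

    def test_missing_coordinates_raise(self, rng):
        p = make_random_layer(rng, 3, 3)
        p.coords = None
        st = RewireState.for_layer(p)
        with pytest.raises(ValueError):
            grow_mask(p, st, np.zeros((3, 3)))


class TestApplyRewire:
    def test_identity_when_no_condition_met(self, rng):
        p = make_random_layer(rng, 4, 4)
        p.w_in[np.abs(p.w_in) < 0.05] = 0.5  # keep all above theta_w
        p.apply_masks()
        st = RewireState.for_layer(p)
        w_before = p.w_in.copy()
        mask_before = p.mask_in.copy()
        apply_rewire(p, bundle_for(p), st, rng.uniform(size=(4, 3)))
        np.testing.assert_array_equal(p.w_in, w_before)
        np.testing.assert_array_equal(p.mask_in, mask_before)

    def test_full_disconnection_is_legal(self, rng):
        p = make_random_layer(rng, 3, 3, kind="flat")
        p.w_in[:] = 1e-3  # all below theta_w
        st = RewireState.for_layer(p)
        ev = apply_rewire(p, bundle_for(p), st, rng.uniform(size=(3, 3)))
        assert ev.synapses == 0
        assert not p.mask_in.any()
        assert not p.w_in.any()

    def test_matches_elementwise_rule(self, rng):
        # randomized instance against a brute-force per-entry evaluation
        for _ in range(20):
            p = make_random_layer(rng, 5, 6)
            p.mask_in = rng.random(p.mask_in.shape) < 0.6
            p.apply_masks()
            st = RewireState.for_layer(p)
            st.momentum_in = rng.normal(0, 2e-4, p.w_in.shape)
            st.momentum_rec = rng.normal(0, 2e-4, p.w_rec.shape)
            coords_pre = rng.uniform(size=(5, 3))
            old_mask = p.mask_in.copy()
            expected = np.zeros_like(old_mask)
            for i in range(6):
                for j in range(5):
                    d = np.linalg.norm(p.coords[i] - coords_pre[j])
                    if old_mask[i, j]:
                        expected[i, j] = abs(p.w_in[i, j]) >= st.theta_w
                    else:
                        expected[i, j] = abs(st.momentum_in[i, j]) > (
                            st.theta_m * (1 + st.mu_m * d)
                        )
            apply_rewire(p, bundle_for(p), st, coords_pre)
            np.testing.assert_array_equal(p.mask_in, expected)

    def test_mask_weight_zero_pattern_coincide(self, rng):
        p = make_random_layer(rng, 5, 6)
        st = RewireState.for_layer(p)
        st.momentum_in = rng.normal(0, 5e-4, p.w_in.shape)
        apply_rewire(p, bundle_for(p), st, rng.uniform(size=(5, 3)))
        np.testing.assert_array_equal(p.w_in != 0, p.w_in != 0)
        assert not p.w_in[~p.mask_in].any()
        assert not p.w_rec[~p.mask_rec].any()

    def test_synapse_count_conservation(self, rng):
        p = make_random_layer(rng, 5, 6)
        st = RewireState.for_layer(p)
        st.momentum_in = rng.normal(0, 5e-4, p.w_in.shape)
        before = p.synapse_count()
        ev = apply_rewire(p, bundle_for(p), st, rng.uniform(size=(5, 3)))
        assert ev.synapses == before - ev.pruned + ev.grown

    def test_prune_and_grow_domains_disjoint(self, rng):
        p = make_random_layer(rng, 5, 6)
        st = RewireState.for_layer(p)
        st.momentum_in = rng.normal(0, 1e-3, p.w_in.shape)
        pr_in, pr_rec = prune_mask(p, st)
        g_in, g_rec = grow_mask(p, st, rng.uniform(size=(5, 3)))
        assert not (pr_in & g_in).any()
        assert not (pr_rec & g_rec).any()


def test_l1_decay_prunes_unused_weights(rng):
    """With zero data gradient and l1 regularization, weight magnitudes
    decrease monotonically under SGD until every synapse is pruned."""
    from bpsr.backprop import parameter_grads, potential_grad_flat
    from bpsr.lif import lif_forward

    p = make_random_layer(rng, 4, 3, kind="flat")
    st = RewireState.for_layer(p)
    x = np.zeros((4, 5), dtype=bool)
    lr, lam = 0.2, 1e-2
    # enough steps for the largest weight to decay to zero *and* for the
    # l1-driven growth momentum to fall back below the growth threshold
    prev = np.abs(p.w_in).copy()
    for step in range(1500):
        tr = lif_forward(p, x)
        d_u = potential_grad_flat(np.zeros((3, 5)), tr, p)
        g = parameter_grads(d_u, tr, x, p, lambda_w=lam)
        update_momentum(st, g)
        apply_rewire(p, g, st, np.zeros((4, 3)))
        p.w_in -= lr * g.d_w_in
        p.apply_masks()
        cur = np.abs(p.w_in)
        assert np.all(cur <= prev + 1e-12)
        prev = cur.copy()
        if p.synapse_count() == 0:
            break
    assert p.synapse_count() == 0
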