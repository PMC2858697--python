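"""STDP event rules, scaling, and the BCM correspondence."""

import numpy as np
import pytest

from spikeica import _kernels
from spikeica.plasticity import (DeadScopeError, PairingState, STDPParams,
                                 ScalingConfig, bcm_threshold,
                                 clip_nonnegative, expected_drift_nn,
                                 scale_weights, stdp_on_post, stdp_on_pre)


def enumerate_pairings(pre_times, post_times, p: STDPParams) -> float:
    """Brute-force oracle: each presynaptic spike pairs once with its nearest
    preceding postsynaptic spike (depression) and once with its nearest
    following postsynaptic spike (potentiation); coincident pairs are void."""
    dw = 0.0
    post = np.asarray(post_times, dtype=float)
    for t in pre_times:
        before = post[post < t]
        if before.size:
            dw -= p.A_minus * np.exp(-(t - before.max()) / p.tau_minus)
        after = post[post > t]
        if after.size:
            dw += p.A_plus * np.exp(-(after.min() - t) / p.tau_plus)
    return dw


def replay(pre_times, post_times, p: STDPParams) -> float:
    """Feed a single-synapse spike sequence through the event-driven rules."""
    events = sorted([(t, "pre") for t in pre_times]
                    + [(t, "post") for t in post_times])
    s = PairingState(n_syn=1)
    dw = 0.0
    for t, kind in events:
        if kind == "pre":
            dw += stdp_on_pre(s, 0, t, p)[0]
        else:
            dw += stdp_on_post(s, t, p)[0]
    return dw


class TestEventRules:
    def test_no_post_spike_means_no_depression(self):
        s = PairingState(n_syn=2)
        dw = stdp_on_pre(s, 0, 10.0, STDPParams())
        assert np.all(dw == 0)

    def test_depression_closed_form(self):
        # post at 10, pre at 20: dw = -A_minus * exp(-10/34)
        p = STDPParams()
        s = PairingState(n_syn=1)
        stdp_on_post(s, 10.0, p)
        dw = stdp_on_pre(s, 0, 20.0, p)
        assert dw[0] == pytest.approx(-0.0035 * np.exp(-10.0 / 34.0))
        assert dw[0] == pytest.approx(-0.002609, abs=1e-6)

    def test_potentiation_closed_form(self):
        # pre at 10, post at 20: dw = A_plus * exp(-10/17)
        p = STDPParams()
        s = PairingState(n_syn=1)
        stdp_on_pre(s, 0, 10.0, p)
        dw = stdp_on_post(s, 20.0, p)
        assert dw[0] == pytest.approx(0.005 * np.exp(-10.0 / 17.0))
        assert dw[0] == pytest.approx(0.002777, abs=1e-6)

    def test_isolated_post_spike_changes_nothing(self):
        s = PairingState(n_syn=3)
        assert np.all(stdp_on_post(s, 5.0, STDPParams()) == 0)

    def test_exact_coincidence_contributes_nothing(self):
        p = STDPParams()
        s = PairingState(n_syn=1)
        stdp_on_pre(s, 0, 10.0, p)
        assert stdp_on_post(s, 10.0, p)[0] == 0.0

    def test_time_regression_rejected(self):
        s = PairingState(n_syn=1)
        stdp_on_pre(s, 0, 10.0, STDPParams())
        with pytest.raises(ValueError):
            stdp_on_pre(s, 0, 5.0, STDPParams())

    def test_quadruplet_nearest_vs_all_to_all(self):
        """pre(0), post(8), post(16), pre(24): hand-enumerated pairings."""
        nn = STDPParams(mode="nearest")
        aa = STDPParams(mode="all_to_all")
        got_nn = replay([0.0, 24.0], [8.0, 16.0], nn)
        got_aa = replay([0.0, 24.0], [8.0, 16.0], aa)
        # nearest: pre(0)+post(8) LTP; pre(24)+post(16) LTD -- pre(0) pairs
        # only with its nearest following post
        want_nn = (0.005 * np.exp(-8 / 17.0) - 0.0035 * np.exp(-8 / 34.0))
        # all-to-all pairs every pre with every post
        want_aa = (0.005 * (np.exp(-8 / 17.0) + np.exp(-16 / 17.0))
                   - 0.0035 * (np.exp(-8 / 34.0) + np.exp(-16 / 34.0)))
        assert got_nn == pytest.approx(want_nn)
        assert got_aa == pytest.approx(want_aa)

    def test_nearest_matches_enumeration_on_random_trains(self, rng):
        p = STDPParams()
        for _ in range(50):
            n_pre, n_post = rng.integers(1, 8, 2)
            pre = np.sort(rng.uniform(0, 200, n_pre))
            post = np.sort(rng.uniform(0, 200, n_post))
            if np.intersect1d(np.round(pre, 6), np.round(post, 6)).size:
                continue
            assert replay(pre, post, p) == pytest.approx(
                enumerate_pairings(pre, post, p), rel=1e-10)

    def test_single_pair_nearest_equals_all_to_all(self, rng):
        for _ in range(20):
            t1, t2 = np.sort(rng.uniform(0, 100, 2))
            for order in [([t1], [t2]), ([t2], [t1])]:
                got_nn = replay(order[0], order[1], STDPParams(mode="nearest"))
                got_aa = replay(order[0], order[1], STDPParams(mode="all_to_all"))
                assert got_nn == pytest.approx(got_aa)

    def test_triplet_with_zero_a3_reduces_to_pair_rule(self, rng):
        pair = STDPParams(mode="nearest")
        trip = STDPParams(mode="triplet", A3_plus=0.0)
        for _ in range(20):
            pre = np.sort(rng.uniform(0, 300, 6))
            post = np.sort(rng.uniform(0, 300, 4))
            assert replay(pre, post, trip) == pytest.approx(
                replay(pre, post, pair))

    def test_triplet_amplifies_with_recent_post_activity(self):
        p = STDPParams(mode="triplet", A3_plus=0.01, tau_y=100.0)
        # two posts close together: the second LTP is amplified
        lone = replay([10.0], [20.0], p)
        s = PairingState(n_syn=1)
        stdp_on_post(s, 15.0, p)
        stdp_on_pre(s, 0, 30.0, p)
        dw = stdp_on_post(s, 40.0, p)[0]
        expected = (0.005 + 0.01 * np.exp(-25.0 / 100.0)) * np.exp(-10.0 / 17.0)
        assert dw == pytest.approx(expected)
        assert dw > lone


class TestClippingAndScaling:
    def test_clip(self):
        np.testing.assert_array_equal(clip_nonnegative(np.array([-0.1, 0.2])),
                                      [0.0, 0.2])
        w = np.array([0.3, 0.0, 1.0])
        np.testing.assert_array_equal(clip_nonnegative(w), w)
        np.testing.assert_array_equal(
            clip_nonnegative(clip_nonnegative(np.array([-1.0, 2.0]))), [0.0, 2.0])

    def test_l1_scaling(self):
        out = scale_weights(np.array([2.0, 2.0]), ScalingConfig(W_total=1.0))
        np.testing.assert_allclose(out, [0.5, 0.5])

    def test_already_normalized_unchanged(self):
        w = np.array([0.25, 0.75])
        out = scale_weights(w, ScalingConfig(W_total=1.0))
        np.testing.assert_allclose(out, w, atol=1e-12)

    def test_l2_scaling(self):
        out = scale_weights(np.array([3.0, 4.0]),
                            ScalingConfig(W_total=1.0, norm_order="L2"))
        assert np.linalg.norm(out) == pytest.approx(1.0)

    def test_per_population_scopes_independent(self):
        w = np.array([1.0, 3.0, 10.0, 30.0])
        masks = [np.array([True, True, False, False]),
                 np.array([False, False, True, True])]
        out = scale_weights(w, ScalingConfig(W_total=2.0), masks)
        assert out[:2].sum() == pytest.approx(2.0)
        assert out[2:].sum() == pytest.approx(2.0)

    def test_dead_scope_raises(self):
        with pytest.raises(DeadScopeError):
            scale_weights(np.zeros(3), ScalingConfig(W_total=1.0))

    def test_scaling_norm_accuracy(self, rng):
        for _ in range(20):
            w = rng.uniform(0, 5, 30)
            out = scale_weights(w, ScalingConfig(W_total=7.0))
            assert abs(out.sum() - 7.0) < 1e-9 * 7.0


class TestBCMCorrespondence:
    def test_zero_post_rate_gives_zero_drift(self):
        assert expected_drift_nn(10.0, 0.0, STDPParams()) == 0.0

    def test_drift_linear_in_presynaptic_rate(self):
        p = STDPParams()
        base = expected_drift_nn(5.0, 12.0, p) / 5.0
        for rho in (10.0, 20.0):
            assert expected_drift_nn(rho, 12.0, p) / rho == pytest.approx(
                base, rel=1e-9)

    def test_threshold_closed_form(self):
        p = STDPParams(A_plus=0.01, A_minus=0.006, tau_plus=20.0, tau_minus=40.0)
        assert bcm_threshold(p) == pytest.approx(12.5)

    def test_threshold_zero_when_areas_balance(self):
        p = STDPParams(A_plus=0.0070, A_minus=0.0035, tau_plus=17.0,
                       tau_minus=34.0)
        assert bcm_threshold(p) == pytest.approx(0.0, abs=1e-9)

    def test_outside_regime_rejected(self):
        with pytest.raises(ValueError, match="A_plus > A_minus"):
            bcm_threshold(STDPParams(A_plus=0.003, A_minus=0.0035))
        with pytest.raises(ValueError, match="tau_minus"):
            bcm_threshold(STDPParams(A_plus=0.0069, A_minus=0.0035,
                                     tau_plus=17.0, tau_minus=17.0))

    def test_threshold_is_root_of_drift(self):
        p = STDPParams(A_plus=0.01, A_minus=0.006, tau_plus=20.0, tau_minus=40.0)
        th = bcm_threshold(p)
        from scipy.optimize import brentq
        root = brentq(lambda r: expected_drift_nn(10.0, r, p), 1e-3, 1e3)
        assert root == pytest.approx(th, rel=1e-9)

    def test_monte_carlo_drift_matches_closed_form(self):
        """Mandatory validation: continuous-time Poisson simulation of the
        pairing scheme reproduces the closed-form drift within 3 SE."""
        p = STDPParams()
        T, reps = 5000.0, 10
        mc = np.array([_kernels.stdp_drift_kernel(
            np.random.default_rng(500 + i), 10.0, 10.0, T,
            p.A_plus, p.A_minus, p.tau_plus, p.tau_minus) / T
            for i in range(reps)])
        cf = expected_drift_nn(10.0, 10.0, p)
        se = mc.std(ddof=1) / np.sqrt(reps)
        assert abs(mc.mean() - cf) < 3 * se

    def test_drift_sign_change_across_threshold(self):
        """BCM signature: negative drift below theta, positive above."""
        p = STDPParams(A_plus=0.01, A_minus=0.006, tau_plus=20.0, tau_minus=40.0)
        th = bcm_threshold(p)
        T, reps = 3000.0, 8
        for rho, sign in ((th / 2, -1.0), (2 * th, 1.0)):
            mc = np.array([_kernels.stdp_drift_kernel(
                np.random.default_rng(900 + i), rho, rho, T,
                p.A_plus, p.A_minus, p.tau_plus, p.tau_minus) / T
                for i in range(reps)])
            se = mc.std(ddof=1) / np.sqrt(reps)
            assert sign * mc.mean() > 3 * se
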