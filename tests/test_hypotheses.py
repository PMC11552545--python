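import numpy as np
import pytest

from sdokit.core import check_sdo_constraints, perievent_distributions, predict_post
from sdokit.hypotheses import (
    build_all_hypotheses,
    h1_null,
    h2_diffusion,
    h3_sta,
    h4_background,
    h5_markov,
    h6_background_plus_sta,
    h7_spike_sdo,
    markov_transition_matrix,
)
from sdokit.quantize import StateSeries

from .conftest import random_ensemble


def states_from(seq, n_states, fs=2000.0):
    return StateSeries(states=np.asarray(seq), fs=fs, n_states=n_states)


def random_walk_states(rng, T, n_states):
    steps = rng.integers(-1, 2, size=T)
    x = np.clip(np.cumsum(steps) + n_states // 2, 1, n_states)
    return states_from(x, n_states)


class TestH1H2H3:
    def test_h1_identity_prediction(self, rng):
        h = h1_null(6)
        p0 = rng.dirichlet(np.ones(6))
        assert np.allclose(predict_post(h, p0), p0)

    def test_h2_small_sigma_approaches_null(self):
        M = h2_diffusion(20, sigma=1e-3).M
        assert np.abs(M).max() < 1e-6

    def test_h2_spreads_symmetrically_and_inflates_variance(self, rng):
        h = h2_diffusion(20, sigma=2.0)
        p0 = np.zeros(20)
        p0[9] = 1.0
        p1 = predict_post(h, p0)
        # symmetric about state 10 up to edge-truncation renormalization
        assert np.allclose(p1[:9][::-1][:8], p1[10:18], atol=1e-5)
        states = np.arange(20)
        var = lambda p: np.sum(p * states**2) - np.sum(p * states) ** 2
        assert var(p1) > var(p0)
        assert abs(np.sum(p1 * states) - 9.0) < 1e-4  # interior mean unchanged

    def test_h3_prediction_constant_in_p0(self, rng):
        p1_bar = rng.dirichlet(np.ones(8))
        h = h3_sta(p1_bar)
        a = predict_post(h, rng.dirichlet(np.ones(8)))
        b = predict_post(h, rng.dirichlet(np.ones(8)))
        assert np.allclose(a, p1_bar) and np.allclose(b, p1_bar)

    def test_h3_fixed_point(self, rng):
        p1_bar = rng.dirichlet(np.ones(8))
        assert np.allclose(predict_post(h3_sta(p1_bar), p1_bar), p1_bar)


class TestH4:
    def test_constant_series_zero_matrix(self):
        h = h4_background(states_from([3] * 200, 5), pre_bins=4, post_bins=4)
        assert np.allclose(h.M, 0.0)

    def test_iid_noise_near_symmetric(self, rng):
        s = states_from(rng.integers(1, 11, size=50_000), 10)
        h = h4_background(s, 10, 10)
        up = np.tril(h.M, -1).sum()
        down = np.triu(h.M, 1).sum()
        assert abs(up - down) < 0.05 * (up + down)

    def test_stabilizing_data_pushes_toward_setpoint(self, rng):
        # mean-reverting walk: states above the midpoint flow down, below flow up
        x = np.zeros(40_000)
        for t in range(1, x.size):
            x[t] = 0.95 * x[t - 1] + rng.standard_normal()
        edges = np.linspace(x.min(), x.max() + 1e-9, 11)
        s = states_from(np.clip(np.searchsorted(edges, x, "right"), 1, 10), 10)
        h = h4_background(s, 10, 10)
        from sdokit.viz import quiver_summary

        qs = quiver_summary(h.M)
        net = qs["up_mass"] - qs["down_mass"]
        occ = np.flatnonzero(np.abs(h.M).sum(axis=0) > 1e-6)
        lo = occ[: len(occ) // 3]
        hi = occ[-len(occ) // 3 :]
        assert net[lo].mean() > 0 > net[hi].mean()


class TestH5:
    def test_identity_chain_gives_zero(self):
        s = states_from([2] * 500, 4)
        h = h5_markov(s, np.arange(50, 450, 20), pre_bins=10, T=5)
        assert np.allclose(h.M, 0.0)

    def test_two_state_flip_closed_form(self):
        # alternating states -> M0 = [[0,1],[1,0]]; averaged over T=2 -> 0.5 everywhere
        s = states_from(np.tile([1, 2], 200), 2)
        h = h5_markov(s, np.arange(20, 380, 10), pre_bins=10, T=2)
        assert np.allclose(h.M + np.eye(2), 0.5, atol=1e-12)

    def test_matches_power_sum_oracle(self, rng):
        s = random_walk_states(rng, 5000, 5)
        spikes = np.arange(100, 4900, 37)
        M0 = markov_transition_matrix(s, spikes, pre_bins=12)
        T = 4
        acc = np.zeros_like(M0)
        P = np.eye(5)
        for _ in range(T):
            P = M0 @ P
            acc = acc + P
        h = h5_markov(s, spikes, pre_bins=12, T=T)
        assert np.allclose(h.M, acc / T - np.eye(5))

    def test_averaged_chain_columns_stochastic(self, rng):
        s = random_walk_states(rng, 3000, 6)
        h = h5_markov(s, np.arange(50, 2900, 23), pre_bins=10, T=8)
        assert np.allclose((h.M + np.eye(6)).sum(axis=0), 1.0)

    def test_no_transitions_error(self):
        s = states_from([1, 1, 1], 3)
        with pytest.raises(ValueError, match="transition"):
            h5_markov(s, np.array([1]), pre_bins=1, T=2)


class TestH6H7:
    def test_h6_reduces_to_h4_when_no_mean_change(self, rng):
        s = random_walk_states(rng, 10_000, 6)
        h4 = h4_background(s, 8, 8)
        h6 = h6_background_plus_sta(h4, np.zeros(6))
        assert np.allclose(h6.M, h4.M)

    def test_h6_adds_mean_shift_onto_background_flow(self, rng):
        # when the background diagonal absorbs the shift (no constraint
        # repair), the prediction is exactly background flow plus the mean
        # spike-triggered change
        n = 6
        from sdokit.hypotheses import HypothesisMatrix

        lb = HypothesisMatrix(M=h2_diffusion(n, sigma=3.0).M, h_id="H4")
        dp = np.zeros(n)
        dp[4], dp[1] = 0.05, -0.05
        h6 = h6_background_plus_sta(lb, dp)
        assert h6.provenance["repair_mass"] == 0.0
        p0 = np.full(n, 1 / n)
        assert np.allclose(predict_post(h6, p0), p0 + lb.M @ p0 + dp, atol=1e-9)

    def test_h7_equals_linear_estimate_normalized(self, rng):
        from sdokit.core import estimate_sdo_linear, normalize_sdo

        ens = random_ensemble(rng, 6, 25)
        h7 = h7_spike_sdo(ens)
        want = normalize_sdo(estimate_sdo_linear(ens)).L
        assert np.array_equal(h7.M, want)

    def test_all_seven_satisfy_constraints(self, rng):
        s = random_walk_states(rng, 30_000, 8)
        spikes = np.sort(rng.choice(np.arange(100, 29_900), size=300, replace=False))
        ens = perievent_distributions(s, spikes, 10, 10)
        hyps = build_all_hypotheses(s, ens, 10, 10)
        assert set(hyps) == {"H1", "H2", "H3", "H4", "H5", "H6", "H7"}
        for h_id, h in hyps.items():
            assert check_sdo_constraints(h.M, tol=1e-8) == [], h_id

    def test_h7_state_dependent_h3_not(self, rng):
        # prediction variance across distinct priors: zero for H3, positive for H7
        s = random_walk_states(rng, 30_000, 8)
        spikes = np.sort(rng.choice(np.arange(100, 29_900), size=300, replace=False))
        ens = perievent_distributions(s, spikes, 10, 10)
        h3 = h3_sta(ens.p1_bar)
        h7 = h7_spike_sdo(ens)
        priors = [rng.dirichlet(np.ones(8)) for _ in range(5)]
        preds3 = np.array([predict_post(h3, p) for p in priors])
        preds7 = np.array([predict_post(h7, p) for p in priors])
        assert np.ptp(preds3, axis=0).max() < 1e-12
        assert np.ptp(preds7, axis=0).max() > 1e-3
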