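import numpy as np
import pytest

from sdokit.core import (
    DistributionEnsemble,
    SpikeTrain,
    check_sdo_constraints,
    estimate_sdo_linear,
    estimate_sdo_optim,
    normalize_sdo,
    perievent_distributions,
    predict_post,
    rescale_sdo,
    solve_sdo_lsq_oracle,
)
from sdokit.quantize import StateSeries

from .conftest import random_ensemble


def brute_force_sdo(ens):
    """Independent oracle: per-spike sum over binary pre-state columns.

    Column j of the per-spike operator is the outer product of
    (p(x1) − indicator_j) with indicator_j, weighted by the pre-spike
    probability of state j, averaged over spikes.
    """
    n, k = ens.n_states, ens.k
    L = np.zeros((n, n))
    for s in range(k):
        p0, p1 = ens.P0[:, s], ens.P1[:, s]
        for j in range(n):
            e = np.zeros(n)
            e[j] = 1.0
            L += p0[j] * np.outer(p1 - e, e)
    return L / k


class TestPerievent:
    def make_states(self, states, fs=2000.0, n_states=4):
        return StateSeries(states=np.asarray(states), fs=fs, n_states=n_states)

    def test_constant_state_gives_indicator_and_zero_change(self):
        s = self.make_states([2] * 50)
        ens = perievent_distributions(s, np.array([25]), pre_bins=4, post_bins=4)
        want = np.array([0.0, 1.0, 0.0, 0.0])
        assert np.allclose(ens.P0[:, 0], want)
        assert np.allclose(ens.P1[:, 0], want)
        assert np.allclose(ens.dP, 0.0)

    def test_hand_histogram(self):
        # states ...1 1 2 2 | spike at last 2 | 3 3 4 4...
        seq = [1] * 10 + [1, 1, 2, 2] + [3, 3, 4, 4] + [1] * 10
        s = self.make_states(seq)
        spike = np.array([13])  # index of the second 2 (last pre bin)
        ens = perievent_distributions(s, spike, pre_bins=4, post_bins=4)
        assert np.allclose(ens.P0[:, 0], [0.5, 0.5, 0.0, 0.0])
        assert np.allclose(ens.P1[:, 0], [0.0, 0.0, 0.5, 0.5])

    def test_boundary_spikes_dropped_and_counted(self):
        s = self.make_states([1] * 30)
        ens = perievent_distributions(s, np.array([2, 15, 28]), pre_bins=5, post_bins=5)
        assert ens.k == 1 and ens.n_dropped == 2

    def test_all_boundary_spikes_is_error(self):
        s = self.make_states([1] * 10)
        with pytest.raises(ValueError, match="no spikes"):
            perievent_distributions(s, np.array([0]), pre_bins=5, post_bins=5)

    def test_spike_times_in_seconds_match_indices(self):
        seq = np.tile([1, 2, 3, 4], 25)
        s = self.make_states(seq)
        train = SpikeTrain(times=np.array([50 / 2000.0]))
        a = perievent_distributions(s, train, 10, 10)
        b = perievent_distributions(s, np.array([50]), 10, 10)
        assert np.allclose(a.P0, b.P0) and np.allclose(a.P1, b.P1)


class TestLinearEstimator:
    def test_no_change_gives_zero_matrix(self, rng):
        n, k = 6, 10
        P = np.eye(n)[:, rng.integers(0, n, k)]
        ens = DistributionEnsemble(P0=P, P1=P, n_states=n)
        assert np.allclose(estimate_sdo_linear(ens).L, 0.0)

    def test_single_transition_forced(self):
        P0 = np.zeros((3, 1))
        P0[0] = 1.0
        P1 = np.zeros((3, 1))
        P1[1] = 1.0
        L = estimate_sdo_linear(DistributionEnsemble(P0=P0, P1=P1, n_states=3)).L
        want = np.zeros((3, 3))
        want[1, 0], want[0, 0] = 1.0, -1.0
        assert np.allclose(L, want)

    @pytest.mark.parametrize("n,k", [(4, 3), (20, 10), (20, 50)])
    def test_matches_brute_force_sum(self, rng, n, k):
        ens = random_ensemble(rng, n, k)
        assert np.allclose(estimate_sdo_linear(ens).L, brute_force_sdo(ens), atol=1e-12)

    def test_constraints_hold_on_random_ensembles(self, rng):
        for _ in range(50):
            ens = random_ensemble(rng, 8, int(rng.integers(1, 30)))
            assert check_sdo_constraints(estimate_sdo_linear(ens).L) == []

    def test_single_spike_upholds_update_equation(self, rng):
        # for one spike with a binary pre-distribution (the outer-product
        # case), L·p(x0) reproduces Δp(x) exactly
        ens = random_ensemble(rng, 7, 1, binary_p0=True)
        L = estimate_sdo_linear(ens).L
        assert np.allclose(L @ ens.P0[:, 0], ens.dP[:, 0], atol=1e-12)

    def test_concatenation_is_spike_weighted_average(self, rng):
        n = 5
        a, b = random_ensemble(rng, n, 12), random_ensemble(rng, n, 30)
        both = DistributionEnsemble(
            P0=np.hstack([a.P0, b.P0]), P1=np.hstack([a.P1, b.P1]), n_states=n
        )
        La, Lb = estimate_sdo_linear(a).L, estimate_sdo_linear(b).L
        want = (12 * La + 30 * Lb) / 42
        assert np.allclose(estimate_sdo_linear(both).L, want)


class TestConstraints:
    def test_zero_matrix_valid(self):
        assert check_sdo_constraints(np.zeros((4, 4))) == []

    @pytest.mark.parametrize(
        "mutate,expected",
        [
            (lambda L: L.__setitem__((0, 0), 0.1), "diagonal nonpositive"),
            (lambda L: L.__setitem__((1, 0), -0.1), "off-diagonal nonnegative"),
            (lambda L: L.__setitem__((2, 1), 0.2), "columns sum to zero"),
        ],
    )
    def test_violations_reported(self, mutate, expected):
        L = np.zeros((4, 4))
        mutate(L)
        assert expected in check_sdo_constraints(L)

    def test_excess_positive_mass_reported(self):
        L = np.zeros((3, 3))
        L[1, 0], L[2, 0], L[0, 0] = 0.8, 0.5, -1.3
        assert "positive column mass at most one" in check_sdo_constraints(L)


class TestNormalizeRescale:
    def test_uniform_p0_scales_by_n(self, rng):
        ens = random_ensemble(rng, 5, 20)
        sdo = estimate_sdo_linear(ens)
        p = np.full(5, 0.2)
        assert np.allclose(normalize_sdo(sdo, p).L, 5 * sdo.L)

    def test_round_trip(self, rng):
        ens = random_ensemble(rng, 6, 15)
        sdo = estimate_sdo_linear(ens)
        back = rescale_sdo(normalize_sdo(sdo), sdo.p0_bar)
        assert np.allclose(back.L, sdo.L)

    def test_unobserved_input_state_zeroed_and_flagged(self, rng):
        n, k = 5, 12
        P0 = np.eye(n)[:, rng.integers(1, n, k)]  # state 1 never observed
        P1 = rng.dirichlet(np.ones(n), k).T
        sdo = estimate_sdo_linear(DistributionEnsemble(P0=P0, P1=P1, n_states=n))
        norm = normalize_sdo(sdo)
        assert norm.zeroed_columns[0]
        assert np.allclose(norm.L[:, 0], 0.0)

    def test_rescale_to_indicator_isolates_one_column(self, rng):
        ens = random_ensemble(rng, 4, 10)
        norm = normalize_sdo(estimate_sdo_linear(ens))
        target = np.zeros(4)
        target[2] = 1.0
        out = rescale_sdo(norm, target).L
        assert np.allclose(np.delete(out, 2, axis=1), 0.0)

    def test_normalized_form_is_still_a_valid_sdo(self, rng):
        for _ in range(20):
            ens = random_ensemble(rng, 6, int(rng.integers(2, 40)))
            norm = normalize_sdo(estimate_sdo_linear(ens))
            assert check_sdo_constraints(norm.L, tol=1e-8) == []


class TestPredict:
    def test_zero_matrix_is_identity_map(self, rng):
        p0 = rng.dirichlet(np.ones(6))
        assert np.allclose(predict_post(np.zeros((6, 6)), p0), p0)

    def test_forced_transition(self):
        L = np.zeros((3, 3))
        L[1, 0], L[0, 0] = 1.0, -1.0
        p0 = np.array([1.0, 0.0, 0.0])
        assert np.allclose(predict_post(L, p0), [0.0, 1.0, 0.0])

    def test_output_is_simplex_over_many_draws(self, rng):
        for _ in range(200):
            ens = random_ensemble(rng, 8, int(rng.integers(1, 20)))
            L = estimate_sdo_linear(ens).L
            p1 = predict_post(L, rng.dirichlet(np.ones(8)))
            assert p1.min() >= 0.0
            assert abs(p1.sum() - 1.0) < 1e-12

    def test_constraint_violating_matrix_rejected(self, rng):
        M = np.zeros((4, 4))
        M[0, 0] = 0.5
        with pytest.raises(ValueError, match="constraints"):
            predict_post(M, rng.dirichlet(np.ones(4)))


class TestOptimEstimator:
    def test_recovers_exact_linear_relationship(self, rng):
        # build a valid SDO and an exactly consistent ensemble
        gen = random_ensemble(rng, 4, 25)
        A = estimate_sdo_linear(gen).L
        P0 = rng.dirichlet(np.ones(4), 30).T
        P1 = P0 + A @ P0
        ens = DistributionEnsemble(P0=P0, P1=np.maximum(P1, 0), n_states=4)
        opt = estimate_sdo_optim(ens)
        resid = np.linalg.norm(opt.L @ P0 - ens.dP)
        assert resid < 1e-3

    def test_objective_not_worse_than_linear(self, rng):
        ens = random_ensemble(rng, 5, 20)
        lin, opt = estimate_sdo_linear(ens), estimate_sdo_optim(ens)

        def obj(L):
            return np.sum((L @ ens.P0 - ens.dP) ** 2) / ens.k

        assert obj(opt.L) <= obj(lin.L) + 1e-9
        assert check_sdo_constraints(opt.L, tol=1e-6) == []

    def test_single_binary_spike_matches_outer_product(self, rng):
        n = 4
        P0 = np.zeros((n, 1))
        P0[2] = 1.0
        P1 = rng.dirichlet(np.ones(n))[:, None]
        ens = DistributionEnsemble(P0=P0, P1=P1, n_states=n)
        opt = estimate_sdo_optim(ens)
        want = estimate_sdo_linear(ens).L  # unique feasible zero-residual solution
        assert np.allclose(opt.L @ P0, want @ P0, atol=1e-6)


class TestLsqOracle:
    def test_binary_cover_invertible_and_consistent(self, rng):
        n, k = 4, 60
        P0 = np.eye(n)[:, np.arange(k) % n]
        P1 = rng.dirichlet(np.ones(n), k).T
        ens = DistributionEnsemble(P0=P0, P1=P1, n_states=n)
        L, ok = solve_sdo_lsq_oracle(ens)
        assert ok
        # training-set residual of the lsq solution never exceeds the
        # compliant linear estimate's residual (it is the unconstrained optimum)
        lin = estimate_sdo_linear(ens).L
        r_lsq = np.sum((L @ P0 - ens.dP) ** 2)
        r_lin = np.sum((lin @ P0 - ens.dP) ** 2)
        assert r_lsq <= r_lin + 1e-9

    def test_identical_columns_singular(self, rng):
        n, k = 5, 10
        p = rng.dirichlet(np.ones(n))
        ens = DistributionEnsemble(
            P0=np.tile(p[:, None], (1, k)), P1=rng.dirichlet(np.ones(n), k).T, n_states=n
        )
        _, ok = solve_sdo_lsq_oracle(ens)
        assert not ok

    def test_rank_deficient_when_fewer_spikes_than_states(self, rng):
        ens = random_ensemble(rng, 8, 3)
        _, ok = solve_sdo_lsq_oracle(ens)
        assert not ok
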