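"""Stochastic simulator: payoff balances, updates, stationarity, first passage."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from targetpunish import (
    DynamicsParams,
    SimulationConfig,
    StateVector,
    StrategyRule,
    build_linear_profile,
    cooperation_probabilities,
    effective_punishers,
    estimate_stationary,
    influence,
    run_trajectory,
    step,
    time_to_cooperation,
)
from targetpunish.dynamics import time_to_density

from conftest import ALL_POOLS, ALL_RULES


class TestEffectivePunishers:
    def test_pool_policies(self):
        s = StateVector(np.array([True] * 10 + [False] * 190))
        assert effective_punishers(StateVector.all_defect(200), "cooperators") == 0
        assert effective_punishers(s, "all") == 200
        assert effective_punishers(s, "fraction", 0.5) == 5.0

    def test_unknown_pool_rejected(self):
        with pytest.raises(ValueError):
            effective_punishers(StateVector.all_defect(4), "nobody")


class TestInfluence:
    def test_random_behaviour_at_zero_rationality(self, profile200, rng):
        params = DynamicsParams(beta=0.0, pi_cap=0.9)
        s = StateVector(rng.random(200) < 0.5)
        for i in (1, 57, 200):
            assert influence(i, s, profile200, StrategyRule("uniform"), params).prob_cooperate == 0.5

    def test_defector_not_at_fault_feels_nothing(self):
        profile = build_linear_profile(5)
        s = StateVector(np.array([True, True, False, False, False]))
        b = influence(4, s, profile, StrategyRule("single_file"), DynamicsParams(beta=2.0, pi_cap=1.0))
        assert b.p == 0.0
        assert b.balance == profile.h(4)

    def test_punishment_split_among_defectors(self):
        # one cooperator punishing three defectors at fault: p = pi * 1/3 each
        profile = build_linear_profile(4)
        s = StateVector(np.array([True, False, False, False]))
        params = DynamicsParams(beta=1.0, pi_cap=1.0)
        for i in (2, 3, 4):
            b = influence(i, s, profile, StrategyRule("uniform"), params)
            assert b.p == pytest.approx(1 / 3)
            assert b.n_f == 3

    def test_cooperator_excluded_from_own_counterfactual_punishers(self):
        # all cooperate: flipping i makes her the sole at-fault defector,
        # punished by the remaining n_c - 1 = N - 1 cooperators
        n = 6
        profile = build_linear_profile(n)
        s = StateVector.all_cooperate(n)
        b = influence(3, s, profile, StrategyRule("uniform"), DynamicsParams(beta=1.0, pi_cap=0.5))
        assert b.n_p == n - 1
        assert b.n_f == 1
        assert b.p == pytest.approx(0.5 * (n - 1))

    def test_balance_is_punishment_plus_predisposition(self, profile200, rng):
        params = DynamicsParams(beta=1.7, pi_cap=0.4)
        s = StateVector(rng.random(200) < 0.3)
        for i in (1, 100, 200):
            b = influence(i, s, profile200, StrategyRule("single_file"), params)
            assert b.balance == b.p + b.h
            assert 0.0 <= b.prob_cooperate <= 1.0


class TestVectorizedAgainstReference:
    """The O(N) vectorized probabilities must match per-player assessment."""

    @pytest.mark.parametrize("rule", ALL_RULES, ids=lambda r: f"{r.kind}-{r.group_size}")
    @pytest.mark.parametrize("params", ALL_POOLS, ids=lambda p: p.pool)
    def test_all_rules_and_pools(self, rule, params, rng):
        for n in (5, 11, 23):
            profile = build_linear_profile(n)
            for _ in range(25):
                s = StateVector(rng.random(n) < rng.random())
                vec = cooperation_probabilities(s, profile, rule, params)
                ref = [
                    influence(i, s, profile, rule, params).prob_cooperate
                    for i in range(1, n + 1)
                ]
                np.testing.assert_allclose(vec, ref, atol=1e-14)

    @given(bits=st.lists(st.booleans(), min_size=4, max_size=12))
    @settings(max_examples=60, deadline=None)
    def test_group_counterfactual_counts(self, bits):
        s = StateVector(np.array(bits))
        profile = build_linear_profile(len(bits))
        rule = StrategyRule("groups", group_size=3, threshold=2 / 3)
        params = DynamicsParams(beta=0.9, pi_cap=1.1)
        vec = cooperation_probabilities(s, profile, rule, params)
        ref = [
            influence(i, s, profile, rule, params).prob_cooperate
            for i in range(1, len(bits) + 1)
        ]
        np.testing.assert_allclose(vec, ref, atol=1e-14)


class TestSigmoidProperties:
    def test_half_at_zero_balance_and_symmetry(self):
        from targetpunish.dynamics import _sigmoid

        assert _sigmoid(0.0, 3.0) == 0.5
        h = np.linspace(-2, 2, 41)
        np.testing.assert_allclose(_sigmoid(-h, 1.7), 1 - np.asarray(_sigmoid(h, 1.7)), atol=1e-15)
        assert np.all(np.diff(np.asarray(_sigmoid(h, 1.7))) > 0)

    def test_deterministic_limit_threshold(self):
        from targetpunish.dynamics import _sigmoid

        out = np.asarray(_sigmoid(np.array([-0.1, 0.0, 0.1]), math.inf))
        assert out.tolist() == [0.0, 0.5, 1.0]


class TestStep:
    def test_reproducible_for_fixed_stream(self, profile200):
        params = DynamicsParams(beta=1.0, pi_cap=0.5)
        rule = StrategyRule("uniform")
        out = []
        for _ in range(2):
            rng = np.random.default_rng(99)
            s = StateVector.all_defect(200)
            for _ in range(20):
                s = step(s, profile200, rule, params, rng)
            out.append(s.states)
        assert np.array_equal(out[0], out[1])

    def test_full_cooperation_absorbing_at_strong_punishment(self):
        # every cooperator's counterfactual penalty pi*(N-1)/1 dominates h >= -1
        n = 20
        profile = build_linear_profile(n)
        params = DynamicsParams(beta=math.inf, pi_cap=1.0)
        rng = np.random.default_rng(0)
        s = StateVector.all_cooperate(n)
        for _ in range(50):
            s = step(s, profile, StrategyRule("uniform"), params, rng)
            assert s.n_cooperators == n


class TestTrajectory:
    def test_initial_conditions(self, profile6):
        params = DynamicsParams(beta=1.0, pi_cap=0.0)
        rule = StrategyRule("uniform")
        cfg_c = SimulationConfig(t_max=10, burn_in=0, window=10, realizations=1, init="all_C", seed=1)
        cfg_d = SimulationConfig(t_max=10, burn_in=0, window=10, realizations=1, init="all_D", seed=1)
        assert run_trajectory(cfg_c, profile6, rule, params).rho[0] == 1.0
        assert run_trajectory(cfg_d, profile6, rule, params).rho[0] == 0.0

    def test_coin_flip_dynamics_fluctuates_around_half(self, profile200):
        cfg = SimulationConfig(t_max=200, burn_in=0, window=200, realizations=1, init="all_D", seed=4)
        traj = run_trajectory(cfg, profile200, StrategyRule("uniform"), DynamicsParams(beta=0.0, pi_cap=0.0))
        mean = traj.rho[1:].mean()
        # mean of 200 x Binomial(200, 1/2)/200 draws
        assert abs(mean - 0.5) < 4 * 0.5 / math.sqrt(200 * 200)

    def test_density_init_and_explicit_init(self, profile6):
        params = DynamicsParams(beta=1.0, pi_cap=0.0)
        cfg = SimulationConfig(t_max=2, burn_in=0, window=2, realizations=1, init=0.5, seed=8)
        traj = run_trajectory(cfg, profile6, StrategyRule("uniform"), params)
        assert 0.0 <= traj.rho[0] <= 1.0
        explicit = np.array([True, False, True, False, True, False])
        cfg2 = SimulationConfig(t_max=1, burn_in=0, window=1, realizations=1, init=explicit, seed=8)
        assert run_trajectory(cfg2, profile6, StrategyRule("uniform"), params).rho[0] == 0.5


class TestStationary:
    def test_zero_punishment_decouples_players(self, profile200):
        """With pi=0 the chain factorizes; rho_bar has a closed form."""
        beta = 2.5
        cfg = SimulationConfig(burn_in=500, window=500, realizations=20, init="all_D", seed=21)
        est = estimate_stationary(cfg, profile200, StrategyRule("uniform"), DynamicsParams(beta=beta, pi_cap=0.0))
        closed = float(np.mean(0.5 * (np.tanh(beta * profile200.values) + 1.0)))
        assert abs(est.rho_mean - closed) <= 3 * est.se

    def test_zero_rationality_gives_half(self, profile200):
        cfg = SimulationConfig(burn_in=100, window=200, realizations=10, t_max=300, init="all_C", seed=22)
        est = estimate_stationary(cfg, profile200, StrategyRule("single_file"), DynamicsParams(beta=0.0, pi_cap=0.8))
        assert abs(est.rho_mean - 0.5) <= 3 * max(est.se, 1e-4)

    def test_monotone_in_punishment_for_maintenance(self, profile200):
        """From all-C with the uniform rule, rho_bar never decreases in pi."""
        cfg = SimulationConfig(burn_in=200, window=200, t_max=400, realizations=5, init="all_C", seed=23)
        means = [
            estimate_stationary(
                cfg, profile200, StrategyRule("uniform"), DynamicsParams(beta=2.5, pi_cap=pi)
            ).rho_mean
            for pi in (0.0, 0.2, 0.4, 0.8)
        ]
        assert all(b >= a - 0.02 for a, b in zip(means, means[1:]))

    def test_zero_window_rejected(self, profile6):
        cfg = SimulationConfig(t_max=10, burn_in=10, window=0, realizations=2, seed=0)
        with pytest.raises(ValueError):
            estimate_stationary(cfg, profile6, StrategyRule("uniform"), DynamicsParams())


class TestFirstPassage:
    def test_already_cooperative_start(self, profile6):
        cfg = SimulationConfig(t_max=10, burn_in=0, window=1, realizations=3, init="all_C", seed=5)
        res = time_to_cooperation(cfg, profile6, StrategyRule("uniform"), DynamicsParams(beta=2.0, pi_cap=2.0))
        assert np.all(res.tau == 0)
        assert res.speeds.size == 0

    def test_deterministic_single_file_cascade(self):
        """beta -> inf, all-D: the fault frontier advances one player per
        step after player 2's one-off fair coin, so tau is N-1 or N."""
        n = 100
        profile = build_linear_profile(n)
        cfg = SimulationConfig(t_max=3 * n, burn_in=0, window=1, realizations=30, init="all_D", seed=6)
        res = time_to_cooperation(
            cfg, profile, StrategyRule("single_file"), DynamicsParams(beta=math.inf, pi_cap=0.5)
        )
        assert not np.any(res.censored)
        assert set(res.tau.tolist()) <= {n - 1, n}
        assert set(np.round(res.speeds, 10)) <= {round(n / (n - 1), 10), 1.0}

    def test_no_punishment_never_reaches_cooperation(self, profile200):
        # players i >= 3 have h_i < 0 and, deterministically, never cooperate
        cfg = SimulationConfig(t_max=200, burn_in=0, window=1, realizations=3, init="all_D", seed=7)
        res = time_to_cooperation(
            cfg, profile200, StrategyRule("uniform"), DynamicsParams(beta=math.inf, pi_cap=0.0)
        )
        assert np.all(res.censored)
        assert res.mean_speed == 0.0

    def test_density_threshold_variant(self, profile6):
        cfg = SimulationConfig(t_max=50, burn_in=0, window=1, realizations=5, init="all_D", seed=8)
        res = time_to_density(
            cfg, profile6, StrategyRule("uniform"), DynamicsParams(beta=0.0, pi_cap=0.0), threshold=0.5
        )
        assert np.all(res.tau[~res.censored] >= 1)


class TestAsynchronousMode:
    def test_one_player_changes_per_tick(self, profile200, rng):
        cfg_kwargs = dict(t_max=30, burn_in=0, window=30, realizations=1, seed=9)
        cfg = SimulationConfig(update="asynchronous", init="all_D", **cfg_kwargs)
        traj = run_trajectory(cfg, profile200, StrategyRule("uniform"), DynamicsParams(beta=1.0, pi_cap=0.5))
        assert np.all(np.abs(np.diff(traj.rho)) <= 1 / 200 + 1e-12)


class TestConfigValidation:
    def test_window_overflow_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(t_max=100, burn_in=80, window=40)

    def test_bad_init_rejected(self, profile6):
        cfg = SimulationConfig(t_max=1, burn_in=0, window=1, realizations=1, init="everyone", seed=0)
        with pytest.raises(ValueError):
            run_trajectory(cfg, profile6, StrategyRule("uniform"), DynamicsParams())
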