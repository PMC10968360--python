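import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wolfreg.geometry import DEFAULT_BOUNDS, SearchBounds
from wolfreg.optimizer import (
    GWOConfig,
    behavior_candidate,
    dimensional_candidate,
    leader_pull,
    leader_weights,
    levy_sigma_u,
    levy_step,
    neighborhood_indices,
    optimize,
    rol_point,
    sample_C,
    schedule_a,
    schedule_c,
)


def small_bounds(d: int = 3, lo: float = -1.0, hi: float = 1.0) -> SearchBounds:
    return SearchBounds(lb=np.full(d, lo), ub=np.full(d, hi))


class TestSchedules:
    def test_a_endpoints(self):
        assert schedule_a(0, 2000, mu=1.0) == 2.0
        assert schedule_a(2000, 2000, mu=1.0) == 0.0
        assert schedule_a(0, 100, mu=0.5) == 2.0
        assert schedule_a(0, 100, mu=2.0) == 2.0

    def test_a_halfway_values(self):
        assert schedule_a(1000, 2000, mu=1.0) == pytest.approx(1.0)
        assert schedule_a(1000, 2000, mu=2.0) == pytest.approx(0.5)
        assert schedule_a(1000, 2000, mu=0.5) == pytest.approx(2.0 / math.sqrt(2.0))

    @given(
        mu=st.sampled_from([0.5, 1.0, 1.5, 2.0]),
        T=st.integers(min_value=2, max_value=5000),
    )
    @settings(max_examples=50, deadline=None)
    def test_a_strictly_decreasing(self, mu, T):
        ts = np.linspace(0, T, 11).astype(int)
        vals = [schedule_a(int(t), T, mu) for t in sorted(set(ts))]
        assert all(x > y for x, y in zip(vals, vals[1:]))

    def test_a_out_of_range(self):
        with pytest.raises(ValueError):
            schedule_a(-1, 100, 1.0)
        with pytest.raises(ValueError):
            schedule_a(101, 100, 1.0)

    def test_c_endpoints_and_linearity(self):
        assert schedule_c(1, 2000) == 1.0
        assert schedule_c(2000, 2000) == 0.0
        assert schedule_c(1001, 2001) == pytest.approx(0.5)

    def test_c_single_iteration(self):
        assert schedule_c(1, 1) == 1.0


class TestSampleC:
    def test_c_zero_gives_exact_ones(self, rng):
        np.testing.assert_array_equal(sample_C(0.0, rng), np.ones(15))

    def test_range_is_one_plus_minus_c_squared(self, rng):
        for c in (0.5, 1.0):
            draws = np.array([sample_C(c, rng) for _ in range(2000)])
            assert draws.min() >= 1 - c * c
            assert draws.max() <= 1 + c * c
            # the interval is actually filled
            assert draws.min() < 1 - 0.95 * c * c
            assert draws.max() > 1 + 0.95 * c * c


class TestLeaderWeights:
    @given(t=st.floats(min_value=1e-9, max_value=1e9, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_sum_is_one(self, t):
        w1, w2, w3 = leader_weights(t)
        assert w1 + w2 + w3 == pytest.approx(1.0, abs=1e-12)

    def test_alpha_dominates_early(self):
        w1, w2, w3 = leader_weights(1e-9)
        assert w1 == pytest.approx(1.0, abs=1e-8)
        assert abs(w2) < 1e-8 and abs(w3) < 1e-8

    def test_equal_thirds_late(self):
        w1, w2, w3 = leader_weights(1e6)
        for w in (w1, w2, w3):
            assert w == pytest.approx(1.0 / 3.0, abs=1e-3)

    def test_hierarchy_w1_ge_w2_ge_w3(self):
        for t in (1, 5, 50, 500, 5000):
            w1, w2, w3 = leader_weights(t)
            assert w1 >= w2 >= w3

    def test_invalid_grouping(self):
        with pytest.raises(ValueError):
            leader_weights(1.0, grouping="other")


class TestLevy:
    def test_sigma_u_against_gamma_oracle(self):
        for beta in (1.1, 1.5, 1.9):
            num = math.gamma(1 + beta) * math.sin(math.pi * beta / 2)
            den = math.gamma((1 + beta) / 2) * beta * 2 ** ((beta - 1) / 2)
            assert levy_sigma_u(beta) == pytest.approx((num / den) ** (1 / beta), rel=1e-12)

    def test_step_vanishes_at_alpha(self, rng):
        cfg = GWOConfig(population=10, iterations=10, seed=0)
        pos = np.array([0.3, -0.2, 0.5])
        step = levy_step(pos, pos, t=1, bounds=small_bounds(), config=cfg, rng=rng)
        np.testing.assert_array_equal(step, np.zeros(3))

    def test_step_scale_decays_with_iteration(self):
        cfg = GWOConfig(population=10, iterations=10, seed=0)
        b = small_bounds()
        pos = np.array([0.5, 0.5, 0.5])
        alpha = np.zeros(3)
        mags = []
        for t in (1, 10, 100):
            rng = np.random.default_rng(0)  # same noise, different scale
            mags.append(np.abs(levy_step(pos, alpha, t, b, cfg, rng)).sum())
        assert mags[0] > mags[1] > mags[2]


class TestROL:
    def test_always_in_bounds(self, rng):
        b = DEFAULT_BOUNDS
        for _ in range(100):
            xb = b.sample(rng)[0]
            for _ in range(100):
                p = rol_point(xb, b, rng)
                assert np.all(p >= b.lb) and np.all(p <= b.ub)

    def test_formula_with_stubbed_r(self, monkeypatch, rng):
        b = small_bounds(3, -2.0, 4.0)
        xb = np.array([1.0, -1.0, 3.0])

        class FixedRng:
            def random(self, n):
                return np.full(n, 0.5)

        p = rol_point(xb, b, FixedRng())
        # lb + ub - 0.5*xb = 2 - 0.5*xb, then clipped
        np.testing.assert_allclose(p, np.clip(2.0 - 0.5 * xb, -2.0, 4.0))


class TestLeaderPull:
    def test_hand_computed_two_dim(self):
        b = small_bounds(2, -10, 10)
        wolf = np.array([1.0, 2.0])
        xa = np.array([0.0, 0.0])
        xb = np.array([1.0, 1.0])
        xd = np.array([2.0, 2.0])
        A = np.full((3, 2), 0.5)
        C = np.ones((3, 2))
        x1, x2, x3 = leader_pull(
            wolf, (xa, xb, xd), A, C, rng=None, sca_scale=2.0
        )
        # D_a = 2*|xa - wolf| = (2, 4); x1 = xa - 0.5*D_a = (-1, -2)
        np.testing.assert_allclose(x1, [-1.0, -2.0])
        # D_b = |xb - wolf| = (0, 1); x2 = xb - 0.5*D_b = (1, 0.5)
        np.testing.assert_allclose(x2, [1.0, 0.5])
        # D_d = |xd - wolf| = (1, 0); x3 = xd - 0.5*D_d = (1.5, 2)
        np.testing.assert_allclose(x3, [1.5, 2.0])

    def test_sca_scale_range_literal_vs_scaled(self):
        # literal mode: angles in [0, 1] rad, so sin >= 0 and cos > 0
        from wolfreg.optimizer import _sca_scale

        rng = np.random.default_rng(0)
        lit = [_sca_scale(rng, "literal") for _ in range(5000)]
        assert min(lit) >= 0.0
        rng = np.random.default_rng(0)
        sca = [_sca_scale(rng, "scaled") for _ in range(5000)]
        assert min(sca) < 0.0  # full-circle angles produce negatives


class TestBehaviorCandidate:
    def _pulls(self):
        x1 = np.array([0.1, 0.2, 0.3])
        x2 = np.array([-0.1, 0.0, 0.1])
        x3 = np.array([0.2, -0.2, 0.0])
        return x1, x2, x3

    def test_exploit_branch_equals_rol(self, rng):
        b = small_bounds()
        pbest = np.array([0.5, -0.5, 0.2])
        seed_rng = np.random.default_rng(99)
        cand = behavior_candidate(
            wolf_pos=np.zeros(3),
            personal_best=pbest,
            pulls=self._pulls(),
            weights=(0.5, 0.3, 0.2),
            alpha_pos=np.zeros(3),
            A_branch=0.5,
            t=1,
            bounds=b,
            config=GWOConfig(population=10, iterations=10),
            rng=seed_rng,
        )
        expected = rol_point(pbest, b, np.random.default_rng(99))
        np.testing.assert_array_equal(cand, expected)

    def test_explore_single_levy_branch(self, monkeypatch):
        import wolfreg.optimizer as opt

        b = small_bounds()
        x1, x2, x3 = self._pulls()
        fixed = np.array([0.01, 0.01, 0.01])
        monkeypatch.setattr(opt, "levy_step", lambda *a, **k: fixed)

        class CoinRng:
            def random(self, *a):
                return 0.3  # <= 0.5 -> single-step branch

        cand = opt.behavior_candidate(
            wolf_pos=np.zeros(3),
            personal_best=np.zeros(3),
            pulls=(x1, x2, x3),
            weights=(0.5, 0.3, 0.2),
            alpha_pos=np.zeros(3),
            A_branch=1.5,
            t=1,
            bounds=b,
            config=GWOConfig(population=10, iterations=10),
            rng=CoinRng(),
        )
        wsum = 0.5 * x1 + 0.3 * x2 + 0.2 * x3
        np.testing.assert_allclose(cand, np.clip(wsum + fixed, -1, 1))

    def test_explore_three_leader_branch_with_unit_alpha_weight(self, monkeypatch):
        import wolfreg.optimizer as opt

        b = small_bounds()
        x1, x2, x3 = self._pulls()
        fixed = np.array([0.02, 0.0, -0.02])
        monkeypatch.setattr(opt, "levy_step", lambda *a, **k: fixed)

        class CoinRng:
            def random(self, *a):
                return 0.9  # > 0.5 -> three-leader branch

        cand = opt.behavior_candidate(
            wolf_pos=np.zeros(3),
            personal_best=np.zeros(3),
            pulls=(x1, x2, x3),
            weights=(1.0, 0.0, 0.0),
            alpha_pos=np.zeros(3),
            A_branch=-1.2,
            t=1,
            bounds=b,
            config=GWOConfig(population=10, iterations=10),
            rng=CoinRng(),
        )
        np.testing.assert_allclose(cand, np.clip(x1 + fixed, -1, 1))


class TestNeighborhood:
    def test_matches_brute_force_table(self):
        pack = np.array(
            [[0.0, 0.0], [0.5, 0.0], [2.0, 0.0], [0.0, 3.0], [1.0, 1.0]]
        )
        wolf = pack[0]
        next_pos = np.array([1.5, 0.0])  # R = 1.5
        idx = neighborhood_indices(wolf, next_pos, pack)
        # distances from wolf 0: 0, 0.5, 2.0, 3.0, sqrt(2)
        np.testing.assert_array_equal(idx, [0, 1, 4])

    def test_fallback_to_nearest_other(self):
        pack = np.array([[0.0, 0.0], [0.5, 0.0], [2.0, 0.0]])
        idx = neighborhood_indices(pack[0], pack[0], pack)  # R = 0
        np.testing.assert_array_equal(idx, [1])

    def test_dimensional_candidate_in_bounds_and_deterministic(self, rng):
        b = small_bounds(4, -2, 2)
        pack = np.random.default_rng(5).uniform(-2, 2, (8, 4))
        wolf = pack[2]
        nxt = pack[2] + 0.8
        c1 = dimensional_candidate(wolf, nxt, pack, b, np.random.default_rng(7))
        c2 = dimensional_candidate(wolf, nxt, pack, b, np.random.default_rng(7))
        np.testing.assert_array_equal(c1, c2)
        assert np.all(c1 >= b.lb) and np.all(c1 <= b.ub)


def sphere(x: np.ndarray) -> float:
    return float(np.sum(x * x))


class TestOptimize:
    def test_config_validation(self):
        with pytest.raises(ValueError):
            GWOConfig(population=3)
        with pytest.raises(ValueError):
            GWOConfig(iterations=1)
        with pytest.raises(ValueError):
            GWOConfig(mu=0.0)
        with pytest.raises(ValueError):
            GWOConfig(beta_levy=2.5)
        with pytest.raises(ValueError):
            GWOConfig(sca_angle_mode="bogus")

    def test_sphere_convergence_15d(self):
        b = SearchBounds(lb=np.full(15, -5.0), ub=np.full(15, 5.0))
        cfg = GWOConfig(population=30, iterations=200, mu=1.0, seed=3)
        res = optimize(sphere, b, cfg)
        assert res.fun < 1e-6
        assert np.all(np.abs(res.x) < 1e-2)

    def test_trace_non_increasing_and_matches_fun(self):
        b = SearchBounds(lb=np.full(5, -3.0), ub=np.full(5, 3.0))
        cfg = GWOConfig(population=12, iterations=60, seed=11)
        res = optimize(sphere, b, cfg)
        assert np.all(np.diff(res.trace) <= 0)
        assert res.trace[-1] == res.fun
        assert res.fun == pytest.approx(sphere(res.x), rel=1e-14)

    def test_deterministic_given_seed(self):
        b = SearchBounds(lb=np.full(5, -3.0), ub=np.full(5, 3.0))
        cfg = GWOConfig(population=10, iterations=40, seed=21)
        r1 = optimize(sphere, b, cfg)
        r2 = optimize(sphere, b, cfg)
        np.testing.assert_array_equal(r1.x, r2.x)
        np.testing.assert_array_equal(r1.trace, r2.trace)
        assert r1.branch_counts == r2.branch_counts

    def test_different_seed_differs(self):
        b = SearchBounds(lb=np.full(5, -3.0), ub=np.full(5, 3.0))
        r1 = optimize(sphere, b, GWOConfig(population=10, iterations=40, seed=1))
        r2 = optimize(sphere, b, GWOConfig(population=10, iterations=40, seed=2))
        assert not np.array_equal(r1.x, r2.x)

    def test_batch_objective_agrees_with_scalar(self):
        b = SearchBounds(lb=np.full(4, -2.0), ub=np.full(4, 2.0))
        cfg = GWOConfig(population=8, iterations=30, seed=4)
        r_scalar = optimize(sphere, b, cfg)
        r_batch = optimize(
            sphere, b, cfg, batch_objective=lambda P: np.sum(P * P, axis=1)
        )
        np.testing.assert_array_equal(r_scalar.x, r_batch.x)
        np.testing.assert_array_equal(r_scalar.trace, r_batch.trace)

    def test_population_stays_in_bounds(self):
        b = SearchBounds(lb=np.full(6, -1.0), ub=np.full(6, 1.0))
        cfg = GWOConfig(population=10, iterations=50, seed=8)
        res = optimize(sphere, b, cfg)
        assert np.all(res.population >= b.lb) and np.all(res.population <= b.ub)
        assert np.all(res.x >= b.lb) and np.all(res.x <= b.ub)

    def test_branch_counts_cover_all_wolves(self):
        b = SearchBounds(lb=np.full(4, -1.0), ub=np.full(4, 1.0))
        cfg = GWOConfig(population=9, iterations=35, seed=2)
        res = optimize(sphere, b, cfg)
        total = sum(res.branch_counts.values())
        assert total == cfg.population * cfg.iterations
        # late iterations force |A| <= 1, so the opposition branch must fire
        assert res.branch_counts["rol"] > 0

    def test_nan_objective_aborts(self):
        b = SearchBounds(lb=np.full(3, -1.0), ub=np.full(3, 1.0))
        cfg = GWOConfig(population=5, iterations=5, seed=0)
        with pytest.raises(ValueError, match="non-finite"):
            optimize(lambda x: float("nan"), b, cfg)

    def test_record_history_shapes(self):
        b = SearchBounds(lb=np.full(3, -1.0), ub=np.full(3, 1.0))
        cfg = GWOConfig(population=6, iterations=12, seed=0)
        res = optimize(sphere, b, cfg, record_history=True)
        assert res.history_fitness.shape == (12, 6)
        assert res.history_positions.shape == (12, 6, 3)
        # per-wolf fitness is non-increasing under the final greedy rule
        assert np.all(np.diff(res.history_fitness, axis=0) <= 0)

    def test_callback_sees_every_iteration(self):
        b = SearchBounds(lb=np.full(3, -1.0), ub=np.full(3, 1.0))
        seen = []
        optimize(
            sphere,
            b,
            GWOConfig(population=5, iterations=9, seed=0),
            callback=lambda t, f: seen.append((t, f)),
        )
        assert [t for t, _ in seen] == list(range(1, 10))
        fs = [f for _, f in seen]
        assert all(x >= y for x, y in zip(fs, fs[1:]))
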