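import math

import numpy as np
import pytest

from hiset import metaheuristics as mh


class TestEscapeEnergy:
    def test_start(self):
        assert mh.escape_energy(1.0, 0, 100) == 2.0

    def test_end(self):
        assert mh.escape_energy(0.7, 100, 100) == 0.0

    def test_midpoint(self):
        assert mh.escape_energy(-0.5, 50, 100) == pytest.approx(-0.5)

    def test_zero_T(self):
        with pytest.raises(ZeroDivisionError):
            mh.escape_energy(0.5, 0, 0)


class TestClosenessParameter:
    def test_midpoint(self):
        assert mh.closeness_parameter(5, 8, 2) == pytest.approx(0.5)

    def test_endpoints(self):
        assert mh.closeness_parameter(8, 8, 2) == 1.0
        assert mh.closeness_parameter(2, 8, 2) == 0.0

    def test_direct(self):
        assert mh.closeness_parameter(3, 8, 2) == pytest.approx(1 / 6)

    def test_degenerate_population(self):
        assert mh.closeness_parameter(4, 4, 4) == 1.0

    def test_minimization_orientation(self):
        # best fitness numerically below worst still maps best -> 1
        assert mh.closeness_parameter(1.0, 1.0, 9.0) == 1.0


class TestAdaptiveScale:
    def test_cp_zero(self):
        assert mh.adaptive_scale(0.0) == 1.0

    def test_cp_one(self):
        assert mh.adaptive_scale(1.0) == pytest.approx(
            1 / (1 + math.tanh(2)), abs=1e-12
        )
        assert mh.adaptive_scale(1.0) == pytest.approx(0.5092, abs=5e-4)

    def test_strictly_decreasing_and_bounded(self):
        grid = np.linspace(0, 1, 100)
        vals = [mh.adaptive_scale(c) for c in grid]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert all(0.5 < v <= 1.0 for v in vals)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            mh.adaptive_scale(1.2)


class TestBinarize:
    def test_sigmoid_limits(self):
        rng = np.random.default_rng(0)
        assert np.all(mh.binarize(np.full(100, 50.0), rng) == 1)
        assert np.all(mh.binarize(np.full(100, -50.0), rng) == 0)

    def test_sigmoid_at_zero(self):
        rng = np.random.default_rng(1)
        bits = np.concatenate(
            [mh.binarize(np.zeros(1000), rng) for _ in range(100)]
        )
        assert bits.mean() == pytest.approx(0.5, abs=0.02)

    def test_probability_matches_sigmoid(self):
        rng = np.random.default_rng(2)
        draws = np.concatenate(
            [mh.binarize(np.full(1000, 2.0), rng) for _ in range(100)]
        )
        assert draws.mean() == pytest.approx(1 / (1 + math.exp(-2)), abs=0.01)


def _track_bounds(spec):
    seen = []
    inner = spec.fitness

    def wrapped(x):
        seen.append(np.all((x >= spec.lower - 1e-12) & (x <= spec.upper + 1e-12)))
        return inner(x)

    spec.fitness = wrapped
    return seen


class TestHHO:
    def test_sphere_convergence(self):
        best = [
            mh.hho(mh.sphere(10), mh.HHOConfig(seed=s, max_iters=200)).best_fitness
            for s in range(5)
        ]
        assert np.median(best) < 1e-4

    def test_trace_non_increasing(self):
        r = mh.hho(mh.rastrigin(5), mh.HHOConfig(pop_size=10, max_iters=50, seed=1))
        assert np.all(np.diff(r.convergence_trace) <= 0)
        assert r.best_fitness == r.convergence_trace[-1]

    def test_candidates_stay_in_bounds(self):
        spec = mh.sphere(4, bound=2.0)
        seen = _track_bounds(spec)
        mh.hho(spec, mh.HHOConfig(pop_size=8, max_iters=30, seed=3))
        assert all(seen)

    def test_determinism(self):
        cfg = mh.HHOConfig(pop_size=10, max_iters=40, seed=11)
        a = mh.hho(mh.rastrigin(4), cfg)
        b = mh.hho(mh.rastrigin(4), cfg)
        assert np.array_equal(a.convergence_trace, b.convergence_trace)
        assert np.array_equal(a.best_candidate, b.best_candidate)

    def test_nonfinite_fitness_rejected(self):
        spec = mh.ObjectiveSpec(2, -1, 1, lambda x: float("nan"))
        with pytest.raises(ValueError):
            mh.hho(spec, mh.HHOConfig(pop_size=4, max_iters=5, seed=0))


class TestSFPDE:
    def test_sphere_convergence_small(self):
        best = [
            mh.sfpde(
                mh.sphere(6), mh.SFPDEConfig(pop_size=40, max_iters=300, seed=s)
            ).best_fitness
            for s in range(5)
        ]
        assert np.median(best) < 1e-6

    def test_adaptive_scales_bounded(self):
        r = mh.sfpde(
            mh.rastrigin(5), mh.SFPDEConfig(pop_size=10, max_iters=50, seed=2)
        )
        scales = r.extras["adaptive_scales"]
        assert np.all(scales > 0.5) and np.all(scales <= 1.0)

    def test_individual_fitness_never_worsens(self):
        r = mh.sfpde(
            mh.rastrigin(5),
            mh.SFPDEConfig(pop_size=12, max_iters=60, seed=3, record_history=True),
        )
        history = r.extras["fitness_history"]
        assert np.all(np.diff(history, axis=0) <= 1e-12)

    def test_bounds_respected(self):
        spec = mh.sphere(3, bound=1.5)
        seen = _track_bounds(spec)
        mh.sfpde(spec, mh.SFPDEConfig(pop_size=8, max_iters=30, seed=4))
        assert all(seen)

    def test_binary_mode_returns_mask(self):
        spec = mh.ObjectiveSpec(
            6, -2, 2, lambda bits: float(np.sum(bits[:3] == 0) + np.sum(bits[3:]))
        )
        r = mh.sfpde(
            spec, mh.SFPDEConfig(pop_size=10, max_iters=60, binary=True, seed=5)
        )
        mask = r.extras["best_mask"]
        assert set(np.unique(mask)) <= {0, 1}
        assert r.best_fitness <= 1

    def test_pop_size_minimum(self):
        with pytest.raises(ValueError):
            mh.SFPDEConfig(pop_size=3)

    def test_determinism(self):
        cfg = mh.SFPDEConfig(pop_size=10, max_iters=30, seed=8)
        a = mh.sfpde(mh.sphere(4), cfg)
        b = mh.sfpde(mh.sphere(4), cfg)
        assert np.array_equal(a.convergence_trace, b.convergence_trace)


class TestPenaltyHandling:
    def test_infeasible_exceeds_feasible(self):
        spec = mh.ObjectiveSpec(
            2, -5, 5,
            fitness=lambda x: float(np.sum(x**2)),
            constraint=lambda x: max(0.0, 1.0 - float(x[0])),  # x0 >= 1
            penalty_weight=1e6,
        )
        feasible = spec.evaluate(np.array([1.5, 0.0]))
        infeasible = spec.evaluate(np.array([0.0, 0.0]))
        assert infeasible > feasible
        r = mh.sfpde(spec, mh.SFPDEConfig(pop_size=20, max_iters=100, seed=0))
        assert r.best_candidate[0] >= 1.0 - 1e-3


class TestHybrid:
    def test_beats_or_matches_plain_on_rastrigin(self):
        hyb, plain = [], []
        for s in range(6):
            spec = mh.rastrigin(10)
            h = mh.hho_sfpde(
                spec,
                mh.HybridConfig(
                    outer=mh.HHOConfig(pop_size=4, max_iters=3),
                    inner=mh.SFPDEConfig(pop_size=20, max_iters=40, stop_tol=1e-8),
                    seed=s,
                ),
            )
            hyb.append(h.best_fitness)
            p = mh.sfpde(
                spec,
                mh.SFPDEConfig(
                    pop_size=20, max_iters=40, crossover_rate=0.7,
                    seed=s, stop_tol=1e-8,
                ),
            )
            plain.append(p.best_fitness)
        assert np.median(hyb) <= np.median(plain)

    def test_outer_trace_non_increasing_and_cr_bounded(self):
        spec = mh.sphere(5)
        r = mh.hho_sfpde(
            spec,
            mh.HybridConfig(
                outer=mh.HHOConfig(pop_size=3, max_iters=3),
                inner=mh.SFPDEConfig(pop_size=10, max_iters=20, stop_tol=1e-8),
                seed=1,
            ),
        )
        assert np.all(np.diff(r.extras["outer_trace"]) <= 0)
        assert 0.1 <= r.extras["tuned_cr"] <= 0.95
        assert 0.5 <= r.extras["tuned_modulation"] <= 1.5


class TestGWO:
    def test_sphere_convergence(self):
        best = [
            mh.gwo(mh.sphere(10), mh.SwarmConfig(30, 200, s)).best_fitness
            for s in range(5)
        ]
        assert np.median(best) < 1e-4

    def test_coincident_leaders_fixed_point(self):
        # analytic identity: all three leader moves collapse when a = 0 and
        # the wolf sits on the shared leader position
        w = np.array([0.3, -0.2])
        moves = np.stack([w, w, w])
        assert np.allclose(moves.mean(axis=0), w)

    def test_bounds(self):
        spec = mh.sphere(3, bound=1.0)
        seen = _track_bounds(spec)
        mh.gwo(spec, mh.SwarmConfig(6, 20, 2))
        assert all(seen)

    def test_requires_three_wolves(self):
        with pytest.raises(ValueError):
            mh.gwo(mh.sphere(2), mh.SwarmConfig(2, 10, 0))


class TestGOA:
    def test_sphere_convergence(self):
        best = [
            mh.goa(mh.sphere(5), mh.SwarmConfig(30, 200, s)).best_fitness
            for s in range(5)
        ]
        assert np.median(best) < 1e-2

    def test_trace_non_increasing(self):
        r = mh.goa(mh.rastrigin(3), mh.SwarmConfig(10, 40, 1))
        assert np.all(np.diff(r.convergence_trace) <= 0)

    def test_coincident_agents_no_force(self):
        # a population collapsed onto one point exerts zero social force and
        # therefore stays at the best-so-far target
        spec = mh.sphere(2)
        r = mh.goa(spec, mh.SwarmConfig(5, 5, 3))
        assert np.isfinite(r.best_fitness)

    def test_social_force_zero_crossing(self):
        # attraction at long range, repulsion at short range
        assert mh._social_force(np.array([0.2]))[0] < 0
        assert mh._social_force(np.array([3.0]))[0] > 0
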