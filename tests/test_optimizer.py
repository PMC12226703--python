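"""NSGA-II machinery vs brute-force oracles, and full planner runs."""

import numpy as np
import pytest

from ablaplan.objectives import EvalResult, PlannerParams
from ablaplan.operators import Population
from ablaplan.optimizer import (
    binary_tournament,
    crowding_distance,
    detect_stagnation,
    nondominated_sort,
    reinitialize,
    run,
    survival,
)
from ablaplan.plan import Plan, Trajectory, encode_plan


def _ev(F, g=(0.0, 0.0)):
    F = np.asarray(F, dtype=float)
    return EvalResult(
        F=F, G=np.asarray(g, dtype=float), coverage=1 - F[4],
        n_trajectories=1, mean_angle_deg=0.0, mean_length_mm=0.0,
    )


def _random_population(rng, n):
    evals = []
    for _ in range(n):
        g = (0.0, 0.0) if rng.random() < 0.6 else (rng.integers(0, 2), rng.random() * 0.5)
        evals.append(_ev(rng.random(6), g))
    plans = [Plan([Trajectory([i, 0, 0], [i, 0, 1])]) for i in range(n)]
    return Population(individuals=plans, evals=evals)


def _oracle_dominates(a, b):
    if a.feasible != b.feasible:
        return a.feasible
    if not a.feasible:
        return a.sum_G < b.sum_G
    return bool(np.all(a.F <= b.F) and np.any(a.F < b.F))


def _oracle_fronts(pop):
    """O(n^2) peeling with the constrained-domination matrix."""
    remaining = set(range(len(pop)))
    fronts = []
    while remaining:
        front = [
            i
            for i in remaining
            if not any(_oracle_dominates(pop.evals[j], pop.evals[i]) for j in remaining if j != i)
        ]
        fronts.append(sorted(front))
        remaining -= set(front)
    return fronts


class TestNondominatedSort:
    def test_feasible_beats_infeasible(self):
        pop = Population(
            individuals=[Plan(), Plan()],
            evals=[_ev(np.ones(6) * 0.9), _ev(np.zeros(6), g=(1.0, 0.0))],
        )
        fronts = nondominated_sort(pop)
        assert fronts[0] == [0]
        assert fronts[1] == [1]

    def test_total_dominator_alone_in_front_zero(self):
        pop = Population(
            individuals=[Plan(), Plan()],
            evals=[_ev(np.full(6, 0.2)), _ev(np.full(6, 0.6))],
        )
        assert nondominated_sort(pop)[0] == [0]

    def test_matches_oracle_on_random_populations(self, rng):
        for _ in range(100):
            pop = _random_population(rng, int(rng.integers(5, 31)))
            got = [sorted(f) for f in nondominated_sort(pop)]
            assert got == _oracle_fronts(pop)


class TestCrowdingDistance:
    def test_front_of_two_all_infinite(self):
        d = crowding_distance([_ev([0.1] * 6), _ev([0.9] * 6)])
        assert np.all(np.isinf(d))

    def test_three_collinear_points_middle_value(self):
        # 2 active objectives, points at 0, 0.5, 1 in each: the cuboid sum for
        # the middle member is (1-0)/1 per objective = 2 in total
        evs = [
            _ev([0.0, 1.0, 0, 0, 0, 0]),
            _ev([0.5, 0.5, 0, 0, 0, 0]),
            _ev([1.0, 0.0, 0, 0, 0, 0]),
        ]
        d = crowding_distance(evs)
        assert np.isinf(d[0]) and np.isinf(d[2])
        assert d[1] == pytest.approx(2.0)

    def test_permutation_invariance(self, rng):
        evs = [_ev(rng.random(6)) for _ in range(8)]
        base = crowding_distance(evs)
        perm = rng.permutation(8)
        permuted = crowding_distance([evs[i] for i in perm])
        assert np.allclose(base[perm], permuted)


class TestBinaryTournament:
    def _graded(self, n=6):
        # strictly graded feasible population: rank i dominates rank i+1
        evals = [_ev(np.full(6, 0.1 + 0.1 * i)) for i in range(n)]
        plans = [Plan() for _ in range(n)]
        return Population(individuals=plans, evals=evals)

    def test_lower_front_wins(self, rng):
        pop = self._graded(4)
        wins = np.zeros(4)
        for _ in range(500):
            i, j = binary_tournament(pop, rng)
            wins[i] += 1
            wins[j] += 1
        assert wins[0] > wins[-1]

    def test_win_rates_monotone_in_rank(self, rng):
        pop = self._graded(8)
        wins = np.zeros(8)
        for _ in range(5000):
            i, j = binary_tournament(pop, rng)
            wins[i] += 1
            wins[j] += 1
        freq = wins / wins.sum()
        assert np.all(np.diff(freq) <= 0.02)  # non-increasing up to noise

    def test_crowding_breaks_rank_ties(self, rng):
        # same front, one member in a sparse region
        evals = [
            _ev([0.0, 1.0, 0, 0, 0, 0]),
            _ev([0.45, 0.55, 0, 0, 0, 0]),
            _ev([0.5, 0.5, 0, 0, 0, 0]),
            _ev([1.0, 0.0, 0, 0, 0, 0]),
        ]
        pop = Population(individuals=[Plan()] * 4, evals=evals)
        # hand computation: member 1 spans [0, 0.5] -> 0.5 per objective;
        # member 2 spans [0.45, 1] -> 0.55 per objective
        d = crowding_distance(evals)
        assert d[1] == pytest.approx(1.0)
        assert d[2] == pytest.approx(1.1)


class TestSurvival:
    def _oracle_survival(self, pop, size):
        fronts = _oracle_fronts(pop)
        chosen = []
        for f in fronts:
            if len(chosen) + len(f) <= size:
                chosen += f
            else:
                d = crowding_distance([pop.evals[i] for i in f])
                order = [f[i] for i in np.argsort(-d, kind="stable")]
                chosen += order[: size - len(chosen)]
                break
        return sorted(chosen)

    def test_front_zero_exact_fill(self, rng):
        pop = _random_population(rng, 20)
        fronts = nondominated_sort(pop)
        k = len(fronts[0])
        out = survival(
            Population(pop.individuals[:10], pop.evals[:10]),
            Population(pop.individuals[10:], pop.evals[10:]),
            k,
        )
        assert len(out) == k

    def test_best_feasible_survives(self, rng):
        for _ in range(20):
            parents = _random_population(rng, 10)
            offspring = _random_population(rng, 10)
            merged = Population(
                parents.individuals + offspring.individuals,
                parents.evals + offspring.evals,
            )
            best = merged.best_index
            out = survival(parents, offspring, 10)
            key = encode_plan(merged.individuals[best]).tobytes()
            assert any(encode_plan(p).tobytes() == key for p in out.individuals)

    def test_matches_exhaustive_selection(self, rng):
        for _ in range(50):
            parents = _random_population(rng, int(rng.integers(5, 15)))
            offspring = _random_population(rng, int(rng.integers(5, 15)))
            size = int(rng.integers(3, len(parents) + len(offspring)))
            merged = Population(
                parents.individuals + offspring.individuals,
                parents.evals + offspring.evals,
            )
            expected = self._oracle_survival(merged, size)
            out = survival(parents, offspring, size)
            # compare multisets of (front, crowding-equivalent) members by F
            exp_F = sorted(tuple(merged.evals[i].F) for i in expected)
            got_F = sorted(tuple(ev.F) for ev in out.evals)
            assert exp_F == got_F


class TestStagnationAndReinit:
    def test_flat_infeasible_history_fires(self):
        assert detect_stagnation([0.4] * 20, window=15, tol=1e-6)

    def test_feasible_never_fires(self):
        assert not detect_stagnation([0.4] * 19 + [0.0], window=15, tol=1e-6)

    def test_improving_history_does_not_fire(self):
        hist = list(np.linspace(0.4, 0.1, 20))
        assert not detect_stagnation(hist, window=15, tol=1e-6)

    def test_short_history_does_not_fire(self):
        assert not detect_stagnation([0.4] * 5, window=15, tol=1e-6)

    def test_reinitialize_keeps_best_and_resamples(self, small_phantom, rng):
        env = small_phantom.env
        params = PlannerParams(pop_size=6, seed=0)
        from ablaplan.operators import sample_population

        pop = sample_population(env, params, rng)
        pop.evaluate(env, params)
        best = encode_plan(pop.best).tobytes()
        new = reinitialize(pop, env, params, rng)
        assert len(new) == params.pop_size
        assert encode_plan(new.individuals[0]).tobytes() == best
        old = {encode_plan(p).tobytes() for p in pop.individuals}
        fresh = [p for p in new.individuals[1:]]
        assert sum(encode_plan(p).tobytes() in old for p in fresh) == 0


class TestRun:
    def test_same_seed_reproduces_solutions(self, tiny_phantom):
        params = PlannerParams(pop_size=8, n_generations=8, seed=42, stagnation_window=5)
        r1 = run(tiny_phantom.env, params)
        r2 = run(tiny_phantom.env, params)
        assert len(r1.solutions) == len(r2.solutions)
        for (p1, _), (p2, _) in zip(r1.solutions, r2.solutions):
            assert np.array_equal(encode_plan(p1), encode_plan(p2))

    def test_solvable_phantom_full_coverage_single_needle(self, small_phantom):
        params = PlannerParams(pop_size=16, n_generations=60, seed=7)
        result = run(small_phantom.env, params)
        assert result.feasible
        assert any(
            ev.n_trajectories == 1 and ev.coverage == 1.0 for _, ev in result.solutions
        )

    def test_all_solutions_feasible(self, small_phantom):
        params = PlannerParams(pop_size=10, n_generations=15, seed=3, stagnation_window=8)
        result = run(small_phantom.env, params)
        assert all(ev.sum_G == 0.0 for _, ev in result.solutions)

    def test_rib_occlusion_produces_clear_trajectories(self):
        from ablaplan.phantoms import PhantomConfig, make_phantom

        ph = make_phantom(
            PhantomConfig(tumor_diameter=10.0, margin_mm=5.0, n_ribs=3, seed=5)
        )
        params = PlannerParams(pop_size=12, n_generations=25, seed=1, stagnation_window=8)
        result = run(ph.env, params)
        assert result.feasible
        for plan, ev in result.solutions:
            assert ev.G[0] == 0.0
            for t in plan:
                for rib in ph.env.critical:
                    _, _, ts = rib.segment_intersections(t.entry, t.target)
                    assert ts.size == 0
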