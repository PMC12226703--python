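"""Sampling, crossover, mutation and the conform filter."""

import numpy as np
import pytest

from ablaplan.environment import build_environment
from ablaplan.objectives import PlannerParams, entry_angles, pairwise_segment_distance
from ablaplan.operators import (
    OperatorLog,
    conform_to_environment,
    crossover,
    crossover_uniform,
    mutate,
    mutate_trajectory,
    sample_individual,
    sample_population,
)
from ablaplan.plan import Plan, Trajectory, encode_plan, trajectory_lengths
from ablaplan.primitives import ellipsoid, icosphere


def _coords(plan):
    return {t.entry.tobytes() + t.target.tobytes() for t in plan}


class TestSampling:
    def test_prolate_tumor_directions_follow_principal_axis(self, rng):
        env = build_environment(
            icosphere(90.0, 3), icosphere(45.0, 3),
            ellipsoid((15.0, 5.0, 5.0), subdivisions=3),
            margin=2.0, spacing=2.0,
        )
        dirs = []
        for _ in range(30):
            plan = sample_individual(env, PlannerParams(), rng)
            dirs.extend(t.direction for t in plan)
        mean = np.mean(dirs, axis=0)
        mean /= np.linalg.norm(mean)
        assert np.degrees(np.arccos(abs(mean[0]))) < 15.0

    def test_18mm_sphere_needle_count(self, rng):
        env = build_environment(
            icosphere(90.0, 3), icosphere(45.0, 3), icosphere(9.0, 3),
            margin=0.0, spacing=2.0,
        )
        for _ in range(30):
            plan = sample_individual(env, PlannerParams(ablation_radius_mm=10.0), rng)
            assert len(plan) in {1, 2, 3}

    def test_entries_on_entry_surface(self, small_phantom, rng):
        env = small_phantom.env
        for _ in range(10):
            plan = sample_individual(env, PlannerParams(), rng)
            for t in plan:
                assert env.entry_surface.surface_distance(t.entry[None])[0] < 1e-6

    def test_targets_in_treatment_volume(self, small_phantom, rng):
        env = small_phantom.env
        tv_set = {tuple(p) for p in env.treatment.points}
        plan = sample_individual(env, PlannerParams(), rng)
        assert all(tuple(t.target) in tv_set for t in plan)

    def test_population_size(self, small_phantom, rng):
        pop = sample_population(small_phantom.env, PlannerParams(pop_size=7), rng)
        assert len(pop) == 7


class TestCrossover:
    def _parents(self, env, rng, n=3):
        p = PlannerParams()
        return (
            sample_individual(env, p, rng),
            sample_individual(env, p, rng),
        )

    def test_children_are_subsets_of_parents(self, tiny_phantom, rng):
        env = tiny_phantom.env
        params = PlannerParams()
        for _ in range(200):
            pa, pb = self._parents(env, rng)
            ca, cb = crossover(pa, pb, None, env, params, rng)
            pool = _coords(pa) | _coords(pb)
            assert _coords(ca) <= pool
            assert _coords(cb) <= pool

    def test_keep_best_parent_returned_verbatim(self, tiny_phantom, rng):
        env = tiny_phantom.env
        params = PlannerParams()
        pa, pb = self._parents(env, rng)
        ca, _ = crossover(pa, pb, pa, env, params, rng)
        assert np.array_equal(encode_plan(ca), encode_plan(pa))
        _, cb = crossover(pa, pb, pb, env, params, rng)
        assert np.array_equal(encode_plan(cb), encode_plan(pb))

    def test_uniform_child_respects_needle_spacing(self, tiny_phantom, rng):
        env = tiny_phantom.env
        params = PlannerParams(ablation_radius_mm=10.0)
        for _ in range(50):
            pa, pb = self._parents(env, rng)
            child = crossover_uniform(list(pa) + list(pb), env, params)
            for i in range(len(child)):
                for j in range(i + 1, len(child)):
                    assert pairwise_segment_distance(child[i], child[j]) > 10.0

    def test_empty_parents_give_empty_children(self, tiny_phantom, rng):
        ca, cb = crossover(Plan(), Plan(), None, tiny_phantom.env, PlannerParams(), rng)
        assert len(ca) == 0 and len(cb) == 0


@pytest.fixture(scope="module")
def obstacle_env():
    # sphere obstacle r=5 at the origin, tumor below it
    return build_environment(
        icosphere(80.0, 3), icosphere(40.0, 3),
        icosphere(4.0, 3, center=(0.0, 0.0, -20.0)),
        critical=[icosphere(5.0, 3)],
        margin=3.0, spacing=2.0,
    )


class TestMutateTrajectory:

    def test_repulsion_along_obstacle_normal(self, obstacle_env, rng):
        params = PlannerParams()
        # grazing the +x side of the obstacle: normal there points along +x
        traj = Trajectory([4.5, 0.0, 60.0], [4.5, 0.0, -20.0])
        log = OperatorLog()
        out = mutate_trajectory(
            traj, obstacle_env, obstacle_env.treatment.points, params, rng, log
        )
        assert log["repulsion_steps"] >= 1
        shift = out.entry - traj.entry
        assert shift[0] > 0  # pushed in +x, away from the obstacle
        assert np.allclose(out.target - traj.target, shift)  # pure translation
        from ablaplan.operators import _first_collision

        assert _first_collision(out, obstacle_env) is None

    def test_noncolliding_coverage_never_decreases(self, tiny_phantom, rng):
        env = tiny_phantom.env
        params = PlannerParams()
        pts = env.treatment.points
        from ablaplan.plan import capsule_cover_mask

        for _ in range(50):
            traj = sample_individual(env, params, rng)[0]
            before = capsule_cover_mask(traj, pts, 10.0).sum()
            out = mutate_trajectory(traj, env, pts, params, rng)
            after = capsule_cover_mask(out, pts, 10.0).sum()
            assert after >= before

    def test_obstacle_free_no_repulsions(self, tiny_phantom, rng):
        env = tiny_phantom.env
        params = PlannerParams()
        log = OperatorLog()
        for _ in range(100):
            traj = sample_individual(env, params, rng)[0]
            mutate_trajectory(traj, env, env.treatment.points, params, rng, log)
        assert log["repulsion_steps"] == 0


class TestMutate:
    def test_full_coverage_never_adds(self, tiny_phantom, rng):
        env = tiny_phantom.env
        params = PlannerParams(p_remove=0.0)
        center = env.treatment.points[
            np.argmin(np.linalg.norm(env.treatment.points - env.treatment.centroid, axis=1))
        ]
        plan = Plan([Trajectory(center + np.array([0, 0, 90.0]), center)])
        log = OperatorLog()
        for _ in range(30):
            out = mutate(plan, env, params, rng, log, conform=False)
            assert len(out) <= len(plan)
        assert log["additions"] == 0

    def test_zero_coverage_adds_new_trajectory(self, tiny_phantom, rng):
        env = tiny_phantom.env
        params = PlannerParams(p_remove=0.0, n_perturb=0)
        # a needle far away from the treatment volume: zero coverage
        far = Trajectory([200.0, 200.0, 100.0], [200.0, 200.0, 0.0])
        log = OperatorLog()
        out = mutate(Plan([far]), env, params, rng, log, conform=False)
        assert len(out) >= 2
        assert log["additions"] == 1

    def test_removal_branch_frequency(self, tiny_phantom, rng):
        env = tiny_phantom.env
        params = PlannerParams(p_remove=0.35, n_perturb=1)
        center = env.treatment.points[
            np.argmin(np.linalg.norm(env.treatment.points - env.treatment.centroid, axis=1))
        ]
        plan = Plan([Trajectory(center + np.array([0, 0, 90.0]), center)])
        log = OperatorLog()
        trials = 2000
        for _ in range(trials):
            mutate(plan, env, params, rng, log, conform=False)
        assert log["removals"] / trials == pytest.approx(0.35, abs=0.035)

    def test_main_loop_bounded_by_input_plus_one(self, tiny_phantom, rng):
        env = tiny_phantom.env
        params = PlannerParams(p_remove=0.0)
        bundle = list(sample_individual(env, params, rng))
        for n in (0, 1, 3, 6):
            plan = Plan((bundle * (n // len(bundle) + 1))[:n])
            out = mutate(plan, env, params, rng, conform=False)
            assert len(out) <= n + 1

    def test_worst_removal_prefers_redundant_needle(self, tiny_phantom, rng):
        from ablaplan.operators import _worst_index

        env = tiny_phantom.env
        params = PlannerParams()
        center = env.treatment.points[
            np.argmin(np.linalg.norm(env.treatment.points - env.treatment.centroid, axis=1))
        ]
        good = Trajectory(center + np.array([0, 0, 90.0]), center)
        useless = Trajectory([150.0, 150.0, 90.0], [150.0, 150.0, 0.0])
        assert _worst_index(Plan([good, useless]), env, params) == 1
        assert _worst_index(Plan([useless, good]), env, params) == 0


class TestConform:
    def test_shallow_liver_path_removed(self, subcapsular_env):
        env = subcapsular_env
        params = PlannerParams()
        # deepest treatment point sits just under the capsule: < 5 mm of liver
        target = env.treatment.points[np.argmax(env.treatment.points[:, 2])]
        traj = Trajectory([0.0, 0.0, 79.0], target)
        _, in_liver, _ = trajectory_lengths(traj, env)
        assert in_liver < 5.0
        out = conform_to_environment(Plan([traj]), env, params)
        assert len(out) == 0

    def test_steep_tangent_angle_removed(self, subcapsular_env):
        env = subcapsular_env
        params = PlannerParams()
        # nearly tangent to the liver capsule at z=39: > 70 deg to the normal
        pts = env.treatment.points
        near_axis = (np.abs(pts[:, 0]) <= 0.6) & (np.abs(pts[:, 1]) <= 0.6)
        cand = pts[near_axis]
        target = cand[np.argmin(np.abs(cand[:, 2] - 38.8))]
        entry = np.array([-69.0, target[1], target[2]])
        traj = Trajectory(entry, target)
        _, a_liver = entry_angles(traj, env)
        assert a_liver > 70.0
        _, in_liver, _ = trajectory_lengths(traj, env)
        assert in_liver > 5.0  # angle, not depth, is the violation
        out = conform_to_environment(Plan([traj]), env, params)
        assert len(out) == 0

    def test_overlong_trajectory_shortened_on_same_line(self, elongated_env):
        env = elongated_env
        params = PlannerParams()
        traj = Trajectory([-160.0, 0.0, 0.0], [0.0, 0.0, 0.0])
        out = conform_to_environment(Plan([traj]), env, params)
        assert len(out) == 1
        kept = out[0]
        assert kept.length <= 150.0 + 1e-9
        assert np.array_equal(kept.target, traj.target)
        # entry moved along the original line
        assert abs(kept.entry[1]) < 1e-9 and abs(kept.entry[2]) < 1e-9

    def test_compliant_trajectory_survives_unchanged_direction(self, concentric_env):
        params = PlannerParams()
        traj = Trajectory([0.0, 0.0, 79.0], [0.0, 0.0, 0.0])
        out = conform_to_environment(Plan([traj]), concentric_env, params)
        assert len(out) == 1
        assert np.array_equal(out[0].target, traj.target)

    def test_idempotent_on_mutated_plans(self, tiny_phantom, rng):
        env = tiny_phantom.env
        params = PlannerParams()
        for _ in range(20):
            plan = mutate(sample_individual(env, params, rng), env, params, rng)
            once = conform_to_environment(plan, env, params)
            twice = conform_to_environment(once, env, params)
            assert np.array_equal(encode_plan(once), encode_plan(twice))

    def test_filters_self_consistent_after_conform(self, tiny_phantom, rng):
        env = tiny_phantom.env
        params = PlannerParams()
        tv = env.treatment
        for _ in range(20):
            raw = sample_individual(env, params, rng)
            plan = conform_to_environment(raw, env, params)
            for t in plan:
                total, in_liver, _ = trajectory_lengths(t, env)
                assert total <= params.max_length_mm + 1e-6
                assert in_liver >= params.min_liver_mm - 1e-6
                a_skin, a_liver = entry_angles(t, env)
                assert max(a_skin, a_liver) <= params.max_normal_angle_deg + 1e-6
                assert np.min(np.linalg.norm(tv.points - t.target, axis=1)) <= tv.spacing
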