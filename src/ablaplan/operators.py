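"""Bespoke GA operators: sampling, crossover, mutation, conforming.

Sampling builds near-parallel needle bundles along the longest axis of the
treatment volume, mirroring how interventionalists insert applicators for the
pullback technique.  Crossover recombines whole trajectories from the two
parents without touching their coordinates; when one parent is the current
best individual it is kept verbatim as one child.  Mutation greedily rebuilds
a solution trajectory-by-trajectory against the residual uncovered volume,
pushes colliding needles along the obstacle's surface normal, may add a
needle when coverage is insufficient and may delete the worst-performing one,
and finally conforms everything to the physical limits of the environment
(entry on skin, target in the treatment volume, >= 5 mm in liver, <= 150 mm
long, >= 20 deg to the skin/capsule tangent plane).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .environment import Environment
from .errors import PlanningInfeasibleError
from .objectives import (
    EvalResult,
    PlannerParams,
    entry_angles,
    evaluate_plan,
    pairwise_segment_distance,
)
from .plan import (
    Plan,
    Trajectory,
    ablation_positions,
    capsule_cover_mask,
    point_segment_distance,
    trajectory_lengths,
)

__all__ = [
    "Population",
    "OperatorLog",
    "sample_individual",
    "sample_population",
    "crossover",
    "crossover_uniform",
    "crossover_random",
    "mutate",
    "mutate_trajectory",
    "conform_to_environment",
]


class OperatorLog(Counter):
    """Diagnostic event counter (removals, additions, repulsion steps...)."""


def _best_key(ev: EvalResult):
    """Ordering for the single 'best' individual: least violation first, then
    coverage shortfall, then total objective."""
    return (ev.sum_G, float(ev.F[4]), float(ev.F.sum()))


@dataclass
class Population:
    """Plans paired with their cached evaluations."""

    individuals: list = field(default_factory=list)  # list[Plan]
    evals: list = field(default_factory=list)  # list[EvalResult | None]

    def __len__(self) -> int:
        return len(self.individuals)

    def evaluate(self, env: Environment, params: PlannerParams) -> None:
        for i, ev in enumerate(self.evals):
            if ev is None:
                self.evals[i] = evaluate_plan(self.individuals[i], env, params)

    @property
    def best_index(self) -> int:
        if not self.individuals:
            raise ValueError("empty population")
        if any(ev is None for ev in self.evals):
            raise ValueError("population not fully evaluated")
        return min(range(len(self.evals)), key=lambda i: _best_key(self.evals[i]))

    @property
    def best(self) -> Plan:
        return self.individuals[self.best_index]


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def _project_entry(env: Environment, target: np.ndarray, direction: np.ndarray):
    """Entry point: where the backward ray from the target exits the entry
    surface; falls back to the nearest entry-surface point."""
    p1 = target - 400.0 * direction
    pts, _, ts = env.entry_surface.segment_intersections(target, p1)
    if ts.size:
        return pts[0]
    probe = target - 100.0 * direction
    return env.entry_surface.closest_points(probe[None, :])[0]


def _bundle_direction(env: Environment, rng: np.random.Generator) -> np.ndarray:
    """Needle direction for one individual: the treatment volume's longest
    axis (so pullback sweeps the tumor lengthwise), slightly jittered, with
    the sign chosen so the backward ray reaches the entry surface."""
    tv = env.treatment
    axis = tv.principal_axis.copy()
    jitter = rng.normal(0.0, np.tan(np.radians(8.0)), 3)
    axis = axis + jitter - (jitter @ axis) * axis
    axis /= np.linalg.norm(axis)
    c = tv.centroid
    for sign in (1.0, -1.0):
        _, _, ts = env.entry_surface.segment_intersections(c, c - 400.0 * sign * axis)
        if ts.size:
            return sign * axis
    # no skin behind either axis direction: aim from a random entry point
    entry_ref = env.sample_entry_points(rng, 1)[0]
    d = c - entry_ref
    return d / np.linalg.norm(d)


def sample_individual(
    env: Environment, params: PlannerParams, rng: np.random.Generator
) -> Plan:
    """One near-parallel needle bundle along the treatment volume's long axis.

    Needle count follows the axis-length/radius heuristic (jittered by one);
    targets are the deepest treatment points of transversally spread columns,
    entries the backward projections onto the entry surface.
    """
    tv = env.treatment
    base = int(np.ceil(tv.axis_length / params.ablation_radius_mm))
    n = max(1, base + int(rng.integers(-1, 2)))
    u = _bundle_direction(env, rng)

    # spread column anchors over the transverse footprint of the volume
    depth = tv.points @ u
    transverse = tv.points - np.outer(depth, u)
    t_centroid = transverse.mean(axis=0)
    trajectories = []
    for _ in range(n):
        anchor = t_centroid + rng.normal(0.0, 0.35 * max(tv.axis_length, tv.spacing), 3)
        anchor -= (anchor @ u) * u
        d_trans = np.linalg.norm(transverse - anchor, axis=1)
        column = d_trans <= max(params.ablation_radius_mm, d_trans.min() + tv.spacing)
        idx = np.flatnonzero(column)
        target = tv.points[idx[np.argmax(depth[idx])]]  # deepest point of column
        entry = _project_entry(env, target, u)
        if np.linalg.norm(target - entry) < 1e-6:
            continue
        trajectories.append(Trajectory(entry, target))
    if not trajectories:
        raise PlanningInfeasibleError("sampling produced no admissible trajectory")
    return Plan(trajectories)


def sample_population(
    env: Environment, params: PlannerParams, rng: np.random.Generator
) -> Population:
    plans = [sample_individual(env, params, rng) for _ in range(params.pop_size)]
    return Population(individuals=plans, evals=[None] * len(plans))


# ---------------------------------------------------------------------------
# crossover (whole-trajectory recombination, Algorithm 2 style)
# ---------------------------------------------------------------------------

def crossover_uniform(
    pool: list, env: Environment, params: PlannerParams
) -> Plan:
    """Greedy marginal-coverage subset of the parents' trajectories, keeping
    every selected pair of needles farther apart than the ablation radius."""
    points = env.treatment.points
    radius = params.ablation_radius_mm
    step = params.pullback_step
    masks = [capsule_cover_mask(t, points, radius, step) for t in pool]
    chosen: list[int] = []
    covered = np.zeros(len(points), dtype=bool)
    remaining = list(range(len(pool)))
    while remaining:
        gains = [int(np.sum(masks[i] & ~covered)) for i in remaining]
        order = int(np.argmax(gains))
        if gains[order] <= 0:
            break
        cand = remaining[order]
        if all(
            pairwise_segment_distance(pool[cand], pool[j]) > radius for j in chosen
        ):
            chosen.append(cand)
            covered |= masks[cand]
        remaining.remove(cand)
    if not chosen and pool:
        # nothing gains coverage (degenerate parents): keep the single best
        chosen = [int(np.argmax([m.sum() for m in masks]))]
    return Plan([pool[i] for i in sorted(chosen)])


def crossover_random(pool: list, rng: np.random.Generator) -> Plan:
    """Uniform random non-empty subset of the parents' trajectories."""
    if not pool:
        return Plan([])
    keep = rng.random(len(pool)) < 0.5
    if not keep.any():
        keep[int(rng.integers(len(pool)))] = True
    return Plan([t for t, k in zip(pool, keep) if k])


def _same_plan(a: Plan, b: Plan) -> bool:
    if len(a) != len(b):
        return False
    return all(
        np.array_equal(x.entry, y.entry) and np.array_equal(x.target, y.target)
        for x, y in zip(a, b)
    )


def crossover(
    parent_a: Plan,
    parent_b: Plan,
    best: Plan | None,
    env: Environment,
    params: PlannerParams,
    rng: np.random.Generator,
    log: OperatorLog | None = None,
):
    """Two offspring from two parents; the best individual passes unchanged."""
    pool = list(parent_a) + list(parent_b)
    if best is not None and _same_plan(parent_a, best):
        if log is not None:
            log["keep_best"] += 1
        return parent_a.copy(), crossover_uniform(pool, env, params)
    if best is not None and _same_plan(parent_b, best):
        if log is not None:
            log["keep_best"] += 1
        return crossover_uniform(pool, env, params), parent_b.copy()
    child_a = crossover_uniform(pool, env, params)
    child_b = crossover_random(pool, rng)
    return child_a, child_b


# ---------------------------------------------------------------------------
# mutation
# ---------------------------------------------------------------------------

def _first_collision(traj: Trajectory, env: Environment):
    """(t, outward normal) of the nearest critical-structure hit, or None."""
    best_t, best_n = None, None
    for obstacle in env.critical:
        _, normals, ts = obstacle.segment_intersections(traj.entry, traj.target)
        if ts.size and (best_t is None or ts[0] < best_t):
            best_t, best_n = float(ts[0]), normals[0]
    return (best_t, best_n) if best_t is not None else None


def mutate_trajectory(
    traj: Trajectory,
    env: Environment,
    residual_points: np.ndarray,
    params: PlannerParams,
    rng: np.random.Generator,
    log: OperatorLog | None = None,
) -> Trajectory:
    """Repel a colliding needle along the obstacle normal; otherwise try a few
    local entry/target perturbations and keep the best residual coverage."""
    hit = _first_collision(traj, env)
    if hit is not None:
        current = traj
        for _ in range(params.repulsion_max_steps):
            _, normal = hit
            current = current.translated(params.repulsion_step_mm * normal)
            if log is not None:
                log["repulsion_steps"] += 1
            hit = _first_collision(current, env)
            if hit is None:
                break
        if hit is not None and log is not None:
            log["unresolved_collisions"] += 1
        return current

    radius = params.ablation_radius_mm
    step = params.pullback_step

    def score(t: Trajectory):
        # primary: residual points covered; secondary: negative total distance
        # shortfall of the near-misses (continuous signal for refinement)
        if not len(residual_points):
            return (0, 0.0)
        zone = ablation_positions(t, residual_points, radius, step)
        d = point_segment_distance(residual_points, zone.a, zone.b)
        covered = d <= radius
        shortfall = float(np.clip(d[~covered] - radius, 0.0, 2.0).sum())
        return (int(covered.sum()), -shortfall)

    best = traj
    best_score = score(traj)
    candidates = []
    if len(residual_points):
        # deterministic candidate: nudge the whole needle toward the worst
        # near-miss so the last uncovered points can be reeled in
        zone = ablation_positions(traj, residual_points, radius, step)
        d = point_segment_distance(residual_points, zone.a, zone.b)
        worst = int(np.argmax(d)) if np.any(d > radius) else None
        if worst is not None:
            p = residual_points[worst]
            ab = zone.b - zone.a
            denom = float(ab @ ab)
            t = np.clip(((p - zone.a) @ ab) / denom, 0, 1) if denom > 0 else 0.0
            v = p - (zone.a + t * ab)
            norm = np.linalg.norm(v)
            if norm > 1e-9:
                shift = min(0.5 * (norm - radius) + 0.05, 1.0) * v / norm
                candidates.append(traj.translated(shift))
    # candidate scales shrink from the configured sigma down to sub-mm nudges
    scales = np.geomspace(1.0, 0.05, max(1, params.n_perturb))
    for s in scales:
        candidates.append(
            Trajectory(
                traj.entry + rng.normal(0.0, s * params.sigma_entry_mm, 3),
                traj.target + rng.normal(0.0, s * params.sigma_target_mm, 3),
            )
        )
    for cand in candidates:
        if np.linalg.norm(cand.target - cand.entry) < 1e-6:
            continue
        if _first_collision(cand, env) is not None:
            continue
        cand_score = score(cand)
        if cand_score > best_score:
            best, best_score = cand, cand_score
    return best


def _worst_index(plan: Plan, env: Environment, params: PlannerParams) -> int:
    """Smallest marginal coverage contribution; ties -> longest, then lowest index."""
    points = env.treatment.points
    radius = params.ablation_radius_mm
    step = params.pullback_step
    masks = [capsule_cover_mask(t, points, radius, step) for t in plan]
    total = np.zeros(len(points), dtype=bool)
    for m in masks:
        total |= m
    best = None
    for i, (t, m) in enumerate(zip(plan, masks)):
        others = np.zeros(len(points), dtype=bool)
        for j, mj in enumerate(masks):
            if j != i:
                others |= mj
        marginal = int(np.sum(m & ~others))
        key = (marginal, -t.length, i)
        if best is None or key < best[0]:
            best = (key, i)
    return best[1]


def _new_trajectory(
    env: Environment,
    uncovered_points: np.ndarray,
    intermediate: list,
    params: PlannerParams,
    rng: np.random.Generator,
) -> Trajectory | None:
    """A fresh needle aimed at the residual volume, parallel to the bundle."""
    centroid = uncovered_points.mean(axis=0)
    target = uncovered_points[
        np.argmin(np.linalg.norm(uncovered_points - centroid, axis=1))
    ]
    if intermediate:
        direction = np.mean([t.direction for t in intermediate], axis=0)
        norm = np.linalg.norm(direction)
        direction = direction / norm if norm > 1e-9 else None
    else:
        direction = None
    if direction is None:
        entry_ref = env.sample_entry_points(rng, 1)[0]
        direction = target - entry_ref
        direction /= np.linalg.norm(direction)
    entry = _project_entry(env, target, direction)
    if np.linalg.norm(target - entry) < 1e-6:
        return None
    return Trajectory(entry, target)


def mutate(
    plan: Plan,
    env: Environment,
    params: PlannerParams,
    rng: np.random.Generator,
    log: OperatorLog | None = None,
    conform: bool = True,
) -> Plan:
    """Greedy rebuild of the plan against the residual treatment volume.

    Repeatedly takes the input trajectory with the highest residual coverage,
    mutates it, adds it to the intermediate solution and removes the points
    it covers; stops at the coverage threshold or when the input is
    exhausted.  Then adds a new needle if coverage is still insufficient,
    deletes the worst-performing needle with probability ``p_remove`` and
    conforms the result to the environment.
    """
    points = env.treatment.points
    n_points = len(points)
    radius = params.ablation_radius_mm
    step = params.pullback_step

    remaining = list(plan)
    covered = np.zeros(n_points, dtype=bool)
    intermediate: list[Trajectory] = []
    while remaining and covered.mean() < params.eps_coverage:
        uncovered_idx = np.flatnonzero(~covered)
        gains = [
            int(capsule_cover_mask(t, points[uncovered_idx], radius, step).sum())
            for t in remaining
        ]
        pick = int(np.argmax(gains))
        traj = remaining.pop(pick)
        mutated = mutate_trajectory(
            traj, env, points[uncovered_idx], params, rng, log
        )
        intermediate.append(mutated)
        covered |= capsule_cover_mask(mutated, points, radius, step)

    if covered.mean() < params.eps_coverage:
        uncovered_idx = np.flatnonzero(~covered)
        if uncovered_idx.size:
            fresh = _new_trajectory(
                env, points[uncovered_idx], intermediate, params, rng
            )
            if fresh is not None:
                intermediate.append(fresh)
                if log is not None:
                    log["additions"] += 1

    if rng.random() < params.p_remove and intermediate:
        worst = _worst_index(Plan(intermediate), env, params)
        intermediate.pop(worst)
        if log is not None:
            log["removals"] += 1

    result = Plan(intermediate)
    return conform_to_environment(result, env, params) if conform else result


# ---------------------------------------------------------------------------
# conform filter
# ---------------------------------------------------------------------------

def _snap_entry(traj: Trajectory, env: Environment) -> Trajectory:
    """Put the entry on the entry surface with minimal displacement.

    An entry strictly inside the body is left alone: it belongs to a
    deliberately shortened over-long trajectory.
    """
    if env.entry_surface.surface_distance(traj.entry[None, :])[0] < 1e-6:
        return traj
    inside_skin = env.skin.contains_point(traj.entry)
    if inside_skin:
        return traj
    u = traj.direction
    p1 = traj.target - 400.0 * u
    pts, _, ts = env.entry_surface.segment_intersections(traj.target, p1)
    if ts.size:
        i = int(np.argmin(np.linalg.norm(pts - traj.entry, axis=1)))
        return Trajectory(pts[i], traj.target)
    nearest = env.entry_surface.closest_points(traj.entry[None, :])[0]
    return Trajectory(nearest, traj.target)


def conform_to_environment(
    plan: Plan, env: Environment, params: PlannerParams
) -> Plan:
    """Project trajectories onto the admissible set; drop the unfixable ones.

    Surviving trajectories have their entry on the entry surface (or inside
    the body after shortening), target in the treatment volume, at least
    ``min_liver_mm`` of liver on the path, length at most ``max_length_mm``
    (shortened along the same line toward the target) and an angle of at
    least ``min_tangent_angle_deg`` to the skin and capsule tangent planes.
    Idempotent: conforming a conformed plan changes nothing.
    """
    tv = env.treatment
    kept = []
    for traj in plan:
        if np.linalg.norm(traj.target - traj.entry) < 1e-6:
            continue
        # target into the treatment volume
        d = np.linalg.norm(tv.points - traj.target, axis=1)
        nearest = int(np.argmin(d))
        if d[nearest] > tv.spacing:
            traj = Trajectory(traj.entry, tv.points[nearest])
            if np.linalg.norm(traj.target - traj.entry) < 1e-6:
                continue
        traj = _snap_entry(traj, env)
        if traj.length > params.max_length_mm:
            traj = Trajectory(
                traj.target - params.max_length_mm * traj.direction, traj.target
            )
        _, in_liver, _ = trajectory_lengths(traj, env)
        if in_liver < params.min_liver_mm:
            continue
        try:
            a_skin, a_liver = entry_angles(traj, env)
        except ValueError:
            continue
        if max(a_skin, a_liver) > params.max_normal_angle_deg:
            continue
        kept.append(traj)
    return Plan(kept)
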