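"""Objective vector F and constraint vector G for a candidate plan.

Six objectives, all normalized to [0, 1] and minimized (quantities that
should be maximized enter as 1 - value):

* f0 - mean trajectory length / maximum applicator length (150 mm)
* f1 - 1 - mean in-tumor length / longest treatment-volume chord
* f2 - mean in-liver length / maximum applicator length
* f3 - mean angle to the skin and liver-capsule normals / 90 deg
* f4 - 1 - coverage of the tumor plus margin
* f5 - trajectory count / maximum needle budget

Two constraints (feasible iff both are zero):

* g0 - 1 if any trajectory crosses a critical structure or two needles come
  closer than the inter-needle clearance, else 0
* g1 - max(0, eps_coverage - coverage): the coverage shortfall below the
  epsilon threshold
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .environment import Environment
from .plan import Plan, Trajectory, plan_cover_mask, trajectory_lengths

__all__ = [
    "PlannerParams",
    "EvalResult",
    "evaluate_plan",
    "evaluate_objectives",
    "evaluate_constraints",
    "pairwise_segment_distance",
    "entry_angles",
    "plan_collides",
]


@dataclass
class PlannerParams:
    """Tunable planning parameters (lengths in mm, angles in degrees)."""

    ablation_radius_mm: float = 10.0
    eps_coverage: float = 0.98
    max_needles: int = 30
    p_remove: float = 0.35
    max_length_mm: float = 150.0
    min_liver_mm: float = 5.0
    min_tangent_angle_deg: float = 20.0
    needle_clearance_mm: float = 2.0
    pullback_step_mm: float | None = None  # None -> ablation radius

    # GA budgets
    pop_size: int = 40
    n_generations: int = 200
    max_restarts: int = 10
    stagnation_window: int = 15
    stagnation_tol: float = 1e-6
    f4_improve_tol: float = 1e-4

    # mutation internals
    repulsion_step_mm: float = 2.0
    repulsion_max_steps: int = 10
    n_perturb: int = 5
    sigma_entry_mm: float = 3.0
    sigma_target_mm: float = 2.0

    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.eps_coverage <= 1.0):
            raise ValueError("eps_coverage must lie in (0, 1]")
        for name in (
            "ablation_radius_mm",
            "max_needles",
            "max_length_mm",
            "min_liver_mm",
            "min_tangent_angle_deg",
            "pop_size",
            "n_generations",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def pullback_step(self) -> float:
        return (
            self.ablation_radius_mm
            if self.pullback_step_mm is None
            else self.pullback_step_mm
        )

    @property
    def max_normal_angle_deg(self) -> float:
        """Steepest admissible angle to the surface normal (90 - tangent limit)."""
        return 90.0 - self.min_tangent_angle_deg


@dataclass
class EvalResult:
    """Objectives, constraints and summary metrics for one plan."""

    F: np.ndarray  # (6,) in [0, 1]
    G: np.ndarray  # (2,) non-negative
    coverage: float
    n_trajectories: int
    mean_angle_deg: float
    mean_length_mm: float

    @property
    def feasible(self) -> bool:
        return float(self.G.sum()) == 0.0

    @property
    def sum_G(self) -> float:
        return float(self.G.sum())

    def to_dict(self) -> dict:
        return {
            "F": self.F.tolist(),
            "G": self.G.tolist(),
            "coverage": self.coverage,
            "n_trajectories": self.n_trajectories,
            "mean_angle_deg": self.mean_angle_deg,
            "mean_length_mm": self.mean_length_mm,
            "feasible": self.feasible,
        }


# ---------------------------------------------------------------------------
# segment-segment distance (used by g0 and by crossoverUniform spacing)
# ---------------------------------------------------------------------------

def _segment_segment_distance(p1, q1, p2, q2) -> float:
    """Exact minimum distance between segments [p1,q1] and [p2,q2]."""
    d1 = q1 - p1
    d2 = q2 - p2
    r = p1 - p2
    a = float(d1 @ d1)
    e = float(d2 @ d2)
    f = float(d2 @ r)
    eps = 1e-15
    if a <= eps and e <= eps:
        return float(np.linalg.norm(r))
    if a <= eps:
        s, t = 0.0, np.clip(f / e, 0.0, 1.0)
    else:
        c = float(d1 @ r)
        if e <= eps:
            t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
        else:
            b = float(d1 @ d2)
            denom = a * e - b * b
            s = np.clip((b * f - c * e) / denom, 0.0, 1.0) if denom > eps else 0.0
            t = (b * s + f) / e
            if t < 0.0:
                t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
            elif t > 1.0:
                t, s = 1.0, np.clip((b - c) / a, 0.0, 1.0)
    closest1 = p1 + s * d1
    closest2 = p2 + t * d2
    return float(np.linalg.norm(closest1 - closest2))


def pairwise_segment_distance(t1: Trajectory, t2: Trajectory) -> float:
    """Minimum Euclidean distance between two needle shafts, mm."""
    return _segment_segment_distance(t1.entry, t1.target, t2.entry, t2.target)


# ---------------------------------------------------------------------------
# entry angles
# ---------------------------------------------------------------------------

def _first_crossing(indexed, traj: Trajectory, back: float = 300.0):
    """Crossing where the needle passes the surface, searching the extended
    shaft (``back`` mm behind the entry) so shortened trajectories whose entry
    was pulled inside the body still report their skin/capsule crossing."""
    u = traj.direction
    p0 = traj.entry - back * u
    _, normals, ts = indexed.segment_intersections(p0, traj.target)
    if ts.size == 0:
        return None
    seg_len = float(np.linalg.norm(traj.target - p0))
    t_entry = back / seg_len
    before = np.flatnonzero(ts <= t_entry + 1e-9)
    i = int(before[-1]) if before.size else 0
    return normals[i]


def entry_angles(traj: Trajectory, env: Environment):
    """(skin angle, liver-capsule angle) between shaft and outward normal.

    Angles are in [0, 90] degrees; 0 means perpendicular insertion.  Raises
    ``ValueError`` when the shaft crosses neither surface.
    """
    u = traj.direction
    out = []
    for indexed in (env.skin, env.liver):
        n = _first_crossing(indexed, traj)
        if n is None:
            raise ValueError("trajectory does not cross the surface")
        cosang = np.clip(abs(float(u @ n)), 0.0, 1.0)
        out.append(float(np.degrees(np.arccos(cosang))))
    return tuple(out)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def plan_collides(plan: Plan, env: Environment, params: PlannerParams) -> bool:
    """True if any needle crosses a critical structure or two needles come
    within the inter-needle clearance of each other."""
    trajs = list(plan)
    for t in trajs:
        for obstacle in env.critical:
            _, _, ts = obstacle.segment_intersections(t.entry, t.target)
            if ts.size:
                return True
    for i in range(len(trajs)):
        for j in range(i + 1, len(trajs)):
            if pairwise_segment_distance(trajs[i], trajs[j]) < params.needle_clearance_mm:
                return True
    return False


def evaluate_plan(plan: Plan, env: Environment, params: PlannerParams) -> EvalResult:
    tv = env.treatment
    if len(plan) == 0:
        # worst case: nothing is covered, no admissible geometry
        return EvalResult(
            F=np.ones(6),
            G=np.array([0.0, params.eps_coverage]),
            coverage=0.0,
            n_trajectories=0,
            mean_angle_deg=90.0,
            mean_length_mm=0.0,
        )
    mask = plan_cover_mask(plan, tv.points, params.ablation_radius_mm, params.pullback_step)
    coverage = float(mask.mean())

    totals, livers, tumors, angles, skin_angles = [], [], [], [], []
    for t in plan:
        total, in_liver, in_tumor = trajectory_lengths(t, env)
        totals.append(total)
        livers.append(in_liver)
        tumors.append(in_tumor)
        try:
            a_skin, a_liver = entry_angles(t, env)
        except ValueError:
            a_skin = a_liver = 90.0
        skin_angles.append(a_skin)
        angles.append(0.5 * (a_skin + a_liver))

    chord = max(tv.longest_chord, 1e-9)
    f0 = np.mean(totals) / params.max_length_mm
    f1 = 1.0 - np.mean(tumors) / chord
    f2 = np.mean(livers) / params.max_length_mm
    f3 = np.mean(angles) / 90.0
    f4 = 1.0 - coverage
    f5 = len(plan) / params.max_needles
    F = np.clip(np.array([f0, f1, f2, f3, f4, f5]), 0.0, 1.0)

    g0 = 1.0 if plan_collides(plan, env, params) else 0.0
    g1 = max(0.0, params.eps_coverage - coverage)
    return EvalResult(
        F=F,
        G=np.array([g0, g1]),
        coverage=coverage,
        n_trajectories=len(plan),
        mean_angle_deg=float(np.mean(skin_angles)),
        mean_length_mm=float(np.mean(totals)),
    )


def evaluate_objectives(plan: Plan, env: Environment, params: PlannerParams) -> np.ndarray:
    return evaluate_plan(plan, env, params).F


def evaluate_constraints(plan: Plan, env: Environment, params: PlannerParams) -> np.ndarray:
    return evaluate_plan(plan, env, params).G
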