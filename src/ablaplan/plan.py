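"""Trajectories, plans and the cylinder/pullback ablation-zone model.

A *trajectory* is the straight needle path from a skin entry point to an
intra-tumor target.  A *plan* is a variable-length ordered list of
trajectories; for the genetic algorithm it round-trips losslessly to a flat
coordinate array (entry xyz then target xyz per trajectory).

The ablation zone of one needle under the pullback technique is modelled as a
chain of spheres placed backward from the target along the trajectory — a
cylinder with hemispherical caps (a capsule) in the limit of a fine pullback
step.  Coverage of the treatment volume is the fraction of its sample points
within the ablation radius of the union of the plans' active segments.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .environment import Environment, TreatmentVolume

__all__ = [
    "Trajectory",
    "Plan",
    "AblationZone",
    "encode_plan",
    "decode_plan",
    "ablation_positions",
    "capsule_cover_mask",
    "coverage_fraction",
    "trajectory_lengths",
    "point_segment_distance",
    "save_plan_json",
    "load_plan_json",
    "save_plan_csv",
]


@dataclass(frozen=True, eq=False)
class Trajectory:
    """Entry (on skin) and target (in the treatment volume) points, mm."""

    entry: np.ndarray
    target: np.ndarray

    def __post_init__(self):
        object.__setattr__(
            self, "entry", np.asarray(self.entry, dtype=np.float64).reshape(3)
        )
        object.__setattr__(
            self, "target", np.asarray(self.target, dtype=np.float64).reshape(3)
        )

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.target - self.entry))

    @property
    def direction(self) -> np.ndarray:
        """Unit vector from entry toward target."""
        d = self.target - self.entry
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("degenerate trajectory: entry == target")
        return d / n

    def translated(self, offset) -> "Trajectory":
        offset = np.asarray(offset, dtype=np.float64)
        return Trajectory(self.entry + offset, self.target + offset)


@dataclass(eq=False)
class Plan:
    """Ordered, variable-length set of trajectories (one GA individual)."""

    trajectories: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)

    def __getitem__(self, i):
        return self.trajectories[i]

    def copy(self) -> "Plan":
        return Plan(list(self.trajectories))

    def entries(self) -> np.ndarray:
        return np.array([t.entry for t in self.trajectories]).reshape(-1, 3)

    def targets(self) -> np.ndarray:
        return np.array([t.target for t in self.trajectories]).reshape(-1, 3)


def encode_plan(plan: Plan) -> np.ndarray:
    """Flatten to ``[e0x e0y e0z t0x t0y t0z e1x ...]``."""
    if len(plan) == 0:
        return np.empty(0)
    return np.concatenate(
        [np.concatenate([t.entry, t.target]) for t in plan.trajectories]
    )


def decode_plan(array) -> Plan:
    array = np.asarray(array, dtype=np.float64).ravel()
    if array.size % 6:
        raise ValueError(f"plan array length {array.size} not divisible by 6")
    coords = array.reshape(-1, 6)
    return Plan([Trajectory(row[:3], row[3:]) for row in coords])


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def point_segment_distance(points: np.ndarray, a, b) -> np.ndarray:
    """Distance from each point to segment [a, b]."""
    points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        return np.linalg.norm(points - a, axis=1)
    t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    closest = a + t[:, None] * ab
    return np.linalg.norm(points - closest, axis=1)


# ---------------------------------------------------------------------------
# pullback ablation model
# ---------------------------------------------------------------------------

@dataclass
class AblationZone:
    """Active segment [a, b] (b = deepest = target side) plus sphere centers."""

    a: np.ndarray
    b: np.ndarray
    radius: float
    centers: np.ndarray  # (k, 3), first center at the target

    @property
    def n_ablations(self) -> int:
        return len(self.centers)


def ablation_positions(
    traj: Trajectory,
    tv: TreatmentVolume | np.ndarray,
    radius: float,
    step: float | None = None,
) -> AblationZone:
    """Pullback sphere centers for one needle.

    The first ablation is at the target; the applicator is then pulled back
    along the trajectory in increments of ``step`` (default: the ablation
    radius) for as long as the next sphere still covers at least one
    treatment point missed by the previous spheres.  A trajectory whose
    spheres never touch the treatment volume gets a single ablation at the
    target.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    step = radius if step is None else step
    points = tv.points if isinstance(tv, TreatmentVolume) else np.asarray(tv)
    u = traj.direction
    centers = [traj.target]
    uncovered = np.linalg.norm(points - traj.target, axis=1) > radius
    max_pullback = int(np.ceil(traj.length / step)) if step > 0 else 0
    for k in range(1, max_pullback + 1):
        c = traj.target - k * step * u
        if not uncovered.any():
            break
        gain = np.linalg.norm(points[uncovered] - c, axis=1) <= radius
        if not gain.any():
            break
        idx = np.flatnonzero(uncovered)[gain]
        uncovered[idx] = False
        centers.append(c)
    centers = np.asarray(centers)
    return AblationZone(a=centers[-1], b=traj.target, radius=radius, centers=centers)


def capsule_cover_mask(
    traj: Trajectory,
    points: np.ndarray,
    radius: float,
    step: float | None = None,
) -> np.ndarray:
    """Boolean mask of points within the needle's capsule ablation zone."""
    points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    if len(points) == 0:
        return np.zeros(0, dtype=bool)
    zone = ablation_positions(traj, points, radius, step)
    return point_segment_distance(points, zone.a, zone.b) <= radius


def coverage_fraction(
    plan: Plan,
    tv: TreatmentVolume,
    radius: float,
    step: float | None = None,
) -> float:
    """Fraction of treatment points inside the union of capsule zones."""
    if len(tv) == 0:
        raise ValueError("empty treatment volume")
    if len(plan) == 0:
        return 0.0
    mask = np.zeros(len(tv), dtype=bool)
    for traj in plan:
        mask |= capsule_cover_mask(traj, tv.points, radius, step)
    return float(mask.mean())


def plan_cover_mask(
    plan: Plan, points: np.ndarray, radius: float, step: float | None = None
) -> np.ndarray:
    mask = np.zeros(len(points), dtype=bool)
    for traj in plan:
        mask |= capsule_cover_mask(traj, points, radius, step)
    return mask


# ---------------------------------------------------------------------------
# in-structure path lengths
# ---------------------------------------------------------------------------

def _inside_length(indexed, p0, p1) -> float:
    """Length of segment [p0, p1] inside a watertight mesh, by crossing parity."""
    if not indexed.watertight:
        raise ValueError("in-structure length requires a watertight mesh")
    total = float(np.linalg.norm(np.asarray(p1) - np.asarray(p0)))
    if total == 0:
        return 0.0
    _, _, ts = indexed.segment_intersections(p0, p1)
    inside = indexed.contains_point(p0)
    bounds = np.concatenate([[0.0], ts, [1.0]])
    length = 0.0
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if inside:
            length += hi - lo
        inside = not inside
    return length * total


def trajectory_lengths(traj: Trajectory, env: Environment):
    """(total, in-liver, in-tumor) path lengths in mm."""
    total = traj.length
    in_liver = _inside_length(env.liver, traj.entry, traj.target)
    in_tumor = _inside_length(env.tumor, traj.entry, traj.target)
    return total, in_liver, in_tumor


# ---------------------------------------------------------------------------
# plan I/O
# ---------------------------------------------------------------------------

def plan_to_dict(plan: Plan) -> dict:
    return {
        "trajectories": [
            {"entry": t.entry.tolist(), "target": t.target.tolist()} for t in plan
        ]
    }


def plan_from_dict(d: dict) -> Plan:
    return Plan(
        [Trajectory(t["entry"], t["target"]) for t in d.get("trajectories", [])]
    )


def save_plan_json(plan: Plan, path, extra: dict | None = None) -> None:
    payload = plan_to_dict(plan)
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def load_plan_json(path) -> Plan:
    return plan_from_dict(json.loads(Path(path).read_text()))


def save_plan_csv(plan: Plan, path, env: Environment | None = None) -> None:
    """One row per trajectory; per-trajectory metrics when env is given."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        header = ["index", "ex", "ey", "ez", "tx", "ty", "tz", "length_mm"]
        if env is not None:
            header += ["in_liver_mm", "in_tumor_mm"]
        writer.writerow(header)
        for i, t in enumerate(plan):
            row = [i, *t.entry, *t.target, t.length]
            if env is not None:
                _, in_liver, in_tumor = trajectory_lengths(t, env)
                row += [in_liver, in_tumor]
            writer.writerow([f"{x:.6g}" if isinstance(x, float) else x for x in row])
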