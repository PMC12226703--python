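"""Seedable synthetic abdominal phantoms for testing and benchmarking.

A phantom nests analytic meshes: a skin ellipsoid, a liver ellipsoid inside
it, a spherical-to-ellipsoidal tumor inside the liver (placed deep or
subcapsular), optional bar-shaped ribs in the skin-liver gap and tubular
vessels running through the liver.  Each phantom carries ground-truth
annotations (tumor volume, longest axis, a lower bound on the needle count)
so solver tests can assert against known answers.  All randomness comes from
the config seed; identical configs produce identical vertex arrays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .environment import Environment, build_environment
from .errors import InvalidEnvironmentError
from .mesh import SurfaceMesh
from .primitives import box, ellipsoid, icosphere, tube

__all__ = ["PhantomConfig", "Phantom", "make_phantom", "difficulty_suite"]


@dataclass
class PhantomConfig:
    """Geometry knobs for one synthetic abdomen (lengths in mm)."""

    skin_semi_axes: tuple = (130.0, 110.0, 100.0)
    liver_semi_axes: tuple = (70.0, 50.0, 45.0)
    liver_offset: tuple = (15.0, 10.0, 5.0)
    tumor_diameter: float = 10.0
    tumor_aspect: tuple = (1.0, 1.0, 1.0)  # semi-axis ratios (sphere = isotropic)
    tumor_position: str = "deep"  # "deep" | "subcapsular"
    n_ribs: int = 0
    rib_size: tuple = (120.0, 14.0, 8.0)
    vessel_radius: float = 0.0  # 0 disables the vessel
    vessel_clearance: float = 8.0  # distance from tumor surface to vessel axis
    margin_mm: float = 10.0
    spacing_mm: float = 2.0
    subdivisions: int = 3
    seed: int = 0
    name: str = "phantom"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomConfig":
        cfg = cls(**d)
        cfg.skin_semi_axes = tuple(cfg.skin_semi_axes)
        cfg.liver_semi_axes = tuple(cfg.liver_semi_axes)
        cfg.liver_offset = tuple(cfg.liver_offset)
        cfg.tumor_aspect = tuple(cfg.tumor_aspect)
        cfg.rib_size = tuple(cfg.rib_size)
        return cfg


@dataclass
class Phantom:
    """A built phantom: the planning environment plus ground truth."""

    config: PhantomConfig
    env: Environment
    meshes: dict  # name -> SurfaceMesh (for STL export)
    annotations: dict = field(default_factory=dict)


def _tumor_center(cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    liver_c = np.asarray(cfg.liver_offset, dtype=np.float64)
    semi = np.asarray(cfg.liver_semi_axes, dtype=np.float64)
    t_semi = 0.5 * cfg.tumor_diameter * np.asarray(cfg.tumor_aspect, dtype=np.float64)
    if cfg.tumor_position == "deep":
        jitter = rng.uniform(-0.15, 0.15, 3) * semi
        return liver_c + jitter
    if cfg.tumor_position == "subcapsular":
        # push toward the +z capsule, a couple of mm below the surface
        frac = 1.0 - (t_semi[2] + 4.0) / semi[2]
        lateral = rng.uniform(-0.2, 0.2, 2) * semi[:2] * 0.5
        return liver_c + np.array([lateral[0], lateral[1], frac * semi[2]])
    raise ValueError(f"unknown tumor_position {cfg.tumor_position!r}")


def make_phantom(config: PhantomConfig) -> Phantom:
    """Build meshes, validate nesting, assemble the planning environment."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    skin = ellipsoid(cfg.skin_semi_axes, subdivisions=cfg.subdivisions)
    liver = ellipsoid(
        cfg.liver_semi_axes, center=cfg.liver_offset, subdivisions=cfg.subdivisions
    )
    t_semi = 0.5 * cfg.tumor_diameter * np.asarray(cfg.tumor_aspect, dtype=np.float64)
    t_center = _tumor_center(cfg, rng)
    tumor = ellipsoid(t_semi, center=t_center, subdivisions=cfg.subdivisions)

    # nesting checks on exact ellipsoid algebra (meshes are inscribed)
    liver_c = np.asarray(cfg.liver_offset, dtype=np.float64)
    semi = np.asarray(cfg.liver_semi_axes, dtype=np.float64)
    rel = (tumor.vertices - liver_c) / semi
    if np.any(np.sum(rel**2, axis=1) >= 1.0):
        raise InvalidEnvironmentError("tumor is not inside the liver")
    rel_liver = liver.vertices / np.asarray(cfg.skin_semi_axes)
    if np.any(np.sum(rel_liver**2, axis=1) >= 1.0):
        raise InvalidEnvironmentError("liver is not inside the skin")

    meshes = {"skin": skin, "liver": liver, "tumor": tumor}
    critical, vessels = [], []
    if cfg.n_ribs > 0:
        # bar ribs in the skin-liver gap above the liver, spanning x
        z_top = liver_c[2] + semi[2]
        z_rib = z_top + 0.35 * (cfg.skin_semi_axes[2] - z_top)
        ys = np.linspace(-0.6, 0.6, cfg.n_ribs) * semi[1] + liver_c[1]
        for i, y in enumerate(ys):
            rib = box(cfg.rib_size, center=(liver_c[0], y, z_rib))
            critical.append(rib)
            meshes[f"rib_{i}"] = rib
    if cfg.vessel_radius > 0:
        # a vessel running cranio-caudally past the tumor at fixed clearance
        off = float(np.max(t_semi) + cfg.vessel_clearance)
        xs = t_center[0] + off
        zs = np.linspace(t_center[2] - 40.0, t_center[2] + 40.0, 9)
        sway = 4.0 * np.sin(np.linspace(0, np.pi, 9))
        path = np.column_stack([np.full(9, xs), t_center[1] + sway, zs])
        vessel = tube(path, cfg.vessel_radius, sections=12)
        vessels.append(vessel)
        meshes["vessel"] = vessel

    env = build_environment(
        skin,
        liver,
        tumor,
        critical=critical,
        vessels=vessels,
        margin=cfg.margin_mm,
        spacing=cfg.spacing_mm,
    )

    longest_axis = 2.0 * float(np.max(t_semi))
    radius = 10.0  # reference single-applicator ablation radius
    annotations = {
        "tumor_volume_mm3": tumor.volume(),
        "tumor_longest_axis_mm": longest_axis,
        "tumor_center": t_center.tolist(),
        "min_needles": max(1, math.ceil(longest_axis / radius)),
        "single_needle_solvable": float(np.max(t_semi)) + cfg.margin_mm <= radius,
    }
    return Phantom(config=cfg, env=env, meshes=meshes, annotations=annotations)


def difficulty_suite(seed: int = 0, n_per_tier: tuple = (7, 7, 6)) -> list[PhantomConfig]:
    """Graded phantom configs: small deep tumors (single-needle), mid-size
    multi-needle tumors, and hard subcapsular tumors near a vessel and ribs."""
    rng = np.random.default_rng(seed)
    configs: list[PhantomConfig] = []
    n_easy, n_mid, n_hard = n_per_tier
    for i in range(n_easy):
        configs.append(
            PhantomConfig(
                tumor_diameter=float(rng.uniform(8.0, 14.0)),
                tumor_position="deep",
                margin_mm=5.0,
                seed=int(rng.integers(2**31 - 1)),
                name=f"easy_{i}",
            )
        )
    for i in range(n_mid):
        aspect = np.array([1.0, rng.uniform(0.7, 1.0), rng.uniform(0.6, 0.9)])
        configs.append(
            PhantomConfig(
                tumor_diameter=float(rng.uniform(20.0, 40.0)),
                tumor_aspect=tuple(np.round(aspect, 3)),
                tumor_position="deep",
                margin_mm=5.0,
                seed=int(rng.integers(2**31 - 1)),
                name=f"mid_{i}",
            )
        )
    for i in range(n_hard):
        configs.append(
            PhantomConfig(
                tumor_diameter=float(rng.uniform(15.0, 30.0)),
                tumor_position="subcapsular",
                n_ribs=3,
                vessel_radius=3.0,
                vessel_clearance=float(rng.uniform(4.0, 7.0)),
                margin_mm=5.0,
                seed=int(rng.integers(2**31 - 1)),
                name=f"hard_{i}",
            )
        )
    return configs
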