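"""Planning environment: anatomy groups, entry surface, treatment volume.

The environment splits the anatomy into four groups — skin (entry space),
liver, tumor (target space) and critical structures (ribs, vessels, other
organs) — and derives two objects the optimizer works on:

* the *entry surface*: the part of the skin reachable by a 150 mm applicator,
  i.e. skin triangles entirely within ``max_reach`` of the tumor centroid;
* the *treatment volume*: a regular grid sampling of the tumor dilated by the
  safety margin, clipped to the liver, with vessel interiors excluded.

Dilation is implemented as an unsigned distance test against the tumor
surface (points inside the tumor count as distance 0), which is exact on the
grid and avoids offsetting the mesh itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .errors import InvalidEnvironmentError, PlanningInfeasibleError
from .mesh import IndexedMesh, SurfaceMesh

__all__ = [
    "TreatmentVolume",
    "Environment",
    "filter_entry_surface",
    "build_treatment_volume",
    "build_environment",
]

DEFAULT_MAX_REACH_MM = 150.0
DEFAULT_MARGIN_MM = 10.0
DEFAULT_SPACING_MM = 2.0


@dataclass
class TreatmentVolume:
    """Grid point sample of the margin-dilated, liver-clipped tumor."""

    points: np.ndarray  # (n, 3) mm
    spacing: float  # grid pitch, mm
    margin_mm: float

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if len(self.points) == 0:
            raise InvalidEnvironmentError("treatment volume is empty")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    @property
    def volume_mm3(self) -> float:
        return len(self.points) * self.spacing**3

    @property
    def principal_axis(self) -> np.ndarray:
        """Unit direction of the longest axis (largest second moment)."""
        centered = self.points - self.centroid
        if len(self.points) == 1:
            return np.array([0.0, 0.0, 1.0])
        cov = centered.T @ centered / len(centered)
        w, v = np.linalg.eigh(cov)
        axis = v[:, -1]
        return axis / np.linalg.norm(axis)

    @property
    def axis_length(self) -> float:
        """Extent of the point set along the principal axis, mm."""
        proj = self.points @ self.principal_axis
        return float(proj.max() - proj.min())

    @property
    def longest_chord(self) -> float:
        """Diameter of the point set (max pairwise distance), mm."""
        pts = self.points
        if len(pts) > 4:
            try:
                pts = pts[ConvexHull(pts).vertices]
            except QhullError:
                pass
        if len(pts) == 1:
            return self.spacing
        d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=2)
        return float(np.sqrt(d2.max()))


def _as_indexed(mesh) -> IndexedMesh:
    return mesh if isinstance(mesh, IndexedMesh) else IndexedMesh(mesh)


def filter_entry_surface(
    skin: SurfaceMesh,
    tumor_centroid,
    max_reach: float = DEFAULT_MAX_REACH_MM,
) -> SurfaceMesh:
    """Skin triangles whose every vertex is within ``max_reach`` of the tumor.

    Mirrors filtering the skin to the section reachable by the applicator.
    Raises :class:`PlanningInfeasibleError` if nothing remains.
    """
    if isinstance(skin, IndexedMesh):
        skin = skin.mesh
    centroid = np.asarray(tumor_centroid, dtype=np.float64)
    dist = np.linalg.norm(skin.vertices - centroid, axis=1)
    keep = np.all(dist[skin.faces] <= max_reach, axis=1)
    if not np.any(keep):
        raise PlanningInfeasibleError(
            f"no skin within {max_reach} mm of the tumor centroid"
        )
    return skin.submesh(keep)


def build_treatment_volume(
    tumor,
    liver,
    vessels=(),
    margin: float = DEFAULT_MARGIN_MM,
    spacing: float = DEFAULT_SPACING_MM,
) -> TreatmentVolume:
    """Sample the treatment volume on a regular grid.

    A grid point belongs to the treatment volume iff its unsigned distance to
    the tumor surface is at most ``margin`` (inside counts as 0), it lies
    inside the liver, and outside every vessel.  The grid is anchored at the
    tumor bounding-box minimum so volumes built at different margins share
    their points.
    """
    if margin < 0:
        raise ValueError("margin must be non-negative")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    tumor = _as_indexed(tumor)
    liver = _as_indexed(liver)
    vessels = [_as_indexed(v) for v in vessels]

    lo, hi = tumor.mesh.bounds()
    axes = []
    for k in range(3):
        i0 = int(np.floor((-margin) / spacing))
        i1 = int(np.ceil((hi[k] - lo[k] + margin) / spacing))
        axes.append(lo[k] + spacing * np.arange(i0, i1 + 1))
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)

    inside_tumor = tumor.contains_points(grid)
    near = inside_tumor.copy()
    shell = ~inside_tumor
    if np.any(shell):
        # strict: a grid point exactly on the surface counts as inside only
        # via the containment test, so margin=0 returns interior points only
        near[shell] = tumor.surface_distance(grid[shell]) < margin - 1e-9
    grid = grid[near]
    if len(grid):
        grid = grid[liver.contains_points(grid)]
    for v in vessels:
        if len(grid) == 0:
            break
        grid = grid[~v.contains_points(grid)]
    if len(grid) == 0:
        raise InvalidEnvironmentError(
            "treatment volume is empty (tumor outside liver or swallowed by vessels)"
        )
    return TreatmentVolume(points=grid, spacing=spacing, margin_mm=margin)


@dataclass
class Environment:
    """The four structure groups plus the derived planning spaces."""

    skin: IndexedMesh
    liver: IndexedMesh
    tumor: IndexedMesh
    critical: list  # IndexedMesh obstacles a needle must not cross
    vessels: list  # subset of critical excluded from the treatment volume
    entry_surface: IndexedMesh
    treatment: TreatmentVolume
    tumor_margin_mm: float = DEFAULT_MARGIN_MM

    _entry_area_cdf: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        tri = self.entry_surface.mesh.triangles
        areas = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
        )
        self._entry_area_cdf = np.cumsum(areas) / areas.sum()

    def sample_entry_points(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Uniform-by-area random points on the entry surface."""
        tri = self.entry_surface.mesh.triangles
        idx = np.searchsorted(self._entry_area_cdf, rng.random(n))
        r1, r2 = rng.random(n), rng.random(n)
        flip = r1 + r2 > 1
        r1[flip], r2[flip] = 1 - r1[flip], 1 - r2[flip]
        t = tri[idx]
        return t[:, 0] + r1[:, None] * (t[:, 1] - t[:, 0]) + r2[:, None] * (t[:, 2] - t[:, 0])

    def rebuild_treatment(self, margin: float, spacing: float | None = None) -> TreatmentVolume:
        """Treatment volume at another margin, same grid origin and spacing."""
        return build_treatment_volume(
            self.tumor,
            self.liver,
            self.vessels,
            margin=margin,
            spacing=spacing or self.treatment.spacing,
        )


def build_environment(
    skin: SurfaceMesh,
    liver: SurfaceMesh,
    tumor: SurfaceMesh,
    critical=(),
    vessels=(),
    margin: float = DEFAULT_MARGIN_MM,
    spacing: float = DEFAULT_SPACING_MM,
    max_reach: float = DEFAULT_MAX_REACH_MM,
) -> Environment:
    """Assemble an :class:`Environment` from raw structure meshes.

    ``vessels`` are automatically appended to the critical group (a needle
    may not cross them) and excluded from the treatment volume.
    """
    skin_i = _as_indexed(skin)
    liver_i = _as_indexed(liver)
    tumor_i = _as_indexed(tumor)
    if not (liver_i.watertight and tumor_i.watertight and skin_i.watertight):
        raise InvalidEnvironmentError("skin, liver and tumor meshes must be watertight")
    vessel_i = [_as_indexed(v) for v in vessels]
    critical_i = [_as_indexed(c) for c in critical] + vessel_i
    entry = _as_indexed(
        filter_entry_surface(skin_i.mesh, tumor_i.centroid(), max_reach)
    )
    tv = build_treatment_volume(tumor_i, liver_i, vessel_i, margin, spacing)
    return Environment(
        skin=skin_i,
        liver=liver_i,
        tumor=tumor_i,
        critical=critical_i,
        vessels=vessel_i,
        entry_surface=entry,
        treatment=tv,
        tumor_margin_mm=margin,
    )
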