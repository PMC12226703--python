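"""Triangulated surface meshes and geometric predicates.

All coordinates are millimetres in a common world frame.  Meshes are cleaned
on construction (duplicate vertices merged, degenerate faces dropped) and, when
watertight, oriented so that face normals point outward (positive enclosed
volume).  :class:`IndexedMesh` adds the precomputed per-triangle arrays and
nearest-neighbour structures used by the intersection, containment and
distance queries; its results are defined to agree with exhaustive
all-triangle testing.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "SurfaceMesh",
    "IndexedMesh",
    "load_mesh",
    "save_mesh",
]

# Geometric tolerance (mm) below which points/hits are considered coincident.
_TOL = 1e-9

# Fixed, "irrational" ray directions for parity containment tests.  A point is
# re-tested with the next direction whenever a hit lands suspiciously close to
# a triangle edge or vertex.
_RAY_DIRS = np.array(
    [
        [0.5773502691896258, 0.5773502691896257, 0.5773502691896259],
        [0.2672612419124244, 0.5345224838248488, 0.8017837257372732],
        [0.8111071056538127, 0.3244428422615251, -0.4866642633922876],
        [-0.4558423058385518, 0.5698028822981898, 0.6837634587578276],
        [0.1690308509457033, -0.5070925528371099, 0.8451542547285166],
    ]
)


def _merge_vertices(vertices: np.ndarray, faces: np.ndarray, decimals: int = 6):
    """Merge vertices that coincide after rounding to ``decimals`` (1e-6 mm)."""
    key = np.round(vertices, decimals)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    order = np.argsort(first)
    rank = np.empty_like(order)
    rank[order] = np.arange(order.size)
    new_vertices = vertices[np.sort(first)]
    new_faces = rank[inverse][faces]
    return new_vertices, new_faces


def _drop_degenerate(vertices: np.ndarray, faces: np.ndarray, min_area: float = 1e-12):
    if faces.size == 0:
        return faces
    distinct = (
        (faces[:, 0] != faces[:, 1])
        & (faces[:, 1] != faces[:, 2])
        & (faces[:, 0] != faces[:, 2])
    )
    faces = faces[distinct]
    if faces.size == 0:
        return faces
    tri = vertices[faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    area2 = np.linalg.norm(cross, axis=1)
    return faces[area2 > 2.0 * min_area]


def _orient_consistently(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Flip face windings so adjacent faces agree, then make volume positive.

    Works per connected component; components are signed independently so
    nested shells each end up outward-facing.
    """
    m = len(faces)
    if m == 0:
        return faces
    # undirected edge -> incident faces
    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    face_of_edge = np.tile(np.arange(m), 3)
    und = np.sort(edges, axis=1)
    edge_faces: dict[tuple[int, int], list[int]] = {}
    for (a, b), fidx in zip(und, face_of_edge):
        edge_faces.setdefault((int(a), int(b)), []).append(int(fidx))

    faces = faces.copy()
    visited = np.zeros(m, dtype=bool)
    directed = {}  # face -> set of directed edges, rebuilt lazily

    def directed_edges(f):
        a, b, c = faces[f]
        return ((a, b), (b, c), (c, a))

    import collections

    for seed in range(m):
        if visited[seed]:
            continue
        comp = [seed]
        visited[seed] = True
        queue = collections.deque([seed])
        while queue:
            f = queue.popleft()
            for a, b in directed_edges(f):
                key = (min(a, b), max(a, b))
                for g in edge_faces.get(key, ()):
                    if g == f or visited[g]:
                        continue
                    # neighbour is consistent iff it holds the reversed edge
                    if (a, b) in directed_edges(g):
                        faces[g] = faces[g][::-1]
                    visited[g] = True
                    comp.append(g)
                    queue.append(g)
        comp = np.asarray(comp)
        tri = vertices[faces[comp]]
        vol6 = np.einsum(
            "ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])
        ).sum()
        if vol6 < 0:
            faces[comp] = faces[comp][:, ::-1]
    return faces


@dataclass
class SurfaceMesh:
    """A cleaned triangulated surface in millimetres."""

    vertices: np.ndarray
    faces: np.ndarray
    watertight: bool = field(default=False)

    def __init__(self, vertices, faces, process: bool = True):
        vertices = np.asarray(vertices, dtype=np.float64).reshape(-1, 3)
        faces = np.asarray(faces, dtype=np.int64).reshape(-1, 3)
        if len(vertices) == 0 or len(faces) == 0:
            raise ValueError("empty mesh")
        if faces.min() < 0 or faces.max() >= len(vertices):
            raise ValueError("face indices out of range")
        if process:
            vertices, faces = _merge_vertices(vertices, faces)
            faces = _drop_degenerate(vertices, faces)
            if len(faces) == 0:
                raise ValueError("mesh degenerate after cleanup")
        self.vertices = vertices
        self.faces = faces
        self.watertight = self._check_watertight()
        if process and self.watertight:
            self.faces = _orient_consistently(self.vertices, self.faces)

    def _check_watertight(self) -> bool:
        edges = np.sort(
            np.concatenate(
                [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
            ),
            axis=1,
        )
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    # -- derived quantities -------------------------------------------------
    @property
    def triangles(self) -> np.ndarray:
        return self.vertices[self.faces]

    @property
    def face_normals(self) -> np.ndarray:
        tri = self.triangles
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        return n / np.where(norm == 0, 1.0, norm)

    @property
    def area(self) -> float:
        tri = self.triangles
        return 0.5 * float(
            np.linalg.norm(
                np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
            ).sum()
        )

    def volume(self) -> float:
        """Enclosed volume via the divergence theorem (mm^3, outward winding)."""
        tri = self.triangles
        return float(
            np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0
        )

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return self.vertices.min(axis=0), self.vertices.max(axis=0)

    def submesh(self, face_mask: np.ndarray) -> "SurfaceMesh":
        faces = self.faces[face_mask]
        if len(faces) == 0:
            raise ValueError("submesh has no faces")
        used = np.unique(faces)
        remap = np.full(len(self.vertices), -1, dtype=np.int64)
        remap[used] = np.arange(used.size)
        return SurfaceMesh(self.vertices[used], remap[faces], process=False)

    # -- I/O ----------------------------------------------------------------
    def save(self, path) -> None:
        save_mesh(self, path)


# ---------------------------------------------------------------------------
# file I/O (STL binary/ASCII, OBJ) — no mesh library is assumed installed
# ---------------------------------------------------------------------------

def _read_stl(path: Path):
    raw = path.read_bytes()
    if len(raw) < 84:
        is_ascii = raw.lstrip().startswith(b"solid")
    else:
        (n_tri,) = struct.unpack("<I", raw[80:84])
        is_ascii = raw.lstrip().startswith(b"solid") and len(raw) != 84 + 50 * n_tri
    if is_ascii:
        coords = []
        for line in raw.decode("ascii", errors="replace").splitlines():
            parts = line.split()
            if parts and parts[0] == "vertex":
                coords.append([float(x) for x in parts[1:4]])
        tri = np.asarray(coords, dtype=np.float64)
    else:
        if len(raw) < 84:
            raise ValueError(f"truncated STL file: {path}")
        (n_tri,) = struct.unpack("<I", raw[80:84])
        body = np.frombuffer(raw[84 : 84 + 50 * n_tri], dtype=np.uint8)
        if body.size != 50 * n_tri:
            raise ValueError(f"truncated STL file: {path}")
        rec = body.reshape(n_tri, 50)
        tri = (
            rec[:, 12:48]
            .copy()
            .view("<f4")
            .reshape(n_tri, 3, 3)
            .astype(np.float64)
            .reshape(-1, 3)
        )
    if tri.size == 0 or tri.shape[0] % 3:
        raise ValueError(f"empty or malformed STL file: {path}")
    faces = np.arange(tri.shape[0]).reshape(-1, 3)
    return tri, faces


def _write_stl(mesh: SurfaceMesh, path: Path) -> None:
    tri = mesh.triangles.astype("<f4")
    normals = mesh.face_normals.astype("<f4")
    n = len(tri)
    rec = np.zeros(n, dtype=[("n", "<f4", 3), ("v", "<f4", (3, 3)), ("attr", "<u2")])
    rec["n"] = normals
    rec["v"] = tri
    with open(path, "wb") as fh:
        fh.write(b"\x00" * 80)
        fh.write(struct.pack("<I", n))
        fh.write(rec.tobytes())


def _read_obj(path: Path):
    vertices, faces = [], []
    for line in path.read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "v":
            vertices.append([float(x) for x in parts[1:4]])
        elif parts[0] == "f":
            idx = [int(p.split("/")[0]) for p in parts[1:]]
            idx = [i - 1 if i > 0 else len(vertices) + i for i in idx]
            for k in range(1, len(idx) - 1):  # fan-triangulate polygons
                faces.append([idx[0], idx[k], idx[k + 1]])
    if not vertices or not faces:
        raise ValueError(f"empty or malformed OBJ file: {path}")
    return np.asarray(vertices, dtype=np.float64), np.asarray(faces, dtype=np.int64)


def _write_obj(mesh: SurfaceMesh, path: Path) -> None:
    with open(path, "w") as fh:
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for f in mesh.faces + 1:
            fh.write(f"f {f[0]} {f[1]} {f[2]}\n")


def load_mesh(path) -> SurfaceMesh:
    """Load and clean an STL (binary or ASCII) or OBJ mesh."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == ".stl":
        vertices, faces = _read_stl(path)
    elif suffix == ".obj":
        vertices, faces = _read_obj(path)
    else:
        raise ValueError(f"unsupported mesh format: {suffix!r} (use .stl or .obj)")
    return SurfaceMesh(vertices, faces)


def save_mesh(mesh: SurfaceMesh, path) -> None:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".stl":
        _write_stl(mesh, path)
    elif suffix == ".obj":
        _write_obj(mesh, path)
    else:
        raise ValueError(f"unsupported mesh format: {suffix!r} (use .stl or .obj)")


# ---------------------------------------------------------------------------
# indexed queries
# ---------------------------------------------------------------------------

class IndexedMesh:
    """A :class:`SurfaceMesh` with precomputed triangle arrays and KD-trees.

    Queries (segment intersection, containment, surface distance, closest
    point) are exact: acceleration structures only prune triangles whose
    bounding volumes cannot contain the answer, so results match brute-force
    all-triangle testing.
    """

    def __init__(self, mesh: SurfaceMesh):
        self.mesh = mesh
        tri = mesh.triangles
        self.v0 = np.ascontiguousarray(tri[:, 0])
        self.e1 = np.ascontiguousarray(tri[:, 1] - tri[:, 0])
        self.e2 = np.ascontiguousarray(tri[:, 2] - tri[:, 0])
        self.normals = mesh.face_normals
        self.tri_lo = tri.min(axis=1)
        self.tri_hi = tri.max(axis=1)
        self.lo = self.tri_lo.min(axis=0)
        self.hi = self.tri_hi.max(axis=0)
        self.centroids = tri.mean(axis=1)
        self._centroid_tree = cKDTree(self.centroids)
        # max distance from a centroid to its triangle's vertices
        self.tri_radius = np.linalg.norm(
            tri - self.centroids[:, None, :], axis=2
        ).max(axis=1)
        self.max_tri_radius = float(self.tri_radius.max())

    # convenience passthroughs
    @property
    def watertight(self) -> bool:
        return self.mesh.watertight

    def volume(self) -> float:
        return self.mesh.volume()

    def centroid(self) -> np.ndarray:
        return self.mesh.centroid()

    # -- segment intersection ----------------------------------------------
    def segment_intersections(self, p0, p1):
        """Ordered intersections of segment ``p0 -> p1`` with the surface.

        Returns ``(points (k,3), normals (k,3), ts (k,))`` sorted by the arc
        parameter ``t`` in ``[0, 1]``.  Normals are the (outward, for
        watertight meshes) unit normals of the hit triangles.  Hits closer
        than 1e-9 in ``t`` (a segment piercing a shared edge) are merged.
        """
        p0 = np.asarray(p0, dtype=np.float64)
        p1 = np.asarray(p1, dtype=np.float64)
        d = p1 - p0
        if np.linalg.norm(d) <= _TOL:
            raise ValueError("degenerate segment: p0 == p1")
        # global and per-triangle AABB pruning
        seg_lo = np.minimum(p0, p1) - _TOL
        seg_hi = np.maximum(p0, p1) + _TOL
        if np.any(seg_hi < self.lo) or np.any(seg_lo > self.hi):
            empty = np.empty((0, 3))
            return empty, empty.copy(), np.empty(0)
        cand = np.flatnonzero(
            np.all(self.tri_lo <= seg_hi, axis=1) & np.all(self.tri_hi >= seg_lo, axis=1)
        )
        if cand.size == 0:
            empty = np.empty((0, 3))
            return empty, empty.copy(), np.empty(0)
        v0, e1, e2 = self.v0[cand], self.e1[cand], self.e2[cand]
        pvec = np.cross(d, e2)
        det = np.einsum("ij,ij->i", e1, pvec)
        ok = np.abs(det) > 1e-12
        inv = np.where(ok, det, 1.0)
        tvec = p0 - v0
        u = np.einsum("ij,ij->i", tvec, pvec) / inv
        qvec = np.cross(tvec, e1)
        v = np.einsum("j,ij->i", d, qvec) / inv
        t = np.einsum("ij,ij->i", e2, qvec) / inv
        bt = 1e-10
        hit = ok & (u >= -bt) & (v >= -bt) & (u + v <= 1 + bt) & (t >= -bt) & (t <= 1 + bt)
        idx = cand[hit]
        ts = np.clip(t[hit], 0.0, 1.0)
        order = np.argsort(ts, kind="stable")
        idx, ts = idx[order], ts[order]
        # merge duplicate hits on shared edges/vertices
        if ts.size > 1:
            keep = np.ones(ts.size, dtype=bool)
            keep[1:] = np.diff(ts) > 1e-9
            idx, ts = idx[keep], ts[keep]
        points = p0 + ts[:, None] * d
        return points, self.normals[idx], ts

    # -- containment --------------------------------------------------------
    def contains_points(self, points: np.ndarray) -> np.ndarray:
        """Parity ray-cast containment for an array of points.

        Requires a watertight mesh.  Points whose ray grazes an edge or
        vertex are re-tested with alternate ray directions.
        """
        if not self.watertight:
            raise ValueError("containment requires a watertight mesh")
        points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
        result = np.zeros(len(points), dtype=bool)
        in_box = np.all(points >= self.lo - _TOL, axis=1) & np.all(
            points <= self.hi + _TOL, axis=1
        )
        todo = np.flatnonzero(in_box)
        for d in _RAY_DIRS:
            if todo.size == 0:
                break
            parity, ambiguous = self._raycast_parity(points[todo], d)
            settled = ~ambiguous
            result[todo[settled]] = parity[settled]
            todo = todo[ambiguous]
        if todo.size:  # pathological points: accept the last parity estimate
            result[todo] = parity[ambiguous]
        return result

    def contains_point(self, p) -> bool:
        return bool(self.contains_points(np.asarray(p, dtype=np.float64)[None, :])[0])

    def _raycast_parity(self, points: np.ndarray, d: np.ndarray, chunk: int = 128):
        m = len(self.v0)
        pvec = np.cross(d, self.e2)
        det = np.einsum("ij,ij->i", self.e1, pvec)
        ok = np.abs(det) > 1e-12
        inv = np.where(ok, det, 1.0)
        n = len(points)
        counts = np.zeros(n, dtype=np.int64)
        ambiguous = np.zeros(n, dtype=bool)
        edge_tol = 1e-9
        for s in range(0, n, chunk):
            P = points[s : s + chunk]
            tvec = P[:, None, :] - self.v0[None, :, :]  # (c, m, 3)
            u = np.einsum("cmj,mj->cm", tvec, pvec) / inv
            qvec = np.cross(tvec, self.e1[None, :, :])
            v = np.einsum("j,cmj->cm", d, qvec) / inv
            t = np.einsum("mj,cmj->cm", self.e2, qvec) / inv
            hit = ok & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > 0)
            counts[s : s + chunk] = hit.sum(axis=1)
            near_edge = (
                (np.abs(u) < edge_tol)
                | (np.abs(v) < edge_tol)
                | (np.abs(1 - u - v) < edge_tol)
                | (np.abs(t) < edge_tol)
            )
            ambiguous[s : s + chunk] = np.any(
                (ok & (u >= -edge_tol) & (v >= -edge_tol) & (u + v <= 1 + edge_tol) & (t > 0))
                & near_edge,
                axis=1,
            )
        return (counts % 2).astype(bool), ambiguous

    # -- distance / closest point -------------------------------------------
    def surface_distance(self, points: np.ndarray) -> np.ndarray:
        """Unsigned Euclidean distance from each point to the surface."""
        d, _ = self._closest(points)
        return d

    def closest_points(self, points: np.ndarray) -> np.ndarray:
        """Closest point on the surface for each query point."""
        _, cp = self._closest(points)
        return cp

    def _closest(self, points: np.ndarray):
        points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
        m = len(self.v0)
        k = min(32, m)
        dc, cand = self._centroid_tree.query(points, k=k)
        if k == 1:
            dc, cand = dc[:, None], cand[:, None]
        flat_p = np.repeat(points, k, axis=0)
        flat_c = cand.ravel()
        d2, cp = _point_triangle_dist2(
            flat_p, self.v0[flat_c], self.e1[flat_c], self.e2[flat_c]
        )
        d2 = d2.reshape(-1, k)
        cp = cp.reshape(-1, k, 3)
        best = np.argmin(d2, axis=1)
        rows = np.arange(len(points))
        dist = np.sqrt(d2[rows, best])
        cpts = cp[rows, best]
        if k < m:
            # guarantee: true nearest triangle has centroid within
            # dist + max_tri_radius; if the k-th centroid is closer than that
            # bound, widen to a brute-force check for those points.
            unsure = np.flatnonzero(dc[:, -1] < dist + self.max_tri_radius)
            chunk = max(1, 200_000 // m)
            for s in range(0, unsure.size, chunk):
                sel = unsure[s : s + chunk]
                P = np.repeat(points[sel], m, axis=0)
                d2_all, cp_all = _point_triangle_dist2(
                    P,
                    np.tile(self.v0, (len(sel), 1)),
                    np.tile(self.e1, (len(sel), 1)),
                    np.tile(self.e2, (len(sel), 1)),
                )
                d2_all = d2_all.reshape(len(sel), m)
                j = np.argmin(d2_all, axis=1)
                r = np.arange(len(sel))
                dist[sel] = np.sqrt(d2_all[r, j])
                cpts[sel] = cp_all.reshape(len(sel), m, 3)[r, j]
        return dist, cpts


def _point_triangle_dist2(p, v0, e1, e2):
    """Squared distance and closest point, pairwise p[i] vs triangle i.

    The closest point is the in-plane barycentric projection when it falls
    inside the triangle, otherwise the best of the three edge projections.
    """
    n = np.cross(e1, e2)
    nn = np.einsum("ij,ij->i", n, n)
    nn = np.where(nn == 0, 1.0, nn)
    w = p - v0
    # plane projection barycentrics via normal equations
    a = np.einsum("ij,ij->i", e1, e1)
    b = np.einsum("ij,ij->i", e1, e2)
    c = np.einsum("ij,ij->i", e2, e2)
    d1 = np.einsum("ij,ij->i", w, e1)
    d2 = np.einsum("ij,ij->i", w, e2)
    det = a * c - b * b
    det_safe = np.where(np.abs(det) < 1e-30, 1.0, det)
    s = (c * d1 - b * d2) / det_safe
    t = (a * d2 - b * d1) / det_safe
    inside = (s >= 0) & (t >= 0) & (s + t <= 1) & (np.abs(det) >= 1e-30)
    proj = v0 + s[:, None] * e1 + t[:, None] * e2

    def edge_closest(base, edge):
        ee = np.einsum("ij,ij->i", edge, edge)
        ee = np.where(ee == 0, 1.0, ee)
        u = np.clip(np.einsum("ij,ij->i", p - base, edge) / ee, 0.0, 1.0)
        return base + u[:, None] * edge

    c0 = edge_closest(v0, e1)
    c1 = edge_closest(v0, e2)
    c2 = edge_closest(v0 + e1, e2 - e1)
    cands = np.stack([c0, c1, c2], axis=1)
    d2s = np.einsum("ikj,ikj->ik", p[:, None, :] - cands, p[:, None, :] - cands)
    best = np.argmin(d2s, axis=1)
    rows = np.arange(len(p))
    closest = np.where(inside[:, None], proj, cands[rows, best])
    diff = p - closest
    return np.einsum("ij,ij->i", diff, diff), closest
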