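"""Analytic watertight primitives: icospheres, ellipsoids, boxes, tubes.

These back the synthetic phantoms and the geometry tests; resolution is
controllable so tests can trade accuracy for speed.
"""

from __future__ import annotations

import numpy as np

from .mesh import SurfaceMesh

__all__ = ["icosphere", "ellipsoid", "box", "tube", "transform"]


def _icosahedron():
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    v = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=np.float64,
    )
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    f = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    return v, f


def icosphere(radius: float = 1.0, subdivisions: int = 3, center=(0.0, 0.0, 0.0)) -> SurfaceMesh:
    """Unit icosahedron subdivided ``subdivisions`` times, projected to a sphere."""
    v, f = _icosahedron()
    for _ in range(subdivisions):
        cache: dict[tuple[int, int], int] = {}
        verts = list(v)
        new_faces = []

        def midpoint(i, j):
            key = (min(i, j), max(i, j))
            if key not in cache:
                m = verts[i] + verts[j]
                m /= np.linalg.norm(m)
                cache[key] = len(verts)
                verts.append(m)
            return cache[key]

        for a, b, c in f:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        v = np.asarray(verts)
        f = np.asarray(new_faces, dtype=np.int64)
    return SurfaceMesh(v * radius + np.asarray(center, dtype=np.float64), f)


def ellipsoid(semi_axes, center=(0.0, 0.0, 0.0), subdivisions: int = 3,
              rotation: np.ndarray | None = None) -> SurfaceMesh:
    """Axis-aligned (or rotated) ellipsoid from a scaled icosphere."""
    sphere = icosphere(1.0, subdivisions)
    v = sphere.vertices * np.asarray(semi_axes, dtype=np.float64)
    if rotation is not None:
        v = v @ np.asarray(rotation, dtype=np.float64).T
    return SurfaceMesh(v + np.asarray(center, dtype=np.float64), sphere.faces)


def box(extents, center=(0.0, 0.0, 0.0), rotation: np.ndarray | None = None) -> SurfaceMesh:
    """Axis-aligned (or rotated) rectangular box with given full extents."""
    e = np.asarray(extents, dtype=np.float64) / 2.0
    corner = np.array(
        [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)],
        dtype=np.float64,
    )
    v = corner * e
    # 12 triangles, outward winding
    f = np.array(
        [
            [0, 1, 3], [0, 3, 2],  # -x
            [4, 6, 7], [4, 7, 5],  # +x
            [0, 4, 5], [0, 5, 1],  # -y
            [2, 3, 7], [2, 7, 6],  # +y
            [0, 2, 6], [0, 6, 4],  # -z
            [1, 5, 7], [1, 7, 3],  # +z
        ],
        dtype=np.int64,
    )
    if rotation is not None:
        v = v @ np.asarray(rotation, dtype=np.float64).T
    return SurfaceMesh(v + np.asarray(center, dtype=np.float64), f)


def tube(path: np.ndarray, radius: float, sections: int = 16) -> SurfaceMesh:
    """Watertight tube of constant ``radius`` swept along a 3D polyline.

    Ring frames are propagated along the path (parallel transport) and the
    ends are closed with fans; self-intersecting paths are not checked.
    """
    path = np.asarray(path, dtype=np.float64).reshape(-1, 3)
    if len(path) < 2:
        raise ValueError("tube path needs at least 2 points")
    tangents = np.gradient(path, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    # initial frame
    t0 = tangents[0]
    ref = np.array([0.0, 0.0, 1.0]) if abs(t0[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    u = np.cross(t0, ref)
    u /= np.linalg.norm(u)
    theta = np.linspace(0, 2 * np.pi, sections, endpoint=False)
    rings = []
    for i, (p, t) in enumerate(zip(path, tangents)):
        if i > 0:  # parallel-transport u across the tangent change
            u = u - np.dot(u, t) * t
            u /= np.linalg.norm(u)
        w = np.cross(t, u)
        ring = p + radius * (np.outer(np.cos(theta), u) + np.outer(np.sin(theta), w))
        rings.append(ring)
    v = np.concatenate(rings)
    faces = []
    for i in range(len(path) - 1):
        base0, base1 = i * sections, (i + 1) * sections
        for j in range(sections):
            jn = (j + 1) % sections
            faces.append([base0 + j, base1 + j, base1 + jn])
            faces.append([base0 + j, base1 + jn, base0 + jn])
    # end caps
    c0, c1 = len(v), len(v) + 1
    v = np.concatenate([v, path[[0]], path[[-1]]])
    last = (len(path) - 1) * sections
    for j in range(sections):
        jn = (j + 1) % sections
        faces.append([c0, jn, j])
        faces.append([c1, last + j, last + jn])
    return SurfaceMesh(v, np.asarray(faces, dtype=np.int64))


def transform(mesh: SurfaceMesh, rotation: np.ndarray | None = None, translation=None) -> SurfaceMesh:
    v = mesh.vertices
    if rotation is not None:
        v = v @ np.asarray(rotation, dtype=np.float64).T
    if translation is not None:
        v = v + np.asarray(translation, dtype=np.float64)
    return SurfaceMesh(v, mesh.faces, process=False)
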