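"""Binary label masks -> smoothed surface meshes.

Segmentation masks (e.g. NIfTI exports) are converted with marching cubes at
the 0.5 iso-level followed by Taubin smoothing, which removes voxel
staircasing while keeping the enclosed volume close to the voxel-count
volume (the smoothing contract is volume preservation within ~10%).
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from skimage import measure

from .mesh import SurfaceMesh

__all__ = ["mask_to_mesh", "load_nifti_mask", "taubin_smooth"]


def taubin_smooth(
    vertices: np.ndarray,
    faces: np.ndarray,
    iterations: int = 10,
    lam: float = 0.5,
    mu: float = -0.53,
) -> np.ndarray:
    """Taubin lambda/mu smoothing (shrink step followed by inflate step)."""
    n = len(vertices)
    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    und = np.unique(np.sort(edges, axis=1), axis=0)
    rows = np.concatenate([und[:, 0], und[:, 1]])
    cols = np.concatenate([und[:, 1], und[:, 0]])
    adj = sparse.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    ).tocsr()
    deg = np.asarray(adj.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    inv_deg = sparse.diags(1.0 / deg)
    lap = inv_deg @ adj  # row-stochastic neighbour average
    v = vertices.copy()
    for _ in range(iterations):
        v += lam * (lap @ v - v)
        v += mu * (lap @ v - v)
    return v


def mask_to_mesh(
    mask: np.ndarray,
    spacing=(1.0, 1.0, 1.0),
    origin=(0.0, 0.0, 0.0),
    smooth_iterations: int = 10,
) -> SurfaceMesh:
    """Extract a smoothed watertight mesh from a binary 3D mask.

    ``spacing`` is the voxel pitch in mm per axis and ``origin`` the world
    position of voxel (0,0,0); voxel centers sit at
    ``origin + index * spacing``.
    """
    mask = np.asarray(mask)
    if mask.ndim != 3:
        raise ValueError("mask must be a 3D array")
    fg = mask > 0
    if not fg.any():
        raise ValueError("mask has no foreground voxels")
    padded = np.pad(fg.astype(np.float64), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5)
    verts = (verts - 1.0) * np.asarray(spacing, dtype=np.float64) + np.asarray(
        origin, dtype=np.float64
    )
    if smooth_iterations > 0 and len(verts) > 8:
        verts = taubin_smooth(verts, faces, iterations=smooth_iterations)
    return SurfaceMesh(verts, faces)


def load_nifti_mask(path, label: int | None = None):
    """Read a NIfTI label volume; returns ``(mask, spacing, origin)``.

    ``label`` selects one label value; by default any nonzero voxel is
    foreground.  Only the scaling/translation part of the affine is used
    (axis-aligned volumes); oblique affines raise.
    """
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    affine = img.affine
    rot = affine[:3, :3]
    if not np.allclose(rot - np.diag(np.diag(rot)), 0.0, atol=1e-6):
        raise ValueError("oblique NIfTI affines are not supported; resample first")
    mask = (data == label) if label is not None else (data > 0)
    spacing = np.diag(rot)
    origin = affine[:3, 3]
    # normalize negative spacings so voxel index increases with world coord
    for k in range(3):
        if spacing[k] < 0:
            mask = np.flip(mask, axis=k)
            origin[k] = origin[k] + spacing[k] * (mask.shape[k] - 1)
            spacing[k] = -spacing[k]
    return mask.astype(bool), spacing, origin
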