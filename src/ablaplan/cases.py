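"""Load segmentation cases (per-structure meshes or masks) into environments.

A case is a directory of structure files plus a manifest mapping structure
names to the four planning groups (skin, liver, tumor, critical — with
vessels as the tagged subgroup excluded from the treatment volume).  Both
surface meshes (STL/OBJ) and binary masks (NIfTI) are accepted; masks go
through marching cubes + smoothing first, so mesh- and mask-based cases run
the identical pipeline.  Datasets shipped as one file per organ (e.g. the
3D-IRCADb-01 layout) are described by such a manifest.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .environment import Environment, build_environment
from .errors import InvalidEnvironmentError
from .masks import load_nifti_mask, mask_to_mesh
from .mesh import SurfaceMesh, load_mesh

__all__ = ["load_structure", "load_segmentation_case"]


def load_structure(path) -> SurfaceMesh:
    """Load one structure file, converting masks to meshes when needed."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith(".nii") or name.endswith(".nii.gz"):
        mask, spacing, origin = load_nifti_mask(path)
        return mask_to_mesh(mask, spacing=spacing, origin=origin)
    return load_mesh(path)


def load_segmentation_case(
    case_dir,
    manifest: dict | str | Path,
    margin: float = 10.0,
    spacing: float = 2.0,
    max_reach: float = 150.0,
) -> Environment:
    """Build an :class:`Environment` from a case directory and manifest.

    ``manifest`` is a mapping (or YAML file) with keys ``skin``, ``liver``,
    ``tumor`` (file names relative to ``case_dir``), optional ``critical``
    (mapping name -> file) and optional ``vessels`` (mapping name -> file).
    Cases without a tumor are rejected — there is nothing to plan.
    """
    case_dir = Path(case_dir)
    if not isinstance(manifest, dict):
        manifest = yaml.safe_load(Path(manifest).read_text())
    for required in ("skin", "liver", "tumor"):
        if required not in manifest:
            raise InvalidEnvironmentError(
                f"case manifest is missing the required structure {required!r}"
            )
    def resolve(rel):
        p = case_dir / rel
        if not p.exists():
            raise FileNotFoundError(p)
        return p

    skin = load_structure(resolve(manifest["skin"]))
    liver = load_structure(resolve(manifest["liver"]))
    tumor = load_structure(resolve(manifest["tumor"]))
    critical = [
        load_structure(resolve(p)) for p in dict(manifest.get("critical", {})).values()
    ]
    vessels = [
        load_structure(resolve(p)) for p in dict(manifest.get("vessels", {})).values()
    ]
    return build_environment(
        skin,
        liver,
        tumor,
        critical=critical,
        vessels=vessels,
        margin=manifest.get("margin_mm", margin),
        spacing=manifest.get("spacing_mm", spacing),
        max_reach=manifest.get("max_reach_mm", max_reach),
    )
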