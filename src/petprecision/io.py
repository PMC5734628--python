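"""NIfTI-1 and JSON interchange for images, scenes and provenance.

Images are written RAS axis-aligned with mm voxel sizes in the affine, so
the metrics module can run on real quantitative PET volumes exported as
NIfTI (with a user-supplied background value or mask where the simulation
geometry is unavailable).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .grids import ActivityImage, GridSpec

__all__ = ["write_nifti", "read_nifti", "write_scene", "read_scene"]


def write_nifti(image: ActivityImage, path, *, sidecar: bool = True) -> Path:
    """Write an activity image as NIfTI-1 plus a JSON provenance sidecar."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(image.values, dtype=np.float32), image.grid.affine())
    img.header.set_xyzt_units(xyz="mm")
    nib.save(img, str(path))
    if sidecar:
        side = path.with_suffix(path.suffix + ".json")
        side.write_text(json.dumps({"provenance": image.provenance}, indent=2, default=str))
    return path


def read_nifti(path) -> ActivityImage:
    """Load an axis-aligned NIfTI-1 volume as an :class:`ActivityImage`.

    The affine must be diagonal (no rotation/shear); the provenance sidecar
    is restored when present.
    """
    path = Path(path)
    img = nib.load(str(path))
    aff = img.affine
    if not np.allclose(aff[:3, :3], np.diag(np.diag(aff[:3, :3])), atol=1e-6):
        raise ValueError("only axis-aligned (diagonal-affine) volumes are supported")
    voxel = np.diag(aff[:3, :3])
    if np.any(voxel <= 0):
        raise ValueError("negative or zero voxel sizes in affine; reorient to RAS first")
    grid = GridSpec(tuple(voxel), tuple(img.shape[:3]), tuple(aff[:3, 3]))
    provenance = []
    side = path.with_suffix(path.suffix + ".json")
    if side.exists():
        provenance = json.loads(side.read_text()).get("provenance", [])
    return ActivityImage(np.asarray(img.dataobj, dtype=np.float64), grid, provenance)


def write_scene(scene, path) -> Path:
    path = Path(path)
    path.write_text(scene.to_json())
    return path


def read_scene(path):
    from .phantoms import Scene

    return Scene.from_json(Path(path).read_text())
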