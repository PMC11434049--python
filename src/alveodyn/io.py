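"""Reading and writing label volumes, grayscale stacks, meshes and tables.

Volumes travel as multi-page TIFF (uint16 labels or float32 grayscale)
with a JSON sidecar carrying spacing/state/condition metadata, or as
NIfTI (spacing in the affine).  Meshes are written as binary PLY;
morphometry and ground truth as CSV with a JSON sidecar echoing the
generating spec.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .labels import LabeledVolume
from .morphometry import SurfaceMesh

__all__ = [
    "write_volume",
    "read_volume",
    "write_image",
    "read_image",
    "write_mesh",
    "read_mesh",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_volume(path: str | Path, volume: LabeledVolume) -> None:
    """Write a label volume as uint16 TIFF stack or NIfTI, plus metadata."""
    path = Path(path)
    meta = {
        "spacing_um": list(volume.spacing),
        "origin_um": list(volume.origin),
        "state": volume.state,
        "condition": volume.condition,
    }
    if path.suffix in (".tif", ".tiff"):
        if volume.voxels.max() > np.iinfo(np.uint16).max:
            raise ValueError("too many labels for uint16 TIFF")
        tifffile.imwrite(path, volume.voxels.astype(np.uint16),
                         photometric='minisblack')
        _sidecar(path).write_text(json.dumps(meta, indent=2))
    elif path.name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        dz, dy, dx = volume.spacing
        affine = np.diag([dx, dy, dz, 1.0])
        # NIfTI is (x, y, z); our arrays are (z, y, x)
        img = nib.Nifti1Image(
            volume.voxels.transpose(2, 1, 0).astype(np.int32), affine
        )
        img.header.set_xyzt_units("micron")
        nib.save(img, path)
        _sidecar(path).write_text(json.dumps(meta, indent=2))
    else:
        raise ValueError(f"unsupported volume format: {path.suffix}")


def read_volume(path: str | Path) -> LabeledVolume:
    path = Path(path)
    meta = {}
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
    if path.suffix in (".tif", ".tiff"):
        voxels = np.asarray(tifffile.imread(path)).astype(np.int32)
    elif path.name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(path)
        voxels = np.asarray(img.dataobj).transpose(2, 1, 0).astype(np.int32)
        if "spacing_um" not in meta:
            zooms = img.header.get_zooms()[:3]
            meta["spacing_um"] = [zooms[2], zooms[1], zooms[0]]
    else:
        raise ValueError(f"unsupported volume format: {path.suffix}")
    return LabeledVolume(
        voxels,
        tuple(meta.get("spacing_um", (1.0, 1.0, 1.0))),
        state=meta.get("state", "expiration"),
        condition=meta.get("condition", {}),
        origin=tuple(meta.get("origin_um", (0.0, 0.0, 0.0))),
    )


def write_image(path: str | Path, image: np.ndarray,
                spacing: tuple[float, float, float] | None = None) -> None:
    """Write a grayscale stack as float32 TIFF (spacing in a sidecar)."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32),
                     photometric='minisblack')
    if spacing is not None:
        _sidecar(path).write_text(
            json.dumps({"spacing_um": list(spacing)}, indent=2)
        )


def read_image(path: str | Path) -> tuple[np.ndarray, tuple | None]:
    path = Path(path)
    img = np.asarray(tifffile.imread(path))
    spacing = None
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
        if "spacing_um" in meta:
            spacing = tuple(meta["spacing_um"])
    return img, spacing


def write_mesh(path: str | Path, mesh: SurfaceMesh) -> None:
    """Write a surface mesh; format from the extension (.ply binary, .obj)."""
    mesh.to_trimesh().export(str(path))


def read_mesh(path: str | Path) -> SurfaceMesh:
    import trimesh

    tm = trimesh.load(str(path), force="mesh", process=False)
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
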