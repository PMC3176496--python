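"""Readers and writers: NIfTI tensor volumes, TRK/JSON fibers, caches.

Tensor volumes travel as 4-D NIfTI images with six components per
voxel.  Component ordering varies between tools, so the reader takes a
dialect name: ``lower`` (xx, xy, yy, xz, yz, zz — lower-triangular row
order, the default) or ``fsl`` (xx, xy, xz, yy, yz, zz).  Internally
components are always (xx, xy, xz, yy, yz, zz).

Fibers are written either as TrackVis TRK (world coordinates, via the
volume's voxel-to-world affine) or as JSON (voxel coordinates plus
termination and indices).  All writers are deterministic: identical
inputs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Sequence

import nibabel as nib
import numpy as np
from nibabel.streamlines import Tractogram
from nibabel.streamlines.header import Field

from .tensors import PrecomputedFields, TensorVolume
from .tracking import Fiber

__all__ = [
    "DIALECTS",
    "read_tensor_volume",
    "write_tensor_volume",
    "write_fibers",
    "read_fibers_json",
    "read_fibers_trk",
    "save_fields_cache",
    "load_fields_cache",
]

# Permutation mapping internal component position -> file component
# position.  Both dialects happen to be involutions.
DIALECTS = {
    "lower": np.array([0, 1, 3, 2, 4, 5]),
    "fsl": np.array([0, 1, 2, 3, 4, 5]),
}


def _dialect_perm(dialect: str) -> np.ndarray:
    try:
        return DIALECTS[dialect]
    except KeyError:
        raise ValueError(
            f"unknown tensor dialect {dialect!r}; expected one of {sorted(DIALECTS)}"
        ) from None


def read_tensor_volume(path, dialect: str = "lower") -> TensorVolume:
    """Load a 6-component tensor NIfTI image.

    Accepts ``(nx, ny, nz, 6)`` or the 5-D ``(nx, ny, nz, 1, 6)``
    layout; voxel spacing comes from the header zooms.
    """
    perm = _dialect_perm(dialect)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 5 and data.shape[3] == 1:
        data = data[:, :, :, 0, :]
    if data.ndim != 4 or data.shape[-1] != 6:
        found = data.shape[-1] if data.ndim >= 4 else data.ndim
        raise ValueError(
            f"expected 6 tensor components per voxel, found {found} in {path}"
        )
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return TensorVolume(data[..., perm], spacing)


def write_tensor_volume(vol: TensorVolume, path, dialect: str = "lower") -> None:
    """Write a tensor volume as a 4-D float32 NIfTI image."""
    perm = _dialect_perm(dialect)
    out = np.empty_like(vol.data, dtype=np.float32)
    out[..., perm] = vol.data.astype(np.float32)
    img = nib.Nifti1Image(out, vol.affine())
    img.header.set_zooms((*vol.spacing, 1.0))
    nib.save(img, str(path))


def _fiber_dict(fiber: Fiber) -> dict:
    return {
        "points": [[float(c) for c in p] for p in fiber.points],
        "termination": fiber.termination,
        "seed_index": fiber.seed_index,
        "direction_index": fiber.direction_index,
        **({"error": fiber.error} if fiber.error else {}),
    }


def write_fibers(
    fibers: Sequence[Fiber],
    path,
    format: str = "json",
    affine: Optional[np.ndarray] = None,
    dims: Optional[Sequence[int]] = None,
    spacing: Sequence[float] = (1.0, 1.0, 1.0),
) -> None:
    """Write fibers as TRK (world coordinates) or JSON (voxel coords).

    TRK needs the voxel-to-world ``affine`` (identity by default, as
    for phantoms) and cannot represent an empty fiber set.
    """
    path = Path(path)
    if format == "json":
        doc = {"format": "geotract-fibers", "version": 1, "fibers": [_fiber_dict(f) for f in fibers]}
        path.write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")
        return
    if format != "trk":
        raise ValueError(f"unknown fiber format {format!r}")
    streamlines = [f.points for f in fibers if f.n_points > 0]
    if not streamlines:
        raise ValueError("cannot write an empty fiber set as trk")
    if affine is None:
        affine = np.eye(4)
    affine = np.asarray(affine, dtype=float)
    if dims is None:
        upper = np.max(np.vstack([s for s in streamlines]), axis=0)
        dims = tuple(int(np.ceil(u)) + 1 for u in upper)
    header = {
        Field.VOXEL_TO_RASMM: affine.astype(np.float32),
        Field.VOXEL_SIZES: tuple(float(s) for s in spacing),
        Field.DIMENSIONS: tuple(int(d) for d in dims),
        Field.VOXEL_ORDER: b"RAS",
    }
    tractogram = Tractogram(streamlines, affine_to_rasmm=affine)
    nib.streamlines.save(tractogram, str(path), header=header)


def read_fibers_json(path) -> List[Fiber]:
    doc = json.loads(Path(path).read_text())
    fibers = []
    for rec in doc["fibers"]:
        fibers.append(
            Fiber(
                np.asarray(rec["points"], dtype=float).reshape(-1, 3),
                rec["termination"],
                rec.get("seed_index", 0),
                rec.get("direction_index", 0),
                rec.get("error"),
            )
        )
    return fibers


def read_fibers_trk(path, affine: Optional[np.ndarray] = None) -> List[np.ndarray]:
    """Load TRK streamlines back into voxel coordinates.

    Points in the file are world (RAS mm) coordinates; they are mapped
    back through the inverse of ``affine`` (identity by default).
    """
    trk = nib.streamlines.load(str(path))
    if affine is None:
        affine = np.eye(4)
    inv = np.linalg.inv(np.asarray(affine, dtype=float))
    out = []
    for s in trk.streamlines:
        pts = np.asarray(s, dtype=float)
        out.append(pts @ inv[:3, :3].T + inv[:3, 3])
    return out


def save_fields_cache(fields: PrecomputedFields, path, det_tol=None, dialect="lower") -> None:
    """Cache the four precomputed fields as one npz plus a JSON sidecar."""
    path = Path(path)
    np.savez(
        path,
        diffusion=fields.diffusion.data,
        dG_x=fields.dG_x.data,
        dG_y=fields.dG_y.data,
        dG_z=fields.dG_z.data,
        validity=fields.diffusion.validity,
    )
    sidecar = {
        "dims": list(fields.dims),
        "spacing": list(fields.spacing),
        "dialect": dialect,
        "det_tol": det_tol,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1, sort_keys=True) + "\n"
    )


def load_fields_cache(path) -> PrecomputedFields:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    spacing = tuple(sidecar["spacing"])
    with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as npz:
        validity = npz["validity"]
        vols = {
            name: TensorVolume(npz[name], spacing, validity.copy())
            for name in ("diffusion", "dG_x", "dG_y", "dG_z")
        }
    return PrecomputedFields(vols["diffusion"], vols["dG_x"], vols["dG_y"], vols["dG_z"])
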