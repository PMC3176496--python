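"""Symmetric 3x3 tensor volumes and the tracking-time field preparation.

A diffusion tensor image assigns one symmetric positive-definite 3x3
tensor to every voxel.  Six unique components per tensor are stored in
the fixed order ``(xx, xy, xz, yy, yz, zz)`` along the last axis of a
float array, so a volume is an ``(nx, ny, nz, 6)`` array.

Geodesic tracking needs, at every point along a fiber, four tensors:
the diffusion tensor D itself (the inverse metric) and the three
spatial derivatives of its inverse G = D^-1 (the metric).  This module
computes those fields once per volume (:func:`precompute`) and
evaluates them at continuous positions by component-wise trilinear
interpolation (:func:`interpolate`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

__all__ = [
    "COMPONENT_NAMES",
    "SYM_INDEX",
    "TensorVolume",
    "PrecomputedFields",
    "OutOfVolumeError",
    "sym_to_mat",
    "mat_to_sym",
    "invert_spd",
    "invert_field",
    "derivative_fields",
    "precompute",
    "interpolate",
    "interpolate_many",
]

#: Component order of the 6-vector representation.
COMPONENT_NAMES = ("xx", "xy", "xz", "yy", "yz", "zz")

#: Map (i, j) matrix indices to the 6-vector component index.
SYM_INDEX = np.array([[0, 1, 2], [1, 3, 4], [2, 4, 5]])


class OutOfVolumeError(Exception):
    """A continuous position fell outside the interpolation domain."""


def sym_to_mat(sym: np.ndarray) -> np.ndarray:
    """Expand ``(..., 6)`` symmetric components to ``(..., 3, 3)`` matrices."""
    sym = np.asarray(sym, dtype=float)
    return sym[..., SYM_INDEX]


def mat_to_sym(mat: np.ndarray) -> np.ndarray:
    """Collapse ``(..., 3, 3)`` symmetric matrices to ``(..., 6)`` components."""
    mat = np.asarray(mat, dtype=float)
    iu, ju = np.triu_indices(3)
    return mat[..., iu, ju]


@dataclass
class TensorVolume:
    """A 3-D grid of symmetric 3x3 tensors.

    Parameters
    ----------
    data:
        Array of shape ``(nx, ny, nz, 6)``; components ordered as
        :data:`COMPONENT_NAMES`.
    spacing:
        Physical edge length of a voxel along each axis (default 1).
    validity:
        Boolean per-voxel mask; ``False`` marks voxels whose tensor was
        degenerate and had to be regularized.
    """

    data: np.ndarray
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    validity: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4 or self.data.shape[-1] != 6:
            raise ValueError(
                f"tensor volume must have shape (nx, ny, nz, 6); got {self.data.shape}"
            )
        if any(n < 2 for n in self.data.shape[:3]):
            raise ValueError(f"each dimension must be >= 2; got {self.dims}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive reals; got {self.spacing}")
        if self.validity is None:
            self.validity = np.ones(self.data.shape[:3], dtype=bool)
        else:
            self.validity = np.asarray(self.validity, dtype=bool)
            if self.validity.shape != self.data.shape[:3]:
                raise ValueError("validity mask shape must match volume dims")

    @property
    def dims(self) -> Tuple[int, int, int]:
        return self.data.shape[:3]

    def affine(self) -> np.ndarray:
        """Voxel-to-world affine implied by the spacing (no rotation)."""
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.spacing
        return aff


@dataclass
class PrecomputedFields:
    """The four per-voxel tensor fields read at every integration step.

    ``diffusion`` holds D (the inverse metric, g^{ij}); ``dG_x``,
    ``dG_y``, ``dG_z`` hold the spatial derivatives of the metric
    G = D^-1 along each axis.  The inverse itself is not retained: only
    D and the derivatives of G enter the Christoffel symbols.
    """

    diffusion: TensorVolume
    dG_x: TensorVolume
    dG_y: TensorVolume
    dG_z: TensorVolume

    def __post_init__(self) -> None:
        dims = self.diffusion.dims
        spacing = self.diffusion.spacing
        for vol in (self.dG_x, self.dG_y, self.dG_z):
            if vol.dims != dims or vol.spacing != spacing:
                raise ValueError("all four fields must share dims and spacing")

    @property
    def dims(self) -> Tuple[int, int, int]:
        return self.diffusion.dims

    @property
    def spacing(self) -> Tuple[float, float, float]:
        return self.diffusion.spacing


def _det_sym(sym: np.ndarray) -> np.ndarray:
    xx, xy, xz, yy, yz, zz = (sym[..., i] for i in range(6))
    return (
        xx * (yy * zz - yz * yz)
        - xy * (xy * zz - yz * xz)
        + xz * (xy * yz - yy * xz)
    )


def _inv_sym(sym: np.ndarray, det: np.ndarray) -> np.ndarray:
    # Adjugate of a symmetric 3x3 matrix, divided by the determinant.
    xx, xy, xz, yy, yz, zz = (sym[..., i] for i in range(6))
    out = np.empty_like(sym)
    out[..., 0] = yy * zz - yz * yz
    out[..., 1] = xz * yz - xy * zz
    out[..., 2] = xy * yz - xz * yy
    out[..., 3] = xx * zz - xz * xz
    out[..., 4] = xy * xz - xx * yz
    out[..., 5] = xx * yy - xy * xy
    return out / det[..., None]


def _regularize(sym: np.ndarray, bad: np.ndarray) -> np.ndarray:
    """Add eps*I to the tensors flagged in ``bad``; eps scales with the trace."""
    trace = sym[..., 0] + sym[..., 3] + sym[..., 5]
    eps = 1e-6 * np.where(trace != 0, np.abs(trace) / 3.0, 1.0)
    out = sym.copy()
    for diag in (0, 3, 5):
        out[..., diag] = np.where(bad, out[..., diag] + eps, out[..., diag])
    return out


def default_det_tol(sym: np.ndarray) -> float:
    """Determinant threshold scaled to the field: 1e-12 * (mean trace / 3)^3."""
    trace = sym[..., 0] + sym[..., 3] + sym[..., 5]
    scale = float(np.mean(np.abs(trace))) / 3.0
    return 1e-12 * max(scale, 1.0) ** 3 if scale > 0 else 1e-12


def invert_spd(sym: np.ndarray, det_tol: float = 1e-12):
    """Invert a symmetric 3x3 tensor given as a 6-vector.

    Returns ``(inverse, regularized)`` where ``regularized`` is True if
    ``|det| < det_tol`` forced a diagonal regularization before the
    inversion (the result then inverts the regularized tensor).
    """
    sym = np.asarray(sym, dtype=float)
    if det_tol <= 0:
        raise ValueError("det_tol must be positive")
    if not np.all(np.isfinite(sym)):
        raise ValueError("tensor components must be finite")
    det = _det_sym(sym)
    bad = np.abs(det) < det_tol
    if np.any(bad):
        sym = _regularize(sym, np.asarray(bad))
        det = _det_sym(sym)
    inv = _inv_sym(sym, det)
    if sym.ndim == 1:
        return inv, bool(bad)
    return inv, bad


def invert_field(vol: TensorVolume, det_tol: float | None = None) -> TensorVolume:
    """Voxel-wise inversion of a tensor volume (D -> G = D^-1).

    Degenerate voxels are regularized rather than aborting the volume;
    they come back marked ``False`` in the validity mask.
    """
    if det_tol is None:
        det_tol = default_det_tol(vol.data)
    data = np.where(np.isfinite(vol.data), vol.data, 0.0)
    nonfinite = ~np.all(np.isfinite(vol.data), axis=-1)
    inv, bad = invert_spd(data, det_tol)
    bad = bad | nonfinite
    return TensorVolume(inv, vol.spacing, vol.validity & ~bad)


def derivative_fields(
    metric_vol: TensorVolume,
) -> Tuple[TensorVolume, TensorVolume, TensorVolume]:
    """Spatial derivatives of a tensor field along x, y and z.

    Central (two-sided) differences at interior voxels, one-sided
    first-order differences at the boundary; denominators use the
    per-axis voxel spacing.  Exact for component-wise linear fields.
    """
    outs = []
    for axis in range(3):
        grad = np.gradient(metric_vol.data, metric_vol.spacing[axis], axis=axis)
        outs.append(TensorVolume(grad, metric_vol.spacing, metric_vol.validity.copy()))
    return tuple(outs)  # type: ignore[return-value]


def precompute(
    diffusion_vol: TensorVolume, det_tol: float | None = None
) -> PrecomputedFields:
    """Preprocessing: derive the four tracking-time fields from D.

    The metric G = D^-1 is formed voxel-wise, differentiated along each
    axis, and then discarded; the returned bundle holds D unmodified
    plus the three derivative fields.
    """
    metric = invert_field(diffusion_vol, det_tol)
    dgx, dgy, dgz = derivative_fields(metric)
    diffusion = TensorVolume(
        diffusion_vol.data.copy(), diffusion_vol.spacing, metric.validity.copy()
    )
    return PrecomputedFields(diffusion, dgx, dgy, dgz)


def _interp_weights(points: np.ndarray, dims: Tuple[int, int, int]):
    """Corner indices and trilinear weights for in-bounds points.

    Points on the upper face (coordinate == n-1) anchor at the last
    interior cell with fractional offset 1, so lattice points always
    reproduce voxel values exactly.
    """
    base = np.floor(points).astype(np.intp)
    for axis, n in enumerate(dims):
        base[:, axis] = np.clip(base[:, axis], 0, n - 2)
    frac = points - base
    return base, frac


def in_bounds_mask(points: np.ndarray, dims: Tuple[int, int, int]) -> np.ndarray:
    """True where a point lies in the closed box [0, n-1] per axis."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    ok = np.all(np.isfinite(points), axis=1)
    for axis, n in enumerate(dims):
        ok &= (points[:, axis] >= 0.0) & (points[:, axis] <= n - 1)
    return ok


def interpolate_many(
    fields: PrecomputedFields, points: np.ndarray, mode: str = "trilinear"
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Evaluate the four tensor fields at ``(N, 3)`` in-bounds positions.

    Returns four ``(N, 6)`` arrays (D, dG_x, dG_y, dG_z).  The caller
    is responsible for bounds checking; see :func:`in_bounds_mask`.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    vols = (fields.diffusion, fields.dG_x, fields.dG_y, fields.dG_z)
    if mode == "nearest":
        idx = np.rint(points).astype(np.intp)
        for axis, n in enumerate(fields.dims):
            idx[:, axis] = np.clip(idx[:, axis], 0, n - 1)
        return tuple(v.data[idx[:, 0], idx[:, 1], idx[:, 2]] for v in vols)
    if mode != "trilinear":
        raise ValueError(f"unknown interpolation mode {mode!r}")
    base, frac = _interp_weights(points, fields.dims)
    results = [np.zeros((points.shape[0], 6)) for _ in range(4)]
    for dx in (0, 1):
        wx = frac[:, 0] if dx else 1.0 - frac[:, 0]
        for dy in (0, 1):
            wy = frac[:, 1] if dy else 1.0 - frac[:, 1]
            for dz in (0, 1):
                wz = frac[:, 2] if dz else 1.0 - frac[:, 2]
                w = (wx * wy * wz)[:, None]
                ix, iy, iz = base[:, 0] + dx, base[:, 1] + dy, base[:, 2] + dz
                for out, vol in zip(results, vols):
                    out += w * vol.data[ix, iy, iz]
    return tuple(results)  # type: ignore[return-value]


def interpolate_volume(
    vol: TensorVolume, points: np.ndarray, mode: str = "trilinear"
) -> np.ndarray:
    """Interpolate a single tensor volume at ``(N, 3)`` in-bounds positions."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if mode == "nearest":
        idx = np.rint(points).astype(np.intp)
        for axis, n in enumerate(vol.dims):
            idx[:, axis] = np.clip(idx[:, axis], 0, n - 1)
        return vol.data[idx[:, 0], idx[:, 1], idx[:, 2]]
    if mode != "trilinear":
        raise ValueError(f"unknown interpolation mode {mode!r}")
    base, frac = _interp_weights(points, vol.dims)
    out = np.zeros((points.shape[0], 6))
    for dx in (0, 1):
        wx = frac[:, 0] if dx else 1.0 - frac[:, 0]
        for dy in (0, 1):
            wy = frac[:, 1] if dy else 1.0 - frac[:, 1]
            for dz in (0, 1):
                wz = frac[:, 2] if dz else 1.0 - frac[:, 2]
                w = (wx * wy * wz)[:, None]
                out += w * vol.data[base[:, 0] + dx, base[:, 1] + dy, base[:, 2] + dz]
    return out


def interpolate(
    fields: PrecomputedFields,
    point,
    mode: str = "trilinear",
    strict_validity: bool = False,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Evaluate the four fields at one continuous voxel coordinate.

    Raises :class:`OutOfVolumeError` outside the closed box
    ``[0, n-1]`` per axis (the tracker catches this as its stopping
    condition).  With ``strict_validity`` the 8 surrounding voxels must
    all be valid.
    """
    point = np.asarray(point, dtype=float)
    if not in_bounds_mask(point[None, :], fields.dims)[0]:
        raise OutOfVolumeError(f"point {point.tolist()} outside volume {fields.dims}")
    if strict_validity:
        base, _ = _interp_weights(point[None, :], fields.dims)
        bx, by, bz = base[0]
        corners = fields.diffusion.validity[bx : bx + 2, by : by + 2, bz : bz + 2]
        if not np.all(corners):
            raise ValueError(f"invalid voxel in the neighborhood of {point.tolist()}")
    d, gx, gy, gz = interpolate_many(fields, point[None, :], mode)
    return d[0], gx[0], gy[0], gz[0]
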