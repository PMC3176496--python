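"""Synthetic tensor volumes with known geometry.

Every stage of the tracker can be validated against these phantoms:

* homogeneous — constant tensor, zero Christoffel symbols, geodesics
  are straight lines;
* half-plane — metric diag(y^-2, y^-2, 1), the hyperbolic half-plane,
  whose geodesics are semicircles with a closed form;
* curved — main eigenvector tangent to circles about the central
  z-axis, an oracle for the eigenvector streamline tracker;
* benchmark — a long homogeneous volume with random interior seeds
  aimed along +/-x so that no fiber can leave the volume within the
  step cap, exercising the tracker under maximum load.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np

from .tensors import TensorVolume, mat_to_sym

__all__ = [
    "make_homogeneous",
    "make_halfplane",
    "make_curved",
    "make_benchmark",
    "add_tensor_noise",
]

Vec3 = Sequence[float]


def _rotation_to(axis: np.ndarray) -> np.ndarray:
    """An orthonormal frame whose first column is ``axis``."""
    a = axis / np.linalg.norm(axis)
    helper = np.array([0.0, 0.0, 1.0]) if abs(a[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e2 = np.cross(a, helper)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(a, e2)
    return np.column_stack([a, e2, e3])


def make_homogeneous(
    dims: Tuple[int, int, int],
    eigenvalues: Tuple[float, float, float] = (9.0, 1.0, 1.0),
    principal_axis: Vec3 = (1.0, 0.0, 0.0),
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> TensorVolume:
    """Constant anisotropic tensor field with a chosen main direction."""
    lam = np.asarray(eigenvalues, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("eigenvalues must be positive")
    if not (lam[0] >= lam[1] >= lam[2]):
        raise ValueError("eigenvalues must be ordered descending")
    axis = np.asarray(principal_axis, dtype=float)
    if np.linalg.norm(axis) == 0:
        raise ValueError("principal axis must be nonzero")
    rot = _rotation_to(axis)
    tensor = rot @ np.diag(lam) @ rot.T
    sym = mat_to_sym(tensor)
    data = np.broadcast_to(sym, (*dims, 6)).copy()
    return TensorVolume(data, spacing)


def make_halfplane(
    dims: Tuple[int, int, int],
    y0: float = 4.0,
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> TensorVolume:
    """Hyperbolic half-plane phantom.

    Voxel (i, j, k) carries D = diag(y^2, y^2, 1) with physical height
    y = j * spacing_y + y0, so the metric is diag(y^-2, y^-2, 1) and
    in-plane geodesics are semicircles centered on y = 0.  ``y0`` must
    be positive or the metric is singular inside the volume.
    """
    if dims[1] < 4:
        raise ValueError("half-plane phantom needs at least 4 rows in y")
    if y0 <= 0:
        raise ValueError("y0 must be positive (metric singularity at y = 0)")
    nx, ny, nz = dims
    y = np.arange(ny) * spacing[1] + y0
    data = np.zeros((nx, ny, nz, 6))
    data[:, :, :, 0] = (y**2)[None, :, None]
    data[:, :, :, 3] = (y**2)[None, :, None]
    data[:, :, :, 5] = 1.0
    return TensorVolume(data, spacing)


def make_curved(
    dims: Tuple[int, int, int],
    radius: float = 20.0,
    eigenvalues: Tuple[float, float, float] = (9.0, 1.0, 1.0),
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> TensorVolume:
    """Tangential tensor field: main eigenvector circles the z-axis.

    At each voxel the main eigenvector is the unit tangent of the
    circle about the volume's central z-axis through that voxel; the
    other eigenvectors are the radial and z directions.  Voxels on the
    axis itself, where the tangent is undefined, fall back to an
    isotropic tensor and are flagged invalid.  ``radius`` documents the
    circle the standard test fiber rides and must exceed 2 voxels.
    """
    if radius <= 2:
        raise ValueError("radius must exceed 2 voxels")
    lam = np.asarray(eigenvalues, dtype=float)
    if np.any(lam <= 0) or not lam[0] > lam[1]:
        raise ValueError("need positive eigenvalues with lambda1 > lambda2")
    nx, ny, nz = dims
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    dx = ii - cx
    dy = jj - cy
    r = np.hypot(dx, dy)
    on_axis = r < 1e-9
    r_safe = np.where(on_axis, 1.0, r)
    tx, ty = -dy / r_safe, dx / r_safe  # unit tangent
    rx, ry = dx / r_safe, dy / r_safe  # unit radial
    # T = lam1 t t^T + lam2 rhat rhat^T + lam3 z z^T (2-D slice pattern).
    sym2d = np.zeros((nx, ny, 6))
    sym2d[..., 0] = lam[0] * tx * tx + lam[1] * rx * rx
    sym2d[..., 1] = lam[0] * tx * ty + lam[1] * rx * ry
    sym2d[..., 3] = lam[0] * ty * ty + lam[1] * ry * ry
    sym2d[..., 5] = lam[2]
    iso = np.mean(lam)
    sym2d[on_axis] = [iso, 0.0, 0.0, iso, 0.0, iso]
    data = np.repeat(sym2d[:, :, None, :], nz, axis=2)
    validity = np.repeat((~on_axis)[:, :, None], nz, axis=2)
    return TensorVolume(data, spacing, validity)


def make_benchmark(
    dims: Tuple[int, int, int] = (256, 32, 32),
    n_seeds: int = 128,
    inset: float = 2.0,
    rng_seed: int = 0,
    max_steps: int = 512,
    h: float = 0.1,
    eigenvalues: Tuple[float, float, float] = (9.0, 1.0, 1.0),
    full: bool = False,
) -> Tuple[TensorVolume, List[Tuple[np.ndarray, np.ndarray]]]:
    """Stress-benchmark phantom: long volume, seeds that never exit.

    A homogeneous strongly anisotropic field with main axis +x fills a
    volume much longer in x than in y, z.  Seeds are uniform in the
    interior box inset from every face; each is aimed along +x or -x,
    chosen (randomly when both fit) so the straight-line travel
    distance ``max_steps * h`` stays inside the volume — every fiber
    runs to the step cap.  ``full=True`` selects the large preset
    (1024 x 64 x 64, 2048 seeds, 4096 steps); the default is a
    desk-scale version of the same construction.
    """
    if full:
        dims, n_seeds, max_steps = (1024, 64, 64), 2048, 4096
    if inset < 1:
        raise ValueError("inset must be >= 1 voxel")
    nx, ny, nz = dims
    if nx <= max(ny, nz):
        raise ValueError("benchmark volume must be longest along x")
    travel = max_steps * h
    lo = np.array([inset] * 3, dtype=float)
    hi = np.array([nx - 1 - inset, ny - 1 - inset, nz - 1 - inset], dtype=float)
    if np.any(hi < lo):
        raise ValueError(f"inset {inset} leaves no interior seed box in {dims}")
    # Feasibility: some x in the seed box must allow a +/-x run of `travel`.
    if lo[0] + travel > nx - 1 and hi[0] - travel < 0:
        raise ValueError(
            f"travel distance {travel:.1f} voxels cannot fit in x extent "
            f"[{lo[0]:.0f}, {hi[0]:.0f}] of a {nx}-voxel axis"
        )
    vol = make_homogeneous(dims, eigenvalues, (1.0, 0.0, 0.0))
    rng = np.random.default_rng(int(rng_seed) & 0x7FFFFFFF)
    seeds: List[Tuple[np.ndarray, np.ndarray]] = []
    while len(seeds) < n_seeds:
        pos = rng.uniform(lo, hi)
        plus_ok = pos[0] + travel <= nx - 1
        minus_ok = pos[0] - travel >= 0
        if not (plus_ok or minus_ok):
            continue  # resample: this x admits no full-length run
        if plus_ok and minus_ok:
            sign = 1.0 if rng.random() < 0.5 else -1.0
        else:
            sign = 1.0 if plus_ok else -1.0
        seeds.append((pos, np.array([sign, 0.0, 0.0])))
    return vol, seeds


def add_tensor_noise(
    vol: TensorVolume, sigma: float, rng_seed: int = 0
) -> TensorVolume:
    """Optional Gaussian perturbation of the tensor components.

    Adds N(0, sigma^2) noise to each unique component.  Off by default
    everywhere; the benchmark construction is noise-free.  Positive
    definiteness is not guaranteed after perturbation — degenerate
    voxels are caught later by the inversion's regularization.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(int(rng_seed) & 0x7FFFFFFF)
    data = vol.data + rng.normal(0.0, sigma, size=vol.data.shape)
    return TensorVolume(data, vol.spacing, vol.validity.copy())
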