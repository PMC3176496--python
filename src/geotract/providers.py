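"""Point-wise evaluation of the four tracking-time tensor fields.

A :class:`FieldProvider` answers, for any continuous position, the
four tensors the geodesic ODE needs: the diffusion tensor D and the
three derivatives of the metric G = D^-1.  The grid-backed provider
interpolates precomputed voxel fields; analytic providers evaluate
closed-form fields and serve as exact oracles in tests.
"""

from __future__ import annotations

from typing import Callable, Optional, Tuple

import numpy as np

from .tensors import (
    OutOfVolumeError,
    PrecomputedFields,
    in_bounds_mask,
    interpolate_many,
)

__all__ = [
    "FieldProvider",
    "GridFieldProvider",
    "AnalyticFieldProvider",
    "ConstantFieldProvider",
    "HalfPlaneProvider",
]

FourTensors = Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]


class FieldProvider:
    """Contract: deterministic evaluation of (D, dG_x, dG_y, dG_z)."""

    #: per-axis voxel edge length, used to convert voxel- to physical velocities
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)

    def evaluate_many(self, points: np.ndarray) -> FourTensors:
        """Evaluate at ``(N, 3)`` positions; all must be in bounds."""
        raise NotImplementedError

    def in_bounds(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask over ``(N, 3)`` positions."""
        raise NotImplementedError

    def evaluate(self, point) -> FourTensors:
        """Evaluate at a single position; raises OutOfVolumeError outside."""
        pts = np.asarray(point, dtype=float)[None, :]
        if not self.in_bounds(pts)[0]:
            raise OutOfVolumeError(f"point {np.asarray(point).tolist()} out of bounds")
        d, gx, gy, gz = self.evaluate_many(pts)
        return d[0], gx[0], gy[0], gz[0]


class GridFieldProvider(FieldProvider):
    """Trilinear (or nearest-neighbor) interpolation of precomputed fields."""

    def __init__(self, fields: PrecomputedFields, mode: str = "trilinear"):
        if mode not in ("trilinear", "nearest"):
            raise ValueError(f"unknown interpolation mode {mode!r}")
        self.fields = fields
        self.mode = mode
        self.spacing = fields.spacing

    def evaluate_many(self, points: np.ndarray) -> FourTensors:
        return interpolate_many(self.fields, points, self.mode)

    def in_bounds(self, points: np.ndarray) -> np.ndarray:
        return in_bounds_mask(points, self.fields.dims)


class AnalyticFieldProvider(FieldProvider):
    """Closed-form fields, for oracle tests against exact geometry.

    Parameters
    ----------
    func:
        Vectorized callable mapping ``(N, 3)`` positions to the four
        ``(N, 6)`` tensor arrays.
    bounds_func:
        Optional vectorized in-bounds predicate; default accepts every
        finite position.
    """

    def __init__(
        self,
        func: Callable[[np.ndarray], FourTensors],
        bounds_func: Optional[Callable[[np.ndarray], np.ndarray]] = None,
        spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0),
    ):
        self._func = func
        self._bounds = bounds_func
        self.spacing = spacing

    def evaluate_many(self, points: np.ndarray) -> FourTensors:
        return self._func(np.atleast_2d(np.asarray(points, dtype=float)))

    def in_bounds(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        ok = np.all(np.isfinite(points), axis=1)
        if self._bounds is not None:
            ok &= self._bounds(points)
        return ok


class ConstantFieldProvider(AnalyticFieldProvider):
    """Spatially constant diffusion tensor: all derivatives vanish."""

    def __init__(self, diffusion_sym: np.ndarray):
        d = np.asarray(diffusion_sym, dtype=float)

        def func(points: np.ndarray) -> FourTensors:
            n = points.shape[0]
            zeros = np.zeros((n, 6))
            return np.broadcast_to(d, (n, 6)).copy(), zeros, zeros.copy(), zeros.copy()

        super().__init__(func)


class HalfPlaneProvider(AnalyticFieldProvider):
    """Exact hyperbolic half-plane field in voxel coordinates.

    The metric is diag(y^-2, y^-2, 1) with the physical height
    ``y = y_voxel + y0``, i.e. D = diag(y^2, y^2, 1).  Its geodesics in
    any z-slice are semicircles centered on y = 0, giving a closed-form
    oracle for the integrators.  Positions with y <= y_min (default:
    just above the metric singularity) are out of bounds.
    """

    def __init__(self, y0: float = 4.0, y_min: float = 1e-6):
        if y0 <= 0:
            raise ValueError("y0 must be positive (metric singular at y = 0)")
        self.y0 = float(y0)

        def func(points: np.ndarray) -> FourTensors:
            n = points.shape[0]
            y = points[:, 1] + self.y0
            d = np.zeros((n, 6))
            d[:, 0] = y**2
            d[:, 3] = y**2
            d[:, 5] = 1.0
            dgy = np.zeros((n, 6))
            dgy[:, 0] = -2.0 * y**-3
            dgy[:, 3] = -2.0 * y**-3
            zeros = np.zeros((n, 6))
            return d, zeros, dgy, zeros.copy()

        def bounds(points: np.ndarray) -> np.ndarray:
            return points[:, 1] + self.y0 > y_min

        super().__init__(func, bounds)

    def geodesic_point(self, c: float, r: float, tau: float) -> np.ndarray:
        """Closed-form geodesic launched at (c, r - y0) with velocity (1, 0, 0).

        x = c + r*tanh(tau/r), y_phys = r*sech(tau/r); returned in voxel
        coordinates (y_voxel = y_phys - y0), z = 0.
        """
        s = tau / r
        return np.array([c + r * np.tanh(s), r / np.cosh(s) - self.y0, 0.0])
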