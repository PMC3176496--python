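"""Seeding and fiber tracing.

Fibers are traced one per seed (position + initial direction) by
iterating a fixed-step ODE solver until the fiber leaves the volume or
a hard step cap is reached — the only two stopping conditions.  The
batch tracer advances all unfinished fibers together with an active
mask; every arithmetic operation is element-wise per fiber, so results
are bitwise identical to tracing each fiber alone, in any batch split.

Also included is the classic eigenvector streamline tracker, which
integrates the main eigenvector field of the diffusion tensor directly
and serves as the baseline the geodesic method is compared against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .geodesic import christoffel, geodesic_rhs
from .providers import FieldProvider, GridFieldProvider
from .tensors import (
    OutOfVolumeError,
    PrecomputedFields,
    TensorVolume,
    in_bounds_mask,
    interpolate_volume,
    invert_spd,
    sym_to_mat,
)

__all__ = [
    "TrackingConfig",
    "SeedSpec",
    "Fiber",
    "DegenerateDirectionError",
    "generate_directions",
    "generate_seeds",
    "trace_fiber",
    "trace_batch",
    "trace_streamline",
]

TERMINATIONS = ("left_volume", "max_steps", "error")


class DegenerateDirectionError(ValueError):
    """The main eigenvector is undefined (near-isotropic tensor)."""


@dataclass
class TrackingConfig:
    """Integration parameters shared by every fiber of a run.

    ``h`` is the step size in voxel-traversal units (h = 0.05 means
    about twenty steps per cell); ``max_steps`` is the hard iteration
    cap per fiber.  ``metric_normalize`` switches the initial-velocity
    normalization from Euclidean to unit metric speed.
    """

    h: float = 0.1
    max_steps: int = 4096
    solver: str = "rk2"
    interpolation: str = "trilinear"
    rng_seed: int = 0
    metric_normalize: bool = False

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise ValueError("step size h must be positive")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        if self.solver not in ("euler", "rk2"):
            raise ValueError(f"unknown solver {self.solver!r}")
        if self.interpolation not in ("trilinear", "nearest"):
            raise ValueError(f"unknown interpolation {self.interpolation!r}")


@dataclass
class SeedSpec:
    """Where fibers start and how their initial directions are drawn.

    ``region`` is an axis-aligned box ``((lo), (hi))`` in voxel
    coordinates, or ``points`` gives explicit positions.  Each seed
    gets ``directions_per_seed`` directions: uniform on the sphere,
    uniform in a cone about the local main eigenvector, or a fixed
    vector.
    """

    region: Optional[Tuple[Tuple[float, float, float], Tuple[float, float, float]]] = None
    points: Optional[Sequence[Sequence[float]]] = None
    n_seeds: int = 1
    direction_mode: str = "uniform_sphere"
    cone_angle: float = 0.0
    fixed_direction: Optional[Tuple[float, float, float]] = None
    directions_per_seed: int = 1

    def __post_init__(self) -> None:
        if (self.region is None) == (self.points is None):
            raise ValueError("give exactly one of region or points")
        if self.n_seeds < 1 or self.directions_per_seed < 1:
            raise ValueError("n_seeds and directions_per_seed must be >= 1")
        if self.direction_mode not in ("uniform_sphere", "around_main_eigenvector", "fixed"):
            raise ValueError(f"unknown direction mode {self.direction_mode!r}")
        if not 0.0 <= self.cone_angle <= np.pi:
            raise ValueError("cone_angle must lie in [0, pi]")
        if self.direction_mode == "fixed" and self.fixed_direction is None:
            raise ValueError("fixed mode requires fixed_direction")


@dataclass
class Fiber:
    """An ordered 3-D polyline in voxel coordinates plus bookkeeping."""

    points: np.ndarray
    termination: str
    seed_index: int = 0
    direction_index: int = 0
    error: Optional[str] = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if self.termination not in TERMINATIONS:
            raise ValueError(f"unknown termination {self.termination!r}")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def euclidean_length(self) -> float:
        if self.n_points < 2:
            return 0.0
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))


def _rng_for(master_seed: int, index: int) -> np.random.Generator:
    # Counter-derived substream: draws for seed `index` never depend on
    # how many other seeds were generated before it.
    return np.random.default_rng([int(master_seed) & 0x7FFFFFFF, index])


def generate_directions(
    n: int,
    mode: str,
    axis: Optional[np.ndarray] = None,
    cone_angle: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Draw ``n`` unit directions.

    ``uniform_sphere`` is uniform on S^2; ``around_main_eigenvector``
    is uniform over the spherical cap of half-angle ``cone_angle``
    about ``axis``; ``fixed`` repeats ``axis``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if rng is None:
        rng = np.random.default_rng()
    if mode == "fixed":
        if axis is None:
            raise ValueError("fixed mode requires an axis")
        a = np.asarray(axis, dtype=float)
        norm = np.linalg.norm(a)
        if norm == 0:
            raise ValueError("direction axis must be nonzero")
        return np.tile(a / norm, (n, 1))
    if mode == "uniform_sphere":
        z = rng.uniform(-1.0, 1.0, size=n)
        phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
        r = np.sqrt(1.0 - z**2)
        return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    if mode == "around_main_eigenvector":
        if axis is None:
            raise ValueError("cone mode requires an axis")
        a = np.asarray(axis, dtype=float)
        norm = np.linalg.norm(a)
        if norm == 0:
            raise ValueError("direction axis must be nonzero")
        a = a / norm
        # Uniform over the cap: cos(theta) uniform in [cos(alpha), 1].
        cos_t = rng.uniform(np.cos(cone_angle), 1.0, size=n)
        phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
        sin_t = np.sqrt(np.maximum(1.0 - cos_t**2, 0.0))
        # Orthonormal frame about the axis.
        helper = np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        e1 = np.cross(a, helper)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(a, e1)
        return (
            cos_t[:, None] * a
            + (sin_t * np.cos(phi))[:, None] * e1
            + (sin_t * np.sin(phi))[:, None] * e2
        )
    raise ValueError(f"unknown direction mode {mode!r}")


def main_eigenvector(sym: np.ndarray) -> np.ndarray:
    """Largest-eigenvalue eigenvector with a canonical sign."""
    w, v = np.linalg.eigh(sym_to_mat(sym))
    e = v[:, 2]
    k = int(np.argmax(np.abs(e)))
    return e if e[k] >= 0 else -e


def generate_seeds(
    spec: SeedSpec, fields: PrecomputedFields, rng_seed: int = 0
) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Expand a seed specification into (position, direction) pairs.

    Positions are uniform in the region box (or taken verbatim from
    the explicit list); each position is paired with
    ``directions_per_seed`` directions.  Draws come from per-seed
    counter-derived substreams of ``rng_seed``, so the output is
    reproducible and independent of batching.
    """
    dims = fields.dims
    if spec.points is not None:
        positions = [np.asarray(p, dtype=float) for p in spec.points]
    else:
        lo = np.asarray(spec.region[0], dtype=float)
        hi = np.asarray(spec.region[1], dtype=float)
        upper = np.asarray(dims, dtype=float) - 1.0
        if np.any(np.minimum(hi, upper) < np.maximum(lo, 0.0)):
            raise ValueError(
                f"seed region {spec.region} does not intersect volume {dims}"
            )
        lo_c = np.maximum(lo, 0.0)
        hi_c = np.minimum(hi, upper)
        positions = [
            _rng_for(rng_seed, i).uniform(lo_c, hi_c) for i in range(spec.n_seeds)
        ]
    pairs: List[Tuple[np.ndarray, np.ndarray]] = []
    for i, pos in enumerate(positions):
        rng = _rng_for(rng_seed, 10_000_019 + i)
        if spec.direction_mode == "fixed":
            dirs = generate_directions(
                spec.directions_per_seed, "fixed", np.asarray(spec.fixed_direction, float)
            )
        elif spec.direction_mode == "around_main_eigenvector":
            if not in_bounds_mask(pos[None, :], dims)[0]:
                raise ValueError(f"seed position {pos.tolist()} out of bounds")
            d6 = interpolate_volume(fields.diffusion, pos[None, :])[0]
            axis = main_eigenvector(d6)
            dirs = generate_directions(
                spec.directions_per_seed, "around_main_eigenvector", axis, spec.cone_angle, rng
            )
        else:
            dirs = generate_directions(spec.directions_per_seed, "uniform_sphere", rng=rng)
        for d in dirs:
            pairs.append((pos.copy(), d.copy()))
    return pairs


def _initial_velocity(
    position: np.ndarray, direction: np.ndarray, config: TrackingConfig, provider: FieldProvider
) -> np.ndarray:
    d = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(d)
    if norm == 0 or not np.all(np.isfinite(d)):
        raise ValueError("seed direction must be nonzero and finite")
    v = d / norm
    if config.metric_normalize:
        D6, _, _, _ = provider.evaluate(position)
        # v^T G v with G = D^-1, via a solve instead of an explicit inverse.
        Dm = sym_to_mat(D6)
        speed2 = float(v @ np.linalg.solve(Dm, v))
        v = v / np.sqrt(speed2)
    return v


def _batch_accel(
    pos: np.ndarray, vel: np.ndarray, provider: FieldProvider
) -> np.ndarray:
    d, gx, gy, gz = provider.evaluate_many(pos)
    gamma = christoffel(d, gx, gy, gz)
    s = np.asarray(provider.spacing, dtype=float)
    return geodesic_rhs(vel * s, gamma) / s


def trace_batch(
    seeds: Sequence[Tuple[np.ndarray, np.ndarray]],
    config: TrackingConfig,
    provider: FieldProvider,
) -> List[Fiber]:
    """Trace one fiber per (position, direction) seed.

    All unfinished fibers advance together under an active mask.  Every
    operation is element-wise per fiber, so the output equals mapping
    :func:`trace_fiber` over the list, for any batch size or order.
    Invalid seeds produce ``termination='error'`` records instead of
    aborting the batch.
    """
    n = len(seeds)
    if n == 0:
        return []
    fibers: List[Optional[Fiber]] = [None] * n
    pos_list, vel_list, live_idx = [], [], []
    for i, (p, d) in enumerate(seeds):
        try:
            p = np.asarray(p, dtype=float).reshape(3)
            if not provider.in_bounds(p[None, :])[0]:
                raise ValueError(f"seed position {p.tolist()} out of bounds")
            v = _initial_velocity(p, np.asarray(d, dtype=float).reshape(3), config, provider)
        except (ValueError, OutOfVolumeError) as exc:
            fibers[i] = Fiber(np.empty((0, 3)), "error", seed_index=i, error=str(exc))
            continue
        pos_list.append(p)
        vel_list.append(v)
        live_idx.append(i)
    if not live_idx:
        return [f for f in fibers if f is not None]

    m = len(live_idx)
    pos = np.array(pos_list)
    vel = np.array(vel_list)
    idx = np.array(live_idx)
    points = np.full((m, config.max_steps + 1, 3), np.nan)
    points[:, 0, :] = pos
    counts = np.ones(m, dtype=int)
    h = config.h

    def finish(local: np.ndarray, reason: str) -> None:
        for j in local:
            i = idx[j]
            fibers[i] = Fiber(points[j, : counts[j]], reason, seed_index=int(i))

    active = np.arange(m)
    for _ in range(config.max_steps):
        if active.size == 0:
            break
        p = pos[active]
        v = vel[active]
        if config.solver == "euler":
            a = _batch_accel(p, v, provider)
            new_p = p + h * v
            new_v = v + h * a
            alive = np.ones(active.size, dtype=bool)
        else:
            a1 = _batch_accel(p, v, provider)
            pm = p + 0.5 * h * v
            vm = v + 0.5 * h * a1
            alive = provider.in_bounds(pm)
            # Midpoint escaping the volume terminates the fiber too.
            if not np.all(alive):
                finish(active[~alive], "left_volume")
            new_p = np.full_like(p, np.nan)
            new_v = np.full_like(v, np.nan)
            if np.any(alive):
                a2 = _batch_accel(pm[alive], vm[alive], provider)
                new_p[alive] = p[alive] + h * vm[alive]
                new_v[alive] = v[alive] + h * a2
        inside = np.zeros(active.size, dtype=bool)
        inside[alive] = provider.in_bounds(new_p[alive])
        left = alive & ~inside
        if np.any(left):
            finish(active[left], "left_volume")
        keep = inside
        surv = active[keep]
        pos[surv] = new_p[keep]
        vel[surv] = new_v[keep]
        points[surv, counts[surv], :] = new_p[keep]
        counts[surv] += 1
        active = surv
    if active.size:
        finish(active, "max_steps")
    return [f for f in fibers if f is not None]


def trace_fiber(
    position, direction, config: TrackingConfig, provider: FieldProvider
) -> Fiber:
    """Trace a single fiber from a seed position and direction.

    The first stored point is the seed itself; each completed step
    appends one point.  Raises for an out-of-bounds seed or a zero
    direction.
    """
    p = np.asarray(position, dtype=float).reshape(3)
    if not provider.in_bounds(p[None, :])[0]:
        raise ValueError(f"seed position {p.tolist()} out of bounds")
    d = np.asarray(direction, dtype=float).reshape(3)
    if np.linalg.norm(d) == 0:
        raise ValueError("seed direction must be nonzero")
    (fiber,) = trace_batch([(p, d)], config, provider)
    return fiber


def _streamline_direction(
    d6: np.ndarray, reference: Optional[np.ndarray], tol: float = 1e-9
) -> np.ndarray:
    """Main-eigenvector direction aligned with ``reference``.

    When the top eigenvalues are degenerate the eigenvector is
    undefined; the reference direction is then projected onto the
    dominant eigenspace.  Without a reference, degeneracy is an error.
    """
    w, v = np.linalg.eigh(sym_to_mat(d6))
    lam1, lam2 = w[2], w[1]
    if lam1 - lam2 < tol * abs(lam1):
        if reference is None:
            raise DegenerateDirectionError(
                f"main eigenvector undefined: top eigenvalues {lam1:g}, {lam2:g}"
            )
        near = w >= lam1 - tol * abs(lam1)
        proj = v[:, near] @ (v[:, near].T @ reference)
        norm = np.linalg.norm(proj)
        if norm < 1e-12:
            raise DegenerateDirectionError(
                "reference direction orthogonal to the dominant eigenspace"
            )
        return proj / norm
    e = v[:, 2]
    if reference is not None and float(e @ reference) < 0:
        e = -e
    return e


def trace_streamline(
    position,
    config: TrackingConfig,
    diffusion_vol: TensorVolume,
    reference_direction=None,
) -> Fiber:
    """Baseline tracker: integrate the main eigenvector field of D.

    The eigenvector sign at each evaluation is chosen to have a
    non-negative dot product with the previous direction (the supplied
    reference direction at the first step).  Stopping rules match the
    geodesic tracker: volume exit or the step cap.
    """
    p = np.asarray(position, dtype=float).reshape(3)
    dims = diffusion_vol.dims
    if not in_bounds_mask(p[None, :], dims)[0]:
        raise ValueError(f"seed position {p.tolist()} out of bounds")
    ref = None
    if reference_direction is not None:
        ref = np.asarray(reference_direction, dtype=float)
        norm = np.linalg.norm(ref)
        if norm == 0:
            raise ValueError("reference direction must be nonzero")
        ref = ref / norm

    def direction_at(pt: np.ndarray, previous: Optional[np.ndarray]) -> np.ndarray:
        d6 = interpolate_volume(diffusion_vol, pt[None, :], config.interpolation)[0]
        return _streamline_direction(d6, previous)

    pts = [p.copy()]
    prev = ref
    current = p
    termination = "max_steps"
    for _ in range(config.max_steps):
        d1 = direction_at(current, prev)
        if config.solver == "euler":
            new_p = current + config.h * d1
            step_dir = d1
        else:
            mid = current + 0.5 * config.h * d1
            if not in_bounds_mask(mid[None, :], dims)[0]:
                termination = "left_volume"
                break
            d2 = direction_at(mid, d1)
            new_p = current + config.h * d2
            step_dir = d2
        if not in_bounds_mask(new_p[None, :], dims)[0]:
            termination = "left_volume"
            break
        pts.append(new_p.copy())
        current = new_p
        prev = step_dir
    return Fiber(np.array(pts), termination)
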