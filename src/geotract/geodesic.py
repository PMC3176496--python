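"""Geodesic math: Christoffel symbols, the geodesic ODE, and steppers.

With the Riemannian metric G = D^-1 (g_ij) and its inverse D (g^ij),
the Christoffel symbols are

    Gamma^c_ab = 1/2 sum_s g^{cs} (d_a g_bs + d_b g_as - d_s g_ab)

and a geodesic x(tau) satisfies  xdd^c = -sum_ab Gamma^c_ab xd^a xd^b.
Symmetry in the lower indices leaves 18 unique symbols out of 27; the
quadratic form in the velocity is evaluated from those 18 with the
off-diagonal terms doubled, never by materializing all 27 entries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tensors import SYM_INDEX, sym_to_mat
from .providers import FieldProvider

__all__ = [
    "ChristoffelSet",
    "FiberState",
    "christoffel",
    "expand_christoffel",
    "geodesic_rhs",
    "step_euler",
    "step_rk2",
    "metric_length",
]

#: The 6 unique lower-index pairs (a <= b), matching the component order.
LOWER_PAIRS = ((0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2))

#: ChristoffelSet: array of shape (..., 3, 6) — for each upper index c,
#: the 6 unique lower-index pairs in LOWER_PAIRS order.
ChristoffelSet = np.ndarray


@dataclass
class FiberState:
    """Position and velocity of a fiber tip, in continuous voxel coords."""

    position: np.ndarray
    velocity: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)


def christoffel(
    D: np.ndarray, dG_x: np.ndarray, dG_y: np.ndarray, dG_z: np.ndarray
) -> ChristoffelSet:
    """The 18 unique Christoffel symbols from the four input tensors.

    Inputs are 6-component symmetric tensors (batched along leading
    axes): the diffusion tensor D = g^{ij} and the derivatives of the
    metric d_k g_ij.  Output has shape ``(..., 3, 6)``.
    """
    D = np.asarray(D, dtype=float)
    for name, t in (("D", D), ("dG_x", dG_x), ("dG_y", dG_y), ("dG_z", dG_z)):
        if not np.all(np.isfinite(t)):
            raise ValueError(f"non-finite components in {name}")
    Dm = sym_to_mat(D)
    # dg[..., k, i, j] = d_k g_ij
    dg = np.stack([sym_to_mat(np.asarray(g, dtype=float)) for g in (dG_x, dG_y, dG_z)], axis=-3)
    # term[..., a, b, s] = d_a g_bs + d_b g_as - d_s g_ab
    term = dg + np.swapaxes(dg, -3, -2) - np.moveaxis(dg, -3, -1)
    full = 0.5 * np.einsum("...cs,...abs->...cab", Dm, term)
    ia = [p[0] for p in LOWER_PAIRS]
    ib = [p[1] for p in LOWER_PAIRS]
    return full[..., ia, ib]


def expand_christoffel(gamma: ChristoffelSet) -> np.ndarray:
    """Expand the 18-value set to the full ``(..., 3, 3, 3)`` array."""
    gamma = np.asarray(gamma, dtype=float)
    return gamma[..., SYM_INDEX]


def geodesic_rhs(velocity: np.ndarray, gamma: ChristoffelSet) -> np.ndarray:
    """Acceleration of the geodesic ODE: -Gamma^c_ab v^a v^b.

    The double sum runs over the 18 unique symbols; off-diagonal
    lower-index pairs contribute twice.  Even in the velocity:
    rhs(-v) == rhs(v).
    """
    v = np.asarray(velocity, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    q = np.stack(
        [
            v[..., 0] * v[..., 0],
            2.0 * v[..., 0] * v[..., 1],
            2.0 * v[..., 0] * v[..., 2],
            v[..., 1] * v[..., 1],
            2.0 * v[..., 1] * v[..., 2],
            v[..., 2] * v[..., 2],
        ],
        axis=-1,
    )
    return -np.einsum("...cp,...p->...c", gamma, q)


def _accel(positions: np.ndarray, velocities: np.ndarray, provider: FieldProvider) -> np.ndarray:
    """Voxel-coordinate acceleration at ``(N, 3)`` positions.

    The geodesic equation lives in physical coordinates; for non-unit
    voxel spacing the velocity is scaled into physical units before the
    quadratic form and the acceleration scaled back.
    """
    d, gx, gy, gz = provider.evaluate_many(positions)
    gamma = christoffel(d, gx, gy, gz)
    s = np.asarray(provider.spacing, dtype=float)
    a_phys = geodesic_rhs(velocities * s, gamma)
    return a_phys / s


def step_euler(state: FiberState, h: float, provider: FieldProvider) -> FiberState:
    """One explicit Euler step of the geodesic ODE.

    position' = position + h v;  v' = v + h * rhs(v, Gamma(position)).
    """
    p = np.atleast_2d(state.position)
    v = np.atleast_2d(state.velocity)
    if not provider.in_bounds(p)[0]:
        from .tensors import OutOfVolumeError

        raise OutOfVolumeError(f"position {state.position.tolist()} out of bounds")
    a = _accel(p, v, provider)
    return FiberState(state.position + h * state.velocity, state.velocity + h * a[0])


def step_rk2(state: FiberState, h: float, provider: FieldProvider) -> FiberState:
    """One midpoint (second-order Runge-Kutta) step of the geodesic ODE.

    Half an Euler step to the midpoint state, then a full step using
    the midpoint derivatives.  Both evaluation points must be in
    bounds.
    """
    from .tensors import OutOfVolumeError

    p = np.atleast_2d(state.position)
    v = np.atleast_2d(state.velocity)
    if not provider.in_bounds(p)[0]:
        raise OutOfVolumeError(f"position {state.position.tolist()} out of bounds")
    a1 = _accel(p, v, provider)
    pm = p + 0.5 * h * v
    vm = v + 0.5 * h * a1
    if not provider.in_bounds(pm)[0]:
        raise OutOfVolumeError(f"midpoint {pm[0].tolist()} out of bounds")
    a2 = _accel(pm, vm, provider)
    return FiberState(state.position + h * vm[0], state.velocity + h * a2[0])


def metric_length(points, metric_provider) -> float:
    """Discretized Riemannian length of a polyline.

    ``metric_provider`` maps a point to the 6-component metric tensor
    G; the length is the sum over segments of
    sqrt(dx^T G(midpoint) dx).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 3:
        raise ValueError("need an (n >= 2, 3) array of points")
    total = 0.0
    for a, b in zip(pts[:-1], pts[1:]):
        delta = b - a
        g = sym_to_mat(np.asarray(metric_provider(0.5 * (a + b)), dtype=float))
        q = float(delta @ g @ delta)
        total += np.sqrt(max(q, 0.0))
    return total
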