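"""Region-to-region post-processing: filter fibers and rank them.

Tracing many fibers in many directions from a seed region and keeping
those that reach a target region is how candidate connections between
two areas are found.  The surviving fibers are ordered by a
connectivity score.  The score is pluggable; the default shipped here
— Euclidean length over Riemannian length — is a simple stand-in that
rewards fibers running through high-diffusion corridors (metric length
shrinks where diffusion is large), not a validated connectivity
measure from the literature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

from .geodesic import metric_length
from .tensors import PrecomputedFields, interpolate_volume, invert_spd
from .tracking import Fiber

__all__ = [
    "ROI",
    "filter_through_region",
    "rank_fibers",
    "default_score",
]


@dataclass
class ROI:
    """A target region: an axis-aligned box or a boolean voxel mask."""

    kind: str = "box"
    bounds: Optional[Tuple[Tuple[float, float, float], Tuple[float, float, float]]] = None
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.kind == "box":
            if self.bounds is None:
                raise ValueError("box ROI requires bounds")
            lo = np.asarray(self.bounds[0], dtype=float)
            hi = np.asarray(self.bounds[1], dtype=float)
            if np.any(hi < lo):
                raise ValueError(f"empty box ROI: {self.bounds}")
            self.bounds = (tuple(lo), tuple(hi))
        elif self.kind == "mask":
            if self.mask is None:
                raise ValueError("mask ROI requires a boolean volume")
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.ndim != 3:
                raise ValueError("ROI mask must be 3-D")
            if not self.mask.any():
                raise ValueError("ROI mask selects no voxel")
        else:
            raise ValueError(f"unknown ROI kind {self.kind!r}")

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Membership of ``(N, 3)`` voxel-coordinate points."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if self.kind == "box":
            lo = np.asarray(self.bounds[0])
            hi = np.asarray(self.bounds[1])
            return np.all((points >= lo) & (points <= hi), axis=1)
        idx = np.rint(points).astype(np.intp)
        dims = self.mask.shape
        ok = np.all((idx >= 0) & (idx < np.asarray(dims)), axis=1)
        out = np.zeros(points.shape[0], dtype=bool)
        sel = idx[ok]
        out[ok] = self.mask[sel[:, 0], sel[:, 1], sel[:, 2]]
        return out


def filter_through_region(fibers: Sequence[Fiber], roi: ROI) -> List[Fiber]:
    """Keep fibers with at least one stored point inside the region.

    Membership is tested on stored points only (box: closed bounds;
    mask: nearest-voxel lookup); input order is preserved.
    """
    kept = []
    for fiber in fibers:
        if fiber.n_points and bool(roi.contains(fiber.points).any()):
            kept.append(fiber)
    return kept


def rank_fibers(
    fibers: Sequence[Fiber], score: Callable[[Fiber], float]
) -> List[Tuple[Fiber, float]]:
    """Order fibers by descending score, stably (ties keep input order).

    A score that comes back non-finite does not abort the ranking: the
    fiber is flagged by its NaN score and sorted after every finite
    one.
    """
    scored = []
    for i, fiber in enumerate(fibers):
        s = float(score(fiber))
        if not np.isfinite(s):
            scored.append((1, 0.0, i, fiber, float("nan")))
        else:
            scored.append((0, -s, i, fiber, s))
    scored.sort(key=lambda rec: rec[:3])
    return [(fiber, s) for _, _, _, fiber, s in scored]


def default_score(fields: PrecomputedFields, det_tol: float = 1e-12) -> Callable[[Fiber], float]:
    """Euclidean-over-Riemannian length score against a tensor volume.

    Equals 1 for any fiber under an identity metric; larger when the
    fiber follows directions of high diffusion.  A stand-in default,
    not a validated connectivity measure.
    """

    def metric_at(point: np.ndarray) -> np.ndarray:
        d6 = interpolate_volume(fields.diffusion, point[None, :])[0]
        g6, _ = invert_spd(d6, det_tol)
        return g6

    def score(fiber: Fiber) -> float:
        if fiber.n_points < 2:
            return float("nan")
        ml = metric_length(fiber.points, metric_at)
        if ml == 0.0:
            return float("nan")
        return fiber.euclidean_length() / ml

    return score
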