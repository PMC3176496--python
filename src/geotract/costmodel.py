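"""Analytic memory-traffic model of the tracking data layout.

The tracker reads four tensors per voxel (the diffusion tensor and the
three derivatives of its inverse), six unique float components each.
Per integration step it fetches the 8-voxel interpolation
neighborhood and writes one 3-component point.  These functions turn
that layout into byte counts; they describe the algorithm's data path
arithmetically and make no claim about the memory behavior of this
implementation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

__all__ = ["TrafficModel", "bytes_per_voxel", "bytes_per_step", "total_traffic"]


@dataclass
class TrafficModel:
    """Data-layout parameters; the defaults are the tracker's layout."""

    n_tensors: int = 4
    unique_elems: int = 6
    bytes_per_value: int = 4
    neighborhood: int = 8
    write_components: int = 3

    def __post_init__(self) -> None:
        for name in ("n_tensors", "unique_elems", "bytes_per_value", "neighborhood", "write_components"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def bytes_per_voxel(model: TrafficModel = TrafficModel()) -> int:
    """Stored bytes per voxel: tensors x unique elements x value size."""
    return model.n_tensors * model.unique_elems * model.bytes_per_value


def bytes_per_step(model: TrafficModel = TrafficModel()) -> Tuple[int, int]:
    """(read, write) bytes per integration step of one fiber.

    Read: the interpolation neighborhood of every input tensor.
    Write: the new fiber point.
    """
    read = model.neighborhood * bytes_per_voxel(model)
    write = model.write_components * model.bytes_per_value
    return read, write


def total_traffic(
    model: TrafficModel = TrafficModel(), n_fibers: int = 2048, n_steps: int = 4096
) -> int:
    """Total bytes moved for a run: (read + write) x fibers x steps."""
    if n_fibers < 0 or n_steps < 0:
        raise ValueError("n_fibers and n_steps must be non-negative")
    read, write = bytes_per_step(model)
    return (read + write) * n_fibers * n_steps
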