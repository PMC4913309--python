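"""Per-cell total diffuse fluorescence — the conventional comparator.

Conventional quantification sums a cell's pixel intensities over the whole
z-stack and subtracts an estimate of the field background. The background
estimator here is the column-minimum rule: for each x-column of the field
take the minimum pixel over rows, and average those minima. On a field that
is mostly cell-free this lands near the camera baseline; it is biased low by
noise minima (the minimum of ~10³ noisy pixels sits several read-noise SDs
below the mean), so per-cell net values are systematically non-negative on
blank scenes rather than zero-mean. Net values are deliberately not clipped
at zero: clipping would break linearity and bias the digitized-vs-diffuse
signal-to-noise comparison this module exists to support.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .imgio import ImageStack

__all__ = [
    "CellRecord",
    "global_background",
    "stack_backgrounds",
    "diffuse_per_cell",
]


@dataclass
class CellRecord:
    """Per-cell measurements carried through to the output table."""

    field_id: str
    cell_id: int
    condition: str
    qd_count: int
    diffuse_net: float
    marker_intensity: float = float("nan")
    flags: str = ""

    def __post_init__(self) -> None:
        if self.qd_count < 0:
            raise ValueError("qd_count must be >= 0")


def global_background(field_image: np.ndarray) -> float:
    """Column-minimum global background of one 2D field image.

    For each x-column, take the minimum pixel value over the y rows; return
    the mean of these column minima.
    """
    img = np.asarray(field_image)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("field_image must be a non-empty 2D array")
    return float(img.min(axis=0).mean())


def stack_backgrounds(stack: ImageStack, mode: str = "per_slice") -> np.ndarray:
    """Per-slice background scalars for a stack.

    ``per_slice`` (default) applies the column-minimum rule to every slice
    independently; ``max_projection`` computes one value on the maximum
    projection and repeats it for all slices.
    """
    if mode == "per_slice":
        return np.array([global_background(sl) for sl in stack.voxels], dtype=float)
    if mode == "max_projection":
        bg = global_background(stack.voxels.max(axis=0))
        return np.full(stack.n_slices, bg, dtype=float)
    raise ValueError("mode must be 'per_slice' or 'max_projection'")


def diffuse_per_cell(stack: ImageStack, region, backgrounds: Sequence[float]) -> float:
    """Net summed fluorescence of one cell over the whole z-stack.

    diffuse_net = Σ_slices Σ_footprint intensity − Σ_slices background_z × area.
    The same 2D footprint is used for every slice. ``region`` is a
    :class:`qdcount.segmentation.CellRegion` or a boolean footprint mask of
    the field shape.
    """
    backgrounds = np.asarray(backgrounds, dtype=float)
    if backgrounds.shape != (stack.n_slices,):
        raise ValueError("backgrounds must provide one scalar per slice")
    if hasattr(region, "footprint"):
        mask = region.footprint(stack.field_shape)
    else:
        mask = np.asarray(region, dtype=bool)
    if mask.shape != stack.field_shape:
        raise ValueError("footprint shape does not match the field")
    area = int(mask.sum())
    if area == 0:
        raise ValueError("cell footprint is empty")
    ys, xs = np.nonzero(mask)
    total = float(stack.voxels[:, ys, xs].sum(dtype=np.float64))
    return total - float(backgrounds.sum()) * area
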