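"""Reading and writing image stacks, cell outlines and per-cell tables.

Coordinate convention, fixed once for all localization math: pixel indices
are 0-based, (x, y) = (column, row), sub-pixel positions are continuous with
pixel centers at integer coordinates. Outline polygons rasterize to masks by
the pixel-center rule: a pixel belongs to a cell iff its center lies inside
or on the polygon boundary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import Polygon

log = logging.getLogger(__name__)

DEFAULT_PIXEL_SIZE = 160.0  # nm, used when a file carries no calibration
DEFAULT_SLICE_SPACING = 300.0  # nm

CELL_TABLE_COLUMNS = [
    "field_id",
    "cell_id",
    "condition",
    "qd_count",
    "diffuse_net",
    "marker_intensity",
    "flags",
]


@dataclass(frozen=True)
class ImageStack:
    """One channel's 3D intensity volume, indexed (z, y, x), with calibration."""

    voxels: np.ndarray
    pixel_size: float  # nm
    slice_spacing: float  # nm
    channel_label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 3 or v.shape[0] < 1:
            raise ValueError("voxels must be a (z, y, x) array with >= 1 slice")
        if np.issubdtype(v.dtype, np.floating) and np.any(v < 0):
            raise ValueError("intensities must be non-negative")
        if self.pixel_size <= 0 or self.slice_spacing <= 0:
            raise ValueError("calibration values must be positive")
        object.__setattr__(self, "voxels", v)

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def field_shape(self) -> tuple[int, int]:
        return self.voxels.shape[1], self.voxels.shape[2]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: ImageStack, path) -> None:
    """Write a plain multi-page grayscale TIFF plus a JSON calibration sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.voxels, photometric="minisblack")
    meta = {
        "pixel_size_nm": stack.pixel_size,
        "slice_spacing_nm": stack.slice_spacing,
        "channel_label": stack.channel_label,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_stack(path, pixel_size: float | None = None, slice_spacing: float | None = None,
               channel_label: str | None = None) -> ImageStack:
    """Read a multi-page TIFF into an ImageStack.

    Calibration is taken from explicit arguments first, then from the JSON
    sidecar written by :func:`write_stack`, then from package defaults with
    a logged warning. Page shapes must agree.
    """
    path = Path(path)
    try:
        voxels = tifffile.imread(path)
    except Exception as exc:  # unreadable/corrupt file
        raise IOError(f"cannot read TIFF stack {path}: {exc}") from exc
    voxels = np.asarray(voxels)
    if voxels.ndim == 2:
        voxels = voxels[None, :, :]
    if voxels.ndim != 3:
        raise IOError(f"{path}: pages do not form a single (z, y, x) stack")

    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    px = pixel_size if pixel_size is not None else meta.get("pixel_size_nm")
    dz = slice_spacing if slice_spacing is not None else meta.get("slice_spacing_nm")
    label = channel_label if channel_label is not None else meta.get("channel_label", "")
    if px is None or dz is None:
        log.warning(
            "%s: no calibration metadata; falling back to defaults (%g nm px, %g nm dz)",
            path, DEFAULT_PIXEL_SIZE, DEFAULT_SLICE_SPACING,
        )
        px = DEFAULT_PIXEL_SIZE if px is None else px
        dz = DEFAULT_SLICE_SPACING if dz is None else dz
    return ImageStack(voxels=voxels, pixel_size=float(px), slice_spacing=float(dz),
                      channel_label=label)


def write_cell_table(records, path) -> None:
    """Write per-cell records as CSV with a stable column order.

    ``records`` is a list of :class:`qdcount.diffuse.CellRecord` or a
    DataFrame with the same columns. Duplicate (field_id, cell_id) keys are
    rejected.
    """
    from .diffuse import CellRecord  # record type lives with the quantification

    if isinstance(records, pd.DataFrame):
        df = records.reindex(columns=CELL_TABLE_COLUMNS)
    else:
        df = pd.DataFrame(
            [
                {
                    "field_id": r.field_id,
                    "cell_id": r.cell_id,
                    "condition": r.condition,
                    "qd_count": r.qd_count,
                    "diffuse_net": r.diffuse_net,
                    "marker_intensity": r.marker_intensity,
                    "flags": r.flags,
                }
                for r in records
            ],
            columns=CELL_TABLE_COLUMNS,
        )
    if df.duplicated(subset=["field_id", "cell_id"]).any():
        dupes = df[df.duplicated(subset=["field_id", "cell_id"], keep=False)]
        raise ValueError(f"duplicate (field_id, cell_id) keys:\n{dupes}")
    df.to_csv(path, index=False)


def read_cell_table(path) -> pd.DataFrame:
    """Read a per-cell CSV back; numeric columns round-trip losslessly."""
    df = pd.read_csv(
        path,
        dtype={"field_id": str, "condition": str, "flags": str},
        float_precision="round_trip",
    )
    missing = [c for c in CELL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise IOError(f"{path}: missing cell-table columns {missing}")
    return df[CELL_TABLE_COLUMNS]


# ---------------------------------------------------------------------------
# Cell outlines


def _validate_outline(cell_id, verts: np.ndarray) -> None:
    if verts.shape[0] < 3:
        raise ValueError(f"cell {cell_id}: outline needs >= 3 vertices")
    poly = Polygon(verts)
    if not poly.is_valid or poly.area == 0:
        raise ValueError(f"cell {cell_id}: outline is not a simple closed polygon")


def write_outlines(outlines: dict[int, np.ndarray], path) -> None:
    """Write ordered boundary vertices, one row per vertex.

    ``outlines`` maps cell id -> (k, 2) array of (x, y) vertices.
    """
    rows = []
    for cell_id in sorted(outlines):
        verts = np.asarray(outlines[cell_id], dtype=float)
        _validate_outline(cell_id, verts)
        for k, (x, y) in enumerate(verts):
            rows.append({"cell_id": cell_id, "vertex": k, "x": x, "y": y})
    pd.DataFrame(rows, columns=["cell_id", "vertex", "x", "y"]).to_csv(path, index=False)


def read_outlines(path) -> dict[int, np.ndarray]:
    """Read outlines written by :func:`write_outlines`, preserving vertex order."""
    df = pd.read_csv(path, float_precision="round_trip")
    out: dict[int, np.ndarray] = {}
    for cell_id, grp in df.groupby("cell_id", sort=True):
        verts = grp.sort_values("vertex")[["x", "y"]].to_numpy(float)
        _validate_outline(cell_id, verts)
        out[int(cell_id)] = verts
    return out


def outlines_to_labels(outlines: dict[int, np.ndarray], shape: tuple[int, int]) -> np.ndarray:
    """Rasterize outline polygons to a labeled mask.

    A pixel belongs to a cell iff its center (integer coordinate) lies inside
    or on the polygon boundary. Where polygons share boundary pixels, the
    lowest cell id wins (deterministic).
    """
    ny, nx = shape
    labels = np.zeros((ny, nx), dtype=np.int32)
    for cell_id in sorted(outlines):
        verts = np.asarray(outlines[cell_id], dtype=float)
        _validate_outline(cell_id, verts)
        poly = Polygon(verts)
        x0 = max(0, int(np.floor(verts[:, 0].min())))
        x1 = min(nx - 1, int(np.ceil(verts[:, 0].max())))
        y0 = max(0, int(np.floor(verts[:, 1].min())))
        y1 = min(ny - 1, int(np.ceil(verts[:, 1].max())))
        if x1 < x0 or y1 < y0:
            continue
        yy, xx = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
        inside = shapely.intersects_xy(poly, xx.ravel(), yy.ravel()).reshape(xx.shape)
        block = labels[y0 : y1 + 1, x0 : x1 + 1]
        block[inside & (block == 0)] = cell_id
    return labels
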