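"""Reading, writing and normalisation of silhouette masks.

The pipeline's sole image input is a per-frame binary instance mask of a
single animal, stored as an 8-bit PNG (0/255 in practice).  This module
loads such rasters, rasterises polygon annotations, reduces a raster to
its largest connected component, traces the silhouette boundary, and
writes the final measurement table.

Conventions: coordinates are 0-based with x to the right and y downward
(image convention); pixel regions and rectangle bounds are half-open
``[lo, hi)``.  Components are 8-connected; a boundary pixel is a
foreground pixel with at least one background or out-of-frame 4-neighbor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .errors import EmptyMaskError, ValidationError

log = logging.getLogger(__name__)

# 8-connectivity structuring element for component labelling
_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class BinaryMask:
    """A 2-D boolean silhouette raster.

    ``grid`` is indexed ``[y, x]`` (row-major, image convention); the
    ``(x, y)`` accessors used throughout the pipeline go through
    :meth:`at`.
    """

    grid: np.ndarray  # bool, shape (height, width)

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=bool)
        if g.ndim != 2 or g.shape[0] == 0 or g.shape[1] == 0:
            raise ValidationError(f"mask must be a non-degenerate 2-D raster, got shape {g.shape}")
        object.__setattr__(self, "grid", g)

    @property
    def width(self) -> int:
        return self.grid.shape[1]

    @property
    def height(self) -> int:
        return self.grid.shape[0]

    @property
    def pixel_count(self) -> int:
        return int(self.grid.sum())

    def at(self, x: int, y: int) -> bool:
        return bool(self.grid[y, x])

    def xy_true(self) -> np.ndarray:
        """(n, 2) array of (x, y) coordinates of foreground pixels."""
        ys, xs = np.nonzero(self.grid)
        return np.column_stack([xs, ys])


@dataclass(frozen=True)
class Contour:
    """Ordered closed boundary of a single-component mask.

    ``points`` is an (n, 2) integer array of (x, y) pixel coordinates in
    clockwise order as seen on screen (y down); the traversal implicitly
    returns to ``points[0]``.
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.points)
        if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] < 3:
            raise ValidationError("contour needs >= 3 (x, y) points")
        if np.any(np.all(p == np.roll(p, -1, axis=0), axis=1)):
            raise ValidationError("contour has consecutive duplicate points")
        object.__setattr__(self, "points", p)

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class FrameSequence:
    """Frames of one animal passing the capture channel, one view."""

    animal_id: str
    view: str  # "side" | "back"
    frames: list[tuple[int, BinaryMask]] = field(default_factory=list)

    def __post_init__(self) -> None:
        idx = [i for i, _ in self.frames]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValidationError("frame indices must be strictly increasing")
        shapes = {m.grid.shape for _, m in self.frames}
        if len(shapes) > 1:
            raise ValidationError(f"all frames must share one resolution, got {shapes}")


def load_mask(path: str | Path, threshold: int = 128) -> BinaryMask:
    """Load an 8-bit PNG (gray or RGB) and binarise it.

    A pixel is foreground iff its gray value (luma for RGB) is
    ``>= threshold``.
    """
    if not 1 <= threshold <= 255:
        raise ValidationError(f"threshold must be in [1, 255], got {threshold}")
    with Image.open(path) as im:
        gray = im.convert("L")  # ITU-R 601-2 luma for RGB inputs
        arr = np.asarray(gray)
    if arr.size == 0:
        raise ValidationError(f"zero-area image: {path}")
    return BinaryMask(arr >= threshold)


def rasterize_polygons(
    annotation: dict, width: int | None = None, height: int | None = None
) -> BinaryMask:
    """Rasterise a polygon-annotation record to a mask.

    ``annotation`` follows the labelling-tool JSON dialect: a dict with
    ``shapes`` (each with a ``points`` list of [x, y] vertices) and
    ``imageWidth`` / ``imageHeight``.  A pixel ``(x, y)`` is foreground
    iff its center ``(x + 0.5, y + 0.5)`` lies inside any polygon
    (even-odd rule); overlapping polygons union.
    """
    from matplotlib.path import Path as MplPath

    width = int(width if width is not None else annotation["imageWidth"])
    height = int(height if height is not None else annotation["imageHeight"])
    if width <= 0 or height <= 0:
        raise ValidationError("frame dimensions must be positive")

    grid = np.zeros((height, width), dtype=bool)
    shapes = annotation.get("shapes", [])
    if shapes:
        xs, ys = np.meshgrid(np.arange(width) + 0.5, np.arange(height) + 0.5)
        centers = np.column_stack([xs.ravel(), ys.ravel()])
        for shape in shapes:
            pts = np.asarray(shape["points"], dtype=float)
            if len(np.unique(pts, axis=0)) < 3:
                raise ValidationError("degenerate polygon: fewer than 3 distinct vertices")
            inside = MplPath(pts).contains_points(centers)
            grid |= inside.reshape(height, width)
    return BinaryMask(grid)


def _label8(grid: np.ndarray) -> tuple[np.ndarray, int]:
    return ndimage.label(grid, structure=_STRUCT8)


def largest_component(mask: BinaryMask) -> BinaryMask:
    """Keep only the 8-connected component with the most pixels.

    Ties are broken by the component whose top-left-most pixel comes
    first in row-major order.
    """
    if mask.pixel_count == 0:
        raise EmptyMaskError("cannot extract a component from an empty mask")
    labels, n = _label8(mask.grid)
    if n == 1:
        return mask
    log.warning("mask has %d components; keeping the largest", n)
    sizes = ndimage.sum_labels(mask.grid, labels, index=np.arange(1, n + 1))
    best = np.flatnonzero(sizes == sizes.max()) + 1
    if len(best) > 1:
        # row-major first pixel decides the tie
        flat = labels.ravel()
        firsts = [np.argmax(flat == lab) for lab in best]
        best = [best[int(np.argmin(firsts))]]
    return BinaryMask(labels == best[0])


# Moore-neighbourhood offsets in clockwise screen order (y down),
# starting from "west".
_MOORE = [(-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1), (0, 1), (-1, 1)]


def _is_boundary(grid: np.ndarray, x: int, y: int) -> bool:
    h, w = grid.shape
    for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        nx, ny = x + dx, y + dy
        if not (0 <= nx < w and 0 <= ny < h) or not grid[ny, nx]:
            return True
    return False


def extract_contour(mask: BinaryMask) -> Contour:
    """Trace the silhouette boundary clockwise (as seen with y down).

    Moore-neighbour tracing from the top-left-most foreground pixel,
    keeping the interior on the right of travel; revisited pixels on
    one-pixel-wide necks are collapsed so each boundary pixel appears
    once, in traversal order.
    """
    grid = mask.grid
    if not grid.any():
        raise EmptyMaskError("cannot trace an empty mask")
    _, n = _label8(grid)
    if n != 1:
        raise ValidationError(f"contour requires a single component, found {n}")

    ys, xs = np.nonzero(grid)
    start_i = np.lexsort((xs, ys))[0]
    start = (int(xs[start_i]), int(ys[start_i]))

    h, w = grid.shape

    def fg(x: int, y: int) -> bool:
        return 0 <= x < w and 0 <= y < h and grid[y, x]

    # Raster-scan order guarantees the pixel west of `start` is empty, so
    # the trace "enters" start from the west; scanning the Moore
    # neighbourhood clockwise from the backtrack pixel keeps the interior
    # on the right of travel (clockwise on screen with y down).
    path: list[tuple[int, int]] = [start]
    cur = start
    back = (start[0] - 1, start[1])  # last background pixel examined
    for _ in range(8 * len(xs) + 8):
        i = _MOORE.index((back[0] - cur[0], back[1] - cur[1]))
        nxt = None
        for k in range(1, 9):
            d = (i + k) % 8
            cand = (cur[0] + _MOORE[d][0], cur[1] + _MOORE[d][1])
            if fg(*cand):
                nxt = cand
                break
            back = cand
        if nxt is None:  # isolated pixel
            break
        cur = nxt
        if cur == start:
            break
        path.append(cur)

    # collapse revisits (1-px necks): keep first occurrence, preserve order
    seen: set[tuple[int, int]] = set()
    uniq = [p for p in path if not (p in seen or seen.add(p))]
    if len(uniq) < 3:
        raise ValidationError("contour needs >= 3 points; silhouette too small")
    return Contour(np.asarray(uniq, dtype=int))


MEASUREMENT_COLUMNS = [
    "ear_tag",
    "frame",
    "posture",
    "angle_deg",
    "bsl_px",
    "wh_px",
    "hh_px",
    "cd_px",
    "bsl_cm",
    "wh_cm",
    "hh_cm",
    "cd_cm",
    "flags",
]


_NUMERIC_COLUMNS = ["angle_deg", "bsl_px", "wh_px", "hh_px", "cd_px",
                    "bsl_cm", "wh_cm", "hh_cm", "cd_cm"]


def write_measurements(records: Iterable[dict], path: str | Path) -> None:
    """Write measurement records as a UTF-8 CSV with a fixed 13-column
    schema; floats rendered with 2 decimals, missing values blank."""
    df = pd.DataFrame(list(records), columns=MEASUREMENT_COLUMNS)
    for col in _NUMERIC_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df.to_csv(path, index=False, float_format="%.2f", encoding="utf-8")


def list_animal_dirs(root: str | Path, view: str = "side") -> list[Path]:
    """Ear-tag folders under ``root`` that contain the requested view."""
    root = Path(root)
    if not root.is_dir():
        raise ValidationError(f"not a directory: {root}")
    return sorted(p for p in root.iterdir() if (p / view).is_dir())


def read_animal_dir(tag_dir: str | Path, view: str = "side",
                    threshold: int = 128) -> FrameSequence:
    """Read one animal's ``<tag>/<view>/<frame_index>.png`` frames."""
    tag_dir = Path(tag_dir)
    frames = []
    for png in sorted((tag_dir / view).glob("*.png"), key=lambda p: int(p.stem)):
        frames.append((int(png.stem), load_mask(png, threshold)))
    if not frames:
        raise ValidationError(f"no frames under {tag_dir / view}")
    return FrameSequence(tag_dir.name, view, frames)


def read_frame_tree(
    root: str | Path, view: str = "side", threshold: int = 128
) -> list[FrameSequence]:
    """Read a ``<root>/<ear_tag>/<view>/<frame_index>.png`` capture tree."""
    return [read_animal_dir(d, view, threshold)
            for d in list_animal_dirs(root, view)]
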