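"""Pure geometric primitives underlying the posture and body-size statistics.

Everything here operates on plain point arrays or on :class:`BinaryMask`
and is free of any anatomy: convex hull, axis-aligned and minimum-area
bounding rectangles, the maximal axis-aligned inscribed rectangle of a
mask (histogram-per-row + monotonic stack), U-chord-length curvature of a
digital contour, and point-to-line distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .errors import DegenerateGeometryError, EmptyMaskError, ValidationError
from .mask_io import BinaryMask, Contour


@dataclass(frozen=True)
class AxisRect:
    """Axis-aligned rectangle with half-open pixel bounds."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValidationError(f"degenerate AxisRect {self}")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def area(self) -> int:
        return self.width * self.height


@dataclass(frozen=True)
class RotatedRect:
    """Oriented rectangle; ``angle_deg`` is the orientation of the long
    side against the image horizontal, normalised to [-90, 90)."""

    center: tuple[float, float]
    long_side: float
    short_side: float
    angle_deg: float

    def __post_init__(self) -> None:
        if not (self.long_side >= self.short_side > 0):
            raise ValidationError("RotatedRect requires long_side >= short_side > 0")

    @property
    def area(self) -> float:
        return self.long_side * self.short_side

    def corners(self) -> np.ndarray:
        """(4, 2) corner coordinates in order around the rectangle."""
        a = math.radians(self.angle_deg)
        u = np.array([math.cos(a), math.sin(a)])  # long axis
        v = np.array([-math.sin(a), math.cos(a)])  # short axis
        c = np.asarray(self.center)
        hl, hs = self.long_side / 2, self.short_side / 2
        return np.array([c - hl * u - hs * v, c + hl * u - hs * v,
                         c + hl * u + hs * v, c - hl * u + hs * v])


@dataclass(frozen=True)
class CurvatureSample:
    """Signed U-chord curvature at one contour point.

    ``c = s * sqrt(1 - D^2 / (2U)^2)`` where ``D`` is the distance
    between the backward and forward chord neighbours ``p_ib``/``p_if``
    and ``s`` the turn sign; ``c`` is 0 for a straight run and ``|c|``
    approaches 1 for a hairpin.
    """

    index: int
    c: float
    s: int
    D: float
    p_back: tuple[float, float]
    p_fwd: tuple[float, float]


def convex_hull(points: np.ndarray) -> np.ndarray:
    """Convex-hull vertices in counterclockwise traversal order
    (mathematical convention; clockwise on screen with y down), with
    collinear triples removed."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise DegenerateGeometryError("convex hull needs >= 3 (x, y) points")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise DegenerateGeometryError(f"degenerate point set: {exc}") from exc
    return pts[hull.vertices]


def bounding_rect(points: np.ndarray) -> AxisRect:
    """Tight axis-aligned bounds; max side exclusive."""
    pts = np.asarray(points)
    if pts.size == 0:
        raise ValidationError("bounding_rect of empty point set")
    x0, y0 = np.floor(pts.min(axis=0)).astype(int)
    x1, y1 = np.floor(pts.max(axis=0)).astype(int) + 1
    return AxisRect(int(x0), int(y0), int(x1), int(y1))


def min_area_rect(points: np.ndarray) -> RotatedRect:
    """Minimum-area enclosing rectangle by rotating calipers over the
    convex-hull edges.

    Among orientations whose areas tie within 1e-9, the smallest
    ``|angle|`` wins; the angle reported is that of the long side,
    normalised to [-90, 90).
    """
    hull = convex_hull(points)  # raises on degenerate input
    n = len(hull)
    edges = np.roll(hull, -1, axis=0) - hull
    best = None  # (area, |angle|, rect fields)
    for i in range(n):
        ex, ey = edges[i]
        norm = math.hypot(ex, ey)
        if norm == 0:
            continue
        u = np.array([ex, ey]) / norm        # edge direction
        v = np.array([-u[1], u[0]])          # normal
        pu = hull @ u
        pv = hull @ v
        w_u = pu.max() - pu.min()
        w_v = pv.max() - pv.min()
        area = w_u * w_v
        # long side defines the reported angle
        if w_u >= w_v:
            long_s, short_s = w_u, w_v
            ang = math.degrees(math.atan2(u[1], u[0]))
        else:
            long_s, short_s = w_v, w_u
            ang = math.degrees(math.atan2(v[1], v[0]))
        ang = (ang + 90.0) % 180.0 - 90.0  # [-90, 90)
        cu = (pu.max() + pu.min()) / 2
        cv = (pv.max() + pv.min()) / 2
        center = tuple(cu * u + cv * v)
        cand = (area, abs(ang), center, long_s, short_s, ang)
        if best is None or area < best[0] - 1e-9:
            best = cand
        elif abs(area - best[0]) <= 1e-9 and abs(ang) < best[1]:
            best = cand
    assert best is not None
    _, _, center, long_s, short_s, ang = best
    return RotatedRect(center=center, long_side=float(long_s),
                       short_side=float(max(short_s, 1e-12)), angle_deg=float(ang))


def max_inscribed_rect(mask: BinaryMask) -> AxisRect:
    """Largest axis-aligned all-foreground rectangle of the mask.

    Classic maximal-rectangle algorithm: per row, a histogram of
    consecutive foreground heights per column; per histogram, the largest
    rectangle via a monotonic stack.  Ties in area are broken by the
    smallest ``(y0, x0, y1, x1)``.
    """
    grid = mask.grid
    if not grid.any():
        raise EmptyMaskError("max_inscribed_rect of an empty mask")
    h, w = grid.shape
    heights = np.zeros(w, dtype=int)
    best: tuple | None = None  # (-area, y0, x0, y1, x1)
    for row in range(h):
        heights = np.where(grid[row], heights + 1, 0)
        # largest rectangle in histogram `heights`, bar width 1
        stack: list[int] = []  # indices with increasing heights
        for col in range(w + 1):
            cur = heights[col] if col < w else 0
            while stack and heights[stack[-1]] >= cur:
                top = stack.pop()
                hgt = int(heights[top])
                left = stack[-1] + 1 if stack else 0
                if hgt == 0:
                    continue
                area = hgt * (col - left)
                key = (-area, row - hgt + 1, left, row + 1, col)
                if best is None or key < best:
                    best = key
            stack.append(col)
    assert best is not None
    _, y0, x0, y1, x1 = best
    return AxisRect(x0, y0, x1, y1)


def u_chord_curvature(contour: Contour, i: int, U: float) -> CurvatureSample:
    """Signed U-chord-length curvature at contour index ``i``.

    The backward (forward) chord neighbour is the contour point whose
    Euclidean distance from ``p_i`` is nearest to ``U`` among points
    reached walking backward (forward) along the closed contour; ties go
    to the farther walk.  With ``D`` the distance between the two
    neighbours, ``c = s * sqrt(max(0, 1 - D^2/(4 U^2)))`` and ``s`` is the
    sign of the cross product of (p_i - p_back) x (p_fwd - p_back):
    positive for a bump that is convex toward smaller y (upward on
    screen) when traversal is clockwise on screen.
    """
    if U <= 0:
        raise ValidationError(f"chord constant U must be positive, got {U}")
    pts = np.asarray(contour.points, dtype=float)
    n = len(pts)
    if n < 5:
        raise ValidationError("u_chord_curvature needs a contour of >= 5 points")
    i = int(i) % n
    p = pts[i]

    # Walks are capped at half the contour so the neighbour search cannot
    # wrap around and approach p_i from the other side.
    half = max(2, n // 2)
    order_f = (i + np.arange(1, half + 1)) % n      # forward walk
    order_b = (i - np.arange(1, half + 1)) % n      # backward walk

    def pick(order: np.ndarray) -> np.ndarray:
        d = np.linalg.norm(pts[order] - p, axis=1)
        # candidates: points walked until the chord distance first
        # reaches U (inclusive); the whole walk if it never does
        crossed = np.flatnonzero(d >= U)
        stop = crossed[0] + 1 if len(crossed) else len(order)
        dev = np.abs(d[:stop] - U)
        m = dev.min()
        # ties (within fp eps) -> farther walk = larger step index
        k = np.flatnonzero(dev <= m + 1e-9)[-1]
        return pts[order[k]]

    p_b = pick(order_b)
    p_f = pick(order_f)
    D = float(np.linalg.norm(p_f - p_b))
    cross = (p[0] - p_b[0]) * (p_f[1] - p_b[1]) - (p_f[0] - p_b[0]) * (p[1] - p_b[1])
    if abs(cross) < 1e-12:
        s = 0
    else:
        s = 1 if cross > 0 else -1
    c = s * math.sqrt(max(0.0, 1.0 - D * D / (4.0 * U * U)))
    return CurvatureSample(index=i, c=float(c), s=s, D=D,
                           p_back=tuple(p_b), p_fwd=tuple(p_f))


def point_line_distance(p, a, b) -> float:
    """Perpendicular distance from ``p`` to the infinite line through
    ``a`` and ``b``."""
    p = np.asarray(p, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ab = b - a
    norm = np.linalg.norm(ab)
    if norm == 0:
        raise ValidationError("line endpoints coincide")
    return float(abs(ab[0] * (p[1] - a[1]) - ab[1] * (p[0] - a[0])) / norm)
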