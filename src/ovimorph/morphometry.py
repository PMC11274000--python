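"""Anatomical landmark detection and pixel body measures.

Four body measures are taken from a side-view silhouette of a standing
or walking animal (jumping frames are excluded — the skeleton is not in
a measurable configuration):

* **BSL** (body slanting length): the diagonal of the maximal inscribed
  axis-aligned rectangle of the silhouette, a proxy for the
  shoulder-to-ischium slant length.
* **WH** (withers height): vertical distance from the withers landmark
  to the ground line.
* **HH** (hip height): vertical distance from the hip landmark to the
  ground line.
* **CD** (chest depth): distance from the withers landmark to the
  head-side lower corner of the inscribed rectangle (sternum proxy).

Landmark rules switch on posture.  Head-down: the scapula and hip bones
protrude, so the withers and hip are the points of maximal convex
U-chord curvature inside fractional windows of the horizontal extent S
(withers 3/8-4/8 S, hip 6/8-7/8 S, measured from the head-side
boundary).  Head-up: the hip is the convex-hull apex in the rear window
and the withers is the dorsal point farthest from "line A" joining the
head top to the shoulder (head-side top corner of the inscribed
rectangle).

All left/right phrases map through ``head_side``; the default
(head toward image left) makes "rear" = image right.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .errors import LandmarkNotFoundError, UnsupportedPostureError, ValidationError
from .geometry import (convex_hull, max_inscribed_rect, point_line_distance,
                       u_chord_curvature)
from .mask_io import BinaryMask, Contour, extract_contour

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LandmarkConfig:
    """Tunables of the landmark search.

    ``u_px`` (the chord constant of the curvature statistic) defaults to
    5% of the silhouette length S with a floor of 5 px, so the statistic
    reads curvature at the scale of the dorsal prominences rather than of
    pixel jitter.
    """

    withers_window: tuple[float, float] = (3 / 8, 4 / 8)
    hip_window: tuple[float, float] = (6 / 8, 7 / 8)
    u_px: float | None = None  # None -> max(5, 0.05 * S)
    min_curvature: float = 0.02
    ground_mode: str = "mask_bottom"  # "mask_bottom" | "fixed_row"
    ground_row: int | None = None
    chest_mode: str = "front_lower"  # "front_lower" | "rear_upper"
    head_side: str = "left"

    def __post_init__(self) -> None:
        for w in (self.withers_window, self.hip_window):
            if not (0 <= w[0] < w[1] <= 1):
                raise ValidationError(f"invalid fractional window {w}")
        if self.ground_mode == "fixed_row" and self.ground_row is None:
            raise ValidationError("fixed_row ground mode needs ground_row")

    def chord_u(self, S: float) -> float:
        return self.u_px if self.u_px is not None else max(5.0, 0.05 * S)


class LandmarkSet(NamedTuple):
    withers: tuple[float, float]
    hip: tuple[float, float]
    bsl_p1: tuple[float, float]
    bsl_p2: tuple[float, float]
    head: tuple[float, float]
    ground_y: float


@dataclass
class MeasurementRecord:
    animal_id: str
    posture: str
    bsl_px: float
    wh_px: float
    hh_px: float
    cd_px: float
    bsl_cm: float | None = None
    wh_cm: float | None = None
    hh_cm: float | None = None
    cd_cm: float | None = None
    landmarks: LandmarkSet | None = None


def _extent(contour: Contour) -> tuple[float, float, float, float]:
    pts = np.asarray(contour.points)
    return (float(pts[:, 0].min()), float(pts[:, 0].max()),
            float(pts[:, 1].min()), float(pts[:, 1].max()))


def _window_abs(window, x_min, x_max, head_side) -> tuple[float, float]:
    """Fractional window -> absolute x range, measured from the head-side
    boundary (half-open toward the rear)."""
    S = x_max - x_min
    lo, hi = window
    if head_side == "left":
        return x_min + lo * S, x_min + hi * S
    return x_max - hi * S, x_max - lo * S


def hip_point_headup(contour: Contour, head_side: str = "left") -> tuple[float, float]:
    """Hip landmark for raised-head (or level) postures: the rump apex.

    Candidates are convex-hull vertices of the contour in the upper half
    of the silhouette (y above the vertical midpoint).  Among candidates
    inside the rear hip window (6/8-7/8 of S from the head side) the
    highest wins (ties toward the rear); when the window holds no hull
    vertex — e.g. a plain rectangle — the rear-most upper-half vertex
    wins (ties toward the top), which recovers the rear-top corner.
    """
    pts = np.asarray(contour.points, dtype=float)
    hull = convex_hull(pts)
    x_min, x_max, y_min, y_max = _extent(contour)
    y_mid = (y_min + y_max) / 2.0
    upper = hull[hull[:, 1] < y_mid]
    if len(upper) == 0:
        raise LandmarkNotFoundError("no convex-hull vertex in the upper half")
    lo, hi = _window_abs(LandmarkConfig().hip_window, x_min, x_max, head_side)
    inwin = upper[(upper[:, 0] >= lo) & (upper[:, 0] < hi)]
    rear_sign = 1.0 if head_side == "left" else -1.0
    if len(inwin):
        order = np.lexsort((-rear_sign * inwin[:, 0], inwin[:, 1]))
        return tuple(inwin[order[0]])
    order = np.lexsort((upper[:, 1], -rear_sign * upper[:, 0]))
    return tuple(upper[order[0]])


def withers_point_headup(
    contour: Contour,
    head_top: tuple[float, float],
    shoulder: tuple[float, float],
) -> tuple[float, float]:
    """Withers landmark for the raised-head posture.

    Among contour points on the dorsal arc between ``head_top`` and
    ``shoulder``, the point with maximal perpendicular distance to line A
    (the line joining the two).  A perfectly straight dorsal line is
    degenerate; the first arc point is returned with a logged warning.
    """
    if tuple(head_top) == tuple(shoulder):
        raise ValidationError("head_top and shoulder coincide")
    pts = np.asarray(contour.points, dtype=float)
    i_head = int(np.argmin(np.linalg.norm(pts - np.asarray(head_top, float), axis=1)))
    i_sh = int(np.argmin(np.linalg.norm(pts - np.asarray(shoulder, float), axis=1)))
    if i_head == i_sh:
        # flat-topped silhouette: head top and shoulder collapse onto one
        # point; degenerate like a straight dorsal line
        log.warning("head top and shoulder coincide; withers landmark degenerate")
        return tuple(pts[i_head])
    n = len(pts)
    arc_fwd = np.arange(i_head, i_head + (i_sh - i_head) % n + 1) % n
    arc_bwd = np.arange(i_sh, i_sh + (i_head - i_sh) % n + 1) % n
    # dorsal arc = the one avoiding the lowest contour point (the feet)
    i_bottom = int(np.argmax(pts[:, 1]))
    arc = arc_bwd if i_bottom in set(arc_fwd.tolist()) else arc_fwd
    interior = arc[1:-1]
    if len(interior) < 1:
        raise LandmarkNotFoundError("dorsal arc shorter than 3 points")
    d = np.array([point_line_distance(pts[k], head_top, shoulder) for k in interior])
    if d.max() < 1e-9:
        log.warning("straight dorsal line; withers landmark degenerate")
        return tuple(pts[interior[0]])
    return tuple(pts[interior[int(np.argmax(d))]])


def dorsal_points_headdown(
    contour: Contour, cfg: LandmarkConfig | None = None
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Withers and hip landmarks for the lowered-head posture: within
    each fractional window, the upper-contour point of maximal convex
    U-chord curvature (the protruding scapula / hip bone)."""
    cfg = cfg or LandmarkConfig()
    x_min, x_max, y_min, y_max = _extent(contour)
    S = x_max - x_min
    U = cfg.chord_u(S)
    out = []
    for name, window in (("withers", cfg.withers_window), ("hip", cfg.hip_window)):
        out.append(_max_curvature_point(contour, window, cfg, name, x_min, x_max,
                                        (y_min + y_max) / 2.0, U))
    return out[0], out[1]


def _max_curvature_point(contour, window, cfg, name, x_min, x_max, y_mid, U):
    pts = np.asarray(contour.points, dtype=float)
    lo, hi = _window_abs(window, x_min, x_max, cfg.head_side)
    idx = np.flatnonzero((pts[:, 0] >= lo) & (pts[:, 0] < hi) & (pts[:, 1] < y_mid))
    if len(idx) == 0:
        raise LandmarkNotFoundError(f"no upper-contour point in the {name} window")
    best_i, best_c = None, -np.inf
    for i in idx:
        c = u_chord_curvature(contour, int(i), U).c
        if c > best_c:
            best_i, best_c = int(i), c
    if best_c < cfg.min_curvature:
        raise LandmarkNotFoundError(
            f"no convex curvature maximum in the {name} window "
            f"(max c={best_c:.4f} < {cfg.min_curvature})")
    return tuple(pts[best_i])


def bsl_points(
    mask: BinaryMask, head_side: str = "left"
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Body-slant-length endpoints: the inscribed-rectangle diagonal from
    the head-side lower corner to the rear upper corner."""
    rect = max_inscribed_rect(mask)
    if head_side == "left":
        return (float(rect.x0), float(rect.y1)), (float(rect.x1), float(rect.y0))
    return (float(rect.x1), float(rect.y1)), (float(rect.x0), float(rect.y0))


def measure(
    mask: BinaryMask,
    posture: str,
    cfg: LandmarkConfig | None = None,
    animal_id: str = "",
) -> MeasurementRecord:
    """Locate landmarks for the given posture and compute the four pixel
    measures.  ``posture`` is ``head_down`` or ``head_up``; jumping
    frames raise :class:`UnsupportedPostureError`."""
    cfg = cfg or LandmarkConfig()
    label = getattr(posture, "label", posture)
    if label == "jump":
        raise UnsupportedPostureError("body measures are not defined for jumps")
    if label not in ("head_down", "head_up"):
        raise ValidationError(f"unknown posture {label!r}")

    contour = extract_contour(mask)
    rect = max_inscribed_rect(mask)
    p1, p2 = bsl_points(mask, cfg.head_side)
    shoulder = ((float(rect.x0), float(rect.y0)) if cfg.head_side == "left"
                else (float(rect.x1), float(rect.y0)))

    if label == "head_down":
        withers, hip = dorsal_points_headdown(contour, cfg)
    else:
        hip = hip_point_headup(contour, cfg.head_side)
        head_top = _head_top(contour, shoulder, cfg)
        if tuple(head_top) == tuple(shoulder):
            # flat-topped silhouette: no head above the shoulder line
            log.warning("head top coincides with shoulder; degenerate withers")
            withers = shoulder
        else:
            withers = withers_point_headup(contour, head_top, shoulder)

    pts = np.asarray(contour.points)
    if cfg.ground_mode == "fixed_row":
        ground_y = float(cfg.ground_row)
    else:
        ground_y = float(pts[:, 1].max() + 1)  # row below the lowest hoof pixel

    chest_pt = p1 if cfg.chest_mode == "front_lower" else p2
    head = pts[np.argmin(pts[:, 0])] if cfg.head_side == "left" else \
        pts[np.argmax(pts[:, 0])]
    lm = LandmarkSet(withers=tuple(map(float, withers)), hip=tuple(map(float, hip)),
                     bsl_p1=p1, bsl_p2=p2, head=tuple(map(float, head)),
                     ground_y=ground_y)
    return MeasurementRecord(
        animal_id=animal_id, posture=label,
        bsl_px=math.dist(p1, p2),
        wh_px=ground_y - lm.withers[1],
        hh_px=ground_y - lm.hip[1],
        cd_px=math.dist(lm.withers, chest_pt),
        landmarks=lm,
    )


def _head_top(contour: Contour, shoulder, cfg: LandmarkConfig):
    """Highest contour point on the head side of the shoulder."""
    pts = np.asarray(contour.points, dtype=float)
    if cfg.head_side == "left":
        cand = pts[pts[:, 0] < shoulder[0]]
    else:
        cand = pts[pts[:, 0] > shoulder[0]]
    if len(cand) == 0:
        cand = pts
    return tuple(cand[int(np.argmin(cand[:, 1]))])
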