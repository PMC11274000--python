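"""Walking-posture classification from silhouette geometry.

Three postures are distinguished as an animal passes the capture
channel: head-down, head-up, and jumping.  A jump shows up as a rising
body, measured by the rectangle-angle statistic of the silhouette (how
far the minimum-area enclosing rectangle is rotated against the
axis-aligned one); angles above the decision-stump threshold of 8.9
degrees (fitted on real jump/walk angle data) are jumps.  Non-jumping
frames are split by comparing the head height against the hip landmark:
head above hip means head-up, otherwise head-down.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from . import morphometry
from .errors import DegenerateGeometryError, ValidationError
from .geometry import min_area_rect
from .mask_io import BinaryMask, Contour, extract_contour

#: jump decision-stump threshold (deg) fitted on channel-pass data
DEFAULT_JUMP_THRESHOLD_DEG = 8.9


@dataclass(frozen=True)
class PostureConfig:
    jump_angle_threshold_deg: float = DEFAULT_JUMP_THRESHOLD_DEG
    angle_mode: str = "diagonal"  # "diagonal" | "axis"
    head_side: str = "left"

    def __post_init__(self) -> None:
        if self.jump_angle_threshold_deg <= 0:
            raise ValidationError("jump threshold must be positive")
        if self.angle_mode not in ("axis", "diagonal"):
            raise ValidationError("angle_mode must be 'axis' or 'diagonal'")


@dataclass(frozen=True)
class PostureResult:
    label: str  # head_down | head_up | jump
    angle_deg: float
    head_point: tuple[float, float] | None = None
    hip_point: tuple[float, float] | None = None


def posture_angle(contour: Contour, mode: str = "diagonal",
                  head_side: str = "left") -> float:
    """Rectangle-angle statistic of a silhouette contour, in [0, 90] deg.

    ``diagonal`` (default): acute angle between corner-matched diagonals
    (min-(x+y) corner to max-(x+y) corner) of the minimum-area rectangle
    and of the axis-aligned bounding rectangle.  The diagonal comparison
    damps the aspect-ratio dependence and is far less sensitive to a
    raised head than the raw rectangle orientation, which keeps walking
    frames well under the jump threshold.  ``axis``: absolute
    orientation of the minimum-area rectangle's long side against the
    image horizontal — reads the body rotation directly but also picks
    up head pose.

    The matched corners run from the head-side upper region to the rear
    lower one (``x + y`` scoring for a head on the left); anchoring the
    diagonal anatomically keeps the statistic invariant under horizontal
    mirroring with ``head_side`` flipped.
    """
    pts = np.asarray(contour.points, dtype=float)
    mar = min_area_rect(pts)
    if mode == "axis":
        return abs(mar.angle_deg)
    if mode != "diagonal":
        raise ValidationError(f"unknown angle mode {mode!r}")
    sign = 1.0 if head_side == "left" else -1.0
    mar_diag = _corner_diagonal(mar.corners(), sign)
    # tight continuous bounds (not pixel-quantised) for the box diagonal
    (x0, y0), (x1, y1) = pts.min(axis=0), pts.max(axis=0)
    box_diag = _corner_diagonal(np.array(
        [[x0, y0], [x1, y0], [x1, y1], [x0, y1]]), sign)
    cosang = abs(np.dot(mar_diag, box_diag))
    return math.degrees(math.acos(min(1.0, cosang)))


def _corner_diagonal(corners: np.ndarray, sign: float = 1.0) -> np.ndarray:
    s = sign * corners[:, 0] + corners[:, 1]
    d = corners[int(np.argmax(s))] - corners[int(np.argmin(s))]
    n = np.linalg.norm(d)
    if n == 0:
        raise DegenerateGeometryError("degenerate rectangle diagonal")
    return d / n


def head_point(contour: Contour, head_side: str = "left") -> tuple[int, int]:
    """Extreme contour point on the head side; ties go to the highest
    (smallest y)."""
    pts = np.asarray(contour.points)
    xs = pts[:, 0]
    target = xs.min() if head_side == "left" else xs.max()
    cand = pts[xs == target]
    return tuple(cand[np.argmin(cand[:, 1])])


def classify_posture(mask: BinaryMask, cfg: PostureConfig | None = None) -> PostureResult:
    """Classify one silhouette frame.

    Decision order: (1) rectangle angle above threshold -> jump;
    (2) head strictly higher than the hip landmark -> head_up;
    (3) otherwise head_down (ties included: a head level with the hip is
    the majority head-down case).
    """
    cfg = cfg or PostureConfig()
    contour = extract_contour(mask)
    angle = posture_angle(contour, cfg.angle_mode, cfg.head_side)
    if angle > cfg.jump_angle_threshold_deg:
        return PostureResult("jump", angle)
    head = head_point(contour, cfg.head_side)
    hip = morphometry.hip_point_headup(contour, cfg.head_side)
    label = "head_up" if head[1] < hip[1] else "head_down"
    return PostureResult(label, angle, head_point=tuple(head), hip_point=tuple(hip))


class StumpFit(NamedTuple):
    threshold: float
    accuracy: float


def fit_jump_stump(angles: Sequence[float], labels: Sequence[bool]) -> StumpFit:
    """Fit the one-threshold jump classifier (predict jump iff
    angle > threshold) by exhaustive search over candidate cuts.

    Ties in training accuracy are resolved toward the midpoint between
    the straddling sorted angles closest to the data, then the smallest
    threshold.
    """
    angles = np.asarray(angles, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if len(angles) != len(labels) or len(angles) == 0:
        raise ValidationError("angles and labels must be equal-length and non-empty")
    if labels.all() or not labels.any():
        raise ValidationError("both classes must be present to fit the stump")
    order = np.argsort(angles)
    a_sorted = np.unique(angles[order])
    # candidate thresholds: midpoints between consecutive distinct angles
    cands = (a_sorted[:-1] + a_sorted[1:]) / 2.0
    best: tuple[float, float] | None = None  # (accuracy, -threshold)
    for thr in cands:
        acc = float(np.mean((angles > thr) == labels))
        if best is None or acc > best[0] + 1e-12 or (
                abs(acc - best[0]) <= 1e-12 and thr < -best[1]):
            best = (acc, -thr)
    assert best is not None
    return StumpFit(threshold=-best[1], accuracy=best[0])
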