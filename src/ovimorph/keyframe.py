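"""Key-frame selection by the weighted-region mask-pixel score.

A walking animal is photographed as a burst of frames; the frame in
which the silhouette is largest and most central is the one measured.
Each frame is scored as

    score = n1 * |R1 ∩ mask| + n2 * |R2 ∩ mask| + n3 * |R3 ∩ mask|

over three nested frame regions: R1 the central core (middle third in x,
central quarter in y), R2 a wider band, R3 the full frame.  The default
weights n1=10, n2=0.5, n3=0.01 reward silhouette pixels the closer they
fall to the frame center.  Regions are counted cumulatively (a central
pixel contributes to all three terms); an exclusive (annular) counting
mode is available via ``cumulative=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError
from .mask_io import BinaryMask, FrameSequence

FracRect = tuple[float, float, float, float]  # (x_lo, x_hi, y_lo, y_hi), fractions


@dataclass(frozen=True)
class RegionWeights:
    """Nested scoring regions (fractional frame coordinates, half-open)
    and their weights."""

    r1_frac: FracRect = (1 / 3, 2 / 3, 0.375, 0.625)
    r2_frac: FracRect = (1 / 6, 5 / 6, 0.25, 0.75)
    r3_frac: FracRect = (0.0, 1.0, 0.0, 1.0)
    n1: float = 10.0
    n2: float = 0.5
    n3: float = 0.01
    cumulative: bool = True

    def __post_init__(self) -> None:
        for fr in (self.r1_frac, self.r2_frac, self.r3_frac):
            xlo, xhi, ylo, yhi = fr
            if not (0 <= xlo < xhi <= 1 and 0 <= ylo < yhi <= 1):
                raise ValidationError(f"invalid fractional region {fr}")
        if min(self.n1, self.n2, self.n3) < 0:
            raise ValidationError("region weights must be non-negative")


def region_pixel_count(mask: BinaryMask, region_frac: FracRect) -> int:
    """Count foreground pixels with ``floor(lo*dim) <= coord < floor(hi*dim)``
    on each axis."""
    xlo, xhi, ylo, yhi = region_frac
    x0, x1 = int(xlo * mask.width), int(xhi * mask.width)
    y0, y1 = int(ylo * mask.height), int(yhi * mask.height)
    if x1 <= x0 or y1 <= y0:
        return 0
    return int(mask.grid[y0:y1, x0:x1].sum())


def frame_score(mask: BinaryMask, w: RegionWeights | None = None) -> float:
    """Weighted-region pixel score of one frame."""
    w = w or RegionWeights()
    c1 = region_pixel_count(mask, w.r1_frac)
    c2 = region_pixel_count(mask, w.r2_frac)
    c3 = region_pixel_count(mask, w.r3_frac)
    if not w.cumulative:
        # annular counting: each pixel contributes to its innermost region only
        c3 -= c2
        c2 -= c1
    return w.n1 * c1 + w.n2 * c2 + w.n3 * c3


def select_key_frame(
    seq: FrameSequence, w: RegionWeights | None = None
) -> tuple[int, float]:
    """Frame index with the maximal score; ties go to the smallest index."""
    if not seq.frames:
        raise ValidationError(f"empty frame sequence for animal {seq.animal_id!r}")
    w = w or RegionWeights()
    best_idx, best_score = None, -1.0
    for idx, mask in seq.frames:
        s = frame_score(mask, w)
        if best_idx is None or s > best_score:
            best_idx, best_score = idx, s
    return best_idx, best_score
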