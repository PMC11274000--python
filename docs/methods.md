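# Methods

This note documents the measurement model implemented by `ovimorph`, the
choices made where the construction was genuinely open, what the synthetic
data generator does and does not emulate, and the package's known limits.

## Problem setting

Sheep walk single file through a capture channel; a side camera records at
640 × 480 and an upstream instance-segmentation model emits one binary
silhouette mask per frame. All measurement happens on masks. Coordinates are
0-based, x rightward, y downward; intervals are half-open. Components are
8-connected, boundaries 4-defined; multi-component masks are reduced to the
largest component with a warning (one animal per frame is assumed — sheep
pass the channel one at a time).

## Key-frame score

Each frame scores `n1·|R1∩mask| + n2·|R2∩mask| + n3·|R3∩mask|` over three
nested regions of the frame: R1 = (x: 1/3–2/3, y: 0.375–0.625), R2 =
(x: 1/6–5/6, y: 1/4–3/4), R3 = the full frame, with weights 10 / 0.5 / 0.01.
Counting is cumulative — the regions are nested, and the decreasing weights
already encode the centering emphasis; an exclusive (annular) mode is
available via `RegionWeights(cumulative=False)`. Fractional bounds are
floor-quantised to pixels at the frame's resolution. The key frame is the
argmax; ties go to the earliest frame.

## Posture statistic and decision rule

A jump shows as a rising body. The statistic is the acute angle between the
corner-matched diagonals of (a) the minimum-area enclosing rectangle of the
contour (rotating calipers over the convex hull) and (b) the axis-aligned
bounding box. Corners are matched by the head-side diagonal score
(`x + y` with the head at image left), which makes the statistic invariant
under horizontal mirroring with `head_side` flipped. An alternative `axis`
mode reports the raw orientation of the minimum-area rectangle's long side.

The diagonal construction deliberately damps the rotation: for a w × h
rectangle rotated by θ it evaluates to `θ + φ − atan(sin(θ+φ)/cos(θ−φ))`
with `φ = atan(h/w)` — equal to θ for a square, smaller for elongated
shapes. On sheep-like silhouettes it crosses the decision threshold of
**8.9°** at a body tilt of ≈12.5–13°, and, unlike the axis reading, it is
only mildly inflated (~5° at zero tilt) by a raised head. Both properties
match the field behaviour the threshold was fitted to; the axis mode would
fire on head-up walkers. The threshold is consumed as a parameter;
`fit_jump_stump` refits it from labelled angles by exhaustive stump search
(ties resolved to the midpoint between the straddling angles, then the
smaller cut).

Non-jumping frames: head-up iff the head point (extreme pixel on the head
side, ties to the highest) is strictly above the hip landmark; ties are
head-down, the majority class.

## Landmarks and measures

* **Body slanting length (BSL)** — diagonal of the maximal inscribed
  axis-aligned rectangle of the mask, computed by the histogram-per-row +
  monotonic-stack algorithm (ties broken by smallest (y0, x0, y1, x1), a
  total refinement of top-left preference). The diagonal runs from the
  head-side lower corner to the rear upper corner.
* **Withers / hip, head lowered** — the scapula and hip bone protrude, so
  each landmark is the upper-contour point of maximal convex U-chord
  curvature within its fractional window of the horizontal span S
  (withers 3/8–4/8 S, hip 6/8–7/8 S, measured from the head-side boundary;
  the windows sit on either side of the mid-back, withers forward of hip).
  U-chord curvature at contour point i: walk the closed contour both ways to
  the first crossing of Euclidean distance U (ties to the farther point);
  with D the distance between the two chord neighbours,
  `c = s·√(max(0, 1 − D²/4U²))`, signed by the turn direction (collinear
  triples give c = 0). D ∈ [0, 2U] by construction, so c ∈ [−1, 1], zero on
  straight runs, |c| → 1 at a hairpin. U defaults to `max(5, 0.05·S)` px —
  the scale of the dorsal prominences, well above pixel jitter. A window
  whose best convex curvature falls below `min_curvature = 0.02` (e.g. a
  flat back) raises a landmark error rather than returning noise.
* **Hip, head raised** — convex-hull vertices on the upper half of the
  silhouette, preferring those inside the rear 6/8–7/8 S window, highest
  first (ties rearward). When the window holds no hull vertex (degenerate
  shapes such as rectangles) the rearmost upper-half vertex is used, which
  yields the rear-top corner.
* **Withers, head raised** — "line A" joins the head top to the shoulder
  (the head-side top corner of the inscribed rectangle, which touches the
  torso boundary); the withers is the dorsal-arc point farthest from line A,
  i.e. the base of the raised neck. The dorsal arc is the head-top→shoulder
  arc not containing the lowest contour point. A perfectly straight dorsal
  line (or head top collapsing onto the shoulder) is degenerate: the first
  arc point is returned with a warning.
* **Heights** — ground line = the row just below the lowest mask pixel
  (hoof contact) by default; a fixed channel-floor row is supported because
  a hoof raised mid-stride otherwise biases heights. WH = ground − withers.y,
  HH = ground − hip.y.
* **Chest depth (CD)** — distance from the withers to the head-side *lower*
  corner of the inscribed rectangle (the sternum proxy, per the manual
  standard "withers to the lower edge of the sternum"); the rear-upper
  corner reading is available via `chest_mode="rear_upper"`.

Jumping frames are never measured (`UnsupportedPostureError`); the pipeline
emits them with blank measures and the flag `jump_excluded`.

## Pixel-to-centimeter calibration

The camera scale is modelled as `ratio(u, v) = b0 + a1u + a2u² + a3u³ +
b1v + b2v² + b3v³` in px/cm, fitted by ordinary least squares to
calibration-plate observations taken at 5-cm steps (side plate 0–50 cm,
back plate 0–90 cm). Fitting requires ≥7 samples spanning ≥4 distinct
values per predictor (a cubic needs four support points per axis); rank
deficiency names the offending axis. The shipped presets carry the
published coefficient sets verbatim, including signs, plus their plate
ranges; evaluation outside the range logs a warning. Conversion divides
(`cm = px / ratio`) — at plausible channel geometry the side model gives
≈3 px/cm, the right order for a 640-px frame. A non-positive ratio (e.g.
the back model's negative intercept at u = v = 0, far outside its
calibrated range) raises an error on conversion rather than silently
producing negative lengths.

## Synthetic silhouettes

The generator composes a torso ellipse (default 300 × 110 px), two leg
capsules, a neck capsule with a disk-plus-pointed-muzzle head, and two
narrow elliptical dorsal prominences (8 × 12 px half-axes) at 3.5/8 and
6.5/8 of the nose-to-rear span — i.e. centred in the landmark windows. With
the head raised, a 13-px concave notch is carved where the neck's upper
edge enters the torso: the dorsal dip at the neck base that *is* the
raised-head withers. Whole-body rotation produces the jump posture. Ground
truth (landmarks, the four measures, the posture label) comes from the
generative geometry, never from the measurement code, so the generator is a
valid independent oracle.

Study conditions are fixed: posture mix 65.8 / 16.4 / 17.8 %
(head-down / head-up / jump), walking tilt ~ N(2.84°, 3.64°) truncated to
[0°, 8°], jump tilt ~ N(15.44°, 8.35°) truncated to [12.5°, 25°] (truth
label jump iff tilt > 12°), head-pitch presets −25° / +30°, body sizes
drawn uniformly within ±10 % of the defaults. Truncation is by rejection,
so no probability mass piles up at the interval ends. Dimensions mirror a
~75-cm sheep at ~3 px/cm.

What the generator does **not** emulate: wool and hair boundaries (a known
chest-depth error source in the field), motion blur, segmentation errors,
perspective and lens distortion, leg articulation during gait, and
multi-animal frames. Passing the synthetic suites therefore demonstrates
the geometric correctness and internal consistency of the pipeline — not
its accuracy on real imagery.

## Numerical and degenerate-input choices

* Minimum-area rectangle: orientations tying in area within 1e-9 resolve to
  the smallest |angle|; angles are normalised to [−90°, 90°).
* The curvature chord walk is capped at half the contour so the neighbour
  search cannot wrap around and approach the point from the far side.
* The U-chord statistic is ill-conditioned where D ≈ 2U (near-straight
  arcs): a sub-pixel change in the chord neighbours moves c by O(0.1). The
  closed-form circle check is therefore performed at a chord length exactly
  realizable on the test polygon, where the identity is exact.
* Contour tracing is Moore-neighbour with the interior kept to the right
  (clockwise on screen), starting at the top-left-most boundary pixel;
  revisited pixels on one-pixel necks are collapsed to first occurrence.
* Binarisation threshold 128 by default (masks are 0/255 in practice);
  polygon annotations rasterise by the pixel-centre rule at (x+0.5, y+0.5).
* Percentages in reports round half-up to two decimals.

## Suite sizes

The bundled test suites use 200 silhouettes for posture accuracy, 100 for
the measurement-error study, 200 random ≤16×16 masks for the
maximal-rectangle cross-check, and a 10-animal tree for end-to-end
determinism — sizes at which the binomial noise on the asserted thresholds
is small while the whole suite stays fast on one core.

## Known limitations

* The raised-head withers depends on the inscribed-rectangle shoulder
  corner, which is axis-aligned and therefore shifts under strong body
  tilt; on tilted head-up frames the landmark can drift by tens of pixels.
  (Tilted frames are mostly jumps, which are excluded anyway.)
* Chest depth inherits error from both the withers landmark and the
  rectangle corner and is the least accurate measure (median ≈6 % on the
  synthetic suite vs ≤0.5 % for the heights), consistent with it being the
  hardest measure in the field.
* The jump threshold and the diagonal-angle statistic are calibrated to
  side views of walking sheep; other species, camera angles, or aspect
  ratios need a refit (`fit_jump_stump`).
* No back-view measures are defined; the back calibration preset is shipped
  for completeness of the calibration module.
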