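"""Parametric side-view sheep silhouettes with known ground truth.

Every pipeline stage is testable without real imagery: this module draws
a stylised quadruped silhouette — torso ellipse, leg and neck capsules, a
head disk, and two narrow dorsal prominences at the withers and hip — and
reports, from the generative geometry alone, where every landmark truly
is and what every body measure truly equals.  The generator never calls
the measurement pipeline, so it can serve as an independent oracle.

Geometry conventions: the silhouette is built in a body frame (head
toward -x, y down), optionally rotated by ``body_tilt`` (positive = head
side rising, as in a jump) and placed on the ground line of the frame.
``head_pitch`` is the angle of the neck against horizontal (positive =
raised head).  The dorsal prominences sit at 3.5/8 and 6.5/8 of the
nose-to-rear horizontal extent S, i.e. centered in the landmark search
windows used downstream.

The stochastic presets mirror the field situation the pipeline targets:
walking animals carry small body tilts (normal with mean 2.84 deg, sd
3.64, clipped to [0, 8]) while jumps show large ones (mean 15.44, sd
8.35, clipped to [12.5, 25]); the truth label is jump iff tilt > 12 deg,
otherwise the head-pitch sign decides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .mask_io import BinaryMask, FrameSequence
from .calibration import CalibrationModel, CalibrationSample, eval_ratio

#: body tilt (deg) above which the generated posture is a jump
JUMP_TILT_DEG = 12.0

#: head-pitch presets (deg) for the two walking head states
PITCH_DOWN = -25.0
PITCH_UP = 30.0


@dataclass(frozen=True)
class SilhouetteParams:
    """Generative parameters of one synthetic silhouette (pixels/deg)."""

    torso_length: float = 300.0
    torso_depth: float = 110.0
    leg_length: float = 90.0  # below the torso ellipse
    leg_width: float = 24.0
    leg_flexion: float = 0.0  # deg, forward lean of the legs
    neck_length: float = 95.0
    neck_width: float = 28.0
    head_radius: float = 20.0
    head_pitch: float = PITCH_DOWN  # deg; negative = lowered head
    body_tilt: float = 0.0  # deg; positive = head side rises
    dorsal_bump_amplitude: float = 12.0
    dorsal_bump_halfwidth: float = 8.0
    boundary_noise: float = 0.0  # px, sd of smooth boundary displacement
    resolution: tuple[int, int] = (640, 480)  # (width, height)
    head_side: str = "left"

    def __post_init__(self) -> None:
        for name in ("torso_length", "torso_depth", "leg_length", "neck_length",
                     "head_radius", "dorsal_bump_amplitude"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.head_side not in ("left", "right"):
            raise ValidationError("head_side must be 'left' or 'right'")


@dataclass(frozen=True)
class SilhouetteTruth:
    """A silhouette plus its generative ground truth."""

    mask: BinaryMask
    posture: str  # head_down | head_up | jump
    withers: tuple[float, float]
    hip: tuple[float, float]
    head: tuple[float, float]  # nose tip
    bsl_p1: tuple[float, float]  # head-side lower torso-rectangle corner
    bsl_p2: tuple[float, float]  # rear upper corner
    ground_y: float
    measures_px: dict[str, float] = field(default_factory=dict)  # BSL/WH/HH/CD


def _rot(tilt_deg: float) -> np.ndarray:
    # y-down frame: positive tilt moves the -x (head) side to smaller y
    a = math.radians(tilt_deg)
    return np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])


def make_silhouette(params: SilhouetteParams, seed: int = 0) -> SilhouetteTruth:
    """Rasterise one silhouette and compute its ground truth.

    Deterministic given ``(params, seed)``; the mask is a single
    8-connected component.
    """
    p = params
    a, b = p.torso_length / 2.0, p.torso_depth / 2.0
    pitch = math.radians(p.head_pitch)

    # --- primitive geometry in the body frame (head toward -x, y down) ---
    neck_root = np.array([-0.78 * a, -0.35 * b])  # chest/brisket area, inside torso
    head_dir = np.array([-math.cos(pitch), -math.sin(pitch)])
    head_c = neck_root + p.neck_length * head_dir
    # pointed muzzle: triangle from the head disk to the nose apex
    muzzle_len = 0.6 * p.head_radius
    nose = head_c + (p.head_radius + muzzle_len) * head_dir
    muzzle_half = 0.6 * p.head_radius
    m_perp = np.array([-head_dir[1], head_dir[0]])
    muzzle = (nose, head_c + muzzle_half * m_perp, head_c - muzzle_half * m_perp)
    rear_x = a
    S = rear_x - nose[0]  # nose-to-rear horizontal extent

    def ell_top(x: float) -> float:
        return -b * math.sqrt(max(0.0, 1 - (x / a) ** 2))

    xw = nose[0] + 3.5 / 8.0 * S  # withers prominence center
    xh = nose[0] + 6.5 / 8.0 * S  # hip prominence center
    bump_w = np.array([xw, ell_top(xw)])
    bump_h = np.array([xh, ell_top(xh)])
    amp, bhw = p.dorsal_bump_amplitude, p.dorsal_bump_halfwidth

    flex = math.radians(p.leg_flexion)
    leg_dir = np.array([math.sin(flex), math.cos(flex)])
    leg_len = b + p.leg_length
    legs = []
    for fx in (0.18, 0.82):
        top = np.array([-a + fx * p.torso_length, 0.0])
        legs.append((top, top + leg_len * leg_dir))

    # --- ground truth landmarks (body frame) ---
    withers_apex = bump_w + np.array([0.0, -amp])
    hip_apex = bump_h + np.array([0.0, -amp])
    shoulder = np.array([-a / math.sqrt(2), -b / math.sqrt(2)])
    bsl_front_low = np.array([-a / math.sqrt(2), b / math.sqrt(2)])
    bsl_rear_up = np.array([a / math.sqrt(2), -b / math.sqrt(2)])
    head_top = np.array([head_c[0], head_c[1] - p.head_radius])

    if p.body_tilt > JUMP_TILT_DEG:
        posture = "jump"
    else:
        posture = "head_up" if p.head_pitch > 0 else "head_down"

    # With the head raised, the dorsal profile dips where the neck meets
    # the back — that dip IS the withers in the raised-head posture.  It
    # is modelled as a concave notch (subtracted disk) at the neck-torso
    # junction; the withers truth is the notch point farthest from line A
    # (head top to shoulder), i.e. the tangency of the notch circle with
    # the line direction.
    notch_c = None
    notch_r = 16.0
    if p.head_pitch > 0:
        notch_c, withers_truth = _neck_notch(
            head_top, shoulder, head_c, p.head_radius, neck_root,
            p.neck_width / 2, pitch, a, b, notch_r)
    else:
        withers_truth = withers_apex

    # --- rasterise (vectorised implicit functions on the pixel lattice) ---
    w_res, h_res = p.resolution
    R = _rot(p.body_tilt)
    Rinv = R.T

    # frame placement from the rotated analytic extent
    probe = np.vstack([
        _ellipse_pts(np.zeros(2), a, b),
        _ellipse_pts(bump_w, bhw, amp),
        _ellipse_pts(bump_h, bhw, amp),
        _circle_pts(head_c, p.head_radius),
        np.vstack(muzzle),
        *[_capsule_pts(t, f, p.leg_width / 2) for t, f in legs],
        _capsule_pts(neck_root, head_c, p.neck_width / 2),
    ]) @ R.T
    lo, hi = probe.min(axis=0), probe.max(axis=0)
    margin = 12.0
    if hi[0] - lo[0] > w_res - 2 * margin or hi[1] - lo[1] > h_res - 2 * margin:
        raise ValidationError("silhouette exceeds the frame at this resolution")
    t = np.array([(w_res - (hi[0] + lo[0])) / 2.0, (h_res - margin) - hi[1]])

    xs, ys = np.meshgrid(np.arange(w_res, dtype=float), np.arange(h_res, dtype=float))
    pts_img = np.stack([xs.ravel(), ys.ravel()], axis=1)
    pb = (pts_img - t) @ Rinv.T  # back to body frame

    inside = _in_ellipse(pb, np.zeros(2), a, b)
    inside |= _in_ellipse(pb, bump_w, bhw, amp)
    inside |= _in_ellipse(pb, bump_h, bhw, amp)
    inside |= np.linalg.norm(pb - head_c, axis=1) <= p.head_radius
    inside |= _in_triangle(pb, *muzzle)
    inside |= _in_capsule(pb, neck_root, head_c, p.neck_width / 2)
    for top, foot in legs:
        inside |= _in_capsule(pb, top, foot, p.leg_width / 2)
    if notch_c is not None:
        inside &= np.linalg.norm(pb - notch_c, axis=1) > notch_r
    grid = inside.reshape(h_res, w_res)

    if p.boundary_noise > 0:
        grid = _jitter_boundary(grid, p.boundary_noise, seed)
    # keep a single component (noise can pinch pieces off)
    labels, n = ndimage.label(grid, structure=np.ones((3, 3), bool))
    if n == 0:
        raise ValidationError("silhouette vanished during generation")
    if n > 1:
        sizes = ndimage.sum_labels(grid, labels, index=np.arange(1, n + 1))
        grid = labels == (int(np.argmax(sizes)) + 1)
    mask = BinaryMask(grid)

    to_img = lambda q: tuple((R @ np.asarray(q)) + t)
    ground_y = float(np.nonzero(grid.any(axis=1))[0].max() + 1)

    withers_i = to_img(withers_truth)
    hip_i = to_img(hip_apex)
    p1_i, p2_i = to_img(bsl_front_low), to_img(bsl_rear_up)
    measures = {
        "BSL": math.sqrt(2 * (a ** 2 + b ** 2)),
        "WH": ground_y - withers_i[1],
        "HH": ground_y - hip_i[1],
        "CD": math.dist(withers_i, p1_i),
    }

    truth = SilhouetteTruth(
        mask=mask, posture=posture,
        withers=withers_i, hip=hip_i, head=to_img(nose),
        bsl_p1=p1_i, bsl_p2=p2_i, ground_y=ground_y, measures_px=measures)
    if p.head_side == "right":
        truth = _mirror_truth(truth, w_res)
    return truth


def _neck_notch(head_top, shoulder, head_c, head_r, neck_root, neck_hw,
                pitch, a, b, notch_r) -> tuple[np.ndarray, np.ndarray]:
    """Place the neck-base dorsal notch and return (notch center, withers
    truth).

    The notch disk is centered just above the point where the neck's
    upper edge enters the torso ellipse, biting ~9 px into the dorsal
    profile.  The withers truth is the point of the notch circle with
    maximal perpendicular distance to line A (head top to shoulder): the
    tangency point in the direction of the line's downward normal.
    """
    depth = 13.0
    axis_to_root = np.array([math.cos(pitch), math.sin(pitch)])  # head -> root
    up = np.array([-axis_to_root[1], axis_to_root[0]])
    if up[1] > 0:
        up = -up
    exit_along = math.sqrt(max(0.0, head_r ** 2 - neck_hw ** 2))
    e_start = head_c + exit_along * axis_to_root + neck_hw * up
    e_end = neck_root + neck_hw * up
    s = np.linspace(0, 1, 1000)[:, None]
    edge = e_start + s * (e_end - e_start)
    inside = ((edge[:, 0] / a) ** 2 + (edge[:, 1] / b) ** 2) <= 1.0
    j = int(np.argmax(inside)) if inside.any() else len(edge) - 1
    junction = edge[j]
    # a touch forward of the junction so the dip stays clear of the
    # torso's inscribed-rectangle columns
    notch_c = junction + np.array([-5.0, -(notch_r - depth)])
    line_dir = (np.asarray(shoulder) - np.asarray(head_top))
    line_dir = line_dir / np.linalg.norm(line_dir)
    normal = np.array([-line_dir[1], line_dir[0]])
    if normal[1] < 0:
        normal = -normal  # downward = into the body
    withers = notch_c + notch_r * normal
    return notch_c, withers


def _mirror_truth(t: SilhouetteTruth, w_res: int) -> SilhouetteTruth:
    flip = lambda q: (w_res - 1 - q[0], q[1])
    return replace(
        t, mask=BinaryMask(t.mask.grid[:, ::-1]),
        withers=flip(t.withers), hip=flip(t.hip), head=flip(t.head),
        bsl_p1=flip(t.bsl_p1), bsl_p2=flip(t.bsl_p2))


# ---- implicit/boundary helpers ----

def _in_ellipse(pts, c, sa, sb):
    d = (pts - c) / np.array([sa, sb])
    return (d ** 2).sum(axis=1) <= 1.0


def _in_triangle(pts, A, B, C):
    def half(p1, p2):
        return ((p2[0] - p1[0]) * (pts[:, 1] - p1[1])
                - (p2[1] - p1[1]) * (pts[:, 0] - p1[0]))
    d1, d2, d3 = half(A, B), half(B, C), half(C, A)
    return ((d1 >= 0) & (d2 >= 0) & (d3 >= 0)) | ((d1 <= 0) & (d2 <= 0) & (d3 <= 0))


def _in_capsule(pts, p0, p1, hw):
    v = p1 - p0
    tt = np.clip((pts - p0) @ v / (v @ v), 0.0, 1.0)
    proj = p0 + tt[:, None] * v
    return np.linalg.norm(pts - proj, axis=1) <= hw


def _ellipse_pts(c, sa, sb, n=256):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return c + np.stack([sa * np.cos(th), sb * np.sin(th)], axis=1)


def _circle_pts(c, r, n=128):
    return _ellipse_pts(c, r, r, n)


def _capsule_pts(p0, p1, hw, n=64):
    v = p1 - p0
    nv = np.array([-v[1], v[0]]) / np.linalg.norm(v)
    side1 = p0 + np.linspace(0, 1, n)[:, None] * v + hw * nv
    side2 = p0 + np.linspace(0, 1, n)[:, None] * v - hw * nv
    return np.vstack([side1, side2, _circle_pts(p0, hw, 32), _circle_pts(p1, hw, 32)])


def _jitter_boundary(grid: np.ndarray, sd_px: float, seed: int) -> np.ndarray:
    """Displace the silhouette boundary by a smooth random field with
    the given pixel standard deviation."""
    rng = np.random.default_rng(seed)
    inside = ndimage.distance_transform_edt(grid)
    outside = ndimage.distance_transform_edt(~grid)
    sdf = outside - inside  # negative inside
    noise = ndimage.gaussian_filter(rng.standard_normal(grid.shape), sigma=3.0)
    noise *= sd_px / max(noise.std(), 1e-9)
    return sdf + noise < 0


# ---- stochastic study-condition presets ----

def _trunc_normal(rng: np.random.Generator, mu: float, sd: float,
                  lo: float, hi: float) -> float:
    """Normal draw truncated to [lo, hi] by rejection (no boundary atom)."""
    for _ in range(1000):
        x = rng.normal(mu, sd)
        if lo <= x <= hi:
            return float(x)
    return float((lo + hi) / 2)

def sample_params(
    rng: np.random.Generator,
    posture: str | None = None,
    boundary_noise: float = 0.0,
    resolution: tuple[int, int] = (640, 480),
) -> SilhouetteParams:
    """Draw silhouette parameters for one animal.

    ``posture`` None draws the field-reported posture mix
    (head-down 65.8%, head-up 16.4%, jump 17.8%); tilts follow the
    reported per-posture angle statistics, head pitch the two presets.
    """
    if posture is None:
        posture = rng.choice(["head_down", "head_up", "jump"], p=[0.658, 0.164, 0.178])
    if posture == "jump":
        tilt = _trunc_normal(rng, 15.44, 8.35, 12.5, 25.0)
        pitch = rng.choice([PITCH_DOWN, PITCH_UP])
    else:
        tilt = _trunc_normal(rng, 2.84, 3.64, 0.0, 8.0)
        pitch = PITCH_UP if posture == "head_up" else PITCH_DOWN
    return SilhouetteParams(
        torso_length=float(rng.uniform(270, 330)),
        torso_depth=float(rng.uniform(95, 125)),
        leg_length=float(rng.uniform(75, 105)),
        neck_length=float(rng.uniform(70, 90)),
        head_pitch=float(pitch + rng.uniform(-3, 3)),
        body_tilt=tilt,
        boundary_noise=boundary_noise,
        resolution=resolution,
    )


def make_walk_sequence(
    params: SilhouetteParams, n_frames: int, seed: int = 0
) -> FrameSequence:
    """Translate one silhouette across the frame, centered at the middle
    frame, emulating a channel pass."""
    if n_frames < 1:
        raise ValidationError("n_frames must be >= 1")
    truth = make_silhouette(params, seed)
    grid = truth.mask.grid
    h, w = grid.shape
    # center the silhouette by pixel centroid, so the central frame is
    # the one with the body mass in the middle of the view
    cols = np.nonzero(grid.any(axis=0))[0]
    centroid = float(np.nonzero(grid)[1].mean())
    recenter = int(round(w / 2 - centroid))
    base = np.zeros_like(grid)
    src0, src1 = cols.min(), cols.max() + 1
    d0, d1 = src0 + recenter, src1 + recenter
    base[:, max(d0, 0):min(d1, w)] = grid[:, max(d0, 0) - recenter:
                                          min(d1, w) - recenter]
    cols = np.nonzero(base.any(axis=0))[0]
    span = cols.max() - cols.min() + 1
    max_off = (w - span // 2) // 2  # end frames partially leave the frame
    center = n_frames // 2
    frames = []
    for i in range(n_frames):
        off = int(round((i - center) / max(center, 1) * max_off))
        shifted = np.zeros_like(base)
        src = np.clip([cols.min() + off, cols.max() + 1 + off], 0, w)
        if src[1] > src[0]:
            shifted[:, src[0]:src[1]] = base[:, src[0] - off:src[1] - off]
        frames.append((i, BinaryMask(shifted)))
    return FrameSequence(animal_id="synthetic", view="side", frames=frames)


def make_calibration_samples(
    model: CalibrationModel,
    u_values: np.ndarray | None = None,
    v_values: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[CalibrationSample]:
    """Calibration-plate observations on a (u, v) grid: model ratio plus
    seeded Gaussian noise.  Default grids follow the plate protocol:
    5-cm steps over the model's calibrated u range (0-50 cm side,
    0-90 cm back) and five camera distances."""
    if u_values is None:
        lo, hi = model.u_range if model.u_range else (0.0, 50.0)
        u_values = np.arange(lo, hi + 1e-9, 5.0)
    if v_values is None:
        v_values = np.linspace(0.0, 40.0, 5)
    rng = np.random.default_rng(seed)
    out = []
    for u in np.asarray(u_values, dtype=float):
        for v in np.asarray(v_values, dtype=float):
            r = eval_ratio(model, u, v) + (rng.normal(0, noise_sd) if noise_sd else 0.0)
            out.append(CalibrationSample(float(u), float(v), float(r)))
    return out
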