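"""Pixel-to-centimeter calibration via additive cubic ratio models.

The camera's pixels-per-centimeter scale varies with the geometry of the
capture channel.  It is modelled as an additive cubic polynomial in two
distances,

    ratio(u, v) = b0 + a1*u + a2*u^2 + a3*u^3 + b1*v + b2*v^2 + b3*v^3

fit by ordinary least squares to observations of a calibration plate of
known physical size moved through the channel in 5-cm steps.  Two presets
ship with the package:

* ``paper_side`` — side camera; u = animal-to-backplane distance (cm),
  v = camera-to-backplane distance (cm); plate range 0-50 cm.
* ``paper_back`` — top-down (back) camera; u = animal height (cm),
  v = camera-to-ground distance (cm); plate range 0-90 cm.

A pixel measure converts to centimeters by dividing by the ratio.
Evaluating a preset outside its calibrated plate range can produce a
non-positive ratio (e.g. the back model's negative intercept at
u = v = 0); conversion then raises :class:`NonPhysicalCalibrationError`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import yaml

from .errors import CalibrationError, NonPhysicalCalibrationError, ValidationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CalibrationModel:
    """Intercept plus two cubic coefficient triples mapping distances to
    a pixels-per-centimeter ratio."""

    intercept: float
    coeffs_a: tuple[float, float, float]  # u, u^2, u^3
    coeffs_b: tuple[float, float, float]  # v, v^2, v^3
    name: str = ""
    u_range: tuple[float, float] | None = None  # calibrated plate range, cm
    v_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        vals = (self.intercept, *self.coeffs_a, *self.coeffs_b)
        if not all(np.isfinite(vals)):
            raise ValidationError("calibration coefficients must be finite")


class CalibrationSample(NamedTuple):
    """One calibration-plate observation."""

    u: float  # first predictor, cm
    v: float  # second predictor, cm
    ratio: float  # pixels per cm


class FitResult(NamedTuple):
    model: CalibrationModel
    rmse: float


#: Published coefficient sets, shipped verbatim (printed signs included).
PRESETS: dict[str, CalibrationModel] = {
    "paper_side": CalibrationModel(
        intercept=92.67,
        coeffs_a=(0.05795, -0.0008332, 0.000006949),
        coeffs_b=(-1.529, 0.008718, -0.00001699),
        name="paper_side",
        u_range=(0.0, 50.0),
    ),
    "paper_back": CalibrationModel(
        intercept=-40.38,
        coeffs_a=(0.01818, 0.0001908, 0.000001377),
        coeffs_b=(1.035, -0.007941, 0.00001959),
        name="paper_back",
        u_range=(0.0, 90.0),
    ),
}


def eval_ratio(model: CalibrationModel, u: float, v: float) -> float:
    """Evaluate the pixels-per-centimeter ratio at distances (u, v)."""
    if model.u_range and not (model.u_range[0] <= u <= model.u_range[1]):
        log.warning("u=%s outside calibrated range %s of %s", u, model.u_range,
                    model.name or "model")
    if model.v_range and not (model.v_range[0] <= v <= model.v_range[1]):
        log.warning("v=%s outside calibrated range %s of %s", v, model.v_range,
                    model.name or "model")
    a1, a2, a3 = model.coeffs_a
    b1, b2, b3 = model.coeffs_b
    return (model.intercept
            + a1 * u + a2 * u ** 2 + a3 * u ** 3
            + b1 * v + b2 * v ** 2 + b3 * v ** 3)


def _design(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(u), u, u ** 2, u ** 3, v, v ** 2, v ** 3])


def fit_model(samples: Sequence[CalibrationSample]) -> FitResult:
    """Ordinary least squares on the 7-term additive cubic basis.

    Requires at least 7 samples spanning at least 4 distinct values on
    each predictor axis (a cubic needs 4 support points per axis).
    """
    samples = list(samples)
    if len(samples) < 7:
        raise ValidationError(f"need >= 7 calibration samples, got {len(samples)}")
    u = np.array([s.u for s in samples], dtype=float)
    v = np.array([s.v for s in samples], dtype=float)
    r = np.array([s.ratio for s in samples], dtype=float)
    for axis, vals in (("u", u), ("v", v)):
        if len(np.unique(vals)) < 4:
            raise CalibrationError(
                f"rank-deficient design: predictor {axis} has fewer than 4 "
                f"distinct values")
    X = _design(u, v)
    coef, _, rank, _ = np.linalg.lstsq(X, r, rcond=None)
    if rank < 7:
        raise CalibrationError("rank-deficient design matrix")
    resid = r - X @ coef
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    model = CalibrationModel(
        intercept=float(coef[0]),
        coeffs_a=tuple(float(c) for c in coef[1:4]),
        coeffs_b=tuple(float(c) for c in coef[4:7]),
        name="fitted",
        u_range=(float(u.min()), float(u.max())),
        v_range=(float(v.min()), float(v.max())),
    )
    return FitResult(model, rmse)


def px_to_cm(px: float, ratio: float) -> float:
    """Convert a pixel distance to centimeters by dividing by the
    pixels-per-centimeter ratio."""
    if ratio <= 0:
        raise NonPhysicalCalibrationError(
            f"pixels-per-cm ratio must be positive, got {ratio}; the model was "
            "likely evaluated outside its calibrated range")
    return px / ratio


def save_model(model: CalibrationModel, path: str | Path) -> None:
    doc = {
        "intercept": model.intercept,
        "a1": model.coeffs_a[0], "a2": model.coeffs_a[1], "a3": model.coeffs_a[2],
        "b1": model.coeffs_b[0], "b2": model.coeffs_b[1], "b3": model.coeffs_b[2],
        "name": model.name,
        "u_range": list(model.u_range) if model.u_range else None,
        "v_range": list(model.v_range) if model.v_range else None,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_model(path: str | Path) -> CalibrationModel:
    doc = yaml.safe_load(Path(path).read_text())
    return CalibrationModel(
        intercept=float(doc["intercept"]),
        coeffs_a=(float(doc["a1"]), float(doc["a2"]), float(doc["a3"])),
        coeffs_b=(float(doc["b1"]), float(doc["b2"]), float(doc["b3"])),
        name=doc.get("name", ""),
        u_range=tuple(doc["u_range"]) if doc.get("u_range") else None,
        v_range=tuple(doc["v_range"]) if doc.get("v_range") else None,
    )


def read_samples_csv(path: str | Path) -> list[CalibrationSample]:
    """Read a calibration CSV with columns u_cm, v_cm, ratio_px_per_cm."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"u_cm", "v_cm", "ratio_px_per_cm"}
    if not required.issubset(df.columns):
        raise ValidationError(f"calibration CSV must have columns {sorted(required)}")
    return [CalibrationSample(float(r.u_cm), float(r.v_cm), float(r.ratio_px_per_cm))
            for r in df.itertuples()]
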