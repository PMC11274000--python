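"""End-to-end orchestration and evaluation metrics.

``run_pipeline`` walks a capture tree (``<root>/<ear_tag>/<view>/<n>.png``),
selects the key frame of each animal, classifies its posture, measures
the non-jumping ones, converts pixels to centimeters when a calibration
model is given, and writes one CSV row per animal.  Per-animal failures
are logged and never abort the run — field data is messy.

Evaluation helpers implement precision, recall and the stratified
accuracy table used to report classification performance.
"""

from __future__ import annotations

import decimal
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import calibration as calib
from .errors import UndefinedMetricError, ValidationError
from .keyframe import RegionWeights, select_key_frame
from .mask_io import (MEASUREMENT_COLUMNS, list_animal_dirs, read_animal_dir,
                      write_measurements)
from .morphometry import LandmarkConfig, measure
from .posture import PostureConfig, classify_posture

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvalCounts:
    """Per-class confusion counts."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValidationError("confusion counts must be non-negative")


def precision(counts: EvalCounts) -> float:
    """TP / (TP + FP)."""
    if counts.tp + counts.fp == 0:
        raise UndefinedMetricError("precision undefined: TP + FP = 0")
    return counts.tp / (counts.tp + counts.fp)


def recall(counts: EvalCounts) -> float:
    """TP / (TP + FN)."""
    if counts.tp + counts.fn == 0:
        raise UndefinedMetricError("recall undefined: TP + FN = 0")
    return counts.tp / (counts.tp + counts.fn)


def _pct(x: float) -> float:
    """Percentage rounded half-up to 2 decimals (reporting convention)."""
    return float(decimal.Decimal(x * 100).quantize(
        decimal.Decimal("0.01"), rounding=decimal.ROUND_HALF_UP))


def accuracy_report(
    pred: Sequence, truth: Sequence, groups: Sequence | None = None
) -> pd.DataFrame:
    """Stratified accuracy table: per-group correct, N and accuracy %,
    plus an overall row."""
    pred = list(pred)
    truth = list(truth)
    if len(pred) != len(truth) or len(pred) == 0:
        raise ValidationError("pred and truth must be equal-length and non-empty")
    if groups is None:
        groups = ["all"] * len(pred)
    elif len(groups) != len(pred):
        raise ValidationError("groups must match pred/truth length")
    df = pd.DataFrame({"group": list(groups),
                       "correct": [p == t for p, t in zip(pred, truth)]})
    rows = []
    for g, sub in df.groupby("group", sort=False):
        c, n = int(sub["correct"].sum()), len(sub)
        rows.append({"group": g, "correct": c, "n": n, "accuracy_pct": _pct(c / n)})
    c, n = int(df["correct"].sum()), len(df)
    rows.append({"group": "overall", "correct": c, "n": n, "accuracy_pct": _pct(c / n)})
    return pd.DataFrame(rows)


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run."""

    weights: RegionWeights = field(default_factory=RegionWeights)
    posture: PostureConfig = field(default_factory=PostureConfig)
    landmarks: LandmarkConfig = field(default_factory=LandmarkConfig)
    calibration_model: calib.CalibrationModel | None = None
    side_u_cm: float | None = None  # animal-to-backplane distance
    side_v_cm: float | None = None  # camera-to-backplane distance
    mask_threshold: int = 128

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        kw = {}
        if "weights" in doc:
            kw["weights"] = RegionWeights(**doc["weights"])
        if "posture" in doc:
            kw["posture"] = PostureConfig(**doc["posture"])
        if "landmarks" in doc:
            kw["landmarks"] = LandmarkConfig(**doc["landmarks"])
        cal = doc.get("calibration", {})
        if "preset" in cal:
            kw["calibration_model"] = calib.PRESETS[cal["preset"]]
        elif "model_path" in cal:
            kw["calibration_model"] = calib.load_model(cal["model_path"])
        for k in ("side_u_cm", "side_v_cm", "mask_threshold"):
            if k in doc:
                kw[k] = doc[k]
        return cls(**kw)


@dataclass
class RunSummary:
    n_animals: int = 0
    n_ok: int = 0
    n_jump: int = 0
    failures: dict[str, str] = field(default_factory=dict)


def process_animal(seq, cfg: PipelineConfig) -> dict:
    """Key frame -> posture -> (measures) -> (cm conversion) for one
    animal's frame sequence; returns one measurement-CSV row."""
    frame_idx, _score = select_key_frame(seq, cfg.weights)
    mask = dict(seq.frames)[frame_idx]
    res = classify_posture(mask, cfg.posture)
    row = {c: "" for c in MEASUREMENT_COLUMNS}
    row.update(ear_tag=seq.animal_id, frame=frame_idx, posture=res.label,
               angle_deg=res.angle_deg, flags="")
    if res.label == "jump":
        row["flags"] = "jump_excluded"
        return row
    rec = measure(mask, res.label, cfg.landmarks)
    row.update(bsl_px=rec.bsl_px, wh_px=rec.wh_px, hh_px=rec.hh_px, cd_px=rec.cd_px)
    if cfg.calibration_model is not None:
        if cfg.side_u_cm is None or cfg.side_v_cm is None:
            raise ValidationError("calibration given but side_u_cm/side_v_cm missing")
        ratio = calib.eval_ratio(cfg.calibration_model, cfg.side_u_cm, cfg.side_v_cm)
        for px_col, cm_col in (("bsl_px", "bsl_cm"), ("wh_px", "wh_cm"),
                               ("hh_px", "hh_cm"), ("cd_px", "cd_cm")):
            row[cm_col] = calib.px_to_cm(row[px_col], ratio)
    return row


def run_pipeline(
    root: str | Path,
    cfg: PipelineConfig | None = None,
    out_csv: str | Path | None = None,
    view: str = "side",
) -> tuple[list[dict], RunSummary]:
    """Process every animal under ``root``; write ``out_csv`` if given.

    Returns (rows, summary).  Per-animal failures are recorded in the
    summary and logged; the run continues.
    """
    cfg = cfg or PipelineConfig()
    animal_dirs = list_animal_dirs(root, view)
    if not animal_dirs:
        raise ValidationError(f"no animal folders with '{view}' frames under {root}")
    rows: list[dict] = []
    summary = RunSummary(n_animals=len(animal_dirs))
    for tag_dir in animal_dirs:
        try:
            seq = read_animal_dir(tag_dir, view, cfg.mask_threshold)
            row = process_animal(seq, cfg)
        except Exception as exc:  # noqa: BLE001 - per-animal isolation
            log.error("animal %s failed: %s", tag_dir.name, exc)
            summary.failures[tag_dir.name] = str(exc)
            continue
        rows.append(row)
        summary.n_ok += 1
        summary.n_jump += row["posture"] == "jump"
    if out_csv is not None:
        write_measurements(rows, out_csv)
        summary_path = Path(out_csv).with_suffix(".summary.json")
        summary_path.write_text(json.dumps({
            "n_animals": summary.n_animals, "n_ok": summary.n_ok,
            "n_jump": summary.n_jump, "failures": summary.failures}, indent=2))
    return rows, summary
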