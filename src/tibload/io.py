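"""Plain-text on-disk format for trials and cohorts, plus trial admission.

One trial is a pair of files sharing a stem: ``<stem>.csv`` holds the
synchronized series (columns ``time_ms, ax_L, ay_L, az_L, ax_R, ay_R, az_R,
vgrf``; ``ax``/``ay``/``az`` = axial / anteroposterior / mediolateral) and
``<stem>.json`` holds metadata and optional ground truth. A cohort is a
directory of such pairs plus a ``manifest.csv`` recording admission status.
Numeric text is written at full precision, so a round trip is lossless.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .gait import quality_screen
from .trial import GroundTruth, TrialRecording

logger = logging.getLogger(__name__)

CSV_COLUMNS = ["time_ms", "ax_L", "ay_L", "az_L", "ax_R", "ay_R", "az_R", "vgrf"]
_REQUIRED_META = ["subject_id", "trial_id", "sampling_rate", "speed", "body_mass", "shoe_category"]

#: Speed admission tolerance (m/s) around the targeted speed.
SPEED_TOLERANCE = 0.2


class ParseError(ValueError):
    """Malformed trial file; the message names the offending field."""


@dataclass
class Admission:
    accepted: bool
    reason: str | None = None


@dataclass
class CohortManifest:
    rows: pd.DataFrame  # subject_id, trial_id, path, admitted, reason

    def __post_init__(self) -> None:
        pairs = self.rows[["subject_id", "trial_id"]]
        if pairs.duplicated().any():
            raise ValueError("duplicate (subject_id, trial_id) pairs in manifest")


def write_trial(trial: TrialRecording, path: str | Path) -> tuple[Path, Path]:
    """Write a trial as ``<path>.csv`` + ``<path>.json``; returns both paths."""
    stem = Path(path)
    stem.parent.mkdir(parents=True, exist_ok=True)
    n = trial.n_samples
    df = pd.DataFrame(
        {
            "time_ms": np.arange(n) * 1000.0 / trial.sampling_rate,
            "ax_L": trial.accel_left[:, 0],
            "ay_L": trial.accel_left[:, 1],
            "az_L": trial.accel_left[:, 2],
            "ax_R": trial.accel_right[:, 0],
            "ay_R": trial.accel_right[:, 1],
            "az_R": trial.accel_right[:, 2],
            "vgrf": trial.vgrf,
        }
    )
    csv_path = stem.with_suffix(".csv")
    df.to_csv(csv_path, index=False)  # str(float) round-trips float64 exactly
    meta = {
        "subject_id": trial.subject_id,
        "trial_id": trial.trial_id,
        "sampling_rate": trial.sampling_rate,
        "speed": trial.speed,
        "target_speed": trial.target_speed,
        "body_mass": trial.body_mass,
        "shoe_category": trial.shoe_category,
        "artifact": trial.artifact,
    }
    if trial.ground_truth is not None:
        meta["ground_truth"] = [
            {
                "true_vilr": g.true_vilr,
                "ic_time": g.ic_time,
                "to_time": g.to_time,
                "landing_foot": g.landing_foot,
                "latent_features": list(map(float, g.latent_features)),
            }
            for g in trial.ground_truth
        ]
    json_path = stem.with_suffix(".json")
    json_path.write_text(json.dumps(meta, indent=1))
    return csv_path, json_path


def read_trial(path: str | Path) -> TrialRecording:
    """Read a trial written by :func:`write_trial` (lossless round trip)."""
    stem = Path(path)
    csv_path, json_path = stem.with_suffix(".csv"), stem.with_suffix(".json")
    if not csv_path.exists():
        raise ParseError(f"missing series file {csv_path}")
    if not json_path.exists():
        raise ParseError(f"missing metadata file {json_path}")
    meta = json.loads(json_path.read_text())
    for key in _REQUIRED_META:
        if key not in meta or meta[key] is None:
            raise ParseError(key)
    df = pd.read_csv(csv_path, float_precision="round_trip")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"missing columns: {', '.join(missing)}")
    extra = [c for c in df.columns if c not in CSV_COLUMNS]
    if extra:
        logger.warning("ignoring extra columns %s in %s", extra, csv_path)
    gt = None
    if meta.get("ground_truth") is not None:
        gt = [
            GroundTruth(
                true_vilr=g["true_vilr"],
                ic_time=g["ic_time"],
                to_time=g["to_time"],
                landing_foot=g["landing_foot"],
                latent_features=np.asarray(g.get("latent_features", []), dtype=float),
            )
            for g in meta["ground_truth"]
        ]
    accel_left = df[["ax_L", "ay_L", "az_L"]].to_numpy()
    accel_right = df[["ax_R", "ay_R", "az_R"]].to_numpy()
    try:
        return TrialRecording(
            subject_id=str(meta["subject_id"]),
            trial_id=str(meta["trial_id"]),
            sampling_rate=float(meta["sampling_rate"]),
            accel_left=accel_left,
            accel_right=accel_right,
            vgrf=df["vgrf"].to_numpy(),
            speed=float(meta["speed"]),
            target_speed=None if meta.get("target_speed") is None else float(meta["target_speed"]),
            body_mass=float(meta["body_mass"]),
            shoe_category=meta["shoe_category"],
            ground_truth=gt,
            artifact=meta.get("artifact"),
        )
    except ValueError as exc:
        raise ParseError(str(exc)) from exc


def admit_trial(trial: TrialRecording, tolerance: float = SPEED_TOLERANCE) -> Admission:
    """Apply the trial-admission rules.

    Rejects when the measured speed misses the targeted speed by more than
    ``tolerance`` (skipped when no target speed is recorded) or when the
    quality screen fails. Pure function of the trial.
    """
    if trial.target_speed is not None and abs(trial.speed - trial.target_speed) > tolerance:
        return Admission(False, f"speed: |{trial.speed:.2f} - {trial.target_speed:.2f}| > {tolerance}")
    ok, reason = quality_screen(trial)
    if not ok:
        return Admission(False, f"quality: {reason}")
    return Admission(True, None)


def write_cohort(trials: list[TrialRecording], directory: str | Path) -> CohortManifest:
    """Write every trial plus a manifest CSV with admission status."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for t in trials:
        stem = directory / f"{t.subject_id}_{t.trial_id}"
        write_trial(t, stem)
        adm = admit_trial(t)
        rows.append(
            {
                "subject_id": t.subject_id,
                "trial_id": t.trial_id,
                "path": stem.with_suffix(".csv").name,
                "admitted": adm.accepted,
                "reason": adm.reason or "",
            }
        )
    manifest = CohortManifest(pd.DataFrame(rows))
    manifest.rows.to_csv(directory / "manifest.csv", index=False)
    return manifest


def read_cohort(directory: str | Path, admitted_only: bool = True) -> list[TrialRecording]:
    """Read a cohort directory written by :func:`write_cohort`."""
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    trials = []
    for _, row in manifest.iterrows():
        if admitted_only and not row["admitted"]:
            continue
        trials.append(read_trial(directory / row["path"]))
    return trials
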