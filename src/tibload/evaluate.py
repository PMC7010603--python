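"""Cross-validated evaluation, diagnostics and effect sizes.

Two learning settings mirror the study design: the subject-independent
model (SIM) is assessed by leave-one-subject-out cross-validation, the
subject-dependent model (SDM) by leave-one-trial-out within each subject.
Global metrics use a two-step aggregation — per-subject means first, then
the mean (+/- SD) over subjects that completed at least ``min_trials``
trials — so that runners with many trials do not dominate. Diagnostic
ability for screening high-impact runners (top third of subject mean VILR)
is summarized by ROC curves and AUC; paired model comparisons use the
repeated-measures Cohen's d.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FeatureTable, fresh_select
from .models import ModelSpec, predict, train_model

# ---------------------------------------------------------------------------
# Error metrics
# ---------------------------------------------------------------------------


def mae(y: np.ndarray, f: np.ndarray) -> float:
    y, f = _pair(y, f)
    return float(np.mean(np.abs(y - f)))


def mape(y: np.ndarray, f: np.ndarray) -> float:
    """Mean absolute percentage error (%), denominator the true value."""
    y, f = _pair(y, f)
    if np.any(y == 0):
        raise ValueError("mape undefined when a true value is 0")
    return float(100.0 * np.mean(np.abs((y - f) / y)))


def r2(y: np.ndarray, f: np.ndarray) -> float | None:
    """Coefficient of determination; ``None`` when y is constant."""
    y, f = _pair(y, f)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return None
    return 1.0 - float(np.sum((y - f) ** 2)) / ss_tot


def _pair(y, f) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    f = np.asarray(f, dtype=float)
    if y.shape != f.shape or y.size == 0:
        raise ValueError("y and f must be nonempty and of equal length")
    return y, f


# ---------------------------------------------------------------------------
# Two-step aggregation and reports
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    setting: str  # subject_independent | subject_dependent
    learner: str
    per_subject: pd.DataFrame  # subject_id, n_trials, n_strides, mae, mape, r2
    mae_mean: float
    mae_sd: float
    mape_mean: float
    r2_mean: float | None
    n_qualifying: int
    predictions: pd.DataFrame | None = None  # subject_id, trial_id, foot, y, f


@dataclass
class DiagnosticReport:
    labels: pd.Series  # high-impact flag per subject
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    cutoff: float  # Youden-optimal threshold
    sensitivity: float
    specificity: float


@dataclass
class EffectSize:
    d: float | None
    bin: str | None  # small | medium | large

    @staticmethod
    def from_d(d: float | None) -> "EffectSize":
        if d is None or not np.isfinite(d):
            return EffectSize(None, None)
        mag = abs(d)
        if mag <= 0.2:
            b = "small"
        elif mag <= 0.8:
            b = "medium"
        else:
            b = "large"
        return EffectSize(float(d), b)


def per_subject_metrics(pred: pd.DataFrame) -> pd.DataFrame:
    """Per-subject mean metrics over strides (step one of the aggregation)."""
    rows = []
    for sid, g in pred.groupby("subject_id", sort=True):
        y, f = g["y"].to_numpy(), g["f"].to_numpy()
        rows.append(
            {
                "subject_id": sid,
                "n_trials": g["trial_id"].nunique(),
                "n_strides": len(g),
                "mae": mae(y, f),
                "mape": mape(y, f),
                "r2": r2(y, f),
            }
        )
    return pd.DataFrame(rows)


def aggregate_two_step(
    pred: pd.DataFrame,
    min_trials: int = 10,
    setting: str = "subject_independent",
    learner: str = "",
) -> EvaluationReport:
    """Two-step global metrics from per-stride predictions.

    ``pred`` needs columns subject_id, trial_id, y, f. Step one averages
    within subject; step two averages those per-subject values over subjects
    with at least ``min_trials`` trials (SD taken over the same subjects).
    """
    per_subject = per_subject_metrics(pred)
    qual = per_subject[per_subject["n_trials"] >= min_trials]
    if len(qual) == 0:
        raise ValueError(f"no subject completed {min_trials}+ trials")
    r2_vals = qual["r2"].dropna()
    return EvaluationReport(
        setting=setting,
        learner=learner,
        per_subject=per_subject,
        mae_mean=float(qual["mae"].mean()),
        mae_sd=float(qual["mae"].std(ddof=1)) if len(qual) > 1 else 0.0,
        mape_mean=float(qual["mape"].mean()),
        r2_mean=float(r2_vals.mean()) if len(r2_vals) else None,
        n_qualifying=len(qual),
        predictions=pred,
    )


# ---------------------------------------------------------------------------
# Cross-validation settings
# ---------------------------------------------------------------------------


def loso_cv(
    table: FeatureTable,
    specs: list[ModelSpec] | ModelSpec,
    q: float = 0.05,
    min_trials: int = 10,
    select: bool = True,
) -> dict[str, EvaluationReport]:
    """Leave-one-subject-out (subject-independent) cross-validation.

    For each held-out subject, FRESH feature selection is refitted on the
    training subjects only (no leakage), every requested learner is trained
    on the training rows, and the held-out subject's strides are predicted.
    Returns one report per learner, keyed by learner name.
    """
    if isinstance(specs, ModelSpec):
        specs = [specs]
    subjects = sorted(table.data["subject_id"].unique())
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects")
    preds: dict[str, list[pd.DataFrame]] = {s.learner: [] for s in specs}
    for sid in subjects:
        test_mask = table.data["subject_id"] == sid
        if not test_mask.any():  # pragma: no cover
            warnings.warn(f"subject {sid} has no rows; skipped")
            continue
        train = table.rows(~test_mask)
        test = table.rows(test_mask)
        fold_table = train
        if select:
            sel = fresh_select(train, q)
            keep = sel.selected + [f for f in train.feature_names if train.provenance[f] != "auto"]
            fold_table = train.with_features(keep)
        for spec in specs:
            model = train_model(fold_table, spec)
            f = predict(model, test.data)
            preds[spec.learner].append(
                pd.DataFrame(
                    {
                        "subject_id": test.data["subject_id"],
                        "trial_id": test.data["trial_id"],
                        "foot": test.data["foot"],
                        "y": test.y,
                        "f": f,
                    }
                )
            )
    return {
        learner: aggregate_two_step(
            pd.concat(frames, ignore_index=True), min_trials, "subject_independent", learner
        )
        for learner, frames in preds.items()
    }


def loto_cv(
    subject_table: FeatureTable,
    spec: ModelSpec,
    q: float = 0.05,
    select: bool = True,
) -> pd.DataFrame | None:
    """Leave-one-trial-out within one subject; per-stride predictions.

    Returns the prediction frame (subject_id, trial_id, foot, y, f), or
    ``None`` (with a warning) when the subject has fewer than two trials.
    """
    trials = sorted(subject_table.data["trial_id"].unique())
    if len(trials) < 2:
        warnings.warn("subject has < 2 trials; excluded from subject-dependent setting")
        return None
    frames = []
    for tid in trials:
        test_mask = subject_table.data["trial_id"] == tid
        train = subject_table.rows(~test_mask)
        test = subject_table.rows(test_mask)
        if len(train) < 5:
            warnings.warn(f"trial fold {tid}: too few training rows; skipped")
            continue
        fold_table = train
        if select and len(train) >= 10:
            sel = fresh_select(train, q)
            keep = sel.selected + [f for f in train.feature_names if train.provenance[f] != "auto"]
            fold_table = train.with_features(keep)
        model = train_model(fold_table, spec)
        f = predict(model, test.data)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": test.data["subject_id"],
                    "trial_id": test.data["trial_id"],
                    "foot": test.data["foot"],
                    "y": test.y,
                    "f": f,
                }
            )
        )
    if not frames:
        return None
    return pd.concat(frames, ignore_index=True)


def sdm_cv(
    table: FeatureTable,
    spec: ModelSpec,
    q: float = 0.05,
    min_trials: int = 10,
    select: bool = True,
) -> EvaluationReport:
    """Subject-dependent setting: leave-one-trial-out for every subject."""
    frames = []
    for sid in sorted(table.data["subject_id"].unique()):
        sub = table.rows(table.data["subject_id"] == sid)
        pred = loto_cv(sub, spec, q, select)
        if pred is not None:
            frames.append(pred)
    if not frames:
        raise ValueError("no subject had enough trials for the subject-dependent setting")
    return aggregate_two_step(
        pd.concat(frames, ignore_index=True), min_trials, "subject_dependent", spec.learner
    )


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------


def high_impact_labels(subject_means: pd.Series) -> pd.Series:
    """Flag runners whose mean VILR lies in the highest third of the cohort.

    Nearest-rank rule: with n subjects the ceil(n/3) largest means are
    flagged; ties at the cutoff are all flagged.
    """
    n = len(subject_means)
    if n < 3:
        raise ValueError("need at least 3 subjects")
    k = int(np.ceil(n / 3))
    cutoff = np.sort(subject_means.to_numpy())[::-1][k - 1]
    return subject_means >= cutoff


def roc_curve(labels: pd.Series, scores: pd.Series) -> DiagnosticReport:
    """ROC over all score thresholds; AUC by the trapezoid rule.

    The chosen cutoff maximizes Youden's J (sensitivity + specificity - 1).
    """
    lab = labels.to_numpy(dtype=bool)
    sc = scores.loc[labels.index].to_numpy(dtype=float)
    n_pos, n_neg = int(lab.sum()), int((~lab).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    thresholds = np.concatenate([[np.inf], np.sort(np.unique(sc))[::-1]])
    tpr = np.array([(sc[lab] >= t).mean() for t in thresholds])
    fpr = np.array([(sc[~lab] >= t).mean() for t in thresholds])
    auc = float(np.trapezoid(tpr, fpr))
    j = tpr - fpr
    best = int(np.argmax(j))
    return DiagnosticReport(
        labels=labels,
        fpr=fpr,
        tpr=tpr,
        thresholds=thresholds,
        auc=auc,
        cutoff=float(thresholds[best]),
        sensitivity=float(tpr[best]),
        specificity=float(1.0 - fpr[best]),
    )


def screen_high_impact(
    true_subject_means: pd.Series, predicted_subject_means: pd.Series
) -> DiagnosticReport:
    """Label runners by true mean VILR, score them by predicted mean VILR."""
    labels = high_impact_labels(true_subject_means)
    return roc_curve(labels, predicted_subject_means)


def cumulative_error_curve(
    relative_errors: np.ndarray, thresholds: np.ndarray
) -> np.ndarray:
    """Fraction of predictions with relative error <= each threshold."""
    e = np.asarray(relative_errors, dtype=float)
    if not np.isfinite(e).all():
        raise ValueError("relative errors must be finite")
    t = np.asarray(thresholds, dtype=float)
    return np.array([(e <= ti).mean() for ti in t])


def cohens_drm(errors_a: np.ndarray, errors_b: np.ndarray) -> EffectSize:
    """Repeated-measures Cohen's d for paired samples.

    d_rm = (M1 - M2) / sqrt(SD1^2 + SD2^2 - 2 r SD1 SD2) * sqrt(2 (1 - r)),
    with r the Pearson correlation of the paired values; the denominator
    before the sqrt(2(1-r)) factor equals the SD of the paired differences,
    so a zero-variance nonzero difference is undefined (reported missing)
    and identical samples give d = 0. Bins use |d|: small <= 0.2 < medium
    <= 0.8 < large.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("need paired samples of equal length >= 2")
    if np.array_equal(a, b):
        return EffectSize.from_d(0.0)
    diff_sd = float(np.std(a - b, ddof=1))
    sd_a, sd_b = float(np.std(a, ddof=1)), float(np.std(b, ddof=1))
    if diff_sd == 0 or sd_a == 0 or sd_b == 0:
        return EffectSize(None, None)
    r = float(np.corrcoef(a, b)[0, 1])
    d = (a.mean() - b.mean()) / diff_sd * np.sqrt(2.0 * (1.0 - r))
    return EffectSize.from_d(d)
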