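"""Per-stride feature construction and FRESH univariate selection.

Three feature categories feed the loading-rate regressors:

* auto-generated statistical features of the impact-window signals — a
  fixed, named catalog (25 features per channel over 16 channels: the six
  filtered acceleration channels of both legs, their jerk, and each leg's
  roll and pitch);
* trial-specific features: running speed, ground contact time, and the
  axial peak tibial acceleration (APTA);
* subject-describing features: body weight and one-hot shoe category.

Auto-generated features are screened by the FRESH procedure: a univariate
significance test per feature against the target (Kendall rank test for
real-valued features, two-sample Kolmogorov-Smirnov for binary ones)
followed by Benjamini-Yekutieli step-up control of the false discovery
rate, which is valid under arbitrary dependence between the feature tests.
Trial and subject features bypass selection.
"""

from __future__ import annotations

import warnings
from collections import OrderedDict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy import stats

from .gait import (
    DEFAULT_FILTER,
    FilterConfig,
    StrideWindow,
    derive_channels,
    detect_gait_events,
    extract_impact_window,
    mirror_strides,
    segment_strides,
)
from .grf import compute_apta, reference_vilr_per_stance
from .io import admit_trial
from .trial import SHOE_CATEGORIES, TrialRecording

META_COLUMNS = ("subject_id", "trial_id", "foot", "mirrored")
TARGET_COLUMN = "target_vilr"

AR_ORDER = 4
N_FFT = 8
CWT_WIDTHS = (2, 5, 10, 20)


# ---------------------------------------------------------------------------
# Feature catalog
# ---------------------------------------------------------------------------


def _channel_features(x: np.ndarray, sampling_rate: float) -> OrderedDict:
    """The named per-channel catalog, in fixed order."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    f: OrderedDict[str, float] = OrderedDict()
    f["mean"] = float(np.mean(x))
    f["max"] = float(np.max(x))
    f["min"] = float(np.min(x))
    f["std"] = float(np.std(x))
    f["mean_abs_change"] = float(np.mean(np.abs(np.diff(x))))
    t = np.arange(n)
    coef = np.polyfit(t, x, 1)
    f["linear_trend_residual_sd"] = float(np.std(x - np.polyval(coef, t)))
    interior = x[1:-1]
    f["n_peaks"] = float(np.sum((interior > x[:-2]) & (interior > x[2:])))
    f["time_to_peak_ms"] = float(np.argmax(x) * 1000.0 / sampling_rate)
    # autoregressive coefficients, least squares, no intercept
    if n >= 2 * AR_ORDER + 1:
        rows = np.column_stack([x[AR_ORDER - i - 1 : n - i - 1] for i in range(AR_ORDER)])
        ar, *_ = np.linalg.lstsq(rows, x[AR_ORDER:], rcond=None)
    else:
        ar = np.full(AR_ORDER, np.nan)
    for i in range(AR_ORDER):
        f[f"ar_coef_{i}"] = float(ar[i])
    mags = np.abs(np.fft.rfft(x))
    for i in range(N_FFT):
        f[f"fft_mag_{i}"] = float(mags[i]) if i < len(mags) else np.nan
    coeffs, _ = pywt.cwt(x, scales=list(CWT_WIDTHS), wavelet="mexh")
    mid = n // 2
    for w, row in zip(CWT_WIDTHS, coeffs):
        f[f"cwt_w{w}"] = float(row[mid])
    if n >= 3:
        f["time_reversal_asymmetry"] = float(
            np.mean(x[2:] ** 2 * x[1:-1] - x[1:-1] * x[:-2] ** 2)
        )
    else:
        f["time_reversal_asymmetry"] = np.nan
    return f


def compute_feature_catalog(
    channels: dict[str, np.ndarray],
    sampling_rate: float = 1000.0,
) -> OrderedDict:
    """Named auto-generated features over a dict of same-length channels.

    Returns ``{channel}__{feature}`` keys in fixed, documented order.
    Raises if any channel is shorter than 4 samples.
    """
    out: OrderedDict[str, float] = OrderedDict()
    for name, x in channels.items():
        x = np.asarray(x, dtype=float)
        if len(x) < 4:
            raise ValueError(f"channel {name!r} shorter than 4 samples")
        for feat, value in _channel_features(x, sampling_rate).items():
            out[f"{name}__{feat}"] = value
    return out


def stride_channels(stride: StrideWindow) -> dict[str, np.ndarray]:
    """The 16 impact-window channels of one (mirrored) stride."""
    if stride.impact_window is None:
        extract_impact_window(stride)
    i0, i1 = stride.impact_window
    chans: dict[str, np.ndarray] = {}
    for leg in ("lead", "trail"):
        seg = stride.accel[leg][i0:i1]
        for j, axis in enumerate(("ax", "ap", "ml")):
            chans[f"{leg}_{axis}"] = seg[:, j]
        derived = derive_channels(seg, stride.sampling_rate)
        for j, axis in enumerate(("ax", "ap", "ml")):
            chans[f"{leg}_jerk_{axis}"] = derived.jerk[:, j]
        chans[f"{leg}_roll"] = derived.roll
        chans[f"{leg}_pitch"] = derived.pitch
    return chans


# ---------------------------------------------------------------------------
# Univariate tests and FDR control
# ---------------------------------------------------------------------------


def kendall_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Kendall rank-test p-value.

    Exact null distribution for n <= 8 tie-free samples, tie-adjusted
    normal approximation otherwise. A constant input carries no evidence
    against independence, so p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return 1.0
    tie_free = len(np.unique(x)) == len(x) and len(np.unique(y)) == len(y)
    method = "exact" if (len(x) <= 8 and tie_free) else "asymptotic"
    return float(stats.kendalltau(x, y, method=method).pvalue)


def ks_pvalue(binary_feature: np.ndarray, y: np.ndarray) -> float:
    """Two-sample Kolmogorov-Smirnov p-value between the two feature groups."""
    b = np.asarray(binary_feature)
    y = np.asarray(y, dtype=float)
    values = np.unique(b)
    if len(values) > 2:
        raise ValueError("feature is not binary")
    if len(values) < 2:
        return 1.0
    g0, g1 = y[b == values[0]], y[b == values[1]]
    if len(g0) == 0 or len(g1) == 0:
        return 1.0
    return float(stats.ks_2samp(g0, g1, method="auto").pvalue)


def benjamini_yekutieli(p_values: np.ndarray, q: float) -> np.ndarray:
    """Benjamini-Yekutieli step-up rejection mask at FDR level ``q``.

    With m p-values and harmonic correction c(m) = sum_{i=1..m} 1/i, the
    k* = max{k : p_(k) <= k q / (m c(m))} smallest p-values are rejected
    (all of them if ties straddle p_(k*)); none if no such k exists.
    """
    if not (0 < q < 1):
        raise ValueError("q must be in (0, 1)")
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return np.zeros(0, dtype=bool)
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    p_sorted = np.sort(p)
    k = np.arange(1, m + 1)
    passing = np.nonzero(p_sorted <= k * q / (m * c_m))[0]
    if len(passing) == 0:
        return np.zeros(m, dtype=bool)
    threshold = p_sorted[passing[-1]]
    return p <= threshold


@dataclass
class SelectionResult:
    """Outcome of FRESH selection over the auto-generated features."""

    table: pd.DataFrame  # index: feature; columns: p_value, test, selected
    q: float

    @property
    def selected(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])


@dataclass
class FeatureTable:
    """Per-stride feature rows aligned with the force-plate VILR target."""

    data: pd.DataFrame
    provenance: dict[str, str] = field(default_factory=dict)  # feature -> auto|trial|subject

    def __post_init__(self) -> None:
        missing = [c for c in (*META_COLUMNS, TARGET_COLUMN) if c not in self.data.columns]
        if missing:
            raise ValueError(f"feature table missing columns {missing}")
        unknown = [f for f in self.provenance if f not in self.data.columns]
        if unknown:
            raise ValueError(f"provenance refers to absent features {unknown[:3]}")

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.data.columns if c in self.provenance]

    def features_of(self, kind: str) -> list[str]:
        return [f for f in self.feature_names if self.provenance[f] == kind]

    @property
    def y(self) -> np.ndarray:
        return self.data[TARGET_COLUMN].to_numpy(dtype=float)

    def rows(self, mask) -> "FeatureTable":
        return FeatureTable(self.data.loc[mask].reset_index(drop=True), dict(self.provenance))

    def with_features(self, keep: list[str]) -> "FeatureTable":
        cols = list(META_COLUMNS) + [f for f in self.feature_names if f in set(keep)] + [TARGET_COLUMN]
        prov = {f: self.provenance[f] for f in self.feature_names if f in set(keep)}
        return FeatureTable(self.data[cols].copy(), prov)

    def __len__(self) -> int:
        return len(self.data)


def fresh_select(table: FeatureTable, q: float = 0.05) -> SelectionResult:
    """FRESH univariate relevance screening of the auto-generated features.

    Each auto feature is tested against the target (Kendall for real-valued
    features, Kolmogorov-Smirnov for features taking at most two distinct
    values); the Benjamini-Yekutieli procedure is applied jointly over all
    auto features at level ``q``. Trial and subject features are not
    screened (they are always kept downstream).
    """
    if len(table) < 10:
        raise ValueError("need at least 10 rows for selection")
    y = table.y
    names = table.features_of("auto")
    p_values, tests = [], []
    for name in names:
        col = table.data[name].to_numpy(dtype=float)
        valid = np.isfinite(col) & np.isfinite(y)
        xv, yv = col[valid], y[valid]
        distinct = np.unique(xv)
        if len(xv) < 3 or len(distinct) < 2:
            p, test = 1.0, "kendall"
        elif len(distinct) <= 2:
            p, test = ks_pvalue(xv, yv), "ks"
        else:
            p, test = kendall_pvalue(xv, yv), "kendall"
        p_values.append(p)
        tests.append(test)
    mask = benjamini_yekutieli(np.asarray(p_values), q) if names else np.zeros(0, bool)
    result = pd.DataFrame(
        {"p_value": p_values, "test": tests, "selected": mask}, index=pd.Index(names, name="feature")
    )
    return SelectionResult(result, q)


# ---------------------------------------------------------------------------
# Table assembly
# ---------------------------------------------------------------------------


def assemble_features(
    trials: list[TrialRecording],
    selection: SelectionResult | None = None,
    include_subject: bool = True,
    filter_config: FilterConfig = DEFAULT_FILTER,
    min_window_samples: int = 4,
) -> FeatureTable:
    """Build the per-stride feature table for a list of trials.

    Per admitted trial: detect gait events, segment and mirror strides (both
    feet's stances become right-lead examples), extract impact windows,
    compute the auto catalog plus APTA, speed and ground contact time, and —
    when ``include_subject`` — body weight (N) and one-hot shoe category.
    The target is the force-plate reference VILR of the matching contact;
    strides without a matching contact or with a degenerate impact window
    are dropped with a warning.
    """
    records: list[dict] = []
    provenance: dict[str, str] = {}
    for trial in trials:
        adm = admit_trial(trial)
        if not adm.accepted:
            warnings.warn(f"trial {trial.subject_id}/{trial.trial_id} not admitted: {adm.reason}")
            continue
        refs = reference_vilr_per_stance(trial)
        events = detect_gait_events(trial, filter_config)
        strides = mirror_strides(segment_strides(trial, events, filter_config))
        for stride in strides:
            i0, i1 = extract_impact_window(stride)
            if i1 - i0 < min_window_samples:
                warnings.warn("impact window too short; stride dropped")
                continue
            ic_abs_ms = stride.start_ms + 1000.0 * stride.ic_index / stride.sampling_rate
            target = _target_for(refs, ic_abs_ms)
            if target is None:
                warnings.warn("no force contact matches stride; stride dropped")
                continue
            auto = compute_feature_catalog(stride_channels(stride), stride.sampling_rate)
            row: dict = {
                "subject_id": stride.subject_id,
                "trial_id": stride.trial_id,
                "foot": stride.original_foot,
                "mirrored": stride.mirrored,
                TARGET_COLUMN: target,
            }
            row.update(auto)
            for name in auto:
                provenance.setdefault(name, "auto")
            row["apta"] = compute_apta(stride.accel["lead"][i0:i1, 0])
            row["speed"] = trial.speed
            row["gct_ms"] = stride.stance_ms
            provenance.setdefault("apta", "trial")
            provenance.setdefault("speed", "trial")
            provenance.setdefault("gct_ms", "trial")
            if include_subject:
                row["body_weight_n"] = trial.body_weight
                provenance.setdefault("body_weight_n", "subject")
                for cat in SHOE_CATEGORIES:
                    row[f"shoe_{cat}"] = float(trial.shoe_category == cat)
                    provenance.setdefault(f"shoe_{cat}", "subject")
            records.append(row)
    if not records:
        raise ValueError("no usable strides in the given trials")
    table = FeatureTable(pd.DataFrame.from_records(records), provenance)
    if selection is not None:
        keep = set(selection.selected) | {
            f for f in table.feature_names if table.provenance[f] != "auto"
        }
        table = table.with_features(sorted(keep, key=table.feature_names.index))
    return table


def _target_for(refs: list[dict], ic_ms: float, slack_ms: float = 40.0) -> float | None:
    for r in refs:
        if r["start_ms"] - slack_ms <= ic_ms <= r["end_ms"]:
            return r["vilr"]
    return None
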