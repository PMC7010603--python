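"""Force-plate reference computations.

The vertical instantaneous loading rate (VILR) is the maximal slope of the
rising vertical ground reaction force after initial contact, normalized to
body weight. This module implements the reference pipeline used to produce
the regression target: zero-phase low-pass filtering of the force, 5 N
contact detection, and the forward-difference loading-rate maximum. It also
provides the axial peak tibial acceleration (APTA), the traditional
single-number accelerometer surrogate the learned models are compared to.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .trial import TrialRecording

#: Force threshold (N) defining ground contact.
CONTACT_THRESHOLD_N = 5.0


class NoContactError(ValueError):
    """Raised when no sample of the force signal exceeds the contact threshold."""


@dataclass
class ForceSignal:
    samples: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.samples.ndim != 1:
            raise ValueError("force signal must be one-dimensional")


@dataclass
class LoadingRateResult:
    vilr: float  # BW s^-1
    ic_index: int
    argmax_index: int
    body_weight: float  # N


def lowpass_grf(force: ForceSignal, cutoff: float = 60.0, order: int = 2) -> ForceSignal:
    """Zero-lag low-pass Butterworth filter for ground reaction forces.

    Applied forward-backward (``filtfilt``), so the effective magnitude
    response is the squared Butterworth magnitude and the phase is zero.
    """
    nyquist = force.sampling_rate / 2.0
    if cutoff >= nyquist:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist {nyquist} Hz")
    sos = signal.butter(order, cutoff, btype="low", fs=force.sampling_rate, output="sos")
    filtered = signal.sosfiltfilt(sos, force.samples)
    return ForceSignal(filtered, force.sampling_rate)


def detect_initial_contact(force: ForceSignal, threshold: float = CONTACT_THRESHOLD_N) -> int:
    """First sample index where the force strictly exceeds ``threshold``."""
    if len(force.samples) == 0:
        raise NoContactError("empty force signal")
    above = np.nonzero(force.samples > threshold)[0]
    if len(above) == 0:
        raise NoContactError(f"no sample exceeds {threshold} N")
    return int(above[0])


def _stance_end(samples: np.ndarray, ic: int, threshold: float) -> int:
    """Exclusive end of the stance: first index after ``ic`` back below threshold."""
    below = np.nonzero(samples[ic:] < threshold)[0]
    if len(below) == 0:
        return len(samples)
    return ic + int(below[0])


def compute_vilr(
    force: ForceSignal,
    body_weight: float,
    threshold: float = CONTACT_THRESHOLD_N,
) -> LoadingRateResult:
    """Maximal vertical instantaneous loading rate of one stance phase.

    The derivative is estimated by forward differences scaled by the
    sampling rate, searched from initial contact to the end of stance
    (first return below the contact threshold); the maximum is divided by
    body weight (N). Ties resolve to the first occurrence.
    """
    if body_weight <= 0:
        raise ValueError("body_weight must be positive")
    ic = detect_initial_contact(force, threshold)
    end = _stance_end(force.samples, ic, threshold)
    segment = force.samples[ic:end]
    if len(segment) < 2:
        return LoadingRateResult(0.0, ic, ic, body_weight)
    deriv = np.diff(segment) * force.sampling_rate
    k = int(np.argmax(deriv))
    vilr = float(deriv[k]) / body_weight
    return LoadingRateResult(max(vilr, 0.0), ic, ic + k, body_weight)


def compute_apta(axial_accel_window: np.ndarray) -> float:
    """Axial peak tibial acceleration: maximum of the axial component (g).

    The window should span the impact phase of the stance. Ties resolve to
    the first occurrence (irrelevant for the value itself).
    """
    window = np.asarray(axial_accel_window, dtype=float)
    if window.size == 0:
        raise ValueError("empty acceleration window")
    return float(np.max(window))


def contact_spans(
    force: ForceSignal,
    threshold: float = CONTACT_THRESHOLD_N,
    min_duration_ms: float = 100.0,
) -> list[tuple[int, int]]:
    """Half-open ``[start, end)`` index spans of ground contact.

    A span is a maximal run of samples above ``threshold``; runs shorter
    than ``min_duration_ms`` (noise blips) are discarded.
    """
    above = force.samples > threshold
    if not above.any():
        return []
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = list(edges[~above[edges]] + 1)
    ends = list(edges[above[edges]] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(above))
    min_len = int(min_duration_ms * force.sampling_rate / 1000.0)
    return [(int(s), int(e)) for s, e in zip(starts, ends) if e - s >= min_len]


def reference_vilr_per_stance(
    trial: TrialRecording,
    cutoff: float = 60.0,
    order: int = 2,
) -> list[dict]:
    """Force-plate reference VILR for every stance in a trial.

    Runs the full reference pipeline (zero-lag low-pass, contact detection,
    forward-difference maximum) on each contact span of the trial's vGRF.
    Returns one dict per stance with ``start_ms``, ``end_ms`` (span bounds)
    and ``vilr`` (BW s^-1).
    """
    force = ForceSignal(trial.vgrf, trial.sampling_rate)
    filtered = lowpass_grf(force, cutoff=cutoff, order=order)
    out = []
    for start, end in contact_spans(filtered):
        pad = int(0.020 * trial.sampling_rate)  # include sub-threshold shoulders
        lo, hi = max(0, start - pad), min(len(filtered.samples), end + pad)
        seg = ForceSignal(filtered.samples[lo:hi], trial.sampling_rate)
        try:
            res = compute_vilr(seg, trial.body_weight)
        except NoContactError:  # pragma: no cover - span implies contact
            continue
        out.append(
            {
                "start_ms": trial.index_to_ms(start),
                "end_ms": trial.index_to_ms(end),
                "vilr": res.vilr,
            }
        )
    return out
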