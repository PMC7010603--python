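"""Core in-memory containers for synchronized running trials.

A trial is one pass over the force platforms: bilateral tri-axial tibial
acceleration (in g) synchronized with the vertical ground reaction force
(in N), all sampled on a common clock. Acceleration axes follow the fixed
convention ``(axial, anteroposterior, mediolateral)`` with the axial axis
positive upward along the tibia.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Column order of every tri-axial acceleration array in this package.
AXES = ("axial", "anteroposterior", "mediolateral")

#: Shoe categories, in the one-hot encoding order used throughout.
SHOE_CATEGORIES = ("neutral", "stabilization", "racing_flat")

#: Acceleration magnitude (g) treated as the sensor range limit.
DEFAULT_SATURATION_G = 40.0

GRAVITY = 9.81  # m s^-2, converts body mass (kg) to body weight (N)


@dataclass
class GroundTruth:
    """Per-stance generator truth attached to synthetic trials.

    Times are absolute within the trial, in milliseconds. ``true_vilr`` is
    the analytic maximal slope of the constructed vertical ground reaction
    force, normalized to body weight (BW s^-1).
    """

    true_vilr: float
    ic_time: float
    to_time: float
    landing_foot: str  # "left" | "right"
    latent_features: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        if self.landing_foot not in ("left", "right"):
            raise ValueError(f"landing_foot must be left/right, got {self.landing_foot!r}")
        stance = self.to_time - self.ic_time
        if not (160.0 <= stance <= 350.0):
            raise ValueError(f"stance duration {stance:.1f} ms outside [160, 350] ms")
        if self.true_vilr <= 0:
            raise ValueError("true_vilr must be positive")


@dataclass
class TrialRecording:
    """One synchronized running trial.

    ``accel_left``/``accel_right`` are ``(n, 3)`` arrays in g, axes per
    :data:`AXES`; ``vgrf`` is an ``(n,)`` array in N on the same clock.
    """

    subject_id: str
    trial_id: str
    sampling_rate: float
    accel_left: np.ndarray
    accel_right: np.ndarray
    vgrf: np.ndarray
    speed: float
    target_speed: float | None
    body_mass: float
    shoe_category: str
    ground_truth: list[GroundTruth] | None = None
    artifact: str | None = None  # set by inject_artifacts for QC testing

    def __post_init__(self) -> None:
        self.accel_left = np.asarray(self.accel_left, dtype=float)
        self.accel_right = np.asarray(self.accel_right, dtype=float)
        self.vgrf = np.asarray(self.vgrf, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.accel_left.shape != self.accel_right.shape:
            raise ValueError("left/right acceleration arrays must have equal shape")
        if self.accel_left.ndim != 2 or self.accel_left.shape[1] != 3:
            raise ValueError("acceleration arrays must be (n, 3)")
        if len(self.vgrf) != len(self.accel_left):
            raise ValueError("vgrf and acceleration series must share length")
        if self.shoe_category not in SHOE_CATEGORIES:
            raise ValueError(f"unknown shoe category {self.shoe_category!r}")
        if self.body_mass <= 0:
            raise ValueError("body_mass must be positive")

    @property
    def n_samples(self) -> int:
        return len(self.vgrf)

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.n_samples / self.sampling_rate

    @property
    def body_weight(self) -> float:
        """Body weight in N (mass x standard gravity)."""
        return self.body_mass * GRAVITY

    def accel(self, foot: str) -> np.ndarray:
        if foot == "left":
            return self.accel_left
        if foot == "right":
            return self.accel_right
        raise ValueError(f"foot must be left/right, got {foot!r}")

    def ms_to_index(self, t_ms: float) -> int:
        return int(round(t_ms * self.sampling_rate / 1000.0))

    def index_to_ms(self, i: int) -> float:
        return 1000.0 * i / self.sampling_rate
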