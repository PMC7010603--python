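"""Synthetic running cohorts with known ground-truth loading rates.

The generator emulates the statistical structure the downstream analysis
assumes: overground rearfoot-strike running trials in which bilateral
tri-axial tibial acceleration and the vertical ground reaction force (vGRF)
are synchronized at 1000 Hz, with a latent per-subject tibial-shock
intensity that couples monotonically to the true maximal vertical
instantaneous loading rate (VILR).

Each stance's vGRF is the sum of two lobes — an early raised-cosine impact
transient and a ``sin^2`` active peak spanning the stance — the standard
two-peak rearfoot morphology. Because the construction is analytic, the true
VILR of every stance is obtained from the closed-form derivative (evaluated
on a fine grid) rather than re-measured from the sampled signal.

The acceleration channels are driven by the same latent quantities: the
landing leg's axial channel carries a differentiated-transient impact shape
(peaking at half the impact-rise time, crossing 0 g at the impact peak)
plus a damped post-impact oscillation; anteroposterior and mediolateral
channels are attenuated, phase-shifted copies, with a push-off burst on the
anteroposterior channel at toe-off; the contralateral leg receives a small
transmitted copy. A per-subject sensor gain (mounting/coupling
heterogeneity) and a right/left asymmetry ratio make the acceleration-to-
VILR map subject-specific, which is what separates subject-dependent from
subject-independent modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .trial import (
    DEFAULT_SATURATION_G,
    GRAVITY,
    SHOE_CATEGORIES,
    GroundTruth,
    TrialRecording,
)

#: Generator coupling weights linking the latent impact descriptors to the
#: constructed force and acceleration waveforms. ``impact_amp`` is the impact
#: transient's peak in body weights per unit impact level; ``width_ms`` the
#: impact rise time at 3.2 m/s; ``speed_exp`` the power-law speed modulation
#: of the impact amplitude; ``active_base``/``active_slope`` set the active
#: peak in body weights as ``active_base + active_slope * speed``;
#: ``axial_gain_g`` the axial transient peak in g per unit impact level.
DEFAULT_COUPLING: dict[str, float] = {
    "impact_amp": 0.9,
    "width_ms": 40.0,
    "width_exp": 0.45,
    "speed_exp": 1.2,
    "active_base": 1.9,
    "active_slope": 0.19,
    "axial_gain_g": 8.0,
    "mass_exp": 0.25,
}

#: Force-side impact multiplier per shoe category: footwear changes the
#: transmitted loading without an equivalent change in shank acceleration,
#: which is what makes shoe type an informative subject feature.
SHOE_IMPACT: dict[str, float] = {
    "neutral": 1.0,
    "stabilization": 0.90,
    "racing_flat": 1.18,
}

PREFERRED = "preferred"  # sentinel in the speeds list


@dataclass
class SubjectProfile:
    """Latent description of one runner."""

    subject_id: str
    body_mass: float  # kg
    preferred_speed: float  # m s^-1
    shoe_category: str
    impact_level: float  # dimensionless tibial-shock intensity, > 0
    asymmetry_ratio: float  # right/left impact multiplier, > 0
    cadence: float  # strides per minute
    accel_gain: float = 1.0  # per-subject sensor mounting gain

    def __post_init__(self) -> None:
        if self.body_mass <= 0:
            raise ValueError("body_mass must be positive")
        if self.impact_level <= 0:
            raise ValueError("impact_level must be positive")
        if self.asymmetry_ratio <= 0:
            raise ValueError("asymmetry_ratio must be positive")
        if self.shoe_category not in SHOE_CATEGORIES:
            raise ValueError(f"shoe_category must be one of {SHOE_CATEGORIES}")

    @property
    def body_weight(self) -> float:
        return self.body_mass * GRAVITY


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    ``strides_per_trial``: ``None`` draws 2 or 3 stances per trial with
    probability 1/3 and 2/3 (mean 2.67); an int fixes the count; a
    ``(lo, hi)`` tuple draws uniformly over the inclusive range.
    """

    n_subjects: int = 30
    trials_per_subject: int = 15
    strides_per_trial: int | tuple[int, int] | None = None
    speeds: tuple = (2.55, 3.20, 5.10, PREFERRED)
    sampling_rate: float = 1000.0
    noise_sd_accel: float = 0.25  # g
    noise_sd_force: float = 1.0  # N
    coupling_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COUPLING)
    )
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.trials_per_subject < 1:
            raise ValueError("subject and trial counts must be >= 1")
        if isinstance(self.strides_per_trial, int) and self.strides_per_trial < 1:
            raise ValueError("strides_per_trial must be >= 1")
        if self.noise_sd_accel < 0 or self.noise_sd_force < 0:
            raise ValueError("noise SDs must be nonnegative")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")


# ---------------------------------------------------------------------------
# Per-stance parameterization and waveforms
# ---------------------------------------------------------------------------


def _stance_params(
    profile: SubjectProfile,
    speed: float,
    foot: str,
    rng: np.random.Generator,
    coupling: dict[str, float] | None = None,
) -> dict:
    """Draw the analytic parameters of one stance."""
    c = dict(DEFAULT_COUPLING)
    if coupling:
        c.update(coupling)
    side = profile.asymmetry_ratio if foot == "right" else 1.0
    bw = profile.body_weight
    speed_f = speed / 3.2

    stance_ms = float(np.clip(330.0 - 25.0 * speed + rng.normal(0.0, 8.0), 172.0, 345.0))
    # Impact rise time narrows with speed and with shock intensity, so both
    # the amplitude and the sharpness of the transient grow with the true
    # loading rate; the rise time is visible in the acceleration timing,
    # independent of any sensor gain.
    t_imp_ms = float(
        np.clip(
            c["width_ms"] * profile.impact_level ** -c["width_exp"] * speed_f**-0.5,
            20.0,
            52.0,
        )
    )
    a_imp = (
        c["impact_amp"]
        * profile.impact_level
        * side
        * SHOE_IMPACT[profile.shoe_category]
        * (70.0 / profile.body_mass) ** c["mass_exp"]
        * speed_f ** c["speed_exp"]
    )
    amp_imp_n = a_imp * bw
    amp_act_n = (c["active_base"] + c["active_slope"] * speed) * bw
    axial_peak_g = (
        c["axial_gain_g"] * profile.impact_level * side * profile.accel_gain * speed_f**0.8
    )
    return {
        "foot": foot,
        "speed": speed,
        "body_weight": bw,
        "stance_ms": stance_ms,
        "t_imp_ms": t_imp_ms,
        "amp_imp_n": amp_imp_n,
        "amp_act_n": amp_act_n,
        "axial_peak_g": axial_peak_g,
    }


def _force_stance(params: dict, t_ms: np.ndarray) -> np.ndarray:
    """Vertical GRF (N) on times ``t_ms`` measured from initial contact."""
    T = params["stance_ms"]
    ti = params["t_imp_ms"]
    f = np.zeros_like(t_ms, dtype=float)
    in_stance = (t_ms > 0) & (t_ms < T)
    # active peak: sin^2 lobe spanning the stance
    f[in_stance] += params["amp_act_n"] * np.sin(np.pi * t_ms[in_stance] / T) ** 2
    # impact transient: raised cosine centered at t_imp, half-width t_imp
    in_imp = (t_ms > 0) & (t_ms < 2 * ti)
    f[in_imp] += 0.5 * params["amp_imp_n"] * (1 + np.cos(np.pi * (t_ms[in_imp] - ti) / ti))
    return f


def _force_derivative(params: dict, t_ms: np.ndarray) -> np.ndarray:
    """Closed-form dF/dt (N/s) of :func:`_force_stance` at times ``t_ms``."""
    T = params["stance_ms"] / 1000.0
    ti = params["t_imp_ms"] / 1000.0
    t = t_ms / 1000.0
    d = np.zeros_like(t, dtype=float)
    in_stance = (t > 0) & (t < T)
    d[in_stance] += params["amp_act_n"] * np.pi / T * np.sin(2 * np.pi * t[in_stance] / T)
    in_imp = (t > 0) & (t < 2 * ti)
    d[in_imp] += (
        -params["amp_imp_n"] * np.pi / (2 * ti) * np.sin(np.pi * (t[in_imp] - ti) / ti)
    )
    return d


def _true_vilr(params: dict) -> float:
    """Analytic maximal loading rate (BW s^-1) of the constructed stance."""
    t = np.arange(0.0, params["stance_ms"], 0.02)  # 0.02 ms grid
    return float(np.max(_force_derivative(params, t)) / params["body_weight"])


def _axial_transient(params: dict, t_ms: np.ndarray) -> np.ndarray:
    """Landing-leg axial acceleration (g) at times from initial contact.

    Differentiated impact shape, positive peak at half the impact-rise time,
    zero crossing at the impact peak, negative rebound, then a damped 20 Hz
    oscillation through the remainder of the stance.
    """
    ti = params["t_imp_ms"]
    out = np.zeros_like(t_ms, dtype=float)
    in_imp = (t_ms >= 0) & (t_ms <= 2 * ti)
    out[in_imp] = -params["axial_peak_g"] * np.sin(np.pi * (t_ms[in_imp] - ti) / ti)
    tail = (t_ms > ti) & (t_ms < params["stance_ms"])
    dt = t_ms[tail] - ti
    out[tail] += (
        0.25
        * params["axial_peak_g"]
        * np.exp(-dt / 30.0)
        * np.sin(2 * np.pi * 0.020 * dt)
    )
    return out


def _raised_cos(t_ms: np.ndarray, center: float, half_width: float) -> np.ndarray:
    out = np.zeros_like(t_ms, dtype=float)
    m = np.abs(t_ms - center) < half_width
    out[m] = 0.5 * (1 + np.cos(np.pi * (t_ms[m] - center) / half_width))
    return out


def _add_stance_accel(
    accel: dict[str, np.ndarray],
    params: dict,
    ic_ms: float,
    sampling_rate: float,
) -> None:
    """Add one stance's acceleration content (in place) to both legs."""
    n = len(accel["left"])
    t_ms = np.arange(n) * 1000.0 / sampling_rate - ic_ms
    foot, other = params["foot"], ("left" if params["foot"] == "right" else "right")

    axial = _axial_transient(params, t_ms)
    # anteroposterior: attenuated, 5 ms delayed copy + toe-off push-off burst
    ap = 0.45 * _axial_transient(params, t_ms - 5.0)
    ap -= (
        2.5
        * (params["speed"] / 3.2)
        * (params["axial_peak_g"] / DEFAULT_COUPLING["axial_gain_g"] * 0.5 + 0.5)
        * _raised_cos(t_ms, params["stance_ms"], 12.0)
    )
    # mediolateral: attenuated, slightly advanced copy; physical sign flips
    # between legs (medial is mirrored across the sagittal plane)
    ml_sign = 1.0 if foot == "right" else -1.0
    ml = 0.30 * ml_sign * _axial_transient(params, t_ms + 3.0)

    accel[foot][:, 0] += axial
    accel[foot][:, 1] += ap
    accel[foot][:, 2] += ml
    # soft-tissue transmission to the contralateral shank
    accel[other][:, 0] += 0.12 * axial
    accel[other][:, 1] += 0.12 * ap
    accel[other][:, 2] += -0.12 * ml


# ---------------------------------------------------------------------------
# Public generator API
# ---------------------------------------------------------------------------


def simulate_stride(
    profile: SubjectProfile,
    speed: float,
    foot: str,
    rng: np.random.Generator,
    sampling_rate: float = 1000.0,
    noise_sd_accel: float = 0.0,
    noise_sd_force: float = 0.0,
    coupling: dict[str, float] | None = None,
    lead_in_ms: float = 60.0,
    tail_ms: float = 120.0,
) -> tuple[np.ndarray, dict[str, np.ndarray], GroundTruth]:
    """Generate one isolated stance: (vGRF, {left, right} accel, truth).

    The force starts and ends below the 5 N contact threshold; the truth's
    VILR is the analytic maximum slope of the constructed force.
    """
    if speed <= 0:
        raise ValueError("speed must be positive")
    if foot not in ("left", "right"):
        raise ValueError("foot must be left or right")
    params = _stance_params(profile, speed, foot, rng, coupling)
    n = int(round((lead_in_ms + params["stance_ms"] + tail_ms) * sampling_rate / 1000.0))
    t_ms = np.arange(n) * 1000.0 / sampling_rate
    vgrf = _force_stance(params, t_ms - lead_in_ms)
    accel = {"left": np.zeros((n, 3)), "right": np.zeros((n, 3))}
    _add_stance_accel(accel, params, lead_in_ms, sampling_rate)
    for leg in accel.values():
        leg[:, 0] += 1.0  # gravity offset on the raw axial channel
        if noise_sd_accel > 0:
            leg += rng.normal(0.0, noise_sd_accel, leg.shape)
    if noise_sd_force > 0:
        vgrf = np.clip(vgrf + rng.normal(0.0, noise_sd_force, n), 0.0, None)
    truth = GroundTruth(
        true_vilr=_true_vilr(params),
        ic_time=lead_in_ms,
        to_time=lead_in_ms + params["stance_ms"],
        landing_foot=foot,
        latent_features=np.array(
            [params["amp_imp_n"], params["t_imp_ms"], params["amp_act_n"], params["axial_peak_g"]]
        ),
    )
    return vgrf, accel, truth


def _sample_subjects(config: SimulationConfig, rng: np.random.Generator) -> list[SubjectProfile]:
    subjects = []
    for i in range(config.n_subjects):
        # cohort mass mixture follows the observed male/female split
        if rng.random() < 0.59:
            mass = rng.normal(76.5, 10.2)
        else:
            mass = rng.normal(60.6, 7.3)
        subjects.append(
            SubjectProfile(
                subject_id=f"S{i:03d}",
                body_mass=float(np.clip(mass, 45.0, 110.0)),
                preferred_speed=float(np.clip(rng.normal(3.4, 0.4), 2.6, 4.5)),
                shoe_category=SHOE_CATEGORIES[
                    rng.choice(3, p=[0.60, 0.25, 0.15])
                ],
                impact_level=float(np.clip(rng.lognormal(0.0, 0.25), 0.55, 1.8)),
                asymmetry_ratio=float(np.clip(rng.lognormal(0.0, 0.10), 0.80, 1.25)),
                cadence=float(np.clip(rng.normal(83.0, 4.0), 72.0, 95.0)),
                accel_gain=float(np.clip(rng.lognormal(0.0, 0.15), 0.72, 1.40)),
            )
        )
    return subjects


def _n_stances(config: SimulationConfig, rng: np.random.Generator) -> int:
    spt = config.strides_per_trial
    if spt is None:
        return 3 if rng.random() < 2.0 / 3.0 else 2
    if isinstance(spt, int):
        return spt
    lo, hi = spt
    return int(rng.integers(lo, hi + 1))


def generate_trial(
    profile: SubjectProfile,
    trial_id: str,
    target_speed: float,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> TrialRecording:
    """One multi-stance overground trial for a subject at a target speed."""
    fs = config.sampling_rate
    speed = float(target_speed + np.clip(rng.normal(0.0, 0.05), -0.15, 0.15))
    n_stance = _n_stances(config, rng)
    cadence = profile.cadence * (1.0 + 0.06 * (speed - 3.2))
    step_ms = 60000.0 / cadence / 2.0

    params_list = []
    foot = "right" if rng.random() < 0.5 else "left"
    ic_times = []
    t0 = 150.0
    for k in range(n_stance):
        params_list.append(_stance_params(profile, speed, foot, rng, config.coupling_coefficients))
        foot = "left" if foot == "right" else "right"
    # keep a physiological flight phase between consecutive contacts
    step_ms = max(step_ms, max(p["stance_ms"] for p in params_list) + 85.0)
    for k in range(n_stance):
        ic_times.append(t0 + k * step_ms)

    duration_ms = ic_times[-1] + params_list[-1]["stance_ms"] + 400.0
    n = int(round(duration_ms * fs / 1000.0))
    t_ms = np.arange(n) * 1000.0 / fs
    vgrf = np.zeros(n)
    accel = {"left": np.zeros((n, 3)), "right": np.zeros((n, 3))}
    truths = []
    for ic, params in zip(ic_times, params_list):
        vgrf += _force_stance(params, t_ms - ic)
        _add_stance_accel(accel, params, ic, fs)
        truths.append(
            GroundTruth(
                true_vilr=_true_vilr(params),
                ic_time=ic,
                to_time=ic + params["stance_ms"],
                landing_foot=params["foot"],
                latent_features=np.array(
                    [
                        params["amp_imp_n"],
                        params["t_imp_ms"],
                        params["amp_act_n"],
                        params["axial_peak_g"],
                    ]
                ),
            )
        )

    for leg_name in ("left", "right"):
        leg = accel[leg_name]
        leg[:, 0] += 1.0  # gravity on raw axial
        # low-frequency gait sway at the stride frequency (inside the passband)
        phase = 0.0 if leg_name == "right" else np.pi
        leg[:, 0] += 0.3 * np.sin(2 * np.pi * t_ms / (2 * step_ms) + phase)
        if config.noise_sd_accel > 0:
            leg += rng.normal(0.0, config.noise_sd_accel, leg.shape)
    if config.noise_sd_force > 0:
        vgrf = np.clip(vgrf + rng.normal(0.0, config.noise_sd_force, n), 0.0, None)

    return TrialRecording(
        subject_id=profile.subject_id,
        trial_id=trial_id,
        sampling_rate=fs,
        accel_left=accel["left"],
        accel_right=accel["right"],
        vgrf=vgrf,
        speed=speed,
        target_speed=float(target_speed),
        body_mass=profile.body_mass,
        shoe_category=profile.shoe_category,
        ground_truth=truths,
    )


def generate_cohort(
    config: SimulationConfig,
    return_profiles: bool = False,
) -> list[TrialRecording] | tuple[list[TrialRecording], list[SubjectProfile]]:
    """Generate a full cohort of trials, deterministic in ``config.rng_seed``.

    Each subject runs ``trials_per_subject`` trials whose target speeds cycle
    through ``config.speeds`` (the sentinel ``"preferred"`` resolves to the
    subject's preferred speed).
    """
    rng = np.random.default_rng(config.rng_seed)
    subjects = _sample_subjects(config, rng)
    trials: list[TrialRecording] = []
    for profile in subjects:
        for j in range(config.trials_per_subject):
            target = config.speeds[j % len(config.speeds)]
            if target == PREFERRED:
                target = profile.preferred_speed
            trials.append(
                generate_trial(profile, f"T{j:03d}", float(target), config, rng)
            )
    if return_profiles:
        return trials, subjects
    return trials


def inject_artifacts(
    trial: TrialRecording,
    kind: str,
    rng: np.random.Generator,
    saturation_g: float = DEFAULT_SATURATION_G,
) -> TrialRecording:
    """Return a copy of ``trial`` carrying a quality-control-failing artifact.

    ``force_dropout`` zeroes a contiguous mid-stance span of the force;
    ``accel_saturation`` pins a span of one leg's axial channel at the
    sensor range limit. The returned trial is flagged via ``artifact``.
    """
    if kind not in ("force_dropout", "accel_saturation"):
        raise ValueError(f"unknown artifact kind {kind!r}")
    new = replace(
        trial,
        accel_left=trial.accel_left.copy(),
        accel_right=trial.accel_right.copy(),
        vgrf=trial.vgrf.copy(),
        artifact=kind,
    )
    if not trial.ground_truth:
        raise ValueError("artifact injection requires ground-truth stance times")
    gt = trial.ground_truth[int(rng.integers(len(trial.ground_truth)))]
    mid = trial.ms_to_index((gt.ic_time + gt.to_time) / 2.0)
    if kind == "force_dropout":
        span = int(0.030 * trial.sampling_rate)  # 30 ms > 20 ms QC rule
        new.vgrf[mid : mid + span] = 0.0
    else:
        span = max(3, int(0.020 * trial.sampling_rate))
        leg = new.accel_left if gt.landing_foot == "left" else new.accel_right
        leg[mid : mid + span, 0] = saturation_g
    return new
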