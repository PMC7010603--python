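# Methods

`tibload` estimates the maximal vertical instantaneous loading rate (VILR)
of overground running — the peak slope of the rising vertical ground
reaction force (vGRF) after initial contact, in body weights per second
(BW·s⁻¹) — from bilateral tri-axial shin-mounted accelerometers, and
validates the whole chain on synthetic cohorts with analytic ground truth.
This note documents the models, the defaults and their rationale, the
numerical choices, and what the synthetic validation does and does not show.

## Force-plate reference

The reference value every model is trained against is computed from the
vGRF exactly as a gait laboratory would:

1. zero-lag low-pass Butterworth filter, cutoff 60 Hz, order 2, applied
   forward–backward (`scipy.signal.sosfiltfilt`), so the effective magnitude
   response is the squared Butterworth magnitude and the phase is zero;
2. initial contact (IC) at the first sample strictly above 5 N;
3. VILR = max of the forward-difference derivative from IC to the end of
   stance (first return below 5 N), divided by body weight.

Numerical conventions: the derivative estimator is the forward difference
`(f[i+1] − f[i]) · rate` (the instantaneous-slope reading used in the
loading-rate literature); ties in the maximum resolve to the first
occurrence; body weight is mass × 9.81 m·s⁻². The stance-end bound keeps
swing-phase noise out of the derivative search. Contact detection runs on
the filtered signal, matching the filter-then-measure order of operations.

Two identities pin the implementation: a 0→1500 N ramp over 50 ms at
1000 Hz with a 750 N body weight gives exactly 40 BW·s⁻¹, and on noiseless
synthetic strides the pipeline recovers the generator's analytic truth
within 2% (in practice < 1%; the residual is the 60 Hz filter's slight
attenuation of the impact transient plus forward-difference discretization).

A note on the filter contracts: forward–backward filtering squares the
magnitude response, so a 150 Hz sinusoid through the 60 Hz low-pass should
be attenuated to 1/(1 + (150/60)⁴). That analog formula is verified at a
10 kHz sampling rate; at 1 kHz the bilinear transform's frequency warping
alone shifts the response at 150 Hz by ~20%, which is a property of any
discrete Butterworth implementation, not of this package.

## Synthetic cohort generator

No public dataset pairs synchronized plate vGRF with bilateral tibial
acceleration, so the generator is first-class, tested code: it defines the
study conditions under which every claim in this package is evaluated.

**Force model.** Each stance's vGRF is the sum of two lobes — the standard
two-peak rearfoot morphology: a raised-cosine impact transient (peak
`impact_amp · impact_level · side · shoe · (70/mass)^0.25 · (v/3.2)^1.2`
body weights, rise time `40 · impact_level^−0.45 · (v/3.2)^−0.5` ms, clipped
to 20–52 ms) and a `sin²` active peak spanning the stance (1.9 + 0.19·v
body weights, i.e. ≈2.4–2.9 BW over 2.55–5.10 m·s⁻¹). Stance duration is
`330 − 25·v` ms with 8 ms jitter, clipped into the physiological 160–350 ms
band; consecutive contacts alternate feet with a guaranteed flight phase.
The true VILR is the maximum of the closed-form derivative of this
construction, evaluated on a 0.02 ms grid — never re-measured from the
sampled signal — so the reference pipeline can be scored against an
independent truth.

Both the amplitude and the sharpness (inverse rise time) of the transient
grow with the latent shock intensity, which makes the true VILR strictly
monotone in `impact_level` and leaves a gain-free timing signature in the
acceleration. Shoe category (neutral / stabilization / racing flat ×1.0 /
×0.90 / ×1.18) and body mass modulate the transmitted force without an
equivalent change in shank acceleration; this is what makes the
subject-describing features informative, mirroring their documented role.

**Acceleration model.** The landing leg's axial channel carries the
differentiated impact shape (peak `8 · impact_level · side · gain ·
(v/3.2)^0.8` g at half the rise time, 0 g crossing at the impact peak — the
basis of the impact-window rule), a damped 20 Hz post-impact oscillation, a
+1 g gravity offset and low-frequency gait sway. The anteroposterior
channel is an attenuated, 5 ms-delayed copy plus a push-off burst centered
at toe-off (the toe-off detector's likelihood source); the mediolateral
channel is an attenuated copy whose physical sign flips between legs (the
substance of the mirroring convention). The contralateral leg receives a
12% transmitted copy. White Gaussian noise (default 0.25 g per axis, 1 N on
force) is added to the raw signals.

**Subject heterogeneity.** Latent per-subject parameters: shock intensity
(log-normal σ=0.25, clipped 0.55–1.8), right/left asymmetry (σ=0.10,
0.80–1.25 — the generator's rendering of the observed left/right VILR
asymmetry), a sensor mounting gain (σ=0.15, 0.72–1.40) that rescales all
acceleration without touching the force, cadence, preferred speed, and a
body-mass mixture reflecting the cohort's male/female split. The mounting
gain is the deliberate obstacle to subject-independent modelling: within a
subject it is constant (so personalized models can absorb it), across
subjects it is irreducible noise in any amplitude feature (so the
subject-independent error is strictly larger — the study's central
qualitative finding).

**Scale defaults.** 30 subjects × 15 trials is the default desk scale;
trials cycle through the speed protocol {2.55, 3.20, 5.10, preferred}
m·s⁻¹; stances per trial are 2 or 3 with mean 2.67. The full-size cohort
(93 × 16) is reachable through `SimulationConfig`. The generator's
distributional defaults are plausible ranges, not calibrated to any
published table — the source reports model errors, not VILR distribution
parameters — so agreement is asserted only at the level of orderings,
oracles and invariants, never of headline numbers.

**What the synthetic data does not emulate:** non-rearfoot strike patterns,
treadmill running, surface variation, soft-tissue artifact spectra, partial
force-plate contacts, or any biofidelic musculoskeletal coupling. Passing
tests therefore demonstrate the correctness and internal consistency of the
pipeline under the stated generative assumptions, not field accuracy on
real runners.

## Acceleration pipeline

Band-pass: zero-phase Butterworth, defaults order 2, 0.8–45 Hz (the
configuration the original tuning grid selected); Chebyshev I/II available.
The tuning grid search (`tune_filter`) splits subjects ~2/3 train / 1/3
evaluation, fits a small LASSO on per-stride axial summaries per grid cell
and returns the MAE-minimizing cell, ties to grid order. Gait events are
detected once with the default filter and reused across cells; only the
feature signals are re-filtered (a 35× runtime saving with no effect on the
comparison).

Gait events: the IC likelihood is the 9 ms moving-RMS envelope of the
band-passed axial jerk; candidate bursts come from `scipy.signal.find_peaks`
(height ≥ 25% of the trial maximum, ≥ 450 ms apart per foot), and the
contact instant is refined to the burst onset — the earliest upward crossing
of max(12% of peak, 2× the envelope's trial median) that is preceded by
8 ms of quiet, looking back 130 ms so the widest transient is spanned; the
centered RMS kernel smears energy half a kernel early, which is compensated.
The toe-off likelihood is the envelope of the band-passed anteroposterior
channel, maximized inside the constrained window [IC + 160 ms, IC + 350 ms]
— the structured constrained-peak-detection layer, which guarantees every
emitted stance satisfies the physiological bound. Feet are forced to
alternate, resolving conflicts by envelope confidence. This heuristic
detector replaces a trained deep recurrent model for which no weights
exist; on the synthetic conditions it recovers IC within 10 ms and ground
contact time within 15 ms.

Stride segmentation follows the opposite-foot take-off rule: a stance's
window runs from the opposite foot's preceding take-off to its next
take-off, which provably contains the whole impact phase. The rule is
undefined for the first and last stance of a finite trial (no surrounding
opposite take-offs exist), so boundary stances fall back to a fixed margin
(60 ms before IC / 120 ms after toe-off); every detected stance then yields
exactly one window.

Mirroring converts left-lead strides to right-lead form by swapping the two
legs' channels and negating the mediolateral axis (axial and
anteroposterior are side-symmetric); right-lead strides pass through. The
transform is an involution. Because both feet's stances are retained as
examples, mirroring doubles the usable training data relative to analysing
a single side.

Impact window: from IC to the first subsequent sample where the filtered
axial acceleration is ≤ 0 g (inclusive; no sub-sample interpolation — at
1000 Hz the quantization is ≤ 1 ms). The terminating crossing is accepted
only after the transient has risen to 20% of its post-contact maximum, so
that ±few-ms jitter in the detected IC cannot end the window on pre-rise
noise; with no crossing before the stride end the window truncates with a
warning. Indexing is 0-based with half-open `[start, end)` windows; times
are reported in ms.

Quality screen (the operationalization of "clear measurement errors"):
non-finite samples; acceleration saturation (≥3 consecutive samples at the
range limit, default 40 g); force dropout (raw force below 5 N for > 20 ms
inside a stance, stances being above-threshold runs after closing gaps
< 60 ms — below any physiological flight phase). The dropout check uses the
raw force deliberately: the reference low-pass smears short dropouts below
detectability.

## Features and selection

Auto-generated catalog: 25 named features per channel — mean, max, min, SD,
mean absolute successive difference, SD of residuals about the least-squares
linear trend, peak count (strictly greater than both neighbours),
time-to-peak (ms), 4 least-squares autoregressive coefficients, magnitudes
of the first 8 Fourier coefficients, Mexican-hat continuous-wavelet
coefficients at widths {2, 5, 10, 20} sampled at the window midpoint, and
the lag-1 time-reversal asymmetry statistic — over 16 channels (both legs'
three filtered axes, their jerk, and each leg's roll and pitch), computed on
the impact window. This is a fixed, documented stand-in for an open-ended
auto-generation universe; the count of surviving features is
catalog-dependent and is not a comparable quantity. Roll is
`arctan2(a_ap, a_ml)` and pitch `arctan(−a_ax/√(a_ap²+a_ml²))` (quotient
forms; the printed source expressions are garbled, and this reconstruction
is the standard spherical decomposition).

FRESH selection: each auto feature is tested against the target — Kendall
rank test for real-valued features (exact null for n ≤ 8 tie-free samples,
tie-adjusted normal approximation otherwise; constant inputs give p = 1),
two-sample Kolmogorov–Smirnov for binary features (≤ 2 distinct values) —
and the Benjamini–Yekutieli step-up with harmonic correction
c(m) = Σ 1/i is applied jointly at level q (default 0.05; the conventional
level, as the source never states one). BY is valid under arbitrary
dependence, which matters because catalog features are strongly correlated.
Trial features (speed, ground contact time, APTA) and subject features
(body weight in N, one-hot shoe category in the fixed order neutral /
stabilization / racing flat) bypass selection. Selection is pooled across
subjects. Missing values (degenerate AR fits, short windows) are imputed
with training-set medians recorded per column.

## Models

LASSO and Elastic-Net (mixing 0.5) on standardized features, penalty chosen
by internal 5-fold CV on the training rows unless fixed; gradient-boosted
regression trees (XGBoost, squared error, 300 trees, depth 4, learning rate
0.1, subsample 0.8, single thread, seeded). The original hyperparameter
protocol is unreported; these are conservative, reproducible defaults, all
configurable. Baselines: a per-(subject, landing-foot) mean predictor (with
a global-mean fallback for unseen subjects) and a univariate ordinary
least-squares model on APTA. A constant training target short-circuits every
learner to a constant predictor.

## Evaluation

Two settings: subject-independent (leave-one-subject-out; feature selection
and imputation refitted inside every fold, so no information about the
held-out runner leaks into training) and subject-dependent
(leave-one-trial-out within each runner; subjects with fewer than two
trials are excluded with a warning; the APTA baseline is refitted per
subject in this setting). Metrics: MAE (BW·s⁻¹), MAPE (%, denominator the
true per-stride VILR, mirroring MAE's aggregation), R² (standard
coefficient of determination; undefined for a constant target and reported
missing). Global values use the two-step aggregation: per-subject means
over strides first, then mean ± SD over subjects with ≥ 10 trials, so
heavily sampled runners do not dominate. Per-subject R² is computed
within-subject over that runner's strides (the aggregation description is
ambiguous on this point; the within-subject reading is used and flagged
here).

High-impact screening: runners in the top third of true subject-mean VILR
(nearest-rank percentile, ties at the cutoff inclusive) are labelled
positive; each model's subject-mean predictions are swept over all
thresholds; AUC by the trapezoid rule (equal to the normalized
Mann–Whitney U, which the tests verify exhaustively); the reported cutoff
maximizes Youden's J. Effect sizes use the repeated-measures Cohen's d,
`d_rm = (M₁−M₂)/SD_diff · √(2(1−r))` with r the Pearson correlation of the
paired per-subject MAEs, binned |d| ≤ 0.2 small, ≤ 0.8 medium, > 0.8 large;
a zero-variance nonzero difference is undefined and reported missing.
Cumulative relative-error curves report the fraction of predictions within
each relative-error threshold.

On the default seed-fixed cohort the package asserts (and the acceptance
script recomputes) the three qualitative findings of the study design:
subject-dependent XGB < subject-independent XGB < APTA baseline in MAE;
every learned model beats the APTA baseline with a positive d_rm; and the
learned model's screening AUC is at least the APTA's. Numeric magnitudes
depend on the generator's heterogeneity defaults and are reported, not
asserted.

## Known limitations

- The event detector is a tuned heuristic; its 10 ms IC accuracy is
  demonstrated on the generator's rearfoot morphology only.
- The feature catalog is a representative fixed set, not an exhaustive
  auto-generation library; selection counts are not comparable across
  catalogs.
- `mean_baseline` in the subject-independent setting degenerates to the
  global mean (the per-runner mean is unknowable for an unseen runner).
- Repeated-measures ANOVA / post-hoc comparisons across learners are out of
  scope; the package reports paired effect sizes instead.
- All accuracy statements are conditional on the generative assumptions
  listed above.
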