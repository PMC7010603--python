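# tibload

Estimation of the **maximal vertical instantaneous loading rate (VILR)** of
overground running from bilateral, tri-axial, shin-mounted accelerometers.

VILR — the peak slope of the rising vertical ground reaction force (vGRF)
after initial contact, normalized to body weight (BW·s⁻¹) — is a standard
impact-loading variable in running-injury research, but it traditionally
requires a fixed force platform. The time-discrete axial peak tibial
acceleration (APTA) is the usual wearable surrogate; it uses a single
number from a rich 3D signal. `tibload` implements the machine-learning
alternative: extract a broad statistical feature set from the stride's
impact window of both shanks' filtered accelerations, screen it with the
FRESH procedure (univariate Kendall / Kolmogorov–Smirnov tests with
Benjamini–Yekutieli false-discovery-rate control), and regress VILR with
LASSO, Elastic-Net or gradient-boosted trees, evaluated subject-independently
(leave-one-subject-out) and subject-dependently (leave-one-trial-out)
against the APTA and per-runner-mean baselines:

    VILR = max_{t > IC} d/dt vGRF(t) / BW,   IC: first vGRF sample > 5 N
    R² = 1 − Σ(yᵢ−fᵢ)² / Σ(yᵢ−ȳ)²,          global metrics: per-subject
                                              means, then mean ± SD over
                                              runners with ≥ 10 trials

Because no public dataset pairs synchronized plate vGRF with bilateral
tibial acceleration, the package ships a first-class **synthetic cohort
generator**: two-lobe rearfoot force waveforms with an analytic true VILR,
coupled acceleration transients, latent per-subject shock intensity, sensor
gain and left/right asymmetry, and controllable noise. Every stage — from
the 5 N/60 Hz force-plate reference through gait-event detection, stride
mirroring, feature selection, and cross-validated modelling — is validated
against this generator's ground truth. It is intended for researchers in
wearable gait biomechanics who want a reproducible, testable reference
implementation of this estimation pipeline.

## Worked example

```python
import warnings
from tibload import SimulationConfig, generate_cohort
from tibload.features import assemble_features
from tibload.models import ModelSpec
from tibload.evaluate import loso_cv, sdm_cv

warnings.simplefilter("ignore")
trials = generate_cohort(SimulationConfig(n_subjects=8, trials_per_subject=12, rng_seed=1))
table = assemble_features(trials)          # one row per mirrored stride
sim = loso_cv(table, [ModelSpec("xgb"), ModelSpec("apta_baseline")], min_trials=10)
sdm = sdm_cv(table, ModelSpec("xgb"), min_trials=10)
for name, rep in sim.items():
    print(f"SIM {name:<14} MAE {rep.mae_mean:5.2f} ± {rep.mae_sd:4.2f} BW/s  R² {rep.r2_mean:.3f}")
print(f"SDM xgb            MAE {sdm.mae_mean:5.2f} ± {sdm.mae_sd:4.2f} BW/s  R² {sdm.r2_mean:.3f}")
```

prints (seed-fixed):

```
SIM xgb            MAE  6.84 ± 4.47 BW/s  R² 0.855
SIM apta_baseline  MAE 11.45 ± 6.43 BW/s  R² 0.638
SDM xgb            MAE  4.27 ± 1.24 BW/s  R² 0.875
```

Read: on a synthetic 8-runner cohort, a gradient-boosted model predicting an
unseen runner's VILR (subject-independent, "SIM") is accurate to ~7 BW·s⁻¹
on average — roughly 10% of a typical loading rate and markedly better than
the single-feature APTA regression — while a personalized model trained on
the runner's own other trials ("SDM") roughly halves the error again.

The `examples/` directory contains one short script per capability:
cohort simulation and on-disk storage, the force-plate reference
computation, events/strides/features, cross-validated modelling, and
high-impact-runner screening (ROC/AUC and cumulative error curves).

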