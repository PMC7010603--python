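"""Compute the force-plate reference loading rate for each stance.

The reference pipeline low-pass filters the vertical ground reaction force
(zero-lag Butterworth, 60 Hz, order 2), detects initial contact at the 5 N
threshold and takes the maximum forward-difference slope over the stance,
normalized to body weight.
"""

from tibload import SimulationConfig, generate_cohort
from tibload.grf import reference_vilr_per_stance

(trial,) = generate_cohort(
    SimulationConfig(n_subjects=1, trials_per_subject=1, rng_seed=7)
)
print(f"subject {trial.subject_id}: mass {trial.body_mass:.1f} kg "
      f"(body weight {trial.body_weight:.0f} N), speed {trial.speed:.2f} m/s")

refs = reference_vilr_per_stance(trial)
truths = sorted(trial.ground_truth, key=lambda g: g.ic_time)
for ref, truth in zip(refs, truths):
    err = 100 * abs(ref["vilr"] - truth.true_vilr) / truth.true_vilr
    print(f"contact {ref['start_ms']:6.0f}-{ref['end_ms']:6.0f} ms: "
          f"measured VILR {ref['vilr']:6.1f} BW/s, "
          f"truth {truth.true_vilr:6.1f}, error {err:4.2f}%")
# On noiseless data the measured loading rate recovers the generator's
# analytic truth to well under 2% -- the calibration of the whole study.
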