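"""Generate a small synthetic running cohort and store it on disk.

Every trial pairs bilateral tibial acceleration with a synchronized vertical
ground reaction force and carries the generator's analytic ground truth
(initial contact / toe-off times and the true loading rate per stance).
"""

import tempfile
from pathlib import Path

from tibload import SimulationConfig, generate_cohort, read_cohort, write_cohort

config = SimulationConfig(n_subjects=4, trials_per_subject=3, rng_seed=42)
trials = generate_cohort(config)
print(f"generated {len(trials)} trials, "
      f"{sum(len(t.ground_truth) for t in trials)} stances")

out = Path(tempfile.mkdtemp()) / "cohort"
manifest = write_cohort(trials, out)
admitted = int(manifest.rows["admitted"].sum())
print(f"wrote cohort to {out}; {admitted}/{len(manifest.rows)} trials admitted")

back = read_cohort(out)
trial = back[0]
print(f"first trial: subject {trial.subject_id}, {trial.speed:.2f} m/s, "
      f"{trial.n_samples} samples at {trial.sampling_rate:.0f} Hz")
for g in trial.ground_truth:
    print(f"  {g.landing_foot:>5} contact at {g.ic_time:6.1f} ms, "
          f"stance {g.to_time - g.ic_time:5.1f} ms, true VILR {g.true_vilr:6.1f} BW/s")
# The true VILR is the analytic maximum slope of the constructed force,
# normalized to body weight -- the quantity the whole pipeline estimates.
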