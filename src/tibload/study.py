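"""End-to-end study runner on the default synthetic cohort.

Bundles the full analysis — cohort generation, feature construction,
subject-independent (leave-one-subject-out) and subject-dependent
(leave-one-trial-out) cross-validation of the learners and baselines,
high-impact screening ROC, paired effect sizes, and cumulative
relative-error fractions — into one reproducible call. This is the
computation behind the package's headline numbers; tests and the
acceptance script both run it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluate import (
    DiagnosticReport,
    EffectSize,
    EvaluationReport,
    cohens_drm,
    cumulative_error_curve,
    loso_cv,
    screen_high_impact,
    sdm_cv,
)
from .features import FeatureTable, assemble_features
from .models import ModelSpec
from .simulate import SimulationConfig, generate_cohort

#: Learners evaluated in the subject-independent setting.
SIM_LEARNERS = ("xgb", "lasso", "elastic_net", "apta_baseline", "mean_baseline")


@dataclass
class StudyResult:
    table: FeatureTable
    sim: dict[str, EvaluationReport]  # learner -> subject-independent report
    sim_no_subject: EvaluationReport  # XGB without subject-describing features
    sdm: dict[str, EvaluationReport]  # learner -> subject-dependent report
    roc: dict[str, DiagnosticReport]  # xgb / apta_baseline screening ROC
    effect_sizes: dict[str, EffectSize]  # learner -> d_rm of MAE vs APTA baseline
    rel_err_fraction_20pct: dict[str, float] = field(default_factory=dict)


def run_default_study(
    seed: int = 0,
    n_subjects: int = 30,
    trials_per_subject: int = 15,
    min_trials: int = 10,
    q: float = 0.05,
) -> StudyResult:
    """Run the whole analysis on a seed-fixed default synthetic cohort."""
    config = SimulationConfig(
        n_subjects=n_subjects, trials_per_subject=trials_per_subject, rng_seed=seed
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        trials = generate_cohort(config)
        table = assemble_features(trials)

        specs = [ModelSpec(name, rng_seed=seed) for name in SIM_LEARNERS]
        sim = loso_cv(table, specs, q=q, min_trials=min_trials)

        no_subject = table.with_features(
            [f for f in table.feature_names if table.provenance[f] != "subject"]
        )
        sim_ns = loso_cv(no_subject, ModelSpec("xgb", rng_seed=seed), q=q, min_trials=min_trials)

        sdm = {
            name: sdm_cv(table, ModelSpec(name, rng_seed=seed), q=q, min_trials=min_trials)
            for name in ("xgb", "apta_baseline", "mean_baseline")
        }

    true_means = table.data.groupby("subject_id")["target_vilr"].mean()
    roc = {
        name: screen_high_impact(
            true_means, sim[name].predictions.groupby("subject_id")["f"].mean()
        )
        for name in ("xgb", "apta_baseline")
    }

    apta_mae = sim["apta_baseline"].per_subject.set_index("subject_id")["mae"]
    effect_sizes = {}
    for name in ("xgb", "lasso", "elastic_net"):
        ml_mae = sim[name].per_subject.set_index("subject_id")["mae"]
        effect_sizes[name] = cohens_drm(
            apta_mae.to_numpy(), ml_mae.loc[apta_mae.index].to_numpy()
        )

    rel20 = {}
    for label, report in (
        ("sdm_xgb", sdm["xgb"]),
        ("sim_xgb", sim["xgb"]),
        ("apta", sim["apta_baseline"]),
        ("mean_baseline", sim["mean_baseline"]),
    ):
        pred = report.predictions
        rel = np.abs(pred["f"] - pred["y"]) / pred["y"]
        rel20[label] = float(cumulative_error_curve(rel.to_numpy(), np.array([0.20]))[0])

    return StudyResult(
        table=table,
        sim=sim,
        sim_no_subject=sim_ns["xgb"],
        sdm=sdm,
        roc=roc,
        effect_sizes=effect_sizes,
        rel_err_fraction_20pct=rel20,
    )


def study_summary(result: StudyResult) -> pd.DataFrame:
    """Tabular summary (setting, learner, MAE, SD, MAPE, R^2) of a study."""
    rows = []
    for name, rep in result.sim.items():
        rows.append(("subject_independent", name, rep.mae_mean, rep.mae_sd, rep.mape_mean, rep.r2_mean))
    rows.append(
        (
            "subject_independent_no_subject_features",
            "xgb",
            result.sim_no_subject.mae_mean,
            result.sim_no_subject.mae_sd,
            result.sim_no_subject.mape_mean,
            result.sim_no_subject.r2_mean,
        )
    )
    for name, rep in result.sdm.items():
        rows.append(("subject_dependent", name, rep.mae_mean, rep.mae_sd, rep.mape_mean, rep.r2_mean))
    return pd.DataFrame(
        rows, columns=["setting", "learner", "mae", "mae_sd", "mape_pct", "r2"]
    )
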