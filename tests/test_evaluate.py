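"""Metrics, aggregation, cross-validation settings, ROC and effect sizes."""

import numpy as np
import pandas as pd
import pytest

from tibload.evaluate import (
    EffectSize,
    aggregate_two_step,
    cohens_drm,
    cumulative_error_curve,
    high_impact_labels,
    loso_cv,
    loto_cv,
    mae,
    mape,
    r2,
    roc_curve,
    sdm_cv,
)
from tibload.features import FeatureTable
from tibload.models import ModelSpec


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.array([10.0, 20.0, 30.0])
        assert mae(y, y) == 0.0
        assert mape(y, y) == 0.0
        assert r2(y, y) == 1.0

    def test_mean_predictor_r2_zero(self):
        y = np.array([10.0, 20.0, 30.0])
        f = np.full(3, y.mean())
        assert r2(y, f) == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        y = np.array([10.0, 20.0, 30.0])
        f = np.array([12.0, 18.0, 33.0])
        assert mae(y, f) == pytest.approx(7.0 / 3.0)
        assert mape(y, f) == pytest.approx(100 * (0.2 + 0.1 + 0.1) / 3)

    def test_constant_y_r2_missing(self):
        assert r2(np.ones(5), np.zeros(5)) is None


def _pred(subjects, trials_per_subject, errors):
    rows = []
    for sid, err in zip(subjects, errors):
        for t in range(trials_per_subject[sid] if isinstance(trials_per_subject, dict) else trials_per_subject):
            rows.append({"subject_id": sid, "trial_id": f"t{t}", "foot": "right",
                         "y": 50.0, "f": 50.0 + err})
    return pd.DataFrame(rows)


class TestAggregation:
    def test_equal_errors_pass_through(self):
        pred = _pred(["a", "b", "c"], 12, [3.0, 3.0, 3.0])
        rep = aggregate_two_step(pred, min_trials=10)
        assert rep.mae_mean == pytest.approx(3.0)
        assert rep.mae_sd == pytest.approx(0.0)

    def test_two_subject_hand_arithmetic(self):
        pred = _pred(["a", "b"], 10, [4.0, 8.0])
        rep = aggregate_two_step(pred, min_trials=10)
        assert rep.mae_mean == pytest.approx(6.0)
        assert rep.mae_sd == pytest.approx(np.std([4.0, 8.0], ddof=1))

    def test_subject_below_min_trials_excluded(self):
        pred = pd.concat([_pred(["a", "b"], 10, [4.0, 8.0]), _pred(["c"], 9, [100.0])])
        rep = aggregate_two_step(pred, min_trials=10)
        assert rep.n_qualifying == 2
        assert rep.mae_mean == pytest.approx(6.0)
        # the under-sampled subject still appears in the per-subject frame
        assert set(rep.per_subject["subject_id"]) == {"a", "b", "c"}

    def test_equals_flat_mean_in_balanced_case(self):
        rng = np.random.default_rng(0)
        rows = []
        for sid in "abcd":
            for t in range(10):
                y = rng.uniform(40, 80)
                rows.append({"subject_id": sid, "trial_id": f"t{t}", "foot": "r",
                             "y": y, "f": y + rng.normal()})
        pred = pd.DataFrame(rows)
        rep = aggregate_two_step(pred, min_trials=10)
        flat = mae(pred["y"].to_numpy(), pred["f"].to_numpy())
        assert rep.mae_mean == pytest.approx(flat)


class TestHighImpactLabels:
    def test_nine_distinct_means_flag_three(self):
        means = pd.Series(np.arange(9.0), index=[f"s{i}" for i in range(9)])
        labels = high_impact_labels(means)
        assert labels.sum() == 3
        assert labels[means >= 6.0].all()

    def test_all_equal_all_flagged(self):
        means = pd.Series(np.full(6, 5.0), index=list("abcdef"))
        assert high_impact_labels(means).all()

    def test_three_subjects_top_one(self):
        means = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        labels = high_impact_labels(means)
        assert labels.sum() == 1 and labels["c"]


class TestRoc:
    def test_perfect_and_reversed(self):
        labels = pd.Series([True, True, False, False], index=list("abcd"))
        scores = pd.Series([9.0, 8.0, 2.0, 1.0], index=list("abcd"))
        assert roc_curve(labels, scores).auc == pytest.approx(1.0)
        assert roc_curve(labels, -scores).auc == pytest.approx(0.0)

    def test_auc_equals_normalized_mannwhitney(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(4, 13))
            labels = pd.Series(rng.uniform(size=n) > 0.5, index=range(n))
            if labels.all() or not labels.any():
                continue
            scores = pd.Series(rng.normal(size=n), index=range(n))
            auc = roc_curve(labels, scores).auc
            u = mannwhitneyu(scores[labels], scores[~labels]).statistic
            assert auc == pytest.approx(u / (labels.sum() * (~labels).sum()))

    def test_single_class_rejected(self):
        labels = pd.Series([True, True], index=list("ab"))
        with pytest.raises(ValueError):
            roc_curve(labels, pd.Series([1.0, 2.0], index=list("ab")))


class TestCumulativeErrorCurve:
    def test_zero_errors(self):
        out = cumulative_error_curve(np.zeros(5), np.array([0.05, 0.2, 1.0]))
        assert np.allclose(out, 1.0)

    def test_direct_count(self):
        out = cumulative_error_curve(np.array([0.1, 0.3]), np.array([0.2]))
        assert out[0] == pytest.approx(0.5)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(2)
        e = rng.exponential(0.2, 200)
        t = np.sort(rng.uniform(0, 1, 30))
        out = cumulative_error_curve(e, t)
        assert np.all(np.diff(out) >= 0)


class TestCohensDrm:
    def test_identical_samples_give_zero_small(self):
        a = np.array([5.0, 6.0, 7.0])
        es = cohens_drm(a, a.copy())
        assert es.d == 0.0 and es.bin == "small"

    def test_constant_shift_is_degenerate(self):
        # perfectly correlated equal-SD samples: the paired-difference SD is
        # exactly zero and the statistic is undefined
        es = cohens_drm(np.array([5.0, 6.0, 7.0]), np.array([7.0, 8.0, 9.0]))
        assert es.d is None and es.bin is None

    def test_matches_direct_formula(self):
        a = np.array([5.0, 6.0, 7.0, 9.0])
        b = np.array([7.0, 9.0, 8.0, 10.0])
        # oracle: direct arithmetic of the repeated-measures formula
        r = np.corrcoef(a, b)[0, 1]
        sd_a, sd_b = np.std(a, ddof=1), np.std(b, ddof=1)
        expected = (
            (a.mean() - b.mean())
            / np.sqrt(sd_a**2 + sd_b**2 - 2 * r * sd_a * sd_b)
            * np.sqrt(2 * (1 - r))
        )
        assert cohens_drm(a, b).d == pytest.approx(expected)

    @pytest.mark.parametrize(
        "d, bin_", [(0.2, "small"), (0.21, "medium"), (0.8, "medium"), (0.81, "large")]
    )
    def test_bin_boundaries(self, d, bin_):
        assert EffectSize.from_d(d).bin == bin_


def _linear_table(subjects, trials_per_subject, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    for sid in subjects:
        for t in range(trials_per_subject):
            for _ in range(3):
                x = rng.uniform(-1, 1)
                rows.append(
                    {
                        "subject_id": sid,
                        "trial_id": f"t{t}",
                        "foot": "right",
                        "mirrored": False,
                        "feat": x,
                        "apta": 5.0 + x,
                        "target_vilr": 50.0 + 10.0 * x + noise * rng.normal(),
                    }
                )
    return FeatureTable(pd.DataFrame(rows), {"feat": "auto", "apta": "trial"})


class TestCrossValidation:
    def test_loso_perfect_generalization_and_fold_count(self):
        table = _linear_table(["a", "b"], 10)
        reports = loso_cv(table, ModelSpec("lasso", {"alpha": 1e-6}), min_trials=10, select=False)
        rep = reports["lasso"]
        assert rep.mae_mean < 1e-3
        assert len(rep.per_subject) == 2  # one fold per subject

    def test_loso_needs_two_subjects(self):
        table = _linear_table(["a"], 10)
        with pytest.raises(ValueError):
            loso_cv(table, ModelSpec("lasso"), select=False)

    def test_loto_identical_trials_give_zero_error(self):
        rng = np.random.default_rng(3)
        rows = []
        for t in range(6):
            for k in range(3):  # same strides in every trial
                rows.append(
                    {
                        "subject_id": "a",
                        "trial_id": f"t{t}",
                        "foot": "right",
                        "mirrored": False,
                        "feat": float(k),
                        "apta": 5.0 + k,
                        "target_vilr": 50.0 + 10.0 * k,
                    }
                )
        table = FeatureTable(pd.DataFrame(rows), {"feat": "auto", "apta": "trial"})
        pred = loto_cv(table, ModelSpec("lasso", {"alpha": 1e-6}), select=False)
        assert pred["trial_id"].nunique() == 6  # one fold per trial
        assert mae(pred["y"].to_numpy(), pred["f"].to_numpy()) < 1e-3

    def test_loto_single_trial_excluded_with_warning(self):
        table = _linear_table(["a"], 1)
        with pytest.warns(UserWarning, match="< 2 trials"):
            assert loto_cv(table, ModelSpec("lasso")) is None

    def test_sdm_beats_sim_on_subject_specific_structure(self):
        # per-subject intercepts: unlearnable across subjects, trivial within
        rng = np.random.default_rng(4)
        frames = []
        for i, sid in enumerate("abcd"):
            t = _linear_table([sid], 10, seed=i, noise=0.5)
            t.data["target_vilr"] += 20.0 * i
            frames.append(t.data)
        table = FeatureTable(pd.concat(frames, ignore_index=True), {"feat": "auto", "apta": "trial"})
        spec = ModelSpec("lasso", {"alpha": 1e-3})
        sim = loso_cv(table, spec, min_trials=10, select=False)["lasso"]
        sdm = sdm_cv(table, spec, min_trials=10, select=False)
        assert sdm.mae_mean < sim.mae_mean
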