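"""Regressors mapping per-stride features to the vertical loading rate.

Three learners — LASSO and Elastic-Net linear regression (standardized
inputs, penalty chosen by internal cross-validation unless fixed) and
gradient-boosted regression trees — plus the two reference baselines: a
per-(subject, landing-foot) mean predictor and a univariate linear model on
the axial peak tibial acceleration (APTA).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .features import TARGET_COLUMN, FeatureTable

LEARNERS = ("lasso", "elastic_net", "xgb", "apta_baseline", "mean_baseline")

XGB_DEFAULTS = {
    "n_estimators": 300,
    "max_depth": 4,
    "learning_rate": 0.1,
    "subsample": 0.8,
}


@dataclass
class ModelSpec:
    learner: str
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.learner not in LEARNERS:
            raise ValueError(f"learner must be one of {LEARNERS}")


@dataclass
class TrainedModel:
    learner: str
    estimator: Any  # fitted estimator or baseline parameters
    schema: list[str]  # ordered feature names required at prediction time
    medians: pd.Series  # per-feature imputation values fitted on training rows
    scaler: tuple[np.ndarray, np.ndarray] | None  # (mean, sd) for linear learners
    n_train: int
    train_mae: float
    constant: float | None = None  # degenerate constant-prediction fallback


def _design(rows: pd.DataFrame, schema: list[str], medians: pd.Series) -> np.ndarray:
    missing = [f for f in schema if f not in rows.columns]
    if missing:
        raise ValueError(f"rows missing feature columns: {missing}")
    X = rows[schema].to_numpy(dtype=float)
    bad = ~np.isfinite(X)
    if bad.any():
        warnings.warn(f"imputing {int(bad.sum())} missing feature values with training medians")
        X = np.where(bad, np.broadcast_to(medians.to_numpy(), X.shape), X)
    return X


def train_model(table: FeatureTable, spec: ModelSpec) -> TrainedModel:
    """Fit one learner on a feature table. Deterministic given ``rng_seed``."""
    if len(table) < 5:
        raise ValueError("need at least 5 training rows")
    schema = list(table.feature_names)
    y = table.y
    medians = table.data[schema].median(numeric_only=True).fillna(0.0)
    X = _design(table.data, schema, medians)

    if spec.learner == "mean_baseline":
        means = table.data.groupby(["subject_id", "foot"])[TARGET_COLUMN].mean()
        model = TrainedModel(
            spec.learner, means, schema, medians, None, len(table), 0.0, constant=float(np.mean(y))
        )
        model.train_mae = float(np.mean(np.abs(predict(model, table.data) - y)))
        return model

    if np.allclose(y, y[0]):
        # degenerate constant target: every learner predicts the constant
        return TrainedModel(spec.learner, None, schema, medians, None, len(table), 0.0, constant=float(y[0]))

    if spec.learner == "apta_baseline":
        if "apta" not in table.data.columns:
            raise ValueError("apta_baseline requires an 'apta' column")
        a = table.data["apta"].to_numpy(dtype=float)
        slope, intercept = np.polyfit(a, y, 1)
        model = TrainedModel(
            spec.learner, {"slope": float(slope), "intercept": float(intercept)},
            schema, medians, None, len(table), 0.0,
        )
        model.train_mae = float(np.mean(np.abs(predict(model, table.data) - y)))
        return model

    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    scaler: tuple[np.ndarray, np.ndarray] | None = None

    if spec.learner in ("lasso", "elastic_net"):
        from sklearn.linear_model import ElasticNet, ElasticNetCV, Lasso, LassoCV

        scaler = (mu, sd)
        Xs = (X - mu) / sd
        hp = dict(spec.hyperparameters)
        l1_ratio = hp.pop("l1_ratio", 0.5)
        if "alpha" in hp:
            est = (
                Lasso(alpha=hp["alpha"], max_iter=50_000)
                if spec.learner == "lasso"
                else ElasticNet(alpha=hp["alpha"], l1_ratio=l1_ratio, max_iter=50_000)
            )
        elif spec.learner == "lasso":
            est = LassoCV(cv=5, alphas=30, random_state=spec.rng_seed, max_iter=20_000)
        else:
            est = ElasticNetCV(
                cv=5, alphas=30, l1_ratio=l1_ratio, random_state=spec.rng_seed, max_iter=20_000
            )
        with warnings.catch_warnings():
            from sklearn.exceptions import ConvergenceWarning

            warnings.simplefilter("ignore", ConvergenceWarning)
            est.fit(Xs, y)
        pred = est.predict(Xs)
    elif spec.learner == "xgb":
        from xgboost import XGBRegressor

        hp = {**XGB_DEFAULTS, **spec.hyperparameters}
        est = XGBRegressor(
            objective="reg:squarederror",
            random_state=spec.rng_seed,
            n_jobs=1,
            tree_method="hist",
            verbosity=0,
            **hp,
        )
        est.fit(X, y)
        pred = est.predict(X)
    else:  # pragma: no cover - closed set enforced by ModelSpec
        raise ValueError(spec.learner)

    train_mae = float(np.mean(np.abs(pred - y)))
    return TrainedModel(spec.learner, est, schema, medians, scaler, len(table), train_mae)


def predict(model: TrainedModel, rows: pd.DataFrame) -> np.ndarray:
    """Predict VILR (BW s^-1) for feature rows conforming to the schema."""
    if model.constant is not None and model.learner != "mean_baseline":
        return np.full(len(rows), model.constant)
    if model.learner == "mean_baseline":
        means = model.estimator
        out = np.empty(len(rows))
        for i, (_, row) in enumerate(rows.iterrows()):
            key = (row.get("subject_id"), row.get("foot"))
            out[i] = means.get(key, model.constant)
        return out
    if model.learner == "apta_baseline":
        if "apta" not in rows.columns:
            raise ValueError("rows missing feature columns: ['apta']")
        a = rows["apta"].to_numpy(dtype=float)
        return model.estimator["slope"] * a + model.estimator["intercept"]
    X = _design(rows, model.schema, model.medians)
    if model.scaler is not None:
        mu, sd = model.scaler
        X = (X - mu) / sd
    return np.asarray(model.estimator.predict(X), dtype=float)
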