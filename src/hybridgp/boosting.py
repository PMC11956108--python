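"""Gradient-boosted-tree engine on the concatenated hybrid feature vector
X_i = [Z_G,i | A_M,i | D_M,i], with TPE Bayesian hyperparameter tuning that
minimizes inner-cross-validation RMSE.

The ensemble predicts yhat_i = sum_k f_k(X_i) over the K fitted trees.
Backed by scikit-learn's histogram gradient boosting; the search space below
is a documented default and fully overridable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from sklearn.ensemble import HistGradientBoostingRegressor
from sklearn.model_selection import KFold

from ._tpe import ParamSpec, tpe_minimize
from .hybrid_coding import FeatureSet

__all__ = ["BoostingModel", "DEFAULT_SPACE", "tune_hyperparameters", "fit_boosting", "predict_boosting"]

DEFAULT_SPACE: dict[str, ParamSpec] = {
    "learning_rate": ParamSpec("loguniform", 0.01, 0.3),
    "max_depth": ParamSpec("int", 2, 10),
    "max_iter": ParamSpec("int", 100, 1000),
    "max_features": ParamSpec("uniform", 0.5, 1.0),
    "min_samples_leaf": ParamSpec("int", 1, 10),
    "l2_regularization": ParamSpec("loguniform", 1e-3, 10.0),
}

DEFAULT_PARAMS = {
    "learning_rate": 0.1,
    "max_depth": 6,
    "max_iter": 300,
    "max_features": 1.0,
    "min_samples_leaf": 5,
    "l2_regularization": 1e-3,
}


@dataclass
class BoostingModel:
    estimator: HistGradientBoostingRegressor
    hyperparameters: dict
    feature_manifest: dict
    fitted_values: np.ndarray
    tuning_trace: list[tuple[dict, float]] = field(default_factory=list)

    def manifest_json(self) -> str:
        return json.dumps(
            {"hyperparameters": self.hyperparameters, "features": self.feature_manifest},
            indent=2,
        )


def _as_matrix(features: FeatureSet | np.ndarray) -> np.ndarray:
    if isinstance(features, FeatureSet):
        return features.concatenated()
    return np.asarray(features, dtype=float)


def _manifest(features: FeatureSet | np.ndarray) -> dict:
    if isinstance(features, FeatureSet):
        return {
            "model_tag": features.model_tag,
            "blocks": {k: v.shape[1] for k, v in features.blocks.items()},
            "n_columns": features.concatenated().shape[1],
        }
    X = np.asarray(features)
    return {"model_tag": None, "blocks": {}, "n_columns": X.shape[1]}


def _make_estimator(params: Mapping, seed: int) -> HistGradientBoostingRegressor:
    return HistGradientBoostingRegressor(
        learning_rate=float(params["learning_rate"]),
        max_depth=int(params["max_depth"]),
        max_iter=int(params["max_iter"]),
        max_features=float(params["max_features"]),
        min_samples_leaf=int(params["min_samples_leaf"]),
        l2_regularization=float(params["l2_regularization"]),
        early_stopping=False,
        random_state=seed,
    )


def tune_hyperparameters(
    features: FeatureSet | np.ndarray,
    y: np.ndarray,
    n_trials: int = 50,
    inner_folds: int = 5,
    seed: int = 0,
    space: dict[str, ParamSpec] | None = None,
) -> tuple[dict, list[tuple[dict, float]]]:
    """TPE search minimizing mean inner-CV RMSE; returns (best, trace)."""
    X = _as_matrix(features)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("features and y are misaligned")
    space = dict(DEFAULT_SPACE if space is None else space)
    kf = KFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    splits = list(kf.split(X))

    def objective(params: dict) -> float:
        errs = []
        for tr, te in splits:
            est = _make_estimator(params, seed)
            est.fit(X[tr], y[tr])
            pred = est.predict(X[te])
            errs.append(np.sqrt(np.mean((pred - y[te]) ** 2)))
        return float(np.mean(errs))

    return tpe_minimize(objective, space, n_trials=n_trials, seed=seed)


def fit_boosting(
    features: FeatureSet | np.ndarray,
    y: np.ndarray,
    hyperparameters: Mapping | None = None,
    seed: int = 0,
    tuning_trace: list | None = None,
) -> BoostingModel:
    """Train the boosted ensemble; reproducible given the seed."""
    X = _as_matrix(features)
    y = np.asarray(y, dtype=float).ravel()
    if not np.isfinite(y).all():
        raise ValueError("y contains non-finite values")
    params = dict(DEFAULT_PARAMS if hyperparameters is None else hyperparameters)
    est = _make_estimator(params, seed)
    est.fit(X, y)
    return BoostingModel(
        estimator=est,
        hyperparameters=params,
        feature_manifest=_manifest(features),
        fitted_values=est.predict(X),
        tuning_trace=list(tuning_trace or []),
    )


def predict_boosting(model: BoostingModel, features: FeatureSet | np.ndarray) -> np.ndarray:
    """Predict yhat_i = sum_k f_k(X_i) for new hybrids."""
    X = _as_matrix(features)
    manifest = _manifest(features)
    if manifest["n_columns"] != model.feature_manifest["n_columns"]:
        raise ValueError(
            f"feature column count {manifest['n_columns']} does not match "
            f"training manifest {model.feature_manifest['n_columns']} "
            f"(blocks: {manifest['blocks']} vs {model.feature_manifest['blocks']})"
        )
    return model.estimator.predict(X)
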