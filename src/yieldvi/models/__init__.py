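"""Base regressors behind one fit/predict/importance contract.

Two families are provided: a Cubist-style rule model tree
(:mod:`yieldvi.models.cubist`) and a recurrent-network regressor
(:mod:`yieldvi.models.rnn`).  Both expose:

* ``fit(X, y, spec)`` — train on a feature DataFrame;
* ``predict(model, X)`` — pure function of (model, X), requiring exactly
  the training feature names;
* ``model_importance(model, X, y)`` — non-negative per-feature scores
  (attribute usage for the rule tree, permutation importance for the
  network), as needed by recursive feature elimination;
* ``save``/``load`` — JSON round-trip with bit-identical predictions.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ..feature_sets import FeatureRanking
from .cubist import CubistConfig, CubistModel, fit_cubist
from .rnn import RNNConfig, RNNModel, TrainingFailureError, fit_rnn

__all__ = [
    "ModelSpec",
    "fit",
    "predict",
    "model_importance",
    "save_model",
    "load_model",
    "CubistConfig",
    "CubistModel",
    "RNNConfig",
    "RNNModel",
    "TrainingFailureError",
    "fit_cubist",
    "fit_rnn",
]

FAMILIES = ("cubist", "rnn")


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """Which base regressor to fit, with family-specific hyperparameters."""

    family: str
    params: dict = dataclasses.field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}; expected {FAMILIES}")

    def with_seed(self, seed: int) -> "ModelSpec":
        return ModelSpec(self.family, dict(self.params), seed)

    def to_dict(self) -> dict:
        return {"family": self.family, "params": dict(self.params), "seed": self.seed}


def fit(X: pd.DataFrame, y: Sequence[float], spec: ModelSpec):
    """Train the regressor named by *spec* on a feature DataFrame."""
    y = np.asarray(y, dtype=float)
    if spec.family == "cubist":
        return fit_cubist(X, y, CubistConfig.from_params(spec.params))
    cfg = RNNConfig.from_params({**spec.params, "seed": spec.seed})
    return fit_rnn(X, y, cfg)


def _check_columns(model, X: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in model.feature_names if c not in X.columns]
    extra = [c for c in X.columns if c not in model.feature_names]
    if missing or extra:
        raise KeyError(
            f"feature columns do not match the model: missing={missing}, extra={extra}"
        )
    return X[model.feature_names]


def predict(model, X: pd.DataFrame) -> np.ndarray:
    """One finite prediction per row; X must carry exactly the training columns."""
    X = _check_columns(model, X)
    pred = model.predict(X)
    if not np.all(np.isfinite(pred)):
        raise ValueError("model produced non-finite predictions")
    return pred


def model_importance(
    model,
    X: pd.DataFrame,
    y: Sequence[float],
    seed: int = 0,
    n_permutations: int = 5,
) -> FeatureRanking:
    """Per-feature importance of a fitted model (all scores >= 0).

    Rule tree: Cubist-style attribute usage (percentage of cases whose
    rule conditions / regression models involve the feature).  Recurrent
    network: permutation importance — mean RMSE increase over
    ``n_permutations`` seeded shuffles of each feature column, floored
    at zero.
    """
    X = _check_columns(model, X)
    y = np.asarray(y, dtype=float)
    if isinstance(model, CubistModel):
        return FeatureRanking.from_scores("cubist_usage", model.attribute_usage())
    rng = np.random.default_rng(seed)
    base = float(np.sqrt(np.mean((model.predict(X) - y) ** 2)))
    scores = {}
    for f in model.feature_names:
        deltas = []
        for _ in range(n_permutations):
            Xp = X.copy()
            Xp[f] = rng.permutation(Xp[f].to_numpy())
            rmse_p = float(np.sqrt(np.mean((model.predict(Xp) - y) ** 2)))
            deltas.append(rmse_p - base)
        scores[f] = max(0.0, float(np.mean(deltas)))
    return FeatureRanking.from_scores("rnn_permutation", scores)


def save_model(model, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model.to_json()) + "\n")


def load_model(path: str | Path):
    d = json.loads(Path(path).read_text())
    if d["family"] == "cubist":
        return CubistModel.from_json(d)
    if d["family"] == "rnn":
        return RNNModel.from_json(d)
    raise ValueError(f"unknown model family in file: {d['family']!r}")
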