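"""Bilirubin regressors: tree ensembles on feature vectors, DeepSets on pixel sets.

Four model kinds share one train/predict surface.  The tabular models
(decision tree, random forest, gradient-boosted trees) consume the
1567-dimensional color-feature vector; the DeepSets model consumes the raw
RoI pixel set.  Each trained model records which input contract it accepts
and refuses the other.

Default hyperparameters are declared package choices: 500 trees for the
forest; 300 boosting rounds at depth 4 and learning rate 0.1; a single tree
capped at depth 8; and the DeepSets defaults documented in
:mod:`icterus.deepsets`.  All are overridable through ``ModelSpec.hyperparams``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.tree import DecisionTreeRegressor
from xgboost import XGBRegressor

from .deepsets import DeepSetsConfig, DeepSetsRegressor
from .errors import ConfigurationError, ContractViolationError
from .features import FeatureVector, PixelSet


class ModelKind(str, enum.Enum):
    DECISION_TREE = "decision_tree"
    RANDOM_FOREST = "random_forest"
    XGBOOST = "xgboost"
    DEEPSETS = "deepsets"


#: Input contract per model kind.
INPUT_CONTRACTS: dict[ModelKind, str] = {
    ModelKind.DECISION_TREE: "feature_vector",
    ModelKind.RANDOM_FOREST: "feature_vector",
    ModelKind.XGBOOST: "feature_vector",
    ModelKind.DEEPSETS: "pixel_set",
}

_DEFAULTS: dict[ModelKind, dict] = {
    ModelKind.DECISION_TREE: {"max_depth": 8},
    ModelKind.RANDOM_FOREST: {"n_estimators": 500},
    ModelKind.XGBOOST: {"n_estimators": 300, "max_depth": 4, "learning_rate": 0.1},
    ModelKind.DEEPSETS: {},
}


@dataclass
class ModelSpec:
    kind: ModelKind
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.kind = ModelKind(self.kind)

    def resolved_hyperparams(self) -> dict:
        return {**_DEFAULTS[self.kind], **self.hyperparams}


@dataclass
class TrainedModel:
    spec: ModelSpec
    input_contract: str  # "feature_vector" | "pixel_set"
    backend: object  # fitted sklearn/xgboost estimator or DeepSetsRegressor


def _as_matrix(inputs: Sequence[FeatureVector]) -> np.ndarray:
    return np.stack([fv.values for fv in inputs])


def _check_inputs(spec: ModelSpec, inputs: Sequence, targets: Sequence[float]) -> np.ndarray:
    contract = INPUT_CONTRACTS[spec.kind]
    expected = FeatureVector if contract == "feature_vector" else PixelSet
    if any(not isinstance(x, expected) for x in inputs):
        raise ContractViolationError(
            f"{spec.kind.value} expects {contract} inputs only"
        )
    y = np.asarray(targets, dtype=np.float64)
    if len(inputs) != y.shape[0] or len(inputs) < 2:
        raise ConfigurationError("need >= 2 inputs with matching targets")
    if not np.all(np.isfinite(y)):
        raise ConfigurationError("targets must be finite")
    return y


def train(spec: ModelSpec, inputs: Sequence, targets: Sequence[float]) -> TrainedModel:
    """Fit a regressor of the requested kind; deterministic for a fixed seed."""
    y = _check_inputs(spec, inputs, targets)
    hp = spec.resolved_hyperparams()
    kind = spec.kind

    if kind is ModelKind.DEEPSETS:
        cfg = DeepSetsConfig(seed=spec.seed, **hp)
        backend = DeepSetsRegressor(cfg).fit([ps.triplets for ps in inputs], y)
    else:
        X = _as_matrix(inputs)
        if kind is ModelKind.DECISION_TREE:
            backend = DecisionTreeRegressor(random_state=spec.seed, **hp).fit(X, y)
        elif kind is ModelKind.RANDOM_FOREST:
            backend = RandomForestRegressor(
                random_state=spec.seed, n_jobs=1, **hp
            ).fit(X, y)
        else:
            backend = XGBRegressor(
                random_state=spec.seed, n_jobs=1, verbosity=0, **hp
            ).fit(X, y)
    return TrainedModel(spec=spec, input_contract=INPUT_CONTRACTS[kind], backend=backend)


def predict(model: TrainedModel, x: FeatureVector | PixelSet) -> float:
    """Predicted total bilirubin (mg/dL) for one subject's input."""
    if model.input_contract == "pixel_set":
        if not isinstance(x, PixelSet):
            raise ContractViolationError("this model predicts from pixel sets")
        value = model.backend.predict_set(x.triplets)
    else:
        if not isinstance(x, FeatureVector):
            raise ContractViolationError("this model predicts from feature vectors")
        value = float(model.backend.predict(x.values[None, :])[0])
    if not math.isfinite(value):
        raise ConfigurationError("model produced a non-finite prediction")
    return value


def predict_many(model: TrainedModel, inputs: Sequence) -> np.ndarray:
    return np.array([predict(model, x) for x in inputs])


def ensemble_predict(
    pred_sclera: float, pred_urine: float, weights: tuple[float, float] = (0.5, 0.5)
) -> float:
    """Weighted average of the two pathway predictions (weights sum to 1)."""
    w = np.asarray(weights, dtype=np.float64)
    if w.shape != (2,) or np.any(w < 0) or not math.isclose(w.sum(), 1.0, abs_tol=1e-9):
        raise ConfigurationError("weights must be a non-negative pair summing to 1")
    if not (math.isfinite(pred_sclera) and math.isfinite(pred_urine)):
        raise ConfigurationError("ensemble inputs must be finite")
    return float(w[0] * pred_sclera + w[1] * pred_urine)
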