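"""The four reference regressors behind a uniform fit/predict contract.

Hyperparameters are fixed (no tuning): linear-kernel support vector
regression at library defaults; a random forest of 100 trees with maximum
depth 10; ridge regression with penalty alpha = 0.1; and a small dense
network (inputs standardized, then 128-unit and 16-unit relu hidden layers
and a linear output) trained with the squared-error objective by Adam at the
default rate for 100 epochs with batch size 32.  This module is a thin
adapter over scikit-learn — the novel computation of this package lives in
the resampling and loss modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Ridge
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

__all__ = ["MODEL_FAMILIES", "ModelSpec", "FittedModel", "fit", "predict"]

MODEL_FAMILIES = ("svr_linear", "random_forest", "ridge", "deep_net")

#: short CLI aliases
FAMILY_ALIASES: Mapping[str, str] = MappingProxyType(
    {
        "svr": "svr_linear",
        "rf": "random_forest",
        "dnn": "deep_net",
        **{f: f for f in MODEL_FAMILIES},
    }
)

DEEP_NET_TRAINING = MappingProxyType(
    {
        "hidden_layer_sizes": (128, 16),
        "activation": "relu",
        "solver": "adam",
        "batch_size": 32,
        "max_iter": 100,  # epochs
    }
)


@dataclass(frozen=True)
class ModelSpec:
    """A model family plus its fixed hyperparameters and seed."""

    family: str
    seed: int = 0

    def __post_init__(self) -> None:
        family = FAMILY_ALIASES.get(self.family.strip().lower())
        if family is None:
            raise ValueError(
                f"unknown model family {self.family!r}; "
                f"choose from {MODEL_FAMILIES} (aliases svr, rf, dnn)"
            )
        object.__setattr__(self, "family", family)

    @property
    def hyperparameters(self) -> Mapping[str, object]:
        return MappingProxyType(_HYPERPARAMETERS[self.family])


_HYPERPARAMETERS: dict[str, dict[str, object]] = {
    "svr_linear": {"kernel": "linear"},
    "random_forest": {"n_estimators": 100, "max_depth": 10},
    "ridge": {"alpha": 0.1},
    "deep_net": dict(DEEP_NET_TRAINING),
}


def _build(spec: ModelSpec):
    if spec.family == "svr_linear":
        return SVR(kernel="linear")
    if spec.family == "random_forest":
        return RandomForestRegressor(
            n_estimators=100, max_depth=10, random_state=spec.seed
        )
    if spec.family == "ridge":
        return Ridge(alpha=0.1)
    if spec.family == "deep_net":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "net",
                    MLPRegressor(random_state=spec.seed, **DEEP_NET_TRAINING),
                ),
            ]
        )
    raise AssertionError(spec.family)


@dataclass
class FittedModel:
    """A fitted estimator plus the spec that produced it."""

    spec: ModelSpec
    estimator: object
    n_features: int
    is_fitted: bool = field(default=True)


def fit(spec: ModelSpec, X: np.ndarray, y: np.ndarray) -> FittedModel:
    """Fit one model family to a training block.

    ``X`` rows must align with ``y``; at least two training points are
    required.  Refitting with the same seed on identical data reproduces the
    predictions.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError(
            f"X ({X.shape}) rows must align with y ({y.shape})"
        )
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training points")
    est = _build(spec)
    est.fit(X, y)
    return FittedModel(spec=spec, estimator=est, n_features=X.shape[1])


def predict(model: FittedModel, X: np.ndarray) -> np.ndarray:
    """Predict activities for test rows; column count must match training."""
    if not model.is_fitted:
        raise ValueError("model is not fitted")
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"test matrix has {X.shape[1] if X.ndim == 2 else '?'} columns, "
            f"model was trained on {model.n_features}"
        )
    out = np.asarray(model.estimator.predict(X), dtype=float).ravel()
    if not np.all(np.isfinite(out)):
        raise ValueError(f"{model.spec.family} produced non-finite predictions")
    return out
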