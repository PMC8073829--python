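"""Classical-classifier baselines over the 124-dim engineered feature vector.

Deliberately thin wrappers around scikit-learn: a linear SVM, a random
forest and gradient-boosted trees, each preceded by feature standardization
fit on training data only.  All bespoke computation lives upstream in
:mod:`pcgkit.features`; these exist for comparison against the neural
pipeline.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .core import ConfigError, DataError
from .features import FeatureVector

__all__ = ["BaselineSpec", "fit_baseline", "predict_baseline"]

_KINDS = ("svm_linear", "rf", "gbdt")


@dataclass(frozen=True)
class BaselineSpec:
    """Which classical learner to use, with optional hyperparameter overrides."""

    kind: str = "svm_linear"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.kind not in _KINDS:
            raise ConfigError(f"kind must be one of {_KINDS}")


def _coerce_features(features) -> np.ndarray:
    if isinstance(features, np.ndarray):
        x = np.atleast_2d(features)
    else:
        x = np.stack([f.values if isinstance(f, FeatureVector) else np.asarray(f) for f in features])
    if not np.all(np.isfinite(x)):
        raise DataError("feature table contains non-finite values")
    return x


def fit_baseline(features, labels, spec: BaselineSpec | None = None) -> Pipeline:
    """Standardize (training statistics only) and fit the chosen classifier."""
    spec = spec or BaselineSpec()
    spec.validate()
    x = _coerce_features(features)
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise DataError("need both classes to fit a baseline")
    hp = dict(spec.hyperparameters)
    if spec.kind == "svm_linear":
        clf = SVC(kernel="linear", **{"C": 1.0, **hp})
    elif spec.kind == "rf":
        clf = RandomForestClassifier(**{"n_estimators": 200, "random_state": spec.seed, **hp})
    else:
        clf = GradientBoostingClassifier(**{"random_state": spec.seed, **hp})
    pipe = Pipeline([("scaler", StandardScaler()), ("clf", clf)])
    pipe.fit(x, y)
    return pipe


def predict_baseline(model: Pipeline, features) -> np.ndarray:
    """Class predictions for a feature table."""
    return model.predict(_coerce_features(features))
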