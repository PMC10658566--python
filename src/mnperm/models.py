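"""Statistical learners for permeation prediction.

Three model families are fitted on seven features of a permeation
record — skin type, microneedle type, needle length, patch needle
surface area, drug loading, permeation time and drug molecular weight —
with either the cumulative permeation amount (µg/cm²) or percentage as
the response:

* multiple linear regression (MLR), ordinary least squares;
* random forest (RF), via scikit-learn;
* gradient-boosted trees, via xgboost.

Published reference hyperparameters ("reference defaults") are provided per
target: amount — XGBoost {max_depth 4, eta 0.4, nround 100}, RF
{500 trees, mtry 5}; percentage — XGBoost {3, 0.2, 45}, RF {500, 6}.
Separate models are fitted per target, never one multi-output model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .dataset import PermeationRecord

__all__ = [
    "FEATURE_NAMES",
    "ENCODED_COLUMNS",
    "REFERENCE_HYPERPARAMS",
    "MLRModel",
    "TreeModelSpec",
    "FittedModel",
    "encode_features",
    "encode_records",
    "fit_mlr",
    "fit_tree_model",
    "predict",
    "feature_importance",
]

#: The seven semantic features, in canonical order.
FEATURE_NAMES = (
    "skin_type",
    "mn_type",
    "mn_length",
    "mn_surface_area",
    "drug_loading",
    "permeation_time",
    "mw",
)

#: Encoded design-matrix columns: one-hot categoricals with fixed level
#: order, then the numeric features.  9 columns total.
ENCODED_COLUMNS = (
    "skin_type=R",
    "skin_type=H",
    "mn_type=hydrogel",
    "mn_type=plastic",
    "mn_length",
    "mn_surface_area",
    "drug_loading",
    "permeation_time",
    "mw",
)

_ENCODED_TO_FEATURE = {
    "skin_type=R": "skin_type",
    "skin_type=H": "skin_type",
    "mn_type=hydrogel": "mn_type",
    "mn_type=plastic": "mn_type",
    "mn_length": "mn_length",
    "mn_surface_area": "mn_surface_area",
    "drug_loading": "drug_loading",
    "permeation_time": "permeation_time",
    "mw": "mw",
}

#: Reference hyperparameters per target.
REFERENCE_HYPERPARAMS = {
    "amount": {
        "xgboost": {"max_depth": 4, "eta": 0.4, "nround": 100},
        "rf": {"n_trees": 500, "mtry": 5},
    },
    "percentage": {
        "xgboost": {"max_depth": 3, "eta": 0.2, "nround": 45},
        "rf": {"n_trees": 500, "mtry": 6},
    },
}

_TARGETS = ("amount", "percentage")


def encode_features(record: PermeationRecord) -> np.ndarray:
    """Encode one record as the fixed 9-dimensional numeric vector."""
    if record.skin_type not in ("R", "H"):
        raise ValueError(f"unknown skin_type level: {record.skin_type!r}")
    if record.mn_type not in ("hydrogel", "plastic"):
        raise ValueError(f"unknown mn_type level: {record.mn_type!r}")
    vec = np.array(
        [
            1.0 if record.skin_type == "R" else 0.0,
            1.0 if record.skin_type == "H" else 0.0,
            1.0 if record.mn_type == "hydrogel" else 0.0,
            1.0 if record.mn_type == "plastic" else 0.0,
            record.mn_length,
            record.mn_surface_area,
            record.drug_loading,
            record.permeation_time,
            record.mw,
        ]
    )
    if not np.isfinite(vec).all():
        raise ValueError("non-finite feature value")
    return vec


def encode_records(records: Sequence[PermeationRecord]) -> np.ndarray:
    if len(records) == 0:
        return np.empty((0, len(ENCODED_COLUMNS)))
    return np.vstack([encode_features(r) for r in records])


def _targets(records: Sequence[PermeationRecord], target: str) -> np.ndarray:
    if target not in _TARGETS:
        raise ValueError(f"target must be one of {_TARGETS}")
    attr = "permeation_amount" if target == "amount" else "permeation_percentage"
    y = []
    for r in records:
        v = getattr(r, attr)
        if v is None:
            raise ValueError(f"record lacks a {target} response")
        y.append(v)
    return np.asarray(y, dtype=float)


@dataclass
class MLRModel:
    """Ordinary least-squares linear model y = X·k + b."""

    coefficients: np.ndarray  # per encoded column
    intercept: float
    target: str
    columns: tuple = ENCODED_COLUMNS

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.coefficients):
            raise ValueError("feature dimension mismatch")
        return X @ self.coefficients + self.intercept


@dataclass
class TreeModelSpec:
    family: str  # "rf" or "xgboost"
    target: str  # "amount" or "percentage"
    hyperparams: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in ("rf", "xgboost"):
            raise ValueError("family must be 'rf' or 'xgboost'")
        if self.target not in _TARGETS:
            raise ValueError(f"target must be one of {_TARGETS}")
        if not self.hyperparams:
            self.hyperparams = dict(REFERENCE_HYPERPARAMS[self.target][self.family])

    @classmethod
    def reference(cls, family: str, target: str) -> "TreeModelSpec":
        return cls(family=family, target=target)


@dataclass
class FittedModel:
    """A fitted tree ensemble with its spec and feature schema."""

    spec: TreeModelSpec
    estimator: object
    columns: tuple = ENCODED_COLUMNS
    seed: int = 0

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] == 0:
            return np.empty(0)
        if X.shape[1] != len(self.columns):
            raise ValueError("feature dimension mismatch")
        return np.asarray(self.estimator.predict(X), dtype=float)


def fit_mlr(
    records: Sequence[PermeationRecord],
    target: str = "amount",
) -> MLRModel:
    """Fit ordinary least squares on the encoded design.

    The one-hot pairs plus intercept are inherently collinear, so the
    minimum-norm least-squares solution is used (with a warning when
    the design is rank-deficient).
    """
    X = encode_records(records)
    y = _targets(records, target)
    if len(records) <= X.shape[1]:
        warnings.warn(
            f"n={len(records)} not greater than feature dimension "
            f"{X.shape[1]}; fit is underdetermined", stacklevel=2
        )
    A = np.column_stack([X, np.ones(len(y))])
    sol, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < A.shape[1]:
        warnings.warn(
            "rank-deficient design; returning the minimum-norm solution",
            stacklevel=2,
        )
    return MLRModel(coefficients=sol[:-1], intercept=float(sol[-1]), target=target)


def fit_tree_model(
    records: Sequence[PermeationRecord],
    spec: TreeModelSpec,
    seed: int = 0,
) -> FittedModel:
    """Fit a seeded RF (scikit-learn) or gradient-boosted (xgboost)
    ensemble with the spec's hyperparameters."""
    if len(records) == 0:
        raise ValueError("empty training set")
    X = encode_records(records)
    y = _targets(records, spec.target)
    # canonical row order: bootstrap draws index rows by position, so
    # sorting makes seeded fits invariant to the caller's row order
    order = np.lexsort(np.column_stack([X, y]).T)
    X, y = X[order], y[order]

    if spec.family == "rf":
        from sklearn.ensemble import RandomForestRegressor

        hp = spec.hyperparams
        mtry = min(int(hp.get("mtry", 5)), X.shape[1])
        est = RandomForestRegressor(
            n_estimators=int(hp.get("n_trees", 500)),
            max_features=mtry,
            random_state=seed,
            n_jobs=1,
        )
    else:
        from xgboost import XGBRegressor

        hp = spec.hyperparams
        est = XGBRegressor(
            max_depth=int(hp.get("max_depth", 4)),
            learning_rate=float(hp.get("eta", 0.4)),
            n_estimators=int(hp.get("nround", 100)),
            gamma=float(hp.get("gamma", 0.0)),
            reg_lambda=float(hp.get("lambda", 1.0)),
            random_state=seed,
            n_jobs=1,
            importance_type="gain",
            verbosity=0,
        )
    est.fit(X, y)
    return FittedModel(spec=spec, estimator=est, seed=seed)


def predict(model, records: Sequence[PermeationRecord]) -> np.ndarray:
    """Predict the model's target for each record."""
    if len(records) == 0:
        return np.empty(0)
    X = encode_records(records)
    out = model.predict(X)
    if not np.isfinite(out).all():
        raise ValueError("model produced non-finite predictions")
    return out


def feature_importance(model: FittedModel) -> Dict[str, float]:
    """Per-feature importance shares summing to 1.

    RF importances are impurity-based; gradient-boosted importances use
    total gain.  One-hot columns are pooled back to their semantic
    feature.
    """
    if not isinstance(model, FittedModel):
        raise TypeError(
            "feature importance is defined for tree ensembles; "
            "inspect MLR coefficients directly"
        )
    raw = np.asarray(model.estimator.feature_importances_, dtype=float)
    pooled = {name: 0.0 for name in FEATURE_NAMES}
    for col, val in zip(model.columns, raw):
        pooled[_ENCODED_TO_FEATURE[col]] += float(val)
    total = sum(pooled.values())
    if total <= 0:
        # constant response: no splits were informative
        return {name: 1.0 / len(pooled) for name in pooled}
    return {name: v / total for name, v in pooled.items()}
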