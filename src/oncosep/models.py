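"""Classifier families, cross-validated evaluation and metric computation.

Five model families are evaluated over three nested feature sets
(``ehr_only`` ⊂ ``ehr_drug`` ⊂ ``ehr_drug_lab``) with stratified 5-fold
cross-validation and six metrics: accuracy, AUROC, AUPRC, precision, recall
and F1.  Per-fold preprocessing (scaling) is fit on the training folds only.
Reported aggregates are fold means; pooled-prediction metrics are computed
alongside.  The random forest default is a 20-tree ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .nets import ConvResNetClassifier, LSTMClassifier

MODEL_FAMILIES = (
    "logistic_regression",
    "random_forest",
    "feedforward_net",
    "conv_resnet",
    "recurrent_lstm",
)
FEATURE_SETS = ("ehr_only", "ehr_drug", "ehr_drug_lab")
METRICS = ("accuracy", "auroc", "auprc", "precision", "recall", "f1")

CONV_SIDE = 42
CONV_MAX_FEATURES = CONV_SIDE * CONV_SIDE  # 1764

#: permitted hyperparameters per family (schema validation)
_HYPERPARAM_SCHEMA = {
    "logistic_regression": {"C", "max_iter", "penalty"},
    "random_forest": {"n_trees", "max_depth", "max_features"},
    "feedforward_net": {"hidden_layer_sizes", "learning_rate_init", "max_iter", "alpha"},
    "conv_resnet": {"channels", "n_epochs", "lr", "batch_size"},
    "recurrent_lstm": {"hidden", "n_epochs", "lr", "batch_size"},
}


class ModelConfigError(ValueError):
    pass


class MetricError(ValueError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    family: str
    hyperparameters: dict = field(default_factory=dict)
    feature_set: str = "ehr_drug_lab"
    seed: int = 0

    def __post_init__(self):
        if self.family not in MODEL_FAMILIES:
            raise ModelConfigError(f"unknown model family {self.family!r}")
        if self.feature_set not in FEATURE_SETS:
            raise ModelConfigError(f"unknown feature set {self.feature_set!r}")
        extra = set(self.hyperparameters) - _HYPERPARAM_SCHEMA[self.family]
        if extra:
            raise ModelConfigError(
                f"hyperparameters {sorted(extra)} not valid for {self.family}"
            )
        if self.hyperparameters.get("n_trees", 1) < 1:
            raise ModelConfigError("n_trees must be >= 1")


def make_model(config: ModelConfig):
    """Instantiate the (sklearn-compatible) estimator for a config."""
    hp = dict(config.hyperparameters)
    seed = config.seed
    if config.family == "logistic_regression":
        return make_pipeline(
            StandardScaler(),
            LogisticRegression(
                C=hp.get("C", 1.0),
                max_iter=int(hp.get("max_iter", 1000)),
                random_state=seed,
            ),
        )
    if config.family == "random_forest":
        return RandomForestClassifier(
            n_estimators=int(hp.get("n_trees", 20)),
            max_depth=hp.get("max_depth"),
            max_features=hp.get("max_features", "sqrt"),
            random_state=seed,
        )
    if config.family == "feedforward_net":
        return make_pipeline(
            StandardScaler(),
            MLPClassifier(
                hidden_layer_sizes=tuple(hp.get("hidden_layer_sizes", (32, 16))),
                learning_rate_init=hp.get("learning_rate_init", 1e-3),
                alpha=hp.get("alpha", 1e-4),
                max_iter=int(hp.get("max_iter", 300)),
                random_state=seed,
            ),
        )
    if config.family == "conv_resnet":
        return ConvResNetClassifier(
            side=CONV_SIDE,
            channels=int(hp.get("channels", 4)),
            n_epochs=int(hp.get("n_epochs", 30)),
            lr=hp.get("lr", 0.01),
            batch_size=int(hp.get("batch_size", 64)),
            seed=seed,
        )
    if config.family == "recurrent_lstm":
        return LSTMClassifier(
            hidden=int(hp.get("hidden", 8)),
            n_epochs=int(hp.get("n_epochs", 40)),
            lr=hp.get("lr", 0.02),
            batch_size=int(hp.get("batch_size", 64)),
            seed=seed,
        )
    raise ModelConfigError(config.family)  # pragma: no cover


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def compute_metrics(y_true, y_score, threshold: float = 0.5) -> dict[str, float]:
    """Six metrics from scores: rank-based AUROC, step-integrated AUPRC, and
    thresholded accuracy/precision/recall/F1."""
    y_true = np.asarray(y_true).astype(int)
    y_score = np.asarray(y_score, dtype=float)
    if len(np.unique(y_true)) < 2:
        raise MetricError("AUROC/AUPRC undefined for single-class y_true")
    y_pred = (y_score >= threshold).astype(int)
    return {
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "auroc": float(roc_auc_score(y_true, y_score)),
        "auprc": float(average_precision_score(y_true, y_score)),
        "precision": float(precision_score(y_true, y_pred, zero_division=0)),
        "recall": float(recall_score(y_true, y_pred, zero_division=0)),
        "f1": float(f1_score(y_true, y_pred, zero_division=0)),
    }


# ---------------------------------------------------------------------------
# input reshaping
# ---------------------------------------------------------------------------

def reshape_features(X, family: str, sequences: list[np.ndarray] | None = None):
    """Shape the model input per family.

    flat families: (rows, F) array.  ``conv_resnet``: zero-pad each row to
    42*42 = 1764 positions (manifest order) and reshape to (rows, 1, 42, 42);
    more than 1764 features is an error.  ``recurrent_lstm``: explicit
    variable-length ``sequences`` are zero-padded to the cohort maximum
    length -> (rows, time, F); a flat table becomes a length-1 sequence.

    Returns (array, per-sample shape descriptor).
    """
    if family == "recurrent_lstm":
        if sequences is not None:
            f = sequences[0].shape[1]
            tmax = max(s.shape[0] for s in sequences)
            out = np.zeros((len(sequences), tmax, f))
            for i, s in enumerate(sequences):
                out[i, : s.shape[0], :] = s
            return out, (tmax, f)
        Xa = np.asarray(X, dtype=float)
        return Xa[:, None, :], (1, Xa.shape[1])
    Xa = np.asarray(X, dtype=float)
    if family == "conv_resnet":
        n, f = Xa.shape
        if f > CONV_MAX_FEATURES:
            raise ModelConfigError(
                f"{f} features exceed the {CONV_SIDE}x{CONV_SIDE} image capacity"
            )
        padded = np.zeros((n, CONV_MAX_FEATURES))
        padded[:, :f] = Xa
        return padded, (1, CONV_SIDE, CONV_SIDE)
    return Xa, (Xa.shape[1],)


_NEEDS_SCALING = {"conv_resnet", "recurrent_lstm"}


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    per_fold: list[dict[str, float]]
    aggregate: dict[str, float]
    pooled: dict[str, float]
    model_config: ModelConfig
    n_folds: int

    def to_dict(self) -> dict:
        return {
            "per_fold": self.per_fold,
            "aggregate": self.aggregate,
            "pooled": self.pooled,
            "model": {
                "family": self.model_config.family,
                "feature_set": self.model_config.feature_set,
                "hyperparameters": self.model_config.hyperparameters,
                "seed": self.model_config.seed,
            },
            "n_folds": self.n_folds,
        }


def run_cross_validation(
    X,
    y,
    model_config: ModelConfig,
    n_folds: int = 5,
    threshold: float = 0.5,
) -> EvalReport:
    """Stratified k-fold evaluation of one model family.

    Fold assignment is seeded from the config.  Scaling (for the scale-
    sensitive families) and the model itself are fit on training folds only;
    metrics come from held-out predictions.  Aggregate = fold means; pooled
    metrics over concatenated held-out predictions are reported alongside.
    """
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y).astype(int)
    if n_folds < 2:
        raise ModelConfigError("n_folds must be >= 2")
    counts = np.bincount(ya, minlength=2)
    if counts.min() < n_folds:
        raise ModelConfigError(
            f"each class needs >= {n_folds} rows (got {counts.tolist()})"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=model_config.seed)
    per_fold, scores_all, y_all = [], [], []
    for train_idx, test_idx in skf.split(Xa, ya):
        X_tr, X_te = Xa[train_idx], Xa[test_idx]
        if model_config.family in _NEEDS_SCALING:
            scaler = StandardScaler().fit(X_tr)
            X_tr, X_te = scaler.transform(X_tr), scaler.transform(X_te)
        X_tr, _ = reshape_features(X_tr, model_config.family)
        X_te, _ = reshape_features(X_te, model_config.family)
        model = make_model(model_config)
        if model_config.family == "conv_resnet":
            X_tr = X_tr.reshape(len(train_idx), -1)
            X_te = X_te.reshape(len(test_idx), -1)
        model.fit(X_tr, ya[train_idx])
        scores = model.predict_proba(X_te)[:, 1]
        per_fold.append(compute_metrics(ya[test_idx], scores, threshold))
        scores_all.append(scores)
        y_all.append(ya[test_idx])
    aggregate = {
        m: float(np.mean([f[m] for f in per_fold])) for m in METRICS
    }
    pooled = compute_metrics(np.concatenate(y_all), np.concatenate(scores_all), threshold)
    return EvalReport(per_fold, aggregate, pooled, model_config, n_folds)


def grid_search(
    X,
    y,
    family: str,
    grid: list[dict],
    feature_set: str = "ehr_drug_lab",
    seed: int = 0,
    n_folds: int = 3,
) -> ModelConfig:
    """Exhaustive hyperparameter search by nested CV on the given (training)
    data; selects max mean AUROC, ties broken by first-listed grid point."""
    if not grid:
        raise ModelConfigError("empty grid")
    best: tuple[float, int] | None = None
    best_config = None
    for i, hp in enumerate(grid):
        cfg = ModelConfig(family=family, hyperparameters=hp, feature_set=feature_set, seed=seed)
        report = run_cross_validation(X, y, cfg, n_folds=n_folds)
        score = report.aggregate["auroc"]
        if best is None or score > best[0]:
            best = (score, i)
            best_config = cfg
    return best_config
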