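"""Random-forest training, persistence, prediction, and model comparison.

The classifier is a scikit-learn ``RandomForestClassifier`` over the
flattened BLOSUM62 feature vectors (600 features in pair mode, 1280 in
pmhc mode). Class imbalance is handled upstream by negative sampling, so
class weights stay uniform. Defaults: 300 trees, unlimited depth, √p
features per split, single-threaded for byte-reproducibility. A pair is
called binding when its predicted probability is ≥ the threshold
(default 0.5; ties classify as binding).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier

from .encoding import PAIR_FEATURES, PMHC_FEATURES

MODEL_FORMAT_VERSION = 1
DEFAULT_N_TREES = 300
MODE_FEATURES = {"pair": PAIR_FEATURES, "pmhc": PMHC_FEATURES}


@dataclass
class TrainedModel:
    forest: RandomForestClassifier
    mode: str
    n_trees: int
    seed: int
    n_pos: int
    n_neg: int
    format_version: int = MODEL_FORMAT_VERSION
    metadata: dict = field(default_factory=dict)

    @property
    def class_ratio(self) -> float:
        """binding : non-binding ratio of the training set."""
        return self.n_pos / self.n_neg if self.n_neg else float("inf")

    @property
    def n_features(self) -> int:
        return MODE_FEATURES[self.mode]


def _check_xy(features: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D array")
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"{X.shape[0]} feature rows vs {y.shape[0]} labels")
    classes = set(np.unique(y).tolist())
    if not classes <= {0, 1}:
        raise ValueError(f"labels must be binary 0/1, got {sorted(classes)}")
    if len(classes) < 2:
        raise ValueError("both classes must be present for training")
    return X, y.astype(int)


def train(features: np.ndarray, labels: Sequence[int],
          n_trees: int = DEFAULT_N_TREES, seed: int = 0,
          mode: str | None = None, **forest_kwargs) -> TrainedModel:
    """Fit the forest; deterministic under a fixed seed.

    ``mode`` is inferred from the feature width when not given; any extra
    keyword arguments are passed to ``RandomForestClassifier``.
    """
    X, y = _check_xy(features, np.asarray(labels))
    if mode is None:
        widths = {v: k for k, v in MODE_FEATURES.items()}
        mode = widths.get(X.shape[1])
        if mode is None:
            raise ValueError(f"cannot infer mode from {X.shape[1]} features")
    elif X.shape[1] != MODE_FEATURES[mode]:
        raise ValueError(
            f"{mode}-mode expects {MODE_FEATURES[mode]} features, got {X.shape[1]}")
    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1, **forest_kwargs)
    forest.fit(X, y)
    return TrainedModel(forest=forest, mode=mode, n_trees=n_trees, seed=seed,
                        n_pos=int((y == 1).sum()), n_neg=int((y == 0).sum()))


def predict_proba(model: TrainedModel, features: np.ndarray) -> np.ndarray:
    """Binding probability per row, in [0, 1]."""
    X = np.asarray(features, dtype=np.float64)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"{model.mode}-mode model expects {model.n_features} features, "
            f"got {X.shape[1]}")
    pos_col = list(model.forest.classes_).index(1)
    return model.forest.predict_proba(X)[:, pos_col]


def classify(probabilities: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary call: 1 iff probability ≥ threshold."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0,1)")
    p = np.asarray(probabilities, dtype=np.float64)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("probabilities must lie in [0,1]")
    return (p >= threshold).astype(int)


def default_candidates(seed: int = 0) -> dict[str, object]:
    """Model families for the cross-validated comparison harness."""
    return {
        "Random Forest": RandomForestClassifier(
            n_estimators=DEFAULT_N_TREES, random_state=seed, n_jobs=1),
        "Logistic Regression [solver: lbfgs]": LogisticRegression(
            solver="lbfgs", max_iter=2000),
        "KNN [n_neighbors: 3]": KNeighborsClassifier(n_neighbors=3),
        "Gaussian Naive Bayes": GaussianNB(),
    }


def cross_validate_models(candidates: dict[str, object],
                          features: np.ndarray, labels: Sequence[int],
                          k: int = 5, seed: int = 0) -> pd.DataFrame:
    """Stratified k-fold comparison: mean validation accuracy, AUC, fit time.

    Rows are sorted by mean accuracy descending, mirroring the model-
    selection step that singles out the random forest.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    X, y = _check_xy(features, np.asarray(labels))
    if min((y == 0).sum(), (y == 1).sum()) < k:
        raise ValueError("k exceeds the minority-class count")
    if "Random Forest" not in candidates:
        raise ValueError("candidates must include the Random Forest configuration")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    rows = []
    for name, estimator in candidates.items():
        accs, aucs, times = [], [], []
        for train_idx, val_idx in folds:
            est = clone(estimator)
            t0 = time.perf_counter()
            est.fit(X[train_idx], y[train_idx])
            times.append(time.perf_counter() - t0)
            if hasattr(est, "predict_proba"):
                pos = list(est.classes_).index(1)
                scores = est.predict_proba(X[val_idx])[:, pos]
            else:
                scores = est.decision_function(X[val_idx])
            accs.append(accuracy_score(y[val_idx], est.predict(X[val_idx])))
            aucs.append(roc_auc_score(y[val_idx], scores))
        rows.append({"model": name,
                     "mean_validation_accuracy": float(np.mean(accs)),
                     "mean_validation_auc": float(np.mean(aucs)),
                     "mean_fit_time_s": float(np.mean(times))})
    table = pd.DataFrame(rows).sort_values(
        "mean_validation_accuracy", ascending=False, ignore_index=True)
    return table


def save_model(model: TrainedModel, path: str | Path) -> None:
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "mode": model.mode,
        "n_trees": model.n_trees,
        "seed": model.seed,
        "n_pos": model.n_pos,
        "n_neg": model.n_neg,
        "metadata": model.metadata,
        "forest": model.forest,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> TrainedModel:
    try:
        payload = joblib.load(path)
    except Exception as exc:  # corrupt / truncated file
        raise ValueError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ValueError(f"{path} is not a tcrforest model file")
    if payload["format_version"] > MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model format {payload['format_version']} is newer than "
            f"supported {MODEL_FORMAT_VERSION}")
    return TrainedModel(forest=payload["forest"], mode=payload["mode"],
                        n_trees=payload["n_trees"], seed=payload["seed"],
                        n_pos=payload["n_pos"], n_neg=payload["n_neg"],
                        format_version=payload["format_version"],
                        metadata=payload.get("metadata", {}))
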