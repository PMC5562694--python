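"""The three predictive models and their shared utilities.

* **RF-SL** — a random forest on percent-change radiomics features of the
  segmented lesions (reference configuration: 6 trees, minimum 13
  observations per leaf).
* **RF-ROI** — a random forest on per-lesion averaged paired-ROI features
  (reference configuration: 2 trees, minimum 29 observations per leaf).
* **DL-CNN** — the compact CNN from :mod:`bladresp.models.cnn`, scored
  per lesion by averaging the per-ROI T0 probabilities.

Feature utilities: per-feature AUC importance ranking (orientation-folded)
and sequential forward selection driven by cross-validated forest AUC.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from ..types import FeatureVector, ResponseLabel
from .cnn import CNNConfig, TrainedCNN, build_cnn, train_cnn  # noqa: F401

__all__ = [
    "RFConfig", "TrainedModel", "CNNConfig", "TrainedCNN",
    "build_cnn", "train_cnn",
    "rank_features_by_auc", "select_features",
    "train_random_forest", "predict_scores", "score_lesion",
]


@dataclass
class RFConfig:
    """Random-forest configuration (tree count, leaf size, seed)."""

    n_trees: int = 6
    min_leaf: int = 13
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.min_leaf < 1:
            raise ValueError("n_trees and min_leaf must be >= 1")


#: reference configurations from the clinical training cohort (104 pairs)
RF_SL_CONFIG = RFConfig(n_trees=6, min_leaf=13)
RF_ROI_CONFIG = RFConfig(n_trees=2, min_leaf=29)


@dataclass
class TrainedModel:
    """A fitted forest plus its feature manifest and training metadata."""

    kind: str                       # "rf_sl" | "rf_roi"
    estimator: RandomForestClassifier
    feature_names: Tuple[str, ...]
    config: RFConfig
    train_score_check: float = 0.0  # mean training score, for provenance


def _labels_to_binary(y: Sequence) -> np.ndarray:
    return np.asarray([1 if (isinstance(v, ResponseLabel) and v.is_complete)
                       or v == 1 else 0 for v in y], dtype=int)


def rank_features_by_auc(X: np.ndarray, y: Sequence,
                         names: Optional[Sequence[str]] = None
                         ) -> List[Tuple[int, str, float]]:
    """Order features by individual discriminative power.

    Each feature's AUC is folded for orientation, ``max(AUC, 1 − AUC)``,
    so a feature separating in either direction ranks equally high.
    Returns (index, name, folded AUC) sorted descending, ties broken by
    feature index.
    """
    X = np.asarray(X, dtype=float)
    yb = _labels_to_binary(y)
    if len(np.unique(yb)) < 2:
        raise ValueError("both classes must be present")
    names = list(names) if names is not None else [f"f{i}" for i in range(X.shape[1])]
    aucs = []
    for j in range(X.shape[1]):
        a = roc_auc_score(yb, X[:, j])
        aucs.append(max(a, 1.0 - a))
    order = sorted(range(X.shape[1]), key=lambda j: (-aucs[j], j))
    return [(j, names[j], float(aucs[j])) for j in order]


def _cv_auc(X: np.ndarray, y: np.ndarray, cols: Sequence[int],
            cfg: RFConfig, seed: int, n_folds: int) -> float:
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scores = np.zeros(len(y))
    for tr, te in skf.split(X, y):
        # keep the leaf-size-to-training-size ratio on the smaller inner
        # folds, otherwise the scorer forest cannot split at all
        inner = dataclasses.replace(
            cfg, min_leaf=max(1, round(cfg.min_leaf * len(tr) / len(y))))
        model = train_random_forest(inner, X[np.ix_(tr, cols)], y[tr])
        scores[te] = predict_scores(model, X[np.ix_(te, cols)])
    return float(roc_auc_score(y, scores))


def select_features(X: np.ndarray, y: Sequence, method: str = "sfs",
                    k_max: int = 8, seed: int = 0,
                    rf_config: Optional[RFConfig] = None,
                    n_folds: int = 3) -> List[int]:
    """Pick a feature subset for a forest.

    ``"sfs"`` (default) is sequential forward selection maximizing the
    stratified cross-validated AUC of the configured forest, stopping at
    no improvement or ``k_max`` features. ``"auc_rank"`` simply takes the
    ``k_max`` individually best features by folded AUC. Deterministic
    given ``seed``.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    X = np.asarray(X, dtype=float)
    yb = _labels_to_binary(y)
    if len(np.unique(yb)) < 2:
        raise ValueError("both classes must be present")
    if method == "auc_rank":
        return [j for j, _, _ in rank_features_by_auc(X, yb)[:k_max]]
    if method != "sfs":
        raise ValueError(f"unknown selection method: {method}")

    cfg = rf_config or RFConfig()
    n_folds = max(2, min(n_folds, int(np.bincount(yb).min())))
    selected: List[int] = []
    best = -np.inf
    while len(selected) < min(k_max, X.shape[1]):
        candidates = [j for j in range(X.shape[1]) if j not in selected]
        trial = [(_cv_auc(X, yb, selected + [j], cfg, seed, n_folds), j)
                 for j in candidates]
        score, j = max(trial, key=lambda t: (t[0], -t[1]))
        if score <= best + 1e-9:
            break
        best = score
        selected.append(j)
    return selected


def _canonical_order(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Deterministic row order so that fits ignore input permutation."""
    keys = np.vstack([X.T[::-1], y[None, :]])
    return np.lexsort(keys)


def train_random_forest(cfg: RFConfig, X: np.ndarray, y: Sequence,
                        feature_names: Optional[Sequence[str]] = None,
                        kind: str = "rf") -> TrainedModel:
    """Fit a forest with exactly ``cfg.n_trees`` trees honoring
    ``cfg.min_leaf`` observations per leaf; scores are mean tree class-1
    probabilities in [0, 1]."""
    X = np.asarray(X, dtype=float)
    yb = _labels_to_binary(y)
    counts = np.bincount(yb, minlength=2)
    if counts.min() < 1 or len(np.unique(yb)) < 2:
        raise ValueError("training set must contain at least one case per class")
    order = _canonical_order(X, yb)
    est = RandomForestClassifier(
        n_estimators=cfg.n_trees, min_samples_leaf=cfg.min_leaf,
        random_state=cfg.seed, bootstrap=True)
    est.fit(X[order], yb[order])
    names = tuple(feature_names) if feature_names is not None else \
        tuple(f"f{i}" for i in range(X.shape[1]))
    model = TrainedModel(kind=kind, estimator=est, feature_names=names, config=cfg)
    model.train_score_check = float(est.predict_proba(X)[:, 1].mean())
    return model


def predict_scores(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Per-row likelihood of complete response (T0), in [0, 1]."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    return model.estimator.predict_proba(X)[:, 1]


def score_lesion(model: Union[TrainedModel, TrainedCNN],
                 inputs) -> float:
    """One lesion pair → one score in [0, 1].

    CNN: mean of the per-ROI T0 probabilities over the lesion's paired
    ROIs. Forests: the forest score of the lesion's single feature vector
    (the percent-change vector for RF-SL, the per-lesion averaged ROI
    vector for RF-ROI).
    """
    if isinstance(model, TrainedCNN):
        patches = np.asarray(inputs, dtype=float)
        if patches.ndim == 2:
            patches = patches[None]
        if patches.shape[0] == 0:
            raise ValueError("no ROIs to score")
        probs = model.predict_proba(patches)[:, 1]
        return float(probs.mean())
    if isinstance(inputs, FeatureVector):
        inputs = inputs.values
    x = np.asarray(inputs, dtype=float)
    if x.size == 0:
        raise ValueError("empty feature input")
    return float(predict_scores(model, x[None, :])[0])
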