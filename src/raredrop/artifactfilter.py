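"""Machine-learning curation of detected events: cells versus artifacts.

A histogram gradient-boosting classifier is trained on labeled events
(``cell`` vs ``artifact``) with stratified k-fold cross-validation over a
grid of hyperparameters and morphometric feature subsets; the grid point
with the highest mean CV accuracy wins and is refit on all data.  At
application time events are kept when the predicted probability of being a
biological cell reaches a confidence threshold (default 0.90), trading
sensitivity against specificity.
"""

from __future__ import annotations

import hashlib
import pickle
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.model_selection import StratifiedKFold

__all__ = ["CurationModel", "train_curation_model", "apply_confidence_filter"]

POSITIVE_LABEL = "cell"

DEFAULT_GRID: tuple[Mapping[str, object], ...] = (
    {"max_iter": 100, "learning_rate": 0.1, "max_depth": None},
    {"max_iter": 150, "learning_rate": 0.05, "max_depth": 4},
)


def _schema_hash(features: Sequence[str]) -> str:
    return hashlib.sha256("\n".join(features).encode()).hexdigest()[:16]


def _numeric_features(events: pd.DataFrame, exclude: frozenset[str]) -> list[str]:
    return [
        c
        for c in events.columns
        if c not in exclude and pd.api.types.is_numeric_dtype(events[c])
    ]


@dataclass
class CurationModel:
    """Trained curation classifier with its CV audit trail."""

    estimator: HistGradientBoostingClassifier
    features: list[str]
    cv_fold_accuracies: np.ndarray  # per-fold accuracy of the winning config
    cv_table: pd.DataFrame  # one row per (hyperparams, subset) evaluated
    hyperparameters: dict
    confidence_threshold: float = 0.90
    schema_hash: str = ""
    version: str = "1"

    def __post_init__(self) -> None:
        if not 0 < self.confidence_threshold <= 1:
            raise ValueError("confidence_threshold must be in (0, 1]")
        if not self.schema_hash:
            self.schema_hash = _schema_hash(self.features)

    @property
    def mean_cv_accuracy(self) -> float:
        return float(np.mean(self.cv_fold_accuracies))

    def predict_cell_probability(self, events: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.features if f not in events.columns]
        if missing:
            raise KeyError(f"events are missing curation features: {missing}")
        proba = self.estimator.predict_proba(events[self.features].to_numpy(float))
        pos = list(self.estimator.classes_).index(POSITIVE_LABEL)
        return proba[:, pos]

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump({"version": self.version, "schema_hash": self.schema_hash, "model": self}, fh)

    @classmethod
    def load(cls, path) -> "CurationModel":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        model = payload["model"]
        if payload["schema_hash"] != model.schema_hash:
            raise ValueError("schema hash mismatch in serialized curation model")
        return model


def train_curation_model(
    labeled_events: pd.DataFrame,
    label_column: str = "label",
    cv_folds: int = 5,
    grid: Sequence[Mapping[str, object]] = DEFAULT_GRID,
    feature_subsets: Sequence[Sequence[str]] | None = None,
    confidence_threshold: float = 0.90,
    seed: int = 0,
) -> CurationModel:
    """Grid-search a histogram gradient-boosting curation model.

    ``feature_subsets`` defaults to the single subset of all numeric
    feature columns.  Stratified ``cv_folds``-fold CV scores every
    (hyperparameter, subset) pair; the best mean accuracy wins (ties go to
    the earlier grid entry, so a one-point grid returns that point).  The
    winner is refit on all rows.  Fully deterministic given ``seed``.
    """
    if label_column not in labeled_events.columns:
        raise KeyError(f"no label column {label_column!r}")
    y = labeled_events[label_column].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    if cv_folds < 2:
        raise ValueError("cv_folds must be >= 2")
    if counts.min() < cv_folds:
        raise ValueError(
            f"cv_folds={cv_folds} exceeds the smallest class count {counts.min()}"
        )
    if not grid:
        raise ValueError("hyperparameter grid is empty")

    exclude = frozenset({label_column, "cell_id", "sample_id", "slide", "frame", "x", "y"})
    if feature_subsets is None:
        feature_subsets = [_numeric_features(labeled_events, exclude)]

    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    rows = []
    best = None
    for gi, hp in enumerate(grid):
        for si, subset in enumerate(feature_subsets):
            X = labeled_events[list(subset)].to_numpy(float)
            fold_acc = []
            for tr, te in skf.split(X, y):
                clf = HistGradientBoostingClassifier(random_state=seed, **hp)
                clf.fit(X[tr], y[tr])
                fold_acc.append(float((clf.predict(X[te]) == y[te]).mean()))
            fold_acc = np.asarray(fold_acc)
            rows.append(
                {
                    "grid_index": gi,
                    "subset_index": si,
                    "n_features": len(subset),
                    "mean_cv_accuracy": float(fold_acc.mean()),
                    **{f"hp_{k}": v for k, v in hp.items()},
                }
            )
            # strict > keeps the earliest maximal entry
            if best is None or fold_acc.mean() > best[0]:
                best = (fold_acc.mean(), fold_acc, hp, list(subset))

    _, fold_acc, hp, subset = best
    final = HistGradientBoostingClassifier(random_state=seed, **hp)
    final.fit(labeled_events[subset].to_numpy(float), y)
    return CurationModel(
        estimator=final,
        features=subset,
        cv_fold_accuracies=fold_acc,
        cv_table=pd.DataFrame(rows),
        hyperparameters=dict(hp),
        confidence_threshold=confidence_threshold,
    )


def apply_confidence_filter(
    model: CurationModel,
    events: pd.DataFrame,
    threshold: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Partition events into (kept, rejected) at a cell-confidence threshold.

    Events with ``P(cell) >= threshold`` are kept; the per-event confidence
    vector is returned for audit.  ``threshold`` defaults to the model's
    stored confidence threshold.  Kept and rejected are disjoint and their
    union is the input.
    """
    t = model.confidence_threshold if threshold is None else threshold
    if not 0 <= t <= 1:
        raise ValueError("threshold must be in [0, 1]")
    conf = model.predict_cell_probability(events)
    keep = conf >= t
    return events.loc[keep].copy(), events.loc[~keep].copy(), conf
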