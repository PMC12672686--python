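"""Patient-level disease-group prediction from per-sample cells/mL profiles.

Binary tasks (precursor vs overt disease, precursor vs newly diagnosed,
MGUS vs SMM) are evaluated with stratified k-fold cross-validation, always
reporting held-out accuracy: a univariate single-threshold classifier per
feature, and multivariate decision-tree / random-forest models with
impurity-based feature importances averaged over folds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .enumstats import EVENT_TYPES

logger = logging.getLogger(__name__)

__all__ = [
    "PredictionTask",
    "PredictionResult",
    "TASKS",
    "univariate_accuracy",
    "univariate_accuracy_table",
    "multivariate_accuracy",
]


@dataclass(frozen=True)
class PredictionTask:
    """Binary label definition over disease states plus model/CV settings."""

    name: str
    group1: tuple[str, ...]  # positive label states
    group2: tuple[str, ...]
    feature_columns: tuple[str, ...] = tuple(EVENT_TYPES)
    model: str = "random-forest"
    cv_folds: int = 5
    n_repeats: int = 20
    n_estimators: int = 500
    max_depth: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.group1) & set(self.group2):
            raise ValueError("label groups overlap")
        if self.model not in ("univariate-stump", "decision-tree", "random-forest"):
            raise ValueError(f"unknown model {self.model!r}")

    def labels_for(self, states: pd.Series) -> pd.Series:
        lab = pd.Series(pd.NA, index=states.index, dtype=object)
        lab[states.isin(self.group1)] = 1
        lab[states.isin(self.group2)] = 0
        return lab


TASKS: dict[str, PredictionTask] = {
    "precursor_vs_overt": PredictionTask(
        "precursor_vs_overt", ("NDMM", "RRMM"), ("MGUS", "SMM")
    ),
    "precursor_vs_ndmm": PredictionTask(
        "precursor_vs_ndmm", ("NDMM",), ("MGUS", "SMM")
    ),
    "mgus_vs_smm": PredictionTask(
        "mgus_vs_smm", ("SMM",), ("MGUS",), model="decision-tree"
    ),
}


@dataclass
class PredictionResult:
    """Cross-validated evaluation of one task."""

    task: str
    accuracy: float
    importances: pd.Series  # mean impurity importance per feature
    confusion: pd.DataFrame  # 2x2 counts from modal held-out predictions
    fold_accuracies: np.ndarray
    n_samples: int

    @property
    def importance_ranking(self) -> list[str]:
        return list(self.importances.sort_values(ascending=False).index)


def _check_labels(y: np.ndarray, min_per_class: int = 3) -> None:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("all labels identical: nothing to predict")
    if counts.min() < min_per_class:
        raise ValueError(
            f"need >= {min_per_class} samples per class, got {dict(zip(classes, counts))}"
        )


def _best_stump(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Threshold and direction maximizing training accuracy.

    Returns ``(cut, direction)`` where the prediction is 1 when
    ``direction * (x >= cut)`` holds, i.e. direction +1 predicts 1 above
    the cut and -1 predicts 1 below it.  Accuracy ties are broken toward
    the candidate cut closest to the pooled median.
    """
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    uniq = np.unique(xs)
    cuts = np.concatenate([[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]])
    med = np.median(x)
    best = (-1.0, np.inf, 0.0, 1)  # (accuracy, |cut - median|, cut, direction)
    for cut in cuts:
        above = x >= cut
        for direction in (1, -1):
            pred = above if direction == 1 else ~above
            acc = float((pred == (y == 1)).mean())
            key = (acc, -abs(cut - med))
            if key > (best[0], -best[1]):
                best = (acc, abs(cut - med), float(cut), direction)
    return best[2], best[3]


def univariate_accuracy(
    values: Sequence[float],
    labels: Sequence[int],
    cv_folds: int = 5,
    n_repeats: int = 20,
    seed: int = 0,
) -> tuple[float, float]:
    """Cross-validated accuracy of a single-feature threshold classifier.

    Per training fold the cut maximizing training accuracy is chosen (ties
    resolved toward the pooled median) and scored on the held-out fold;
    the mean held-out accuracy over ``n_repeats`` repetitions of stratified
    ``cv_folds``-fold CV is returned together with the cut chosen on the
    full data.  A constant feature falls back to majority-class prediction
    with a logged warning.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    _check_labels(y)
    if np.unique(x).size == 1:
        logger.warning("constant feature: univariate accuracy = majority rate")
        maj = max(np.mean(y == 1), np.mean(y != 1))
        return float(maj), float(x[0])
    accs = []
    for rep in range(n_repeats):
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed + rep)
        for tr, te in skf.split(x.reshape(-1, 1), y):
            cut, direction = _best_stump(x[tr], y[tr])
            above = x[te] >= cut
            pred = above if direction == 1 else ~above
            accs.append(float((pred == (y[te] == 1)).mean()))
    full_cut, _ = _best_stump(x, y)
    return float(np.mean(accs)), float(full_cut)


def univariate_accuracy_table(
    enum_df: pd.DataFrame, task: PredictionTask
) -> pd.DataFrame:
    """Per-feature univariate CV accuracies for a task, sorted descending."""
    y = task.labels_for(enum_df["disease_state"])
    mask = y.notna()
    rows = []
    for feat in task.feature_columns:
        if feat not in enum_df.columns:
            continue
        acc, cut = univariate_accuracy(
            enum_df.loc[mask, feat].to_numpy(),
            y[mask].astype(int).to_numpy(),
            cv_folds=task.cv_folds,
            n_repeats=task.n_repeats,
            seed=task.seed,
        )
        rows.append({"feature": feat, "accuracy": acc, "threshold": cut})
    return (
        pd.DataFrame(rows)
        .sort_values("accuracy", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )


def _make_estimator(task: PredictionTask, seed: int):
    if task.model == "decision-tree":
        return DecisionTreeClassifier(max_depth=task.max_depth, random_state=seed)
    return RandomForestClassifier(
        n_estimators=task.n_estimators, max_depth=task.max_depth, random_state=seed
    )


def multivariate_accuracy(
    enum_df: pd.DataFrame,
    task: PredictionTask,
    groups: Sequence | None = None,
) -> PredictionResult:
    """Cross-validated accuracy and importances of a multivariate model.

    ``groups`` (e.g. patient ids when samples are replicated) forces all
    members of a group into the same fold, guarding against leakage.
    Reported accuracy is always held-out; the confusion table is built from
    each sample's modal held-out prediction across repeats, so its counts
    sum to the task's sample count.
    """
    y_full = task.labels_for(enum_df["disease_state"])
    mask = y_full.notna().to_numpy()
    sub = enum_df.loc[mask]
    y = y_full[mask].astype(int).to_numpy()
    _check_labels(y)
    feats = [f for f in task.feature_columns if f in sub.columns]
    X = sub[feats].to_numpy(float)
    n = len(y)

    accs = []
    importances = np.zeros(len(feats))
    n_fits = 0
    votes = np.zeros((n, 2), dtype=int)
    grp = None if groups is None else np.asarray(groups)[mask]
    for rep in range(task.n_repeats):
        if grp is None:
            splitter = StratifiedKFold(
                n_splits=task.cv_folds, shuffle=True, random_state=task.seed + rep
            )
            split = splitter.split(X, y)
        else:
            splitter = StratifiedGroupKFold(
                n_splits=task.cv_folds, shuffle=True, random_state=task.seed + rep
            )
            split = splitter.split(X, y, grp)
        for tr, te in split:
            est = _make_estimator(task, task.seed + rep)
            est.fit(X[tr], y[tr])
            pred = est.predict(X[te])
            accs.append(float((pred == y[te]).mean()))
            importances += est.feature_importances_
            n_fits += 1
            votes[te, pred] += 1
    modal = votes.argmax(axis=1)
    confusion = pd.DataFrame(
        [
            [(int(((y == t) & (modal == p)).sum())) for p in (0, 1)]
            for t in (0, 1)
        ],
        index=["true_0", "true_1"],
        columns=["pred_0", "pred_1"],
    )
    return PredictionResult(
        task=task.name,
        accuracy=float(np.mean(accs)),
        importances=pd.Series(importances / n_fits, index=feats),
        confusion=confusion,
        fold_accuracies=np.asarray(accs),
        n_samples=n,
    )
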