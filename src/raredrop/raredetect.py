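"""Unsupervised rare-event detection in morphometric feature space.

The detector follows the outlier-clustering approach used in slide-based
rare-cell assays: per-feature robust standardization, PCA retaining a
configured fraction of variance, Euclidean distance of every event to the
coordinate-wise median cell in PC space, and hierarchical clustering of
the high-distance candidate events.  With T the ``distance_quantile``
percentile of all distances, rare flags go to (a) compact candidate
clusters — between ``min_cluster_support`` and ``max_rare_cluster_size``
members — whose centroid lies beyond ``cluster_margin x T``, and (b) any
event beyond ``cluster_margin x T`` outright (when T degenerates to zero
the ``singleton_quantile`` percentile takes its place).  The margin
separates genuinely displaced subpopulations and extreme singletons from
the ordinary tail of the background distance distribution, which any
single percentile rule would flag at a fixed rate.

With ``max_rare_cluster_size=1`` clustering is disabled and the flags
reduce to a pure distance-threshold rule, which provides a brute-force
audit path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from sklearn.decomposition import PCA

__all__ = ["DetectionParams", "DetectionResult", "detect_rare_events", "distance_profile"]

#: Columns never used as detection features.
NON_FEATURE_COLUMNS = frozenset(
    {"cell_id", "sample_id", "slide", "frame", "x", "y", "label", "class"}
)


@dataclass(frozen=True)
class DetectionParams:
    """Free parameters of the rare-event screen.

    None of these is dictated by the underlying assay; defaults are this
    package's documented choices.  ``max_rare_cluster_size`` may be an
    absolute count or a fraction of the event count; ``None`` resolves to
    ``max(10, 0.1% of events)``.
    """

    variance_retained: float = 0.95
    linkage: str = "complete"
    max_rare_cluster_size: int | float | None = None
    distance_quantile: float = 99.5
    singleton_quantile: float = 99.95
    cluster_margin: float = 1.5
    min_cluster_support: int = 3
    standardize: bool = True
    cut_height_factor: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.variance_retained <= 1:
            raise ValueError("variance_retained must be in (0, 1]")
        if not 0 < self.distance_quantile < 100:
            raise ValueError("distance_quantile must be in (0, 100)")
        if not 0 < self.singleton_quantile < 100:
            raise ValueError("singleton_quantile must be in (0, 100)")
        if self.linkage not in ("ward", "average", "complete", "single"):
            raise ValueError("linkage must be ward/average/complete/single")
        if self.max_rare_cluster_size is not None and not (
            self.max_rare_cluster_size >= 1
            or 0 < self.max_rare_cluster_size < 1
        ):
            raise ValueError("max_rare_cluster_size must be >= 1 or a fraction in (0,1)")
        if self.min_cluster_support < 2:
            raise ValueError("min_cluster_support must be >= 2")
        if self.cluster_margin < 1:
            raise ValueError("cluster_margin must be >= 1")

    def resolve_max_cluster(self, n_events: int) -> int:
        m = self.max_rare_cluster_size
        if m is None:
            return max(10, int(0.001 * n_events))
        if 0 < m < 1:
            return max(1, int(m * n_events))
        return int(m)


@dataclass
class DetectionResult:
    """Per-event rare/common flags plus audit quantities."""

    flags: np.ndarray  # "rare" / "common"
    distance: np.ndarray
    cluster_id: np.ndarray  # -1 for non-candidate events
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame  # features x PCs
    threshold: float
    singleton_threshold: float

    @property
    def n_rare(self) -> int:
        return int((self.flags == "rare").sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"flag": self.flags, "distance": self.distance, "cluster_id": self.cluster_id}
        )


def _feature_matrix(
    events: pd.DataFrame, feature_columns: Sequence[str] | None
) -> tuple[np.ndarray, list[str]]:
    if feature_columns is None:
        feature_columns = [
            c
            for c in events.columns
            if c not in NON_FEATURE_COLUMNS
            and pd.api.types.is_numeric_dtype(events[c])
        ]
    X = events.loc[:, list(feature_columns)].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("detection features must be finite")
    return X, list(feature_columns)


def _standardized_pc_space(
    events: pd.DataFrame,
    params: DetectionParams,
    feature_columns: Sequence[str] | None,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame, list[str]]:
    """Robust z-scoring + PCA; returns (scores, evr, loadings, kept columns).

    Constant features are dropped; if every feature is constant the event
    cloud is a single point and an empty PC space (all distances zero) is
    returned rather than an error.
    """
    X, cols = _feature_matrix(events, feature_columns)
    if params.standardize:
        med = np.median(X, axis=0)
        mad = 1.4826 * np.median(np.abs(X - med), axis=0)
        sd = X.std(axis=0)
        scale = np.where(mad > 0, mad, sd)  # fall back to s.d. where MAD collapses
        keep = scale > 0
        X = (X[:, keep] - med[keep]) / scale[keep]
        cols = [c for c, k in zip(cols, keep) if k]
    else:
        keep = X.std(axis=0) > 0
        if keep.any():
            X = X[:, keep]
            cols = [c for c, k in zip(cols, keep) if k]
        else:
            X = X[:, :0]
            cols = []
    if X.shape[1] == 0:
        return (
            np.zeros((len(events), 0)),
            np.zeros(0),
            pd.DataFrame(index=cols),
            cols,
        )
    pca = PCA(n_components=min(X.shape))
    scores = pca.fit_transform(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, params.variance_retained - 1e-12) + 1)
    k = min(k, scores.shape[1])
    loadings = pd.DataFrame(
        pca.components_[:k].T, index=cols, columns=[f"PC{i+1}" for i in range(k)]
    )
    return scores[:, :k], pca.explained_variance_ratio_[:k], loadings, cols


def distance_profile(
    events: pd.DataFrame,
    params: DetectionParams = DetectionParams(),
    feature_columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Distance of every event to the coordinate-wise median cell in PC space.

    Exposes the distance step of the screen on its own for audit.  Scaling
    an already-standardized space by c > 0 scales every distance by c.
    """
    if len(events) < 2:
        raise ValueError("need at least 2 events for a distance profile")
    scores, _, _, _ = _standardized_pc_space(events, params, feature_columns)
    med = np.median(scores, axis=0) if scores.shape[1] else np.zeros(0)
    dist = np.linalg.norm(scores - med, axis=1) if scores.shape[1] else np.zeros(len(events))
    return pd.DataFrame({"distance": dist}, index=events.index)


def detect_rare_events(
    events: pd.DataFrame,
    params: DetectionParams = DetectionParams(),
    feature_columns: Sequence[str] | None = None,
    min_events: int = 50,
) -> DetectionResult:
    """Flag rare events in a per-cell feature table.

    See the module docstring for the algorithm.  Requires at least
    ``min_events`` rows; ties at the distance thresholds resolve inclusively
    (``>=`` counts as beyond), favoring sensitivity.
    """
    n = len(events)
    if n < min_events:
        raise ValueError(f"need >= {min_events} events, got {n}")
    scores, evr, loadings, _ = _standardized_pc_space(events, params, feature_columns)

    if scores.shape[1] == 0:  # all features constant: a single-point cloud
        return DetectionResult(
            flags=np.full(n, "common", dtype=object),
            distance=np.zeros(n),
            cluster_id=np.full(n, -1),
            explained_variance_ratio=evr,
            loadings=loadings,
            threshold=0.0,
            singleton_threshold=0.0,
        )

    med = np.median(scores, axis=0)
    dist = np.linalg.norm(scores - med, axis=1)
    threshold = float(np.percentile(dist, params.distance_quantile))
    max_cluster = params.resolve_max_cluster(n)

    flags = np.full(n, "common", dtype=object)
    cluster_id = np.full(n, -1)

    cand = np.flatnonzero(dist >= threshold)
    if max_cluster == 1:  # pure distance-threshold rule, no clustering
        flags[cand] = "rare"
        cluster_id[cand] = np.arange(len(cand))
        return DetectionResult(
            flags, dist, cluster_id, evr, loadings, threshold, threshold
        )

    if threshold > 0:
        singleton_threshold = params.cluster_margin * threshold
    else:  # degenerate bulk (most events identical): fall back to a percentile
        singleton_threshold = float(np.percentile(dist, params.singleton_quantile))
    if len(cand) > 10000:  # degenerate threshold ties: keep the most extreme
        cand = cand[np.argsort(dist[cand])[-10000:]]

    if len(cand) > 1:
        Z = scipy_linkage(scores[cand], method=params.linkage)
        labels = fcluster(Z, t=params.cut_height_factor * threshold, criterion="distance")
        cluster_id[cand] = labels - 1
        for lab in np.unique(labels):
            members = cand[labels == lab]
            if params.min_cluster_support <= len(members) <= max_cluster:
                centroid = scores[members].mean(axis=0)
                if np.linalg.norm(centroid - med) >= params.cluster_margin * threshold:
                    flags[members] = "rare"
    elif len(cand) == 1:
        cluster_id[cand] = 0

    flags[dist >= singleton_threshold] = "rare"

    return DetectionResult(
        flags, dist, cluster_id, evr, loadings, threshold, singleton_threshold
    )
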