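"""Group feature assembly and k-means clustering of ROIs.

Each ROI contributes five HWFs per subject; concatenating over S subjects
gives an ROI x (5*S) feature matrix, all entries in Hz.  ROIs are clustered
with k-means under squared Euclidean distance; the within-cluster sum of
squares (WCSS) as a function of k is the model-selection curve, with an
advisory knee-rule suggestion (the pipeline default k is user-set).

Features are not standardized by default — every column is a frequency in
Hz on a common scale — but per-column z-scoring is available behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = [
    "FeatureMatrix",
    "ClusterResult",
    "build_group_features",
    "kmeans_cluster",
    "scan_k",
    "suggest_k",
]

HWF_COLUMNS = ["hwf1", "hwf2", "hwf3", "hwf4", "hwf5"]


@dataclass
class FeatureMatrix:
    """ROI x (5*S) matrix of HWF features concatenated across subjects."""

    data: np.ndarray
    roi_ids: list
    subject_ids: list
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != (len(self.roi_ids), len(self.feature_names)):
            raise ValueError("feature matrix shape mismatch")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("feature matrix must be finite")

    @property
    def n_rois(self) -> int:
        return self.data.shape[0]


@dataclass
class ClusterResult:
    """One k-means solution: 1-based labels, centroids and the WCSS."""

    labels: np.ndarray
    k: int
    centroids: np.ndarray
    wcss: float
    seed: int
    n_restarts: int


def build_group_features(per_subject: list[pd.DataFrame],
                         subject_ids: list[str] | None = None) -> FeatureMatrix:
    """Concatenate per-subject ROI x 5 HWF tables, subject-major.

    Every table must have a ``roi_id`` column and ``hwf1..hwf5`` columns with
    identical ROI sets in identical order.
    """
    if not per_subject:
        raise ValueError("need at least one subject table")
    if subject_ids is None:
        subject_ids = [f"sub{i + 1:03d}" for i in range(len(per_subject))]
    ref_rois = list(per_subject[0]["roi_id"])
    blocks = []
    names = []
    for sid, table in zip(subject_ids, per_subject):
        rois = list(table["roi_id"])
        if rois != ref_rois:
            missing = sorted(set(map(str, ref_rois)) ^ set(map(str, rois)))
            raise ValueError(f"subject {sid}: ROI set mismatch, differing ids {missing}")
        blocks.append(table[HWF_COLUMNS].to_numpy(dtype=float))
        names.extend(f"{sid}:{c}" for c in HWF_COLUMNS)
    return FeatureMatrix(data=np.hstack(blocks), roi_ids=ref_rois,
                         subject_ids=list(subject_ids), feature_names=names)


def kmeans_cluster(features: FeatureMatrix, k: int, seed: int = 0,
                   n_restarts: int = 10, standardize: bool = False) -> ClusterResult:
    """Best-of-``n_restarts`` k-means solution, deterministic given seed."""
    if not 1 <= k <= features.n_rois:
        raise ValueError(f"k={k} must be in 1..{features.n_rois}")
    X = features.data
    if standardize:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed,
                algorithm="lloyd")
    labels = km.fit_predict(X) + 1
    return ClusterResult(labels=labels, k=k, centroids=km.cluster_centers_,
                         wcss=float(km.inertia_), seed=seed, n_restarts=n_restarts)


def scan_k(features: FeatureMatrix, k_min: int = 1, k_max: int | None = None,
           seed: int = 0, n_restarts: int = 10) -> list[tuple[int, float]]:
    """WCSS for each k in ``k_min..k_max`` (default up to n_rois)."""
    if k_max is None:
        k_max = features.n_rois
    if not 1 <= k_min <= k_max <= features.n_rois:
        raise ValueError("need 1 <= k_min <= k_max <= n_rois")
    return [(k, kmeans_cluster(features, k, seed=seed, n_restarts=n_restarts).wcss)
            for k in range(k_min, k_max + 1)]


def suggest_k(curve: list[tuple[int, float]]) -> int:
    """Knee of the WCSS curve: the k farthest from the endpoint chord.

    Both axes are rescaled to [0, 1] before measuring perpendicular
    distance.  Advisory only; a flat or straight curve returns the smallest
    k with a warning.
    """
    if len(curve) < 3:
        raise ValueError("need at least 3 (k, wcss) points")
    ks = np.array([k for k, _ in curve], dtype=float)
    ws = np.array([w for _, w in curve], dtype=float)
    k_span = ks[-1] - ks[0]
    w_span = ws[0] - ws[-1]
    if w_span <= 0:
        warnings.warn("flat WCSS curve: no knee, returning k_min")
        return int(ks[0])
    x = (ks - ks[0]) / k_span
    y = (ws - ws[-1]) / w_span
    # distance from (x, y) to the chord joining (0, 1) and (1, 0)
    dist = np.abs(x + y - 1) / np.sqrt(2)
    if dist.max() < 1e-9:
        warnings.warn("straight-line WCSS curve: no knee, returning k_min")
        return int(ks[0])
    return int(ks[int(np.argmax(dist))])


def recompute_wcss(features: FeatureMatrix, labels: np.ndarray) -> float:
    """WCSS implied by a labelling; checks stored values independently."""
    total = 0.0
    for lab in np.unique(labels):
        pts = features.data[labels == lab]
        total += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return total
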