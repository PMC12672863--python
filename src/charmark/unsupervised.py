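"""Unsupervised structure in stationary-feature space.

k-means with silhouette-based selection of k probes whether diagnostic
groups emerge without labels; a 2-D PCA projection of the centered (but not
variance-scaled — the features share a common probability scale on the
simplex) stationary vectors gives the standard visual summary; and rolling
mean/SD traces of a single feature (typically the space probability) expose
group differences in both level and variability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .markov import FeatureMatrix


class UnsupervisedError(ValueError):
    pass


@dataclass
class ClusteringResult:
    k: int
    assignments: np.ndarray
    silhouette: float
    label_agreement: float | None
    silhouette_by_k: dict[int, float]


@dataclass
class PCAProjection:
    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray


def _label_agreement(assignments: np.ndarray, groups: list[str]) -> float | None:
    """Best accuracy over cluster-to-group matchings (Hungarian assignment)."""
    labels = sorted(set(groups))
    if "unknown" in labels or len(labels) < 2:
        return None
    y = np.asarray([labels.index(g) for g in groups])
    k = int(assignments.max()) + 1
    n_lab = len(labels)
    conf = np.zeros((k, n_lab))
    for c, g in zip(assignments, y):
        conf[c, g] += 1
    rows, cols = linear_sum_assignment(-conf)
    return float(conf[rows, cols].sum() / len(groups))


def cluster_kmeans(
    fm: FeatureMatrix,
    k_range=range(2, 7),
    seed: int = 0,
    n_init: int = 10,
) -> ClusteringResult:
    """k-means at each k in ``k_range``; return the silhouette-optimal fit.

    Ties in mean silhouette go to the smaller k. If the true group labels
    are known, the result carries the best cluster/label agreement.
    """
    X = fm.values
    k_range = sorted(k_range)
    if not k_range or k_range[0] < 2 or k_range[-1] > X.shape[0] - 1:
        raise UnsupervisedError(
            f"k_range {list(k_range)} must lie within [2, rows-1={X.shape[0] - 1}]"
        )
    if np.all(np.ptp(X, axis=0) == 0):
        raise UnsupervisedError("all rows identical; silhouette undefined")
    best: tuple[float, int, np.ndarray] | None = None
    by_k: dict[int, float] = {}
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        assignments = km.fit_predict(X)
        sil = float(silhouette_score(X, assignments))
        by_k[k] = sil
        if best is None or sil > best[0] + 1e-12:
            best = (sil, k, assignments)
    sil, k, assignments = best
    return ClusteringResult(
        k=k,
        assignments=assignments,
        silhouette=sil,
        label_agreement=_label_agreement(assignments, fm.row_groups),
        silhouette_by_k=by_k,
    )


def pca_project(fm: FeatureMatrix, n_components: int = 2) -> PCAProjection:
    """Top principal components of the mean-centered feature matrix.

    Sign convention: each component is oriented so its largest-magnitude
    loading is positive, making projections deterministic across runs.
    """
    X = fm.values
    if X.shape[0] < 3:
        raise UnsupervisedError("PCA needs at least 3 rows")
    centered = X - X.mean(axis=0)
    if np.linalg.matrix_rank(centered) < n_components:
        raise UnsupervisedError(
            f"centered data has rank < {n_components}; projection degenerate"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T.copy()
    for j in range(n_components):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return PCAProjection(
        scores=scores,
        loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
    )


def rolling_stats(values, window: int = 25) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window mean and sample SD (ddof=1) of a feature series.

    Output length is len(values) - window + 1.
    """
    values = np.asarray(values, dtype=float)
    if window < 2 or window > values.size:
        raise UnsupervisedError(
            f"window {window} out of range [2, {values.size}]"
        )
    sw = np.lib.stride_tricks.sliding_window_view(values, window)
    return sw.mean(axis=1), sw.std(axis=1, ddof=1)
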