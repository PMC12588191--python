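"""K-Means microstate clustering with principled k-selection and validation.

The cluster count is chosen by scanning k and combining two standard
diagnostics: the elbow of the inertia curve (maximum second difference) and
the mean silhouette score (the deciding vote when the two disagree).  DBSCAN
and Ward-linkage agglomerative clustering serve as baselines on the same
embedding.  Internal validity is reported as Silhouette, Davies-Bouldin, and
Calinski-Harabasz scores, before and after removal of undersized ("noise")
clusters — members of removed clusters are relabeled -1 and kept in the
output, never silently dropped.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as skmetrics
from sklearn.cluster import DBSCAN, AgglomerativeClustering, KMeans
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "ClusterResult",
    "ValidationReport",
    "kmeans",
    "silhouette",
    "davies_bouldin",
    "calinski_harabasz",
    "validate",
    "elbow_from_curve",
    "select_k",
    "dbscan_baseline",
    "ward_baseline",
    "noise_filter",
    "method_comparison",
]


@dataclass
class ClusterResult:
    """Cluster labels (-1 marks filtered/noise points) plus fit metadata."""

    labels: np.ndarray
    k: int
    centroids: np.ndarray | None
    inertia: float
    method: str
    seed: int | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        valid = self.labels[self.labels >= 0]
        if valid.size and valid.max() >= self.k:
            raise ValueError(
                f"label {valid.max()} out of range for k={self.k}"
            )
        if self.inertia < 0:
            raise ValueError("inertia must be non-negative")

    def cluster_sizes(self) -> dict[int, int]:
        labels, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(map(int, labels), map(int, counts)))


@dataclass
class ValidationReport:
    """Internal validity metrics and cluster sizes at one pipeline stage."""

    silhouette: float
    davies_bouldin: float
    calinski_harabasz: float
    cluster_sizes: dict[int, int] = field(default_factory=dict)
    stage: str = "pre_filter"


def kmeans(
    E: np.ndarray, k: int, seed: int = 42, n_init: int = 10
) -> ClusterResult:
    """Lloyd's algorithm from k-means++ starts, best of ``n_init`` by inertia."""
    E = np.asarray(E, dtype=float)
    n = E.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}], got {k}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
    labels = km.fit_predict(E)
    return ClusterResult(
        labels=labels,
        k=k,
        centroids=km.cluster_centers_,
        inertia=float(km.inertia_),
        method="kmeans",
        seed=seed,
    )


def _check_multi_cluster(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ValueError("need at least 2 clusters")
    return labels


def silhouette(E: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette score (b-a)/max(a,b) over points; singletons score 0."""
    labels = _check_multi_cluster(labels)
    return float(skmetrics.silhouette_score(np.asarray(E, dtype=float), labels))


def davies_bouldin(E: np.ndarray, labels: np.ndarray) -> float:
    """Davies-Bouldin index (lower is better).

    Raises when two cluster centroids coincide (the pairwise separation term
    degenerates to zero).
    """
    labels = _check_multi_cluster(labels)
    E = np.asarray(E, dtype=float)
    cents = np.array([E[labels == c].mean(axis=0) for c in np.unique(labels)])
    d = np.linalg.norm(cents[:, None] - cents[None, :], axis=-1)
    if np.any(d[~np.eye(len(cents), dtype=bool)] == 0):
        raise ValueError("coincident cluster centroids: Davies-Bouldin undefined")
    return float(skmetrics.davies_bouldin_score(E, labels))


def calinski_harabasz(E: np.ndarray, labels: np.ndarray) -> float:
    """Calinski-Harabasz score [B/(k-1)]/[W/(n-k)] (higher is better).

    Returns ``inf`` when the within-cluster scatter W is exactly zero.
    """
    labels = _check_multi_cluster(labels)
    E = np.asarray(E, dtype=float)
    n = E.shape[0]
    uniq = np.unique(labels)
    k = uniq.size
    if k >= n:
        raise ValueError("Calinski-Harabasz needs k < n")
    W = sum(
        float(((E[labels == c] - E[labels == c].mean(axis=0)) ** 2).sum())
        for c in uniq
    )
    if W == 0:
        return float("inf")
    return float(skmetrics.calinski_harabasz_score(E, labels))


def validate(
    E: np.ndarray, labels: np.ndarray, stage: str = "pre_filter"
) -> ValidationReport:
    """All three validity metrics on the points with non-negative labels."""
    labels = np.asarray(labels, dtype=int)
    keep = labels >= 0
    E_kept = np.asarray(E, dtype=float)[keep]
    kept_labels = labels[keep]
    sizes_all, counts_all = np.unique(labels, return_counts=True)
    return ValidationReport(
        silhouette=silhouette(E_kept, kept_labels),
        davies_bouldin=davies_bouldin(E_kept, kept_labels),
        calinski_harabasz=calinski_harabasz(E_kept, kept_labels),
        cluster_sizes=dict(zip(map(int, sizes_all), map(int, counts_all))),
        stage=stage,
    )


def elbow_from_curve(
    ks: np.ndarray,
    inertias: np.ndarray,
    k_min: int | None = None,
    k_max: int | None = None,
) -> tuple[int, dict[int, float]]:
    """Elbow of an inertia-vs-k curve: interior k with maximum second difference.

    The curve must be non-increasing (up to numerical noise); ties resolve to
    the smallest k.  Returns the elbow k and the per-k curvature values.
    """
    ks = np.asarray(ks, dtype=int)
    inertias = np.asarray(inertias, dtype=float)
    if np.any(np.diff(inertias) > 1e-9 * max(inertias[0], 1.0)):
        raise ValueError("degenerate inertia curve: inertia increased with k")
    lo = ks[1] if k_min is None else max(k_min, int(ks[1]))
    hi = ks[-2] if k_max is None else min(k_max, int(ks[-2]))
    curvature = {
        int(ks[i]): (inertias[i - 1] - inertias[i]) - (inertias[i] - inertias[i + 1])
        for i in range(1, len(ks) - 1)
        if lo <= ks[i] <= hi
    }
    if not curvature:
        raise ValueError("inertia curve too short for an elbow")
    elbow_k = max(curvature, key=lambda k: (curvature[k], -k))
    return elbow_k, curvature


def select_k(
    E: np.ndarray,
    k_min: int = 2,
    k_max: int = 10,
    seed: int = 42,
    n_init: int = 10,
) -> tuple[int, int, int, dict]:
    """Choose the cluster count by elbow and silhouette scans over k.

    The elbow is the interior k maximizing the second difference of the
    inertia curve (computed from k=1 so k_min itself is eligible); the
    silhouette pick is the k maximizing mean silhouette, smallest k winning
    ties.  The returned k is the silhouette pick; a warning is logged when
    the two disagree.

    Returns ``(k, elbow_k, silhouette_k, diagnostics)`` with the inertia and
    silhouette curves in ``diagnostics``.
    """
    E = np.asarray(E, dtype=float)
    n = E.shape[0]
    if not 2 <= k_min <= k_max <= n - 1:
        raise ValueError(f"k range [{k_min}, {k_max}] invalid for n={n}")
    ks = np.arange(1, k_max + 1)
    fits = {int(k): kmeans(E, int(k), seed=seed, n_init=n_init) for k in ks}
    inertias = np.array([fits[int(k)].inertia for k in ks])
    elbow_k, curvature = elbow_from_curve(ks, inertias, k_min=k_min, k_max=k_max)

    sil = {k: silhouette(E, fits[k].labels) for k in range(k_min, k_max + 1)}
    best = max(sil.values())
    silhouette_k = min(k for k, s in sil.items() if s == best)

    if elbow_k != silhouette_k:
        warnings.warn(
            f"elbow suggests k={elbow_k} but silhouette suggests "
            f"k={silhouette_k}; using the silhouette choice",
            stacklevel=2,
        )
    diagnostics = {
        "k_scan": list(map(int, ks)),
        "inertia": inertias.tolist(),
        "silhouette": sil,
        "curvature": curvature,
    }
    return silhouette_k, elbow_k, silhouette_k, diagnostics


def dbscan_baseline(E: np.ndarray, min_samples: int = 5) -> ClusterResult:
    """DBSCAN with eps from the k-distance-curve knee (k = 2 x dimensionality)."""
    E = np.asarray(E, dtype=float)
    n = E.shape[0]
    if n < 10:
        raise ValueError("DBSCAN baseline needs at least 10 points")
    k = 2 * E.shape[1]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(E)
    dists, _ = nn.kneighbors(E)
    kd = np.sort(dists[:, -1])
    # knee of the sorted k-distance curve: point of maximum discrete curvature
    # (second difference) after light smoothing — the same bend criterion the
    # package uses for the inertia elbow
    w = max(3, n // 50)
    smooth = np.convolve(kd, np.ones(w) / w, mode="valid")
    if smooth.size >= 3:
        knee = int(np.argmax(np.diff(smooth, 2)) + 1 + w // 2)
    else:
        knee = n // 2
    eps = float(kd[min(knee, n - 1)])
    if eps <= 0:
        eps = float(np.median(kd))
    labels = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(E)
    n_clusters = int(labels.max()) + 1 if labels.max() >= 0 else 0
    if n_clusters == 0:
        raise ValueError(f"DBSCAN (eps={eps:.4g}) labeled every point as noise")
    inertia = sum(
        float(((E[labels == c] - E[labels == c].mean(axis=0)) ** 2).sum())
        for c in range(n_clusters)
    )
    return ClusterResult(
        labels=labels, k=n_clusters, centroids=None, inertia=inertia,
        method="dbscan",
    )


def ward_baseline(E: np.ndarray, k: int) -> ClusterResult:
    """Agglomerative clustering with Ward linkage, cut at k clusters."""
    E = np.asarray(E, dtype=float)
    if not 1 <= k <= E.shape[0]:
        raise ValueError(f"k must lie in [1, {E.shape[0]}], got {k}")
    labels = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(E)
    cents = np.array([E[labels == c].mean(axis=0) for c in range(k)])
    inertia = float(sum(((E[labels == c] - cents[c]) ** 2).sum() for c in range(k)))
    return ClusterResult(
        labels=labels, k=k, centroids=cents, inertia=inertia, method="ward"
    )


def noise_filter(
    E: np.ndarray, result: ClusterResult, min_size: int = 20
) -> tuple[ClusterResult, np.ndarray, ValidationReport, ValidationReport]:
    """Relabel clusters with fewer than ``min_size`` members as noise (-1).

    "Fewer than" is strict: clusters of exactly ``min_size`` survive.
    Surviving clusters are relabeled contiguously.  Returns the filtered
    result, a boolean removed-mask, and validity reports before and after.
    """
    E = np.asarray(E, dtype=float)
    labels = result.labels.copy()
    sizes = result.cluster_sizes()
    undersized = [c for c, s in sizes.items() if c >= 0 and s < min_size]
    survivors = sorted(c for c, s in sizes.items() if c >= 0 and s >= min_size)
    if not survivors:
        raise ValueError(f"every cluster has fewer than {min_size} points")
    pre_report = validate(E, labels, stage="pre_filter")

    removed = np.isin(labels, undersized)
    relabel = {old: new for new, old in enumerate(survivors)}
    new_labels = np.array(
        [relabel.get(c, -1) if not rm else -1 for c, rm in zip(labels, removed)],
        dtype=int,
    )
    filtered = ClusterResult(
        labels=new_labels,
        k=len(survivors),
        centroids=np.array([E[new_labels == c].mean(axis=0) for c in range(len(survivors))]),
        inertia=float(
            sum(
                ((E[new_labels == c] - E[new_labels == c].mean(axis=0)) ** 2).sum()
                for c in range(len(survivors))
            )
        ),
        method=result.method,
        seed=result.seed,
    )
    if len(survivors) >= 2:
        post_report = validate(E, new_labels, stage="post_filter")
    else:
        post_report = ValidationReport(
            silhouette=float("nan"),
            davies_bouldin=float("nan"),
            calinski_harabasz=float("nan"),
            cluster_sizes=filtered.cluster_sizes(),
            stage="post_filter",
        )
    return filtered, removed, pre_report, post_report


def method_comparison(
    E: np.ndarray, k: int, seed: int = 42
) -> "pd.DataFrame":
    """Side-by-side validity metrics for K-Means, DBSCAN, and Ward."""
    import pandas as pd

    rows = []
    for name, fit in (
        ("kmeans", lambda: kmeans(E, k, seed=seed)),
        ("dbscan", lambda: dbscan_baseline(E)),
        ("ward", lambda: ward_baseline(E, k)),
    ):
        res = fit()
        keep = res.labels >= 0
        rows.append(
            {
                "method": name,
                "k": res.k,
                "silhouette": silhouette(E[keep], res.labels[keep]),
                "davies_bouldin": davies_bouldin(E[keep], res.labels[keep]),
                "calinski_harabasz": calinski_harabasz(E[keep], res.labels[keep]),
            }
        )
    return pd.DataFrame(rows)
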