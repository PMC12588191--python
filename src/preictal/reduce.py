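"""Two-step dimensionality reduction: variance-thresholded PCA, then UMAP.

Features are column-standardized (zero mean, unit variance; zero-variance
columns dropped with a warning), projected onto the smallest number of
principal components whose cumulative explained variance reaches the
threshold (default 95 %), and finally embedded into two dimensions with
UMAP (n_neighbors=15, min_dist=0.1, Euclidean metric, fixed seed).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .types import FeatureMatrix

__all__ = ["ReductionResult", "fit_pca", "fit_embedding", "reduce_features"]


@dataclass
class ReductionResult:
    """PCA scores plus the 2-D embedding and the parameters that produced them."""

    pca_scores: np.ndarray
    n_components: int
    cumulative_variance: float
    explained_variance_ratio: np.ndarray
    embedding: np.ndarray | None
    n_neighbors: int
    min_dist: float
    metric: str
    seed: int
    dropped_columns: list[int]


def _standardize(X: np.ndarray) -> tuple[np.ndarray, list[int]]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    dropped = np.where(sd == 0)[0]
    if dropped.size:
        warnings.warn(
            f"dropping {dropped.size} zero-variance feature column(s)",
            stacklevel=3,
        )
    keep = sd > 0
    Z = (X[:, keep] - mean[keep]) / sd[keep]
    return Z, list(map(int, dropped))


def fit_pca(
    X: FeatureMatrix | np.ndarray, var_threshold: float = 0.95
) -> tuple[np.ndarray, int, float, np.ndarray, list[int]]:
    """Standardize columns and project onto the leading principal components.

    Returns ``(scores, n_components, cumulative_variance,
    explained_variance_ratio, dropped_columns)`` where ``n_components`` is
    the smallest p with cumulative explained variance >= ``var_threshold``
    and ``explained_variance_ratio`` covers the full decomposition.
    """
    from sklearn.decomposition import PCA

    values = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    if values.shape[0] < 2:
        raise ValueError("PCA needs at least 2 rows")
    if not 0 < var_threshold <= 1:
        raise ValueError("variance threshold must lie in (0, 1]")
    Z, dropped = _standardize(values)
    pca = PCA(n_components=None, svd_solver="full")
    scores_full = pca.fit_transform(Z)
    ratios = pca.explained_variance_ratio_
    cum = np.cumsum(ratios)
    p = int(np.searchsorted(cum, var_threshold) + 1)
    p = min(p, len(ratios))
    return scores_full[:, :p], p, float(cum[p - 1]), ratios, dropped


def fit_embedding(
    scores: np.ndarray,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    metric: str = "euclidean",
    seed: int = 42,
) -> np.ndarray:
    """2-D UMAP embedding; reproducible given ``seed``."""
    import umap

    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    if n <= n_neighbors:
        raise ValueError(
            f"n ({n}) must exceed n_neighbors ({n_neighbors}); "
            "use a smaller n_neighbors for small datasets"
        )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="n_jobs value")
        reducer = umap.UMAP(
            n_components=2,
            n_neighbors=n_neighbors,
            min_dist=min_dist,
            metric=metric,
            random_state=seed,
        )
        emb = reducer.fit_transform(scores)
    return np.asarray(emb, dtype=float)


def reduce_features(
    X: FeatureMatrix | np.ndarray,
    var_threshold: float = 0.95,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    metric: str = "euclidean",
    seed: int = 42,
    embed: bool = True,
) -> ReductionResult:
    """Run PCA then (optionally) UMAP and collect everything in one result."""
    scores, p, cum, ratios, dropped = fit_pca(X, var_threshold=var_threshold)
    embedding = (
        fit_embedding(
            scores, n_neighbors=n_neighbors, min_dist=min_dist,
            metric=metric, seed=seed,
        )
        if embed
        else None
    )
    return ReductionResult(
        pca_scores=scores,
        n_components=p,
        cumulative_variance=cum,
        explained_variance_ratio=ratios,
        embedding=embedding,
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        metric=metric,
        seed=seed,
        dropped_columns=dropped,
    )
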