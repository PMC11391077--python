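"""K-means clustering of cells on the (cover, height) plane.

An unsupervised alternative to threshold biomisation: bias-corrected
cells are grouped into bioclimatically similar regions using k-means on
fractional cover and vegetation height, and (for k = 4) labelled by
centroid ordering from tall dense forest down to sparse shrub/desert.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .grid import BioclimGrid, ConfigurationError, GridGeometry
from .scheme import BiomeMap

__all__ = ["ClusterModel", "fit_clusters", "name_clusters", "CLUSTER_LABELS_K4"]

#: Labels for the four-cluster decomposition, in decreasing
#: (height, cover) centroid order.
CLUSTER_LABELS_K4 = (
    "Tall Dense Forest",
    "Dense Forest/thicket",
    "Sparse savanna/grass",
    "Sparse shrub/desert",
)


@dataclass
class ClusterModel:
    """Fitted k-means partition of land cells in (FPC, height) space."""

    k: int
    centroids: np.ndarray  # (k, 2) in raw (FPC, height) units
    assignments: np.ndarray  # (n_lat, n_lon) int, -1 over masked cells
    geometry: GridGeometry
    seed: int
    scaling: str  # "zscore" or "raw"
    inertia: float
    scale_mean: np.ndarray | None = None
    scale_std: np.ndarray | None = None


def fit_clusters(
    grid: BioclimGrid,
    k: int = 4,
    seed: int = 0,
    scaling: str = "zscore",
    n_restarts: int = 25,
    max_iter: int = 300,
) -> ClusterModel:
    """Cluster land cells by (FPC, height) with seeded k-means.

    Each of FPC and height is z-scored before clustering by default —
    the two variables differ by two orders of magnitude in range — with
    ``scaling="raw"`` retained as an option.  ``n_restarts`` random
    initialisations are run and the best objective kept; a fixed seed
    makes the fit bit-reproducible.
    """
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    X_raw = np.column_stack(
        [grid.fields["fpc"][grid.mask], grid.fields["height"][grid.mask]]
    )
    n_distinct = np.unique(X_raw, axis=0).shape[0]
    if n_distinct < k:
        raise ConfigurationError(f"only {n_distinct} distinct (FPC, height) points for k={k}")

    if scaling == "zscore":
        mean = X_raw.mean(axis=0)
        std = X_raw.std(axis=0)
        std[std == 0] = 1.0
        X = (X_raw - mean) / std
    elif scaling == "raw":
        mean = std = None
        X = X_raw
    else:
        raise ConfigurationError(f"unknown scaling {scaling!r}")

    km = KMeans(
        n_clusters=k,
        n_init=n_restarts,
        max_iter=max_iter,
        random_state=int(seed) % (2**32),
        init="random",
    ).fit(X)

    centroids = km.cluster_centers_
    if scaling == "zscore":
        centroids = centroids * std + mean

    assignments = np.full(grid.geometry.shape, -1, dtype=np.int16)
    assignments[grid.mask] = km.labels_
    return ClusterModel(
        k=k,
        centroids=centroids,
        assignments=assignments,
        geometry=grid.geometry,
        seed=seed,
        scaling=scaling,
        inertia=float(km.inertia_),
        scale_mean=mean,
        scale_std=std,
    )


def name_clusters(model: ClusterModel) -> BiomeMap:
    """Label clusters by centroid ordering and return a categorical map.

    For k = 4 the centroids are ranked by the sum of their (FPC, height)
    ranks, descending: tallest/densest first ("Tall Dense Forest") down
    to "Sparse shrub/desert"; exact ties break by centroid index.  For
    any other k the labels fall back to generic "cluster-i".  The result
    behaves like a biome map and feeds fragmentation directly.
    """
    order = _centroid_order(model.centroids)
    if model.k == 4:
        labels = [CLUSTER_LABELS_K4[rank] for rank in _ranks(order)]
    else:
        labels = [f"cluster-{rank + 1}" for rank in _ranks(order)]

    # remap assignments so code i corresponds to labels sorted by rank
    sorted_labels = [labels[i] for i in order]
    remap = np.full(model.k, -1, dtype=np.int16)
    for new, old in enumerate(order):
        remap[old] = new
    codes = model.assignments.copy()
    land = codes >= 0
    codes[land] = remap[codes[land]]
    return BiomeMap(geometry=model.geometry, codes=codes, scheme_codes=sorted_labels)


def _centroid_order(centroids: np.ndarray) -> list[int]:
    """Centroid indices sorted from tall/dense to short/sparse."""
    k = centroids.shape[0]
    fpc_rank = np.argsort(np.argsort(-centroids[:, 0], kind="stable"), kind="stable")
    h_rank = np.argsort(np.argsort(-centroids[:, 1], kind="stable"), kind="stable")
    score = fpc_rank + h_rank
    return sorted(range(k), key=lambda i: (score[i], i))


def _ranks(order: list[int]) -> list[int]:
    ranks = [0] * len(order)
    for rank, idx in enumerate(order):
        ranks[idx] = rank
    return ranks
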