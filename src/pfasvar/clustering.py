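"""Exposure-state clustering of (z_PFCA, z_PFOS) variability scores.

K-means with silhouette-based selection of k. Cluster labels are
canonicalized (descending size, then lexicographic centroid) so outputs are
reproducible run to run, and colony x species composition tables summarise
the geographic structure of the exposure states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples, silhouette_score

from .errors import DegenerateDataError, ValidationError
from .ingest import BirdMeta

DEFAULT_K_RANGE = (2, 8)
DEFAULT_RESTARTS = 25


@dataclass
class ClusterModel:
    k: int
    centroids: np.ndarray  # k x 2, canonical order
    assignment: pd.Series  # bird_id -> cluster label (0..k-1)
    silhouette_overall: float
    silhouette_per_cluster: np.ndarray
    cluster_sizes: np.ndarray
    seed: int
    n_restarts: int


def _check_scores(scores: pd.DataFrame) -> np.ndarray:
    x = scores.to_numpy(dtype=float)
    if len(x) < 3:
        raise DegenerateDataError(f"need >= 3 points to cluster, got {len(x)}")
    if np.allclose(x, x[0]):
        raise DegenerateDataError("all points identical; clustering undefined")
    return x


def select_k(
    scores: pd.DataFrame,
    k_min: int = DEFAULT_K_RANGE[0],
    k_max: int = DEFAULT_K_RANGE[1],
    seed: int = 0,
    n_restarts: int = DEFAULT_RESTARTS,
) -> int:
    """The k in [k_min, k_max] maximizing mean Euclidean silhouette.

    Ties break toward the smaller k."""
    x = _check_scores(scores)
    if not (2 <= k_min <= k_max <= len(x) - 1):
        raise ValueError(f"need 2 <= k_min <= k_max <= n-1, got [{k_min}, {k_max}]")
    best_k, best_s = None, -np.inf
    for k in range(k_min, k_max + 1):
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(x)
        s = silhouette_score(x, km.labels_, metric="euclidean")
        if s > best_s:  # strict: ties keep the smaller k
            best_k, best_s = k, s
    return int(best_k)


def fit_clusters(
    scores: pd.DataFrame,
    k: int,
    seed: int = 0,
    n_restarts: int = DEFAULT_RESTARTS,
) -> ClusterModel:
    """K-means at fixed k with canonical labels and silhouette diagnostics."""
    x = _check_scores(scores)
    if k < 2:
        raise ValueError("k must be >= 2 (silhouette undefined for k = 1)")
    n_distinct = len(np.unique(x, axis=0))
    if k > n_distinct:
        raise DegenerateDataError(
            f"k = {k} exceeds the number of distinct points ({n_distinct})"
        )
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(x)
    labels = km.labels_

    # canonical order: descending size, then lexicographic centroid
    sizes = np.bincount(labels, minlength=k)
    order = sorted(
        range(k), key=lambda j: (-sizes[j], tuple(km.cluster_centers_[j]))
    )
    relabel = {old: new for new, old in enumerate(order)}
    labels = np.array([relabel[l] for l in labels])
    centroids = np.vstack([x[labels == j].mean(axis=0) for j in range(k)])
    sizes = np.bincount(labels, minlength=k)

    sil = silhouette_samples(x, labels, metric="euclidean")
    per_cluster = np.array([sil[labels == j].mean() for j in range(k)])
    return ClusterModel(
        k=k,
        centroids=centroids,
        assignment=pd.Series(labels, index=scores.index, name="cluster"),
        silhouette_overall=float(sil.mean()),
        silhouette_per_cluster=per_cluster,
        cluster_sizes=sizes,
        seed=seed,
        n_restarts=n_restarts,
    )


def cluster_composition(model: ClusterModel, meta: BirdMeta) -> pd.DataFrame:
    """Proportion of each (colony, species) group assigned to each cluster.

    Rows are (colony, species, cluster); proportions within a group sum to
    1. Groups with no scored birds are omitted."""
    missing = set(model.assignment.index) - set(meta.table.index)
    if missing:
        raise ValidationError(f"metadata missing for assigned bird(s): {sorted(missing)}")
    df = meta.table.loc[model.assignment.index].copy()
    df["cluster"] = model.assignment
    rows = []
    for (colony, species), grp in df.groupby(["colony", "species"], sort=True):
        counts = grp["cluster"].value_counts()
        for cluster in range(model.k):
            rows.append(
                dict(
                    colony=colony,
                    species=species,
                    cluster=cluster,
                    proportion=counts.get(cluster, 0) / len(grp),
                )
            )
    return pd.DataFrame(rows)


def kde_grid(
    scores: pd.DataFrame, gridsize: int = 101, pad: float = 0.25
) -> pd.DataFrame:
    """Gaussian KDE (Scott bandwidth) of the score cloud on a regular grid.

    Data product backing density contours; no styling."""
    x = scores.to_numpy(dtype=float).T
    kde = gaussian_kde(x, bw_method="scott")
    gx = np.linspace(x[0].min() - pad, x[0].max() + pad, gridsize)
    gy = np.linspace(x[1].min() - pad, x[1].max() + pad, gridsize)
    xx, yy = np.meshgrid(gx, gy)
    dens = kde(np.vstack([xx.ravel(), yy.ravel()]))
    return pd.DataFrame(
        {"z_pfca": xx.ravel(), "z_pfos": yy.ravel(), "density": dens}
    )
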