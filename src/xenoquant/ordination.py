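"""Sample-level descriptive views: PCA scores and Pearson clustering.

Both operate on a protein × sample abundance matrix (log-transformed
upstream). PCA treats samples as observations; scores are deterministic
up to sign, fixed here by making each component's largest-magnitude
protein loading positive. Clustering is agglomerative with distance
1 − Pearson correlation between samples and average linkage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist


def pca_coordinates(matrix: pd.DataFrame, n_components: int = 2) -> pd.DataFrame:
    """Principal-component scores of the samples (columns) of ``matrix``.

    The input is row-centred (each protein centred across samples)
    before decomposition, so a pre-centred matrix passes through
    unchanged. Components are ordered by explained variance; if more
    components are requested than the data supports, the count is
    reduced with a warning. Returns a DataFrame indexed by sample with
    columns ``PC1``, ``PC2``, ...
    """
    if matrix.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples")
    X = matrix.to_numpy(dtype=float).T  # samples x proteins
    X = X - X.mean(axis=0, keepdims=True)
    max_rank = max(min(X.shape[0] - 1, X.shape[1]), 1)
    if n_components > max_rank:
        warnings.warn(
            f"requested {n_components} components but rank is at most "
            f"{max_rank}; reducing",
            stacklevel=2,
        )
        n_components = max_rank
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    scores = u[:, :n_components] * s[:n_components]
    loadings = vt[:n_components]
    # deterministic sign: largest-|loading| entry of each component positive
    for k in range(n_components):
        j = int(np.argmax(np.abs(loadings[k])))
        if loadings[k, j] < 0:
            scores[:, k] *= -1.0
    return pd.DataFrame(
        scores,
        index=list(matrix.columns),
        columns=[f"PC{k + 1}" for k in range(n_components)],
    )


@dataclass
class Dendrogram:
    """Agglomerative clustering of samples under Pearson distance."""

    linkage: np.ndarray  # scipy linkage matrix
    labels: list[str]

    def merge_heights(self) -> list[float]:
        return [float(h) for h in self.linkage[:, 2]]

    def leaves_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.linkage)
        return [self.labels[i] for i in order]

    def cut(self, n_clusters: int) -> dict[str, int]:
        assign = hierarchy.fcluster(
            self.linkage, t=n_clusters, criterion="maxclust"
        )
        return dict(zip(self.labels, (int(a) for a in assign)))


def pearson_cluster(matrix: pd.DataFrame) -> Dendrogram:
    """Average-linkage clustering of samples, distance 1 − Pearson r.

    A sample with zero variance has no defined correlation and is an
    error, named explicitly. Tie handling is scipy's deterministic
    input-order behaviour.
    """
    if matrix.shape[1] < 2:
        raise ValueError("clustering needs at least 2 samples")
    X = matrix.to_numpy(dtype=float).T  # samples x proteins
    flat = [
        str(c)
        for c, v in zip(matrix.columns, X.var(axis=1))
        if not v > 0
    ]
    if flat:
        raise ValueError(f"zero-variance sample(s): {flat}")
    dist = pdist(X, metric="correlation")
    linkage = hierarchy.linkage(dist, method="average")
    return Dendrogram(linkage=linkage, labels=[str(c) for c in matrix.columns])
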