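"""Seed clusterings for the refinement pathway.

The refinement ILP starts from a hard clustering W of the experiments
produced by *any* standard method — the choice is user-facing configuration,
not merely an initialization, because the refinement finds the nearest
rectangular partition to whatever structure the seed encodes.  This module
wires three standard methods (agglomerative with average linkage on the
cosine distance, spectral clustering on the similarity graph, k-means on
the rows of the similarity matrix) into the assignment-tensor format, and
externally produced partitions can be supplied through the same CSV schema.
"""

from __future__ import annotations

import numpy as np
from sklearn.cluster import AgglomerativeClustering, KMeans, SpectralClustering

from .rect_partition import labels_to_w
from .tensor_core import SimilarityMatrix, TensorError

METHODS = ("agglomerative-average", "spectral", "kmeans-on-rows")


def cluster_flat(
    S_mat: SimilarityMatrix,
    grid_shape: tuple[int, int],
    m: int,
    method: str = "agglomerative-average",
    seed: int = 0,
) -> np.ndarray:
    """Hard-cluster the N1 experiments into <= m groups; returns W (n1, n2, m).

    Deterministic given the seed (the default agglomerative method is
    seed-free).  The flat experiment order must be the row-major enumeration
    of the grid, as produced by the flattening convention.
    """
    n1, n2 = grid_shape
    if S_mat.n != n1 * n2:
        raise TensorError(
            f"similarity matrix has {S_mat.n} experiments, grid wants {n1 * n2}"
        )
    if not 1 <= m <= S_mat.n:
        raise TensorError(f"m={m} out of range 1..{S_mat.n}")
    if m == 1:
        labels = np.zeros(S_mat.n, dtype=int)
    elif method == "agglomerative-average":
        dist = np.clip(1.0 - S_mat.values, 0.0, None)
        np.fill_diagonal(dist, 0.0)
        labels = AgglomerativeClustering(
            n_clusters=m, metric="precomputed", linkage="average"
        ).fit_predict(dist)
    elif method == "spectral":
        aff = np.clip(S_mat.values, 0.0, None)
        labels = SpectralClustering(
            n_clusters=m, affinity="precomputed", random_state=seed,
            assign_labels="discretize",
        ).fit_predict(aff)
    elif method == "kmeans-on-rows":
        labels = KMeans(n_clusters=m, random_state=seed, n_init=10).fit_predict(
            S_mat.values
        )
    else:
        raise TensorError(f"unknown clustering method {method!r}; use one of {METHODS}")
    return labels_to_w(np.asarray(labels, dtype=int).reshape(n1, n2), m)
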