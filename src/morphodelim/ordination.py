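"""Ordination baselines: PCA and non-metric MDS, with k-means on the first two dimensions.

These are the visualization-first methods morphometric studies traditionally
rely on.  PCA is computed on the covariance matrix of the mean-centred data;
nMDS minimizes Kruskal stress-1 over configurations whose distances are fit
to the Gower dissimilarities by monotone (isotonic) regression.  Clustering
the first two ordination axes with k-means gives the comparison arm against
spectral clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.manifold import MDS

from .io import CharacterMatrix
from .spectral import ClusterAssignment, kmeans_partition

__all__ = ["OrdinationResult", "DistanceMatrix", "pca", "gower_distance", "nmds", "ordination_kmeans"]


@dataclass
class OrdinationResult:
    """Low-dimensional coordinates from an ordination, with its fit diagnostics."""

    coordinates: np.ndarray
    method: str
    explained_variance_fraction: np.ndarray | None = None  # PCA only
    stress: float | None = None  # nMDS only (Kruskal stress-1)


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative pairwise dissimilarities with zero diagonal."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(v < 0):
            raise ValueError("distances must be nonnegative")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have zero diagonal")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


def pca(matrix: CharacterMatrix, n_components: int) -> OrdinationResult:
    """PCA on the covariance matrix of the mean-centred character data.

    Components are ordered by descending covariance eigenvalue; the explained
    variance fraction of each returned component is reported relative to the
    total variance, so the fractions over all d components sum to 1.
    """
    if n_components > matrix.n_characters:
        raise ValueError(
            f"n_components={n_components} exceeds the {matrix.n_characters} characters"
        )
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(matrix.values)
    return OrdinationResult(
        coordinates=scores,
        method="pca",
        explained_variance_fraction=model.explained_variance_ratio_.copy(),
    )


def gower_distance(matrix: CharacterMatrix) -> DistanceMatrix:
    """Continuous-variable Gower dissimilarity: mean over characters of |diff| / range."""
    X = matrix.values
    ranges = np.ptp(X, axis=0)
    if np.any(ranges == 0):
        name = matrix.character_names[int(np.argwhere(ranges == 0)[0][0])]
        raise ValueError(f"character {name!r} has zero range; Gower distance undefined")
    scaled = X / ranges
    D = np.zeros((X.shape[0], X.shape[0]))
    for j in range(scaled.shape[1]):
        D += np.abs(scaled[:, j][:, None] - scaled[:, j][None, :])
    D /= scaled.shape[1]
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(values=(D + D.T) / 2.0)


def nmds(
    distances: DistanceMatrix,
    dims: int = 2,
    n_starts: int = 20,
    max_iter: int = 300,
    seed: int = 0,
) -> OrdinationResult:
    """Non-metric MDS by iterative Kruskal stress-1 minimization.

    SMACOF majorization with isotonic regression of configuration distances
    on the dissimilarity ranks; the best of ``n_starts`` seeded random starts
    is kept and the configuration is centred.  Stress below 0.2 is the
    conventional threshold for an acceptable 2-D representation.
    """
    if dims >= distances.n:
        raise ValueError(f"dims={dims} must be smaller than N={distances.n}")
    model = MDS(
        n_components=dims,
        metric=False,
        dissimilarity="precomputed",
        n_init=n_starts,
        max_iter=max_iter,
        random_state=int(seed) % (2**31),
        normalized_stress=True,
        eps=1e-9,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coords = model.fit_transform(distances.values)
    coords = coords - coords.mean(axis=0)
    return OrdinationResult(coordinates=coords, method="nmds", stress=float(model.stress_))


def ordination_kmeans(
    result: OrdinationResult,
    K: int = 10,
    restarts: int = 100,
    seed: int = 0,
) -> ClusterAssignment:
    """k-means on the first two ordination dimensions (the traditional comparison design)."""
    if result.coordinates.shape[1] < 2:
        raise ValueError("ordination must have at least 2 dimensions")
    return kmeans_partition(result.coordinates[:, :2], K, restarts=restarts, seed=seed)
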