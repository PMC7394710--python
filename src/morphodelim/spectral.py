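"""Spectral clustering of standardized character matrices.

The engine follows the normalized-symmetric-Laplacian variant of spectral
clustering: pairwise similarities from an RBF kernel, the Laplacian
L = I - D^{-1/2} S D^{-1/2}, an embedding from the eigenvectors of the K
smallest eigenvalues (rows renormalized to the unit sphere), and a k-means
partition of the embedded points, keeping the best of many seeded restarts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

from .io import CharacterMatrix

logger = logging.getLogger("morphodelim")

__all__ = [
    "KernelConfig",
    "SimilarityMatrix",
    "LaplacianBundle",
    "SpectralEmbedding",
    "ClusterAssignment",
    "rbf_similarity",
    "normalized_laplacian",
    "laplacian_spectrum",
    "spectral_embed",
    "embed_from_spectrum",
    "kmeans_partition",
    "spectral_cluster",
    "canonicalize_labels",
]

# exponent scale for the RBF kernel: the kernel is exp(-gamma * ||xi-xj||^2 * s)
# with s = 1/d ("divide", default), d ("multiply") or 1 ("none"); d = number of
# characters.  Dividing by d keeps the useful gamma range roughly [0.05, 1] for
# standardized characters regardless of how many characters were measured.
ExponentScale = Literal["divide", "multiply", "none"]


@dataclass(frozen=True)
class KernelConfig:
    """RBF kernel settings: gamma > 0 and how the exponent scales with dimension d."""

    gamma: float
    exponent_scale: ExponentScale = "divide"

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")
        if self.exponent_scale not in ("divide", "multiply", "none"):
            raise ValueError(f"unknown exponent_scale {self.exponent_scale!r}")

    def scale(self, d: int) -> float:
        if self.exponent_scale == "divide":
            return 1.0 / d
        if self.exponent_scale == "multiply":
            return float(d)
        return 1.0


@dataclass
class SimilarityMatrix:
    """Symmetric N x N RBF affinities in (0, 1] with unit diagonal."""

    values: np.ndarray
    gamma: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-12):
            raise ValueError("similarity matrix must have unit diagonal")
        # RBF affinities are strictly positive; zeros are tolerated so hand-built
        # block-diagonal graphs remain valid inputs (isolated vertices are caught
        # later by the zero-degree guard in normalized_laplacian).
        if np.any(v < 0) or np.any(v > 1 + 1e-12):
            raise ValueError("similarity entries must lie in [0, 1]")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class LaplacianBundle:
    """Normalized symmetric graph Laplacian L = I - D^{-1/2} S D^{-1/2} and degrees D_ii."""

    laplacian: np.ndarray
    degrees: np.ndarray


@dataclass
class SpectralEmbedding:
    """Rows of the K leading (smallest-eigenvalue) Laplacian eigenvectors.

    ``coordinates`` are the row-renormalized embedding used by k-means;
    ``eigenvectors`` the raw eigenvector columns (ascending eigenvalue), which
    character–eigenvector correlation works on.
    """

    coordinates: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray


@dataclass
class ClusterAssignment:
    """A k-means partition of the spectral embedding, canonicalized by first occurrence."""

    labels: np.ndarray
    K: int
    gamma: float | None
    kmeans_objective: float
    seed: int
    individual_ids: list[str] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.min(initial=0) < 0 or self.labels.max(initial=0) >= self.K:
            raise ValueError("labels must lie in [0, K)")

    def to_frame(self) -> pd.DataFrame:
        ids = self.individual_ids or [str(i) for i in range(len(self.labels))]
        return pd.DataFrame({"individual_id": ids, "cluster": self.labels})


def rbf_similarity(matrix: CharacterMatrix | np.ndarray, config: KernelConfig) -> SimilarityMatrix:
    """Pairwise RBF similarities S_ij = exp(-gamma * ||x_i - x_j||^2 * scale(d)).

    Expects standardized characters; warns if any column mean exceeds 1e-6.
    Larger gamma sharpens the kernel: off-diagonal similarities between
    distinct individuals shrink strictly.
    """
    X = matrix.values if isinstance(matrix, CharacterMatrix) else np.asarray(matrix, dtype=float)
    if np.any(np.abs(X.mean(axis=0)) > 1e-6):
        warnings.warn("input does not look standardized (column mean > 1e-6)", stacklevel=2)
    d = X.shape[1]
    sq = squareform(pdist(X, metric="sqeuclidean"))
    S = np.exp(-config.gamma * config.scale(d) * sq)
    np.fill_diagonal(S, 1.0)
    S = (S + S.T) / 2.0
    return SimilarityMatrix(values=S, gamma=config.gamma)


def normalized_laplacian(similarity: SimilarityMatrix) -> LaplacianBundle:
    """L = I - D^{-1/2} S D^{-1/2}, D_ii = row sums of S; eigenvalues lie in [0, 2]."""
    S = similarity.values
    deg = S.sum(axis=1)
    if np.any(deg <= 0):
        raise ValueError("zero degree encountered; similarity graph has an isolated vertex")
    inv_sqrt = 1.0 / np.sqrt(deg)
    L = np.eye(S.shape[0]) - (inv_sqrt[:, None] * S) * inv_sqrt[None, :]
    L = (L + L.T) / 2.0
    return LaplacianBundle(laplacian=L, degrees=deg)


def laplacian_spectrum(bundle: LaplacianBundle) -> tuple[np.ndarray, np.ndarray]:
    """Full symmetric eigendecomposition of L, eigenvalues ascending."""
    w, V = linalg.eigh(bundle.laplacian)
    return w, V


def embed_from_spectrum(w: np.ndarray, V: np.ndarray, K: int) -> SpectralEmbedding:
    """Build the K-dimensional embedding from a precomputed spectrum.

    Rows are renormalized to unit Euclidean norm (Ng–Jordan–Weiss); an
    all-zero row is left as zero with a warning.
    """
    n = V.shape[0]
    if not (1 <= K <= n):
        raise ValueError(f"K must be in [1, {n}], got {K}")
    U = V[:, :K].copy()
    norms = np.linalg.norm(U, axis=1)
    zero = norms < 1e-300
    if np.any(zero):
        warnings.warn(f"{int(zero.sum())} zero rows in spectral embedding left unnormalized", stacklevel=2)
        norms[zero] = 1.0
    return SpectralEmbedding(coordinates=U / norms[:, None], eigenvalues=w[:K].copy(), eigenvectors=U)


def spectral_embed(bundle: LaplacianBundle, K: int) -> SpectralEmbedding:
    """Eigenvectors of the K smallest Laplacian eigenvalues, rows renormalized."""
    w, V = laplacian_spectrum(bundle)
    return embed_from_spectrum(w, V, K)


def canonicalize_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters by order of first occurrence, so equal partitions compare equal."""
    labels = np.asarray(labels)
    mapping: dict[int, int] = {}
    out = np.empty(len(labels), dtype=int)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[int(lab)] = len(mapping)
        out[i] = mapping[int(lab)]
    return out


def kmeans_partition(
    embedding: SpectralEmbedding | np.ndarray,
    K: int,
    restarts: int = 100,
    seed: int = 0,
) -> ClusterAssignment:
    """Best-of-``restarts`` k-means on the embedded points.

    Each restart uses greedy k-means++ seeding from a single seeded stream;
    the run with the lowest within-cluster sum of squares wins.  Deterministic
    given ``seed``.
    """
    coords = embedding.coordinates if isinstance(embedding, SpectralEmbedding) else np.asarray(embedding, dtype=float)
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    n_distinct = np.unique(coords, axis=0).shape[0]
    if K > n_distinct:
        raise ValueError(f"K={K} exceeds the {n_distinct} distinct embedding points")
    km = KMeans(n_clusters=K, init="k-means++", n_init=restarts, random_state=int(seed) % (2**31))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn may warn about duplicate points
        raw = km.fit_predict(coords)
    return ClusterAssignment(
        labels=canonicalize_labels(raw),
        K=K,
        gamma=None,
        kmeans_objective=float(km.inertia_),
        seed=int(seed),
    )


def spectral_cluster(
    matrix: CharacterMatrix,
    gamma: float,
    K: int,
    restarts: int = 100,
    seed: int = 0,
    exponent_scale: ExponentScale = "divide",
) -> ClusterAssignment:
    """Full spectral clustering of a standardized character matrix.

    Composition of :func:`rbf_similarity`, :func:`normalized_laplacian`,
    :func:`spectral_embed` and :func:`kmeans_partition`; records the
    (gamma, K, seed) provenance and the winning k-means objective.
    """
    sim = rbf_similarity(matrix, KernelConfig(gamma=gamma, exponent_scale=exponent_scale))
    bundle = normalized_laplacian(sim)
    emb = spectral_embed(bundle, K)
    assignment = kmeans_partition(emb, K, restarts=restarts, seed=seed)
    assignment.gamma = gamma
    assignment.individual_ids = list(matrix.individual_ids)
    return assignment
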