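"""Cluster-defining character analysis.

Three complementary procedures identify which morphological characters drive
the discovered clusters:

1. mutual information between each character and the cluster assignment —
   a high score means the character carries information about cluster identity;
2. Pearson correlation between each character and each Laplacian eigenvector
   used in the embedding — a strong correlation of either sign means the
   character aligns with an axis of cluster formation;
3. a Welch two-sample t-test of each character's values inside a cluster
   against all individuals outside it — a significant difference marks the
   character as diagnostic for that cluster.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.feature_selection import mutual_info_classif
from sklearn.metrics import mutual_info_score
from statsmodels.stats.multitest import multipletests

from .io import CharacterMatrix
from .spectral import ClusterAssignment, SpectralEmbedding

logger = logging.getLogger("morphodelim")

__all__ = [
    "MIEstimatorConfig",
    "mi_character_cluster",
    "eigenvector_correlation",
    "cluster_vs_rest_ttest",
]


@dataclass(frozen=True)
class MIEstimatorConfig:
    """Mutual-information estimator settings for continuous characters vs discrete clusters.

    ``knn`` is the Kraskov-family nearest-neighbor estimator (k neighbors,
    seeded noise-jitter); ``histogram`` discretizes each character into
    ceil(sqrt(N)) equal-frequency bins and computes plug-in contingency MI —
    a coarse but independent cross-check.
    """

    method: Literal["knn", "histogram"] = "knn"
    n_neighbors: int = 3
    seed: int = 0
    n_bins: int | None = None


def mi_character_cluster(
    matrix: CharacterMatrix,
    assignment: ClusterAssignment,
    config: MIEstimatorConfig = MIEstimatorConfig(),
) -> pd.DataFrame:
    """Mutual information (nats) of every character with the cluster assignment.

    Returns a table with columns (character, mi, rank) sorted by descending
    score; negative estimator output is clipped to zero and flagged in the
    ``clipped`` column.  Undefined for a single occupied cluster.
    """
    labels = np.asarray(assignment.labels)
    if len(labels) != matrix.n_individuals:
        raise ValueError("assignment does not cover the matrix's individuals")
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 occupied clusters for character MI")
    if config.method == "knn":
        raw = mutual_info_classif(
            matrix.values,
            labels,
            discrete_features=False,
            n_neighbors=config.n_neighbors,
            random_state=config.seed % (2**31),
        )
    elif config.method == "histogram":
        n_bins = config.n_bins or math.ceil(math.sqrt(matrix.n_individuals))
        raw = np.array(
            [
                mutual_info_score(pd.qcut(col, q=n_bins, duplicates="drop").codes, labels)
                for col in matrix.values.T
            ]
        )
    else:
        raise ValueError(f"unknown MI estimator {config.method!r}")
    clipped = raw < 0
    scores = np.where(clipped, 0.0, raw)
    # a constant character carries no information by definition; the k-NN
    # estimator's tie-breaking jitter would otherwise report spurious MI
    scores = np.where(np.ptp(matrix.values, axis=0) == 0, 0.0, scores)
    df = pd.DataFrame({"character": matrix.character_names, "mi": scores, "clipped": clipped})
    df = df.sort_values("mi", ascending=False, kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def eigenvector_correlation(
    matrix: CharacterMatrix,
    embedding: SpectralEmbedding,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson r and two-sided p for every character x Laplacian-eigenvector pair.

    Eigenvectors are taken raw (before row renormalization) and ordered by
    ascending eigenvalue, i.e. decreasing importance for cluster formation.
    Pairs with p > ``alpha`` get ``significant=False`` so displays can
    suppress them; an r undefined because of a zero-variance column is
    recorded as missing with a reason.
    """
    V = embedding.eigenvectors
    if V.shape[0] != matrix.n_individuals:
        raise ValueError("embedding does not match the matrix's individuals")
    rows = []
    for ci, char in enumerate(matrix.character_names):
        x = matrix.values[:, ci]
        for ei in range(V.shape[1]):
            y = V[:, ei]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rows.append(
                    {"character": char, "eigenvector": ei + 1, "r": np.nan, "p_value": np.nan,
                     "significant": False, "note": "zero variance"}
                )
                continue
            r, p = stats.pearsonr(x, y)
            rows.append(
                {"character": char, "eigenvector": ei + 1, "r": float(r), "p_value": float(p),
                 "significant": bool(p <= alpha), "note": ""}
            )
    return pd.DataFrame(rows, columns=["character", "eigenvector", "r", "p_value", "significant", "note"])


def cluster_vs_rest_ttest(
    matrix: CharacterMatrix,
    assignment: ClusterAssignment,
    adjust: Literal["none", "bh"] = "none",
) -> pd.DataFrame:
    """Welch t-test of each character inside each cluster vs all other individuals.

    Welch's unequal-variance form is used because cluster sizes are unbalanced
    by construction.  Clusters with fewer than 2 members (or fewer than 2
    non-members) are skipped with a logged reason.  Degenerate zero-variance
    cases do not crash: identical groups give t=0, p=1; zero-variance groups
    with different means are flagged as infinitely separated.  Optional
    Benjamini-Hochberg correction over all (character, cluster) p-values.
    """
    labels = np.asarray(assignment.labels)
    if len(labels) != matrix.n_individuals:
        raise ValueError("assignment does not cover the matrix's individuals")
    rows = []
    for cluster in np.unique(labels):
        inside = labels == cluster
        n_in, n_out = int(inside.sum()), int((~inside).sum())
        if n_in < 2 or n_out < 2:
            logger.info("skipping cluster %d in t-tests: %d members, %d non-members", cluster, n_in, n_out)
            continue
        for ci, char in enumerate(matrix.character_names):
            a = matrix.values[inside, ci]
            b = matrix.values[~inside, ci]
            mean_diff = float(a.mean() - b.mean())
            note = ""
            if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
                if mean_diff == 0:
                    t, p = 0.0, 1.0
                else:
                    t = math.copysign(math.inf, mean_diff)
                    p = 0.0
                    note = "degenerate: zero variance in both groups, unequal means"
            else:
                res = stats.ttest_ind(a, b, equal_var=False)
                t, p = float(res.statistic), float(res.pvalue)
            rows.append(
                {"character": char, "cluster": int(cluster), "t": t, "p_value": p,
                 "n_within": n_in, "n_outside": n_out, "mean_difference": mean_diff, "note": note}
            )
    df = pd.DataFrame(
        rows,
        columns=["character", "cluster", "t", "p_value", "n_within", "n_outside", "mean_difference", "note"],
    )
    if adjust == "bh" and len(df):
        df["p_adjusted"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    return df
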