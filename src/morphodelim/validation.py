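"""External cluster validation: agreement between discovered clusters and taxon labels.

Normalized mutual information (NMI) measures the shared information between
two partitions, normalized to [0, 1]; the Rand index counts pairwise
agreements, and its adjusted form corrects for chance agreement and ranges
over [-1, 1].  The adjusted Rand index is the headline pair-counting score
here: the plain Rand index cannot go negative, so a "Rand index from -1 to 1"
can only be the adjusted variant.  Both are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score, rand_score
from sklearn.metrics.cluster import contingency_matrix

__all__ = ["ValidationScores", "nmi", "rand_indices", "score_partitions", "validation_table"]

NMINormalization = Literal["arithmetic", "geometric", "max", "min"]


@dataclass
class ValidationScores:
    """NMI, plain Rand and adjusted Rand for one pair of partitions."""

    nmi: float
    rand: float
    adjusted_rand: float
    contingency: np.ndarray


def _check(labels_a: Sequence, labels_b: Sequence) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"partitions must be 1-D and of equal length, got {a.shape} vs {b.shape}")
    if len(a) < 2:
        raise ValueError("need at least 2 items")
    return a, b


def nmi(labels_a: Sequence, labels_b: Sequence, normalization: NMINormalization = "arithmetic") -> float:
    """Normalized mutual information between two partitions, in [0, 1].

    Mutual information of the label contingency distribution, normalized by
    the arithmetic mean of the two label entropies by default (geometric-mean,
    max and min normalizations available).  Symmetric, and invariant to
    relabeling of either partition.
    """
    a, b = _check(labels_a, labels_b)
    return float(normalized_mutual_info_score(a, b, average_method=normalization))


def rand_indices(labels_a: Sequence, labels_b: Sequence) -> tuple[float, float]:
    """(plain Rand, adjusted Rand) pair-counting agreement between two partitions."""
    a, b = _check(labels_a, labels_b)
    return float(rand_score(a, b)), float(adjusted_rand_score(a, b))


def score_partitions(
    labels_a: Sequence,
    labels_b: Sequence,
    normalization: NMINormalization = "arithmetic",
) -> ValidationScores:
    """All validation indices plus the label co-occurrence contingency table."""
    a, b = _check(labels_a, labels_b)
    r, ar = rand_indices(a, b)
    return ValidationScores(
        nmi=nmi(a, b, normalization=normalization),
        rand=r,
        adjusted_rand=ar,
        contingency=np.asarray(contingency_matrix(a, b)),
    )


def validation_table(assignments: dict, ground_truth: Sequence) -> pd.DataFrame:
    """Score every (gamma, K) assignment of a sweep against taxon labels."""
    rows = []
    for (gamma, K), assignment in sorted(assignments.items()):
        s = score_partitions(assignment.labels, ground_truth)
        rows.append(
            {"gamma": gamma, "K": K, "nmi": s.nmi, "rand": s.rand, "adjusted_rand": s.adjusted_rand}
        )
    return pd.DataFrame(rows, columns=["gamma", "K", "nmi", "rand", "adjusted_rand"])
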