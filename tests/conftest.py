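"""Shared fixtures and independent oracles for the test suite.

The validation-index oracles here deliberately avoid the code paths (and the
libraries) used by the package: they enumerate unordered item pairs and build
contingency tables by hand, so they can arbitrate the package's NMI/Rand
implementations.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from morphodelim.io import CharacterMatrix, center
from morphodelim.synthetic import SpeciesComplexConfig, generate

settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


# ---------------------------------------------------------------- oracles

def all_set_partitions(items: list) -> list[list[list]]:
    """Every set partition of ``items`` (Bell number many; 203 for 6 items)."""
    if not items:
        return [[]]
    first, rest = items[0], items[1:]
    out = []
    for partial in all_set_partitions(rest):
        for i in range(len(partial)):
            out.append(partial[:i] + [[first] + partial[i]] + partial[i + 1 :])
        out.append([[first]] + partial)
    return out


def partition_to_labels(partition: list[list], items: list) -> np.ndarray:
    lookup = {x: ci for ci, block in enumerate(partition) for x in block}
    return np.array([lookup[x] for x in items])


def pair_counts(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int, int]:
    """(n11, n10, n01, n00): unordered item pairs co-clustered in both / only a / only b / neither."""
    n11 = n10 = n01 = n00 = 0
    for i, j in itertools.combinations(range(len(a)), 2):
        sa, sb = a[i] == a[j], b[i] == b[j]
        if sa and sb:
            n11 += 1
        elif sa:
            n10 += 1
        elif sb:
            n01 += 1
        else:
            n00 += 1
    return n11, n10, n01, n00


def rand_oracle(a, b) -> float:
    n11, n10, n01, n00 = pair_counts(np.asarray(a), np.asarray(b))
    return (n11 + n00) / (n11 + n10 + n01 + n00)


def ari_oracle(a, b) -> float:
    """Adjusted Rand via the pair-counting chance-correction formula."""
    n11, n10, n01, n00 = pair_counts(np.asarray(a), np.asarray(b))
    num = 2.0 * (n11 * n00 - n10 * n01)
    den = (n11 + n10) * (n10 + n00) + (n11 + n01) * (n01 + n00)
    if den == 0:
        return 1.0 if (n10 == 0 and n01 == 0) else 0.0
    return num / den


def nmi_oracle(a, b) -> float:
    """NMI from a hand-built contingency table, arithmetic-mean normalization."""
    a, b = np.asarray(a), np.asarray(b)
    n = len(a)
    ua, ub = np.unique(a), np.unique(b)
    counts = np.zeros((len(ua), len(ub)))
    for i, va in enumerate(ua):
        for j, vb in enumerate(ub):
            counts[i, j] = np.sum((a == va) & (b == vb))
    pa, pb = counts.sum(1) / n, counts.sum(0) / n
    ha = -sum(p * math.log(p) for p in pa if p > 0)
    hb = -sum(p * math.log(p) for p in pb if p > 0)
    if ha == 0.0 and hb == 0.0:
        return 1.0
    mi = 0.0
    for i in range(len(ua)):
        for j in range(len(ub)):
            pij = counts[i, j] / n
            if pij > 0:
                mi += pij * math.log(pij / (pa[i] * pb[j]))
    return mi / ((ha + hb) / 2.0)


def welch_oracle(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Closed-form Welch t statistic and Welch–Satterthwaite df."""
    nx, ny = len(x), len(y)
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    se2 = vx / nx + vy / ny
    t = (np.mean(x) - np.mean(y)) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return t, df


# ---------------------------------------------------------------- fixtures

def planted_config(seed: int, **overrides) -> SpeciesComplexConfig:
    """Three well-separated taxa, 4 informative + 12 noise characters."""
    base = dict(
        n_taxa=3, per_taxon_range=(20, 20), n_characters=16, n_informative=4,
        centroid_separation=8.0, seed=seed,
    )
    base.update(overrides)
    return SpeciesComplexConfig(**base)


def planted_matrix(seed: int, **overrides) -> tuple[CharacterMatrix, np.ndarray]:
    """Centred planted matrix plus its integer taxon labels."""
    matrix, _ = generate(planted_config(seed, **overrides))
    labels = np.unique(matrix.ground_truth, return_inverse=True)[1]
    return center(matrix), labels


@pytest.fixture()
def small_matrix() -> CharacterMatrix:
    rng = np.random.default_rng(42)
    return CharacterMatrix(
        [f"i{k}" for k in range(12)],
        [f"c{j}" for j in range(4)],
        rng.normal(size=(12, 4)),
        ground_truth=["a"] * 6 + ["b"] * 6,
    )
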