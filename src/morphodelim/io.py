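"""Reading, transforming and standardizing morphometric character tables.

A character table has one row per measured individual and one numeric column
per continuous morphological character, plus an identifier column and an
optional taxon-label column (ground truth used only for validation, never for
clustering).  Preprocessing mirrors common morphometric practice: paired
length/width measurements are collapsed to ratios to limit pseudoreplication,
highly correlated characters are pruned so no trait is represented twice, and
every character is centred and scaled to unit standard deviation so all
characters contribute on the same scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("morphodelim")

__all__ = [
    "CharacterMatrix",
    "PruningReport",
    "read_character_table",
    "write_character_table",
    "ratio_transform",
    "prune_correlated",
    "center",
    "standardize",
]


@dataclass
class CharacterMatrix:
    """N individuals x d continuous characters, with optional taxon labels.

    ``values`` holds raw measurements (arbitrary units) before
    :func:`standardize` and unitless z-scores after.  ``ground_truth`` is a
    taxonomist-assigned label per individual, used only by validation.
    """

    individual_ids: list[str]
    character_names: list[str]
    values: np.ndarray
    ground_truth: list[str] | None = None

    def __post_init__(self) -> None:
        self.individual_ids = [str(i) for i in self.individual_ids]
        self.character_names = [str(c) for c in self.character_names]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, d = self.values.shape
        if n < 2:
            raise ValueError(f"need at least 2 individuals, got {n}")
        if d < 1:
            raise ValueError("need at least 1 character")
        if len(self.individual_ids) != n:
            raise ValueError("number of ids does not match number of rows")
        if len(self.character_names) != d:
            raise ValueError("number of character names does not match columns")
        if len(set(self.individual_ids)) != n:
            dupes = sorted({i for i in self.individual_ids if self.individual_ids.count(i) > 1})
            raise ValueError(f"duplicate individual ids: {dupes}")
        if len(set(self.character_names)) != d:
            raise ValueError("character names must be unique")
        if not np.all(np.isfinite(self.values)):
            r, c = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"missing/non-finite value for individual {self.individual_ids[r]!r}, "
                f"character {self.character_names[c]!r}"
            )
        if self.ground_truth is not None:
            self.ground_truth = [str(g) for g in self.ground_truth]
            if len(self.ground_truth) != n:
                raise ValueError("ground_truth must have one label per individual")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_characters(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.character_names.index(name)]

    def to_frame(self, id_column: str = "individual_id", label_column: str = "taxon") -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.character_names)
        df.insert(0, id_column, self.individual_ids)
        if self.ground_truth is not None:
            df[label_column] = self.ground_truth
        return df


@dataclass
class PruningReport:
    """Outcome of correlation pruning: flagged character pairs and the action taken."""

    flagged_pairs: list[tuple[str, str, float, float]]
    dropped: list[str]
    retained: list[str]
    actions: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (a, b, r2, p), act in zip(
            self.flagged_pairs, self.actions or ["" for _ in self.flagged_pairs]
        ):
            rows.append({"character_a": a, "character_b": b, "r_squared": r2, "p_value": p, "action": act})
        return pd.DataFrame(rows, columns=["character_a", "character_b", "r_squared", "p_value", "action"])


def _sniff_sep(path: Path) -> str:
    head = path.read_text().splitlines()[0]
    return "\t" if head.count("\t") > head.count(",") else ","


def read_character_table(
    source: str | Path,
    id_column: str = "individual_id",
    label_column: str | None = None,
    sep: str | None = None,
) -> CharacterMatrix:
    """Read a delimited character table (header row; one id column; optional label column).

    All non-id, non-label columns must be numeric with no missing cells; any
    violation raises a ``ValueError`` naming the offending row and column.
    """
    path = Path(source)
    if sep is None:
        sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if id_column not in df.columns:
        raise ValueError(f"id column {id_column!r} not found in {path}")
    ids = df[id_column].tolist()
    labels = None
    label_cols = []
    if label_column is not None and label_column in df.columns:
        labels = df[label_column].tolist()
        label_cols = [label_column]
    char_cols = [c for c in df.columns if c != id_column and c not in label_cols]
    values = np.empty((len(df), len(char_cols)))
    for j, col in enumerate(char_cols):
        raw = df[col]
        for i, cell in enumerate(raw):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell).strip() == "":
                raise ValueError(f"missing value at row {ids[i]!r} (line {i + 2}), column {col!r}")
        try:
            values[:, j] = pd.to_numeric(raw).to_numpy(dtype=float)
        except (ValueError, TypeError):
            bad = next(i for i, cell in enumerate(raw) if not _is_number(cell))
            raise ValueError(
                f"non-numeric value {raw.iloc[bad]!r} at row {ids[bad]!r}, column {col!r}"
            ) from None
    return CharacterMatrix(ids, char_cols, values, ground_truth=labels)


def _is_number(x) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False


def write_character_table(
    matrix: CharacterMatrix,
    dest: str | Path,
    id_column: str = "individual_id",
    label_column: str = "taxon",
    sep: str = ",",
) -> Path:
    """Write the matrix in the same delimited format accepted by :func:`read_character_table`."""
    path = Path(dest)
    matrix.to_frame(id_column=id_column, label_column=label_column).to_csv(path, sep=sep, index=False)
    return path


def ratio_transform(
    matrix: CharacterMatrix,
    pairs: Sequence[tuple[str, str, str]],
) -> CharacterMatrix:
    """Collapse (length, width) column pairs to single length/width ratio columns.

    Each ratio column takes the position of its length column; the width column
    is removed.  Other columns are untouched.  A zero width anywhere is an
    error (the ratio is undefined).
    """
    names = list(matrix.character_names)
    for lcol, wcol, _new in pairs:
        for col in (lcol, wcol):
            if col not in names:
                raise ValueError(f"ratio pair column {col!r} not in character table")
    cols: dict[str, np.ndarray] = {n: matrix.values[:, i] for i, n in enumerate(names)}
    order = list(names)
    for lcol, wcol, new in pairs:
        width = cols[wcol]
        if np.any(width == 0):
            i = int(np.argwhere(width == 0)[0][0])
            raise ValueError(
                f"width column {wcol!r} is 0 for individual {matrix.individual_ids[i]!r}; ratio undefined"
            )
        cols[new] = cols[lcol] / width
        order[order.index(lcol)] = new
        order.remove(wcol)
        del cols[lcol], cols[wcol]
    values = np.column_stack([cols[n] for n in order])
    return CharacterMatrix(matrix.individual_ids, order, values, ground_truth=matrix.ground_truth)


def prune_correlated(
    matrix: CharacterMatrix,
    r2_threshold: float = 0.7,
    alpha: float = 0.05,
    keep: Sequence[str] | None = None,
    report_only: bool = False,
) -> tuple[CharacterMatrix, PruningReport]:
    """Flag character pairs with r² >= threshold (significant at ``alpha``) and drop one of each.

    The keep-first rule drops the later column of a flagged pair, unless the
    later column is listed in ``keep`` (expert override, e.g. retaining the
    number of fertile bracts over the number of old flowers).  In
    ``report_only`` mode pairs are flagged but nothing is dropped.
    """
    if not (0.0 < r2_threshold <= 1.0):
        raise ValueError(f"r2_threshold must be in (0, 1], got {r2_threshold}")
    if matrix.n_characters < 2:
        raise ValueError("need at least 2 characters to test correlations")
    keep_set = set(keep or [])
    names = matrix.character_names
    flagged: list[tuple[str, str, float, float]] = []
    actions: list[str] = []
    dropped: list[str] = []
    retained = list(names)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            r, p = stats.pearsonr(matrix.values[:, i], matrix.values[:, j])
            r2 = r * r
            if r2 >= r2_threshold and p < alpha:
                a, b = names[i], names[j]
                flagged.append((a, b, float(r2), float(p)))
                if report_only:
                    actions.append("flagged")
                    continue
                if a in retained and b in retained:
                    victim = b
                    if b in keep_set and a not in keep_set:
                        victim = a
                    if a in keep_set and b in keep_set:
                        actions.append("kept both (keep-list)")
                        continue
                    retained.remove(victim)
                    dropped.append(victim)
                    actions.append(f"dropped {victim}")
                else:
                    actions.append("already resolved")
    idx = [names.index(n) for n in retained]
    pruned = CharacterMatrix(
        matrix.individual_ids, retained, matrix.values[:, idx], ground_truth=matrix.ground_truth
    )
    report = PruningReport(flagged_pairs=flagged, dropped=dropped, retained=retained, actions=actions)
    logger.info("correlation pruning: %d pairs flagged, %d characters dropped", len(flagged), len(dropped))
    return pruned, report


def center(matrix: CharacterMatrix) -> CharacterMatrix:
    """Subtract each character's mean without rescaling.

    For data already measured on a common scale (notably synthetic surveys
    whose characters share one within-taxon SD by construction), centring
    satisfies the clustering engine's zero-mean expectation while leaving the
    characters' relative weights untouched; :func:`standardize` additionally
    rescales and is the right call for heterogeneous real measurements.
    """
    z = matrix.values - matrix.values.mean(axis=0)
    return CharacterMatrix(matrix.individual_ids, list(matrix.character_names), z, ground_truth=matrix.ground_truth)


def standardize(matrix: CharacterMatrix, ddof: int = 1) -> CharacterMatrix:
    """Centre each character to mean 0 and scale to unit standard deviation.

    Sample SD (divisor N-1) by default — the convention for measured
    specimens; set ``ddof=0`` for the population form.  A constant character
    cannot be scaled and raises a ``ValueError`` naming it.
    """
    sd = matrix.values.std(axis=0, ddof=ddof)
    if np.any(sd == 0):
        name = matrix.character_names[int(np.argwhere(sd == 0)[0][0])]
        raise ValueError(f"character {name!r} is constant; cannot standardize")
    z = (matrix.values - matrix.values.mean(axis=0)) / sd
    return CharacterMatrix(matrix.individual_ids, list(matrix.character_names), z, ground_truth=matrix.ground_truth)
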