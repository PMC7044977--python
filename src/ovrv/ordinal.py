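"""Ordinal data containers and the Goodman–Kruskal gamma statistic.

The gamma statistic measures monotone trend association between two ordinal
variables.  For a pair of subjects, the pair is *concordant* if one subject
ranks strictly higher on both variables and *discordant* if it ranks strictly
higher on one and strictly lower on the other; pairs tied on either variable
contribute to neither count.  With C and D the total numbers of concordant and
discordant pairs,

    gamma_hat = (C - D) / (C + D),

the sample analogue of gamma = (Pi_c - Pi_d) / (Pi_c + Pi_d) defined from the
concordance/discordance probabilities of the joint distribution.  In rare
variant association studies the contingency table of genotype score by
phenotype is extremely sparse, so the classical normal approximation for
gamma_hat is unreliable; the permutation machinery in :mod:`ovrv.permutation`
is used instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "OrdinalVector",
    "ContingencyTable",
    "GammaResult",
    "build_contingency_table",
    "concordance_counts",
    "gamma_statistic",
]


@dataclass(frozen=True)
class OrdinalVector:
    """An integer-coded ordinal variable with an explicit ordered level set.

    Parameters
    ----------
    codes
        Per-subject integer codes (length n >= 1), each a member of ``levels``.
    levels
        Strictly increasing sequence of the permitted codes.  Levels that are
        permitted but unobserved are retained; they produce empty rows/columns
        in the contingency table and do not affect C, D or gamma_hat.
    """

    codes: np.ndarray
    levels: np.ndarray

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes, dtype=np.int64)
        levels = np.asarray(self.levels, dtype=np.int64)
        if codes.ndim != 1 or codes.size < 1:
            raise ValueError("codes must be a non-empty 1-d sequence")
        if levels.ndim != 1 or levels.size < 1:
            raise ValueError("levels must be a non-empty 1-d sequence")
        if np.any(codes < 0):
            raise ValueError("codes must be non-negative integers")
        if np.any(np.diff(levels) <= 0):
            raise ValueError("levels must be strictly increasing")
        if not np.isin(codes, levels).all():
            raise ValueError("every code must appear in levels")
        object.__setattr__(self, "codes", codes)
        object.__setattr__(self, "levels", levels)

    @classmethod
    def from_codes(
        cls, codes: Sequence[int], levels: Sequence[int] | None = None
    ) -> "OrdinalVector":
        """Build an OrdinalVector, inferring the level set from the data
        unless one is supplied explicitly."""
        codes = np.asarray(codes, dtype=np.int64)
        if levels is None:
            levels = np.unique(codes)
        return cls(codes=codes, levels=np.asarray(levels, dtype=np.int64))

    def __len__(self) -> int:
        return int(self.codes.size)

    @property
    def n_levels(self) -> int:
        return int(self.levels.size)

    def level_indices(self) -> np.ndarray:
        """Map each code to its 0-based rank within ``levels``."""
        return np.searchsorted(self.levels, self.codes)


@dataclass(frozen=True)
class ContingencyTable:
    """I x J cross-contingency table of phenotype level by genotype-score level.

    ``counts[i, j]`` is the number of subjects at phenotype level
    ``row_levels[i]`` and score level ``col_levels[j]``; the sample joint
    proportions ``counts / n`` estimate the joint cell probabilities.
    """

    counts: np.ndarray
    row_levels: np.ndarray
    col_levels: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[0] < 1 or counts.shape[1] < 1:
            raise ValueError("counts must be a non-empty 2-d matrix")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        row_levels = np.asarray(self.row_levels, dtype=np.int64)
        col_levels = np.asarray(self.col_levels, dtype=np.int64)
        if row_levels.size != counts.shape[0] or col_levels.size != counts.shape[1]:
            raise ValueError("level labels must match the table dimensions")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "row_levels", row_levels)
        object.__setattr__(self, "col_levels", col_levels)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass(frozen=True)
class GammaResult:
    """Concordant/discordant pair counts and the gamma statistic.

    When every pair is tied (C + D = 0, e.g. a constant phenotype or a
    monomorphic region) no trend information exists: ``gamma`` is reported as
    0.0 with ``defined=False`` and downstream tests return p = 1.
    """

    C: int
    D: int
    gamma: float
    defined: bool


def build_contingency_table(
    phenotype: OrdinalVector, score: OrdinalVector
) -> ContingencyTable:
    """Cross-tabulate phenotype level (rows) by genotype-score level (columns).

    Rows and columns are ordered by ascending level; every subject is counted
    exactly once.
    """
    if len(phenotype) != len(score):
        raise ValueError(
            f"phenotype (n={len(phenotype)}) and score (n={len(score)}) "
            "must have equal length"
        )
    i_idx = phenotype.level_indices()
    j_idx = score.level_indices()
    I, J = phenotype.n_levels, score.n_levels
    counts = np.bincount(i_idx * J + j_idx, minlength=I * J).reshape(I, J)
    return ContingencyTable(
        counts=counts, row_levels=phenotype.levels, col_levels=score.levels
    )


def _concordance_weights(tables: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell counts of strictly-greater/strictly-lesser cells.

    For a batch of tables ``x`` with shape (..., I, J) returns arrays of the
    same shape where element (i, j) holds ``sum_{i'>i, j'>j} x[i', j']`` and
    ``sum_{i'>i, j'<j} x[i', j']`` respectively.
    """
    x = np.asarray(tables, dtype=np.int64)
    # suffix[i, j] = sum over i' >= i, j' >= j
    suffix = x[..., ::-1, ::-1].cumsum(axis=-1).cumsum(axis=-2)[..., ::-1, ::-1]
    greater = np.zeros_like(x)
    greater[..., :-1, :-1] = suffix[..., 1:, 1:]
    # mixed[i, j] = sum over i' >= i, j' <= j
    mixed = x.cumsum(axis=-1)[..., ::-1, :].cumsum(axis=-2)[..., ::-1, :]
    lesser = np.zeros_like(x)
    lesser[..., :-1, 1:] = mixed[..., 1:, :-1]
    return greater, lesser


def concordance_counts_batch(tables: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised (C, D) for a batch of contingency tables of shape (..., I, J).

    Each subject pair is counted once, anchored at its lower-left cell:
    C = sum_{ij} x_ij * sum_{i'>i, j'>j} x_i'j' and
    D = sum_{ij} x_ij * sum_{i'>i, j'<j} x_i'j'.
    """
    x = np.asarray(tables, dtype=np.int64)
    greater, lesser = _concordance_weights(x)
    C = (x * greater).sum(axis=(-1, -2))
    D = (x * lesser).sum(axis=(-1, -2))
    return C, D


def concordance_counts(table: ContingencyTable) -> tuple[int, int]:
    """Total concordant and discordant pair counts (C, D) of a table.

    Uses the cell cross-product sums rather than per-subject pair enumeration;
    pairs tied on either variable contribute to neither count.
    """
    C, D = concordance_counts_batch(table.counts)
    return int(C), int(D)


def gamma_statistic(table: ContingencyTable) -> GammaResult:
    """The sample Goodman–Kruskal gamma, (C - D) / (C + D).

    C + D = 0 is a signalled degenerate result (``defined=False``), not an
    error: with all pairs tied there is no trend to measure.
    """
    C, D = concordance_counts(table)
    if C + D == 0:
        return GammaResult(C=C, D=D, gamma=0.0, defined=False)
    return GammaResult(C=C, D=D, gamma=(C - D) / (C + D), defined=True)
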