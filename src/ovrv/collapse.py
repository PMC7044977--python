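"""Rare-variant filtering, missing-genotype imputation and burden collapsing.

A region of m variants is summarised per subject by a genetic score
``score_i = sum_j w_j * g(G_ij)`` where ``G_ij`` in {0, 1, 2} is the
minor-allele count.  The default configuration uses unit weights and the
presence-indicator link ``g(x) = 1(x > 0)``, i.e. the number of variants at
which the subject carries at least one minor allele — the CAST-style
collapsing convention.  The scores are then rank-encoded into an ordinal
genotype variable for the gamma test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .ordinal import OrdinalVector

__all__ = [
    "GenotypeMatrix",
    "ScoreConfig",
    "EmptyRegionError",
    "filter_rare_variants",
    "impute_missing",
    "genetic_score",
    "ordinal_encode",
]


class EmptyRegionError(ValueError):
    """Raised when a region retains no variants (the test cannot run)."""


@dataclass(frozen=True)
class GenotypeMatrix:
    """n x m minor-allele-count matrix with per-variant MAFs.

    ``counts`` is a float array whose non-missing entries are 0, 1 or 2;
    missing genotypes are ``NaN`` (fill them with :func:`impute_missing`
    before scoring).  Genotypes are assumed pre-oriented to minor-allele
    counts; no allele flipping is performed here.
    """

    counts: np.ndarray
    mafs: np.ndarray
    variant_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.float64)
        mafs = np.asarray(self.mafs, dtype=np.float64)
        if counts.ndim != 2:
            raise ValueError("counts must be an n x m matrix")
        observed = counts[~np.isnan(counts)]
        if not np.isin(observed, (0.0, 1.0, 2.0)).all():
            raise ValueError("non-missing genotype entries must be 0, 1 or 2")
        if mafs.shape != (counts.shape[1],):
            raise ValueError("mafs must have one entry per variant")
        if counts.shape[1] and (np.any(mafs <= 0) or np.any(mafs > 0.5)):
            raise ValueError("MAFs must lie in (0, 0.5]")
        ids = tuple(str(v) for v in self.variant_ids)
        if len(ids) != counts.shape[1]:
            raise ValueError("variant_ids must have one entry per variant")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "mafs", mafs)
        object.__setattr__(self, "variant_ids", ids)

    @property
    def n_subjects(self) -> int:
        return int(self.counts.shape[0])

    @property
    def n_variants(self) -> int:
        return int(self.counts.shape[1])

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.counts).any())


@dataclass(frozen=True)
class ScoreConfig:
    """Configuration of the collapsing score.

    weights
        Per-variant positive weights; ``None`` means unit weights.  Weighted
        schemes (e.g. Madsen–Browning) can be supplied here.
    link
        ``"presence"`` for the indicator link 1(G > 0) (default) or
        ``"identity"`` for the raw allele count.
    maf_threshold
        Variants with MAF strictly below this bound are retained as rare.
    """

    weights: np.ndarray | None = None
    link: Literal["presence", "identity"] = "presence"
    maf_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.link not in ("presence", "identity"):
            raise ValueError("link must be 'presence' or 'identity'")
        if not (0 < self.maf_threshold <= 0.5):
            raise ValueError("maf_threshold must lie in (0, 0.5]")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=np.float64)
            if np.any(w <= 0):
                raise ValueError("weights must be positive")
            object.__setattr__(self, "weights", w)


def filter_rare_variants(g: GenotypeMatrix, maf_threshold: float) -> GenotypeMatrix:
    """Keep variants with MAF strictly below ``maf_threshold``.

    Subject order is preserved.  Raises :class:`EmptyRegionError` when no
    variant passes, so the condition is always signalled explicitly.
    """
    if not (0 < maf_threshold <= 0.5):
        raise ValueError("maf_threshold must lie in (0, 0.5]")
    keep = g.mafs < maf_threshold
    if not keep.any():
        raise EmptyRegionError(
            f"no variant has MAF < {maf_threshold}; the region is empty"
        )
    return GenotypeMatrix(
        counts=g.counts[:, keep],
        mafs=g.mafs[keep],
        variant_ids=tuple(v for v, k in zip(g.variant_ids, keep) if k),
    )


def impute_missing(
    g: GenotypeMatrix, seed: int | np.random.Generator
) -> GenotypeMatrix:
    """Fill missing genotypes by sampling from Hardy–Weinberg proportions.

    A missing entry at a variant with MAF p is replaced by a draw from
    {0, 1, 2} with probabilities {(1-p)^2, 2p(1-p), p^2}.  Deterministic for
    a given seed; non-missing entries are untouched.
    """
    if not g.has_missing:
        return g
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = g.counts.copy()
    rows, cols = np.nonzero(np.isnan(counts))
    p = g.mafs[cols]
    u = rng.random(p.size)
    draw = (u >= (1 - p) ** 2).astype(np.float64) + (u >= 1 - p**2)
    counts[rows, cols] = draw
    return GenotypeMatrix(counts=counts, mafs=g.mafs, variant_ids=g.variant_ids)


def genetic_score(g: GenotypeMatrix, config: ScoreConfig | None = None) -> np.ndarray:
    """Per-subject collapsed genetic score (length n).

    With the default configuration this is the number of variants at which
    the subject carries at least one minor allele.  Missing entries are an
    error: impute first.
    """
    config = config or ScoreConfig()
    if g.has_missing:
        raise ValueError(
            "genotype matrix contains missing entries; run impute_missing first"
        )
    if config.link == "presence":
        contrib = (g.counts > 0).astype(np.float64)
    else:
        contrib = g.counts
    if config.weights is not None:
        if config.weights.shape != (g.n_variants,):
            raise ValueError("weights must have one entry per variant")
        contrib = contrib * config.weights
    return contrib.sum(axis=1)


def ordinal_encode(scores: Sequence[float]) -> OrdinalVector:
    """Rank-encode scores into ordinal levels 0 .. J-1.

    Distinct score values sorted ascending become the levels; each subject is
    mapped to the rank of its score, so any strictly increasing transform of
    the scores yields the same encoding.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if scores.ndim != 1 or scores.size < 1:
        raise ValueError("scores must be a non-empty 1-d sequence")
    _, codes = np.unique(scores, return_inverse=True)
    return OrdinalVector.from_codes(codes.astype(np.int64))
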