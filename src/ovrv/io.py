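"""File input/output: genotype matrices (VCF or TSV), phenotypes, regions.

Coordinates follow the VCF convention throughout: 1-based, inclusive on both
ends.  Genotypes read from VCF are mapped to minor-allele counts using the
ALT allele as the minor allele; multi-allelic sites are rejected rather than
silently split, and an ALT frequency above 0.5 is an error (callers must
pre-orient alleles).  Missing-value tokens in TSV files are "." and "NA".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .collapse import EmptyRegionError, GenotypeMatrix
from .ordinal import OrdinalVector

__all__ = [
    "RegionDefinition",
    "read_genotypes",
    "read_phenotypes",
    "read_regions",
    "write_genotypes_tsv",
    "discretize_phenotype",
]

logger = logging.getLogger("ovrv")

_MISSING_TOKENS = {".", "NA", ""}


@dataclass(frozen=True)
class RegionDefinition:
    """A named set of variants: either explicit IDs or a genomic interval.

    Intervals are 1-based and inclusive (chrom, start, end), matching VCF.
    """

    region_id: str
    variant_ids: tuple[str, ...] | None = None
    chrom: str | None = None
    start: int | None = None
    end: int | None = None

    def __post_init__(self) -> None:
        if not self.region_id:
            raise ValueError("region_id must be non-empty")
        interval = (self.chrom, self.start, self.end)
        if self.variant_ids is None:
            if any(v is None for v in interval):
                raise ValueError(
                    "a region needs either variant_ids or a full (chrom, start, end)"
                )
            if self.start > self.end:
                raise ValueError("interval start must be <= end")
        object.__setattr__(
            self,
            "variant_ids",
            tuple(self.variant_ids) if self.variant_ids is not None else None,
        )

    def contains(self, chrom: str, pos: int, vid: str) -> bool:
        if self.variant_ids is not None:
            return vid in self.variant_ids
        return str(chrom) == str(self.chrom) and self.start <= pos <= self.end


def _finalize_matrix(
    counts: np.ndarray,
    variant_ids: list[str],
    mafs: np.ndarray | None,
    region_id: str,
) -> GenotypeMatrix:
    """Compute MAFs from the data when absent and drop uninformative variants."""
    if counts.shape[1] == 0:
        raise EmptyRegionError(f"region '{region_id}' contains no variants")
    if mafs is None:
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(counts, axis=0) / 2.0
        if np.any(freq > 0.5):
            bad = [v for v, f in zip(variant_ids, freq) if f > 0.5]
            raise ValueError(
                f"ALT allele frequency exceeds 0.5 for {bad}; genotypes must be "
                "pre-oriented to minor-allele counts"
            )
        mono = (freq == 0) | np.isnan(freq)
        if mono.any():
            logger.info(
                "region %s: dropping %d variant(s) monomorphic in the sample",
                region_id,
                int(mono.sum()),
            )
            counts = counts[:, ~mono]
            variant_ids = [v for v, m in zip(variant_ids, mono) if not m]
            freq = freq[~mono]
        mafs = freq
    if counts.shape[1] == 0:
        raise EmptyRegionError(f"region '{region_id}' has no polymorphic variants")
    return GenotypeMatrix(counts=counts, mafs=np.asarray(mafs), variant_ids=tuple(variant_ids))


def _read_vcf(path: Path, region: RegionDefinition | None) -> tuple[np.ndarray, list[str]]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    columns: list[np.ndarray] = []
    ids: list[str] = []
    for k, variant in enumerate(vcf):
        vid = variant.ID or f"{variant.CHROM}:{variant.POS}"
        if region is not None and not region.contains(variant.CHROM, variant.POS, vid):
            continue
        if len(variant.ALT) != 1:
            raise ValueError(
                f"multi-allelic site {vid} is not supported; split or exclude it"
            )
        col = np.empty(len(vcf.samples), dtype=np.float64)
        for s, gt in enumerate(variant.genotypes):
            alleles = [a for a in gt[:-1] if a is not None]
            if any(a < 0 for a in alleles) or not alleles:
                col[s] = np.nan
            else:
                col[s] = float(sum(1 for a in alleles if a > 0))
        columns.append(col)
        ids.append(vid)
    n = len(vcf.samples)
    vcf.close()
    counts = np.column_stack(columns) if columns else np.empty((n, 0))
    return counts, ids


def _read_tsv_matrix(
    path: Path, region: RegionDefinition | None
) -> tuple[np.ndarray, list[str], np.ndarray | None]:
    mafs: np.ndarray | None = None
    with open(path) as fh:
        first = fh.readline()
        second = fh.readline()
    if second.startswith("#mafs"):
        mafs = np.array([float(x) for x in second.rstrip("\n").split("\t")[1:]])
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, index_col=0)
    ids = [str(c) for c in df.columns]
    values = df.to_numpy()
    counts = np.empty(values.shape, dtype=np.float64)
    for (i, j), v in np.ndenumerate(values):
        token = str(v).strip() if v is not None else ""
        if token in _MISSING_TOKENS or token.lower() == "nan":
            counts[i, j] = np.nan
        else:
            try:
                counts[i, j] = float(token)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: non-numeric genotype '{token}' at row {i + 2}, "
                    f"variant {ids[j]}"
                ) from exc
    if region is not None:
        if region.variant_ids is None:
            raise ValueError(
                "interval regions need positional information; use VCF input "
                "or a region with explicit variant_ids"
            )
        keep = [k for k, vid in enumerate(ids) if vid in region.variant_ids]
        counts = counts[:, keep]
        if mafs is not None:
            mafs = mafs[keep]
        ids = [ids[k] for k in keep]
    return counts, ids, mafs


def read_genotypes(
    path: str | Path,
    region: RegionDefinition | None = None,
    maf_threshold: float | None = None,
) -> GenotypeMatrix:
    """Read a genotype matrix from VCF or a subjects-by-variants TSV.

    VCF files (``.vcf``/``.vcf.gz``) are parsed with cyvcf2; anything else is
    treated as a tab-delimited matrix of {0, 1, 2, missing} with subject IDs
    in the first column and variant IDs in the header.  Missing genotypes are
    preserved as missing for later Hardy–Weinberg imputation.  MAFs are
    computed from the data when the file does not carry them.  When
    ``maf_threshold`` is given, only variants with MAF strictly below it are
    retained (raising :class:`EmptyRegionError` if none survive).
    """
    path = Path(path)
    region_id = region.region_id if region is not None else path.name
    if path.name.endswith((".vcf", ".vcf.gz")):
        counts, ids = _read_vcf(path, region)
        mafs = None
    else:
        counts, ids, mafs = _read_tsv_matrix(path, region)
    g = _finalize_matrix(counts, ids, mafs, region_id)
    if maf_threshold is not None:
        from .collapse import filter_rare_variants

        g = filter_rare_variants(g, maf_threshold)
    return g


def write_genotypes_tsv(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a GenotypeMatrix as TSV (with a ``#mafs`` sidecar line) so that
    :func:`read_genotypes` reproduces it exactly."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("subject\t" + "\t".join(g.variant_ids) + "\n")
        fh.write("#mafs\t" + "\t".join(f"{m:.17g}" for m in g.mafs) + "\n")
        for i in range(g.n_subjects):
            row = [
                "." if np.isnan(v) else str(int(v)) for v in g.counts[i]
            ]
            fh.write(f"s{i + 1}\t" + "\t".join(row) + "\n")


def read_phenotypes(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a two-column (subject id, value) delimited file.

    A header row is detected and skipped when its second field is not
    numeric.  Subjects with a missing phenotype are dropped with a logged
    count; a file with no analyzable subjects is an error.
    """
    path = Path(path)
    ids: list[str] = []
    values: list[float] = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.replace(",", "\t").split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            sid, raw = fields[0], fields[1]
            if raw in _MISSING_TOKENS:
                dropped += 1
                continue
            try:
                val = float(raw)
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise ValueError(
                    f"{path}:{lineno}: non-numeric phenotype value '{raw}'"
                ) from None
            ids.append(sid)
            values.append(val)
    if dropped:
        logger.info("%s: dropped %d subject(s) with missing phenotype", path, dropped)
    if not ids:
        raise ValueError(f"{path}: no subjects with a non-missing phenotype")
    return ids, np.asarray(values, dtype=np.float64)


def read_regions(path: str | Path) -> list[RegionDefinition]:
    """Read a gene-list file of 'gene chrom start end' rows (1-based, inclusive)."""
    regions: list[RegionDefinition] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 'gene chrom start end'"
                )
            name, chrom, start, end = fields
            regions.append(
                RegionDefinition(
                    region_id=name, chrom=chrom, start=int(start), end=int(end)
                )
            )
    return regions


def discretize_phenotype(
    values: Sequence[float], cut_points: Sequence[float]
) -> OrdinalVector:
    """Bin a continuous phenotype into ordinal levels at fixed cut points.

    Bins are left-closed: the level of a value v is the number of cut points
    c with v >= c.  With cuts (60, 80, 90) this reproduces the diastolic
    blood pressure convention DBP < 60 -> 0, 60 <= DBP < 80 -> 1,
    80 <= DBP < 90 -> 2, DBP >= 90 -> 3.
    """
    values = np.asarray(values, dtype=np.float64)
    cuts = np.asarray(cut_points, dtype=np.float64)
    if cuts.size < 1 or np.any(np.diff(cuts) <= 0):
        raise ValueError("cut_points must be strictly ascending and non-empty")
    codes = np.searchsorted(cuts, values, side="right")
    return OrdinalVector(codes=codes.astype(np.int64), levels=np.arange(cuts.size + 1))
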