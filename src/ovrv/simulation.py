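"""Synthetic-data generation and operating-characteristic estimation.

The generator reproduces the designed-parameter simulation used to validate
the test: a region of m rare variants with MAFs drawn from U(0.001, 0.01),
Hardy–Weinberg genotypes for n subjects, a continuous intermediate trait

    T_i = sum_j (d * beta_j) * G_ij + eps_i,    eps_i ~ N(0, sigma^2) iid,

with a fixed 0/1 causal pattern beta and effect magnitude d, and an ordinal
phenotype obtained by cutting T at its 20th, 30th and 40th sample percentiles
(levels 0-3 with expected proportions 20/10/10/60%).  d = 0 makes phenotype
and genotype independent, so the rejection rate there estimates the type-I
error; d > 0 gives power.

Defaults follow the validated study conditions: n = 500 subjects, m = 20 or
40 variants, d in {0, 0.2, 0.4, 0.6, 0.8}, 1000 replications.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .collapse import GenotypeMatrix, ScoreConfig
from .ordinal import OrdinalVector
from .permutation import ov_rv_test

__all__ = [
    "SimulationConfig",
    "causal_beta",
    "sample_mafs",
    "simulate_genotypes",
    "simulate_phenotype",
    "simulate_pvalues",
    "estimate_rejection_rate",
]

# Fixed 0/1 causal-variant patterns of the designed simulation:
# 12 of 20 and 18 of 40 variants are causal.
_BETA_20 = (1, 1, 0, 1, 1, 0, 1, 0, 0, 1, 1, 0, 0, 1, 1, 0, 1, 1, 0, 1)
_BETA_40 = (
    1, 0, 1, 1, 0, 0, 1, 0, 1, 0, 1, 0, 0, 1, 0, 0, 1, 0, 1, 0,
    1, 1, 0, 0, 1, 0, 1, 0, 1, 0, 0, 1, 0, 0, 1, 0, 1, 0, 1, 0,
)


def causal_beta(m: int) -> np.ndarray:
    """The fixed 0/1 causal-indicator pattern for a region of m variants.

    Only m = 20 (12 causal) and m = 40 (18 causal) are defined; for other
    region sizes supply a custom pattern through :class:`SimulationConfig`.
    """
    if m == 20:
        return np.array(_BETA_20, dtype=np.float64)
    if m == 40:
        return np.array(_BETA_40, dtype=np.float64)
    raise ValueError(
        f"no built-in causal pattern for m={m}; supply beta_pattern explicitly"
    )


def sample_mafs(
    m: int,
    low: float = 0.001,
    high: float = 0.01,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """m iid Uniform(low, high) minor allele frequencies."""
    if not (0 < low < high):
        raise ValueError("require 0 < low < high")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.uniform(low, high, size=m)


def simulate_genotypes(
    n: int, mafs: np.ndarray, seed: int | np.random.Generator = 0
) -> GenotypeMatrix:
    """Independent Hardy–Weinberg genotypes: P(G=0,1,2) = ((1-p)^2, 2p(1-p), p^2)."""
    mafs = np.asarray(mafs, dtype=np.float64)
    if np.any(mafs <= 0) or np.any(mafs >= 0.5):
        raise ValueError("MAFs must lie in (0, 0.5)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.random((n, mafs.size))
    p = mafs[np.newaxis, :]
    counts = (u >= (1 - p) ** 2).astype(np.float64) + (u >= 1 - p**2)
    ids = tuple(f"v{j + 1}" for j in range(mafs.size))
    return GenotypeMatrix(counts=counts, mafs=mafs, variant_ids=ids)


def simulate_phenotype(
    g: GenotypeMatrix,
    beta_pattern: np.ndarray,
    d: float,
    percentiles: tuple[float, ...] = (0.20, 0.30, 0.40),
    seed: int | np.random.Generator = 0,
    noise_sd: float = 1.0,
) -> OrdinalVector:
    """Ordinal phenotype from the linear intermediate-trait model.

    T_i = sum_j (d * beta_j) G_ij + eps_i with iid Gaussian noise; the trait
    is then cut at the given sample percentiles (values equal to a cut point
    fall in the lower level), giving levels 0 .. len(percentiles).
    """
    beta_pattern = np.asarray(beta_pattern, dtype=np.float64)
    if beta_pattern.shape != (g.n_variants,):
        raise ValueError("beta_pattern must have one entry per variant")
    pct = np.asarray(percentiles, dtype=np.float64)
    if pct.size < 1 or np.any(pct <= 0) or np.any(pct >= 1) or np.any(np.diff(pct) <= 0):
        raise ValueError("percentiles must be strictly increasing within (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eps = rng.normal(0.0, noise_sd, size=g.n_subjects)
    T = g.counts @ (d * beta_pattern) + eps
    cuts = np.quantile(T, pct)
    codes = np.searchsorted(cuts, T, side="left")  # ties go to the lower level
    levels = np.arange(pct.size + 1)
    return OrdinalVector(codes=codes.astype(np.int64), levels=levels)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one operating-characteristic estimate.

    ``beta_pattern=None`` uses the built-in pattern for m; ``d=0`` estimates
    the type-I error, ``d>0`` power.  MAFs are re-sampled independently for
    every replicate, averaging over region configurations.
    """

    n: int = 500
    m: int = 20
    maf_low: float = 0.001
    maf_high: float = 0.01
    d: float = 0.0
    beta_pattern: tuple[int, ...] | None = None
    percentiles: tuple[float, ...] = (0.20, 0.30, 0.40)
    alpha: float = 0.05
    replications: int = 1000
    A: int = 1000
    seed: int = 0
    noise_sd: float = 1.0

    def resolved_beta(self) -> np.ndarray:
        if self.beta_pattern is None:
            return causal_beta(self.m)
        beta = np.asarray(self.beta_pattern, dtype=np.float64)
        if beta.shape != (self.m,) or not np.isin(beta, (0.0, 1.0)).all():
            raise ValueError("beta_pattern must be a length-m 0/1 vector")
        return beta


def simulate_pvalues(config: SimulationConfig) -> np.ndarray:
    """OV-RV p-values over independent replicates of the study design.

    Each replicate draws fresh MAFs, genotypes and phenotype, then runs the
    full test with A permutations.  Per-replicate random streams are spawned
    deterministically from the root seed, so any single replicate is
    reproducible in isolation.
    """
    beta = config.resolved_beta()
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.replications)
    score_config = ScoreConfig()
    pvals = np.empty(config.replications, dtype=np.float64)
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        mafs = sample_mafs(config.m, config.maf_low, config.maf_high, rng)
        g = simulate_genotypes(config.n, mafs, rng)
        y = simulate_phenotype(
            g, beta, config.d, config.percentiles, rng, config.noise_sd
        )
        result = ov_rv_test(y, g, score_config, A=config.A, seed=rng)
        pvals[r] = result.p_value
    return pvals


def estimate_rejection_rate(config: SimulationConfig) -> tuple[float, float]:
    """Empirical rejection rate at level alpha and its binomial standard error.

    With d = 0 this estimates the type-I error; with d > 0, the power.
    """
    pvals = simulate_pvalues(config)
    rate = float(np.mean(pvals <= config.alpha))
    mc_se = float(np.sqrt(rate * (1.0 - rate) / config.replications))
    return rate, mc_se
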