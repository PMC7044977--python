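# Methods

## Model and test

The package tests `H0: Y ⊥ G` for an ordinal phenotype `Y` (levels
`0 … I−1`) against an ordinal collapsed genotype score `G` (levels
`0 … J−1`), restricted to monotone-trend alternatives. The statistic is the
sample Goodman–Kruskal gamma computed from the `I × J` cross-contingency
table `x_ij`:

    C = Σ_ij x_ij · Σ_{i'>i, j'>j} x_i'j'     (concordant pairs)
    D = Σ_ij x_ij · Σ_{i'>i, j'<j} x_i'j'     (discordant pairs)
    γ̂ = (C − D) / (C + D)

Pairs tied on either variable are excluded by construction, so γ̂ conditions
on the untied pairs; it lies in [−1, 1] and reverses sign when either level
order is reversed. The cell cross-product form is `O((IJ)²)` in table cells
(implemented with two-dimensional suffix sums, so effectively `O(IJ)`),
which is what makes the permutation layer cheap; the per-pair enumeration
over all `n(n−1)/2` subject pairs exists only as the test-suite oracle.

Rare-variant tables are too sparse for the classical asymptotic normal
approximation of γ̂, so the null distribution is estimated by Monte Carlo
permutation: the phenotype vector is permuted uniformly at random `A` times
(sampling permutations with replacement), the table rebuilt and γ̂
recomputed for each. All `A` permuted tables are tabulated in a single
vectorised bincount and evaluated by batched suffix sums, which is what
keeps a full simulation study inside seconds rather than hours.

The reported p-value is two-sided with the add-one correction,
`p = (1 + #{a : |γ̂⁽ᵃ⁾| ≥ |γ̂_obs|})/(A + 1)`, giving `p ∈ [1/(A+1), 1]`.
Two-sided because a trend may be increasing or decreasing; add-one because
it can never be zero and is exactly valid (never anti-conservative) for
exchangeable data. Ties `|γ̂⁽ᵃ⁾| = |γ̂_obs|` count as exceedances, the
conservative direction.

### Degenerate inputs

When every pair is tied (`C + D = 0`: a constant phenotype, a monomorphic
region, or a region emptied by the MAF filter) no trend information exists.
The statistic is reported as `γ̂ = 0` with `defined = False` and the p-value
is 1 — the test cannot reject. Permutation replicates that land on a
degenerate table are likewise recorded as 0. A region left empty by the MAF
filter is additionally flagged (`empty_region = True`).

## Collapsing score

`score_i = Σ_j w_j · g(G_ij)` with unit weights and the presence-indicator
link `g(x) = 1(x > 0)` by default — the number of rare variants carried, in
the CAST collapsing tradition. The identity link (raw allele count) and
arbitrary positive weights (e.g. Madsen–Browning) are available through
`ScoreConfig`. Scores are rank-encoded: distinct values sorted ascending
become levels `0 … J−1`, so any strictly increasing transform of the score
yields the same test. Genotypes must arrive as minor-allele counts; no
allele flipping is performed, and VCF input treats ALT as the minor allele
(an ALT frequency above 0.5 raises rather than silently flipping).

Missing genotypes are imputed by a random draw from the Hardy–Weinberg
genotype distribution `{(1−p)², 2p(1−p), p²}` at the variant's MAF `p`,
before scoring. The MAF inclusion threshold defaults to 0.05 (the
convention for "rare" in resequencing panels); variants with MAF strictly
below it are retained.

## Synthetic study designs

The simulation module emulates a designed single-region study:

- `n = 500` subjects, `m = 20` or `40` variants per region (defaults);
- per-variant MAFs drawn iid from `U(0.001, 0.01)`, re-sampled
  independently every replicate so estimates average over region
  configurations;
- genotypes drawn independently per subject and variant from Hardy–Weinberg
  proportions;
- a continuous intermediate trait `T_i = Σ_j (d·β_j) G_ij + ε_i` with
  `ε_i ~ N(0, 1)` iid and a fixed 0/1 causal pattern β (12 of 20, or 18 of
  40, variants causal; the patterns are hard-coded constants);
- the ordinal phenotype cuts `T` at its 20th, 30th and 40th sample
  percentiles, giving levels 0–3 with expected proportions 20/10/10/60%;
  values equal to a cut point fall in the lower level.

`d ∈ {0, 0.2, 0.4, 0.6, 0.8}` scales the effect; `d = 0` makes `Y`
independent of `G`, so the rejection rate over replicates estimates the
type-I error, and `d > 0` gives power. The default noise is standard normal
with configurable variance — with unit-magnitude effects on an
unstandardised carrier count this is the conventional choice for such
intermediate-trait models.

What the generator does *not* emulate: linkage disequilibrium between
variants (draws are independent), covariates, population structure,
relatedness, genotyping error, or effects in opposing directions. Passing
calibration and power checks on these designs therefore demonstrates the
statistical validity of the permutation machinery and the ordering of power
in effect size, not robustness to confounding or to mixed-direction effects
(for which the monotone score is known to lose power).

## Numerical and design choices

- **Replication scheme.** Each replicate's random streams are spawned
  deterministically from the root seed (`numpy.random.SeedSequence`), so any
  single replicate is reproducible in isolation and results are bit-for-bit
  stable for a given seed.
- **Permutation scheme.** Random permutations are sampled with replacement
  from the symmetric group (standard Monte Carlo permutation testing), with
  `A = 1000` by default. No early stopping: a fixed-`A` scheme keeps the
  p-value distribution simple and the runtime predictable.
- **Problem sizes.** The packaged test suite runs the calibration checks at
  a reduced scale (300 null replicates or 150 power replicates, 500
  permutations per test) — large enough for three-standard-error bands to
  be meaningful while the whole suite finishes in seconds; the acceptance
  script runs the full 1000-replicate, 1000-permutation study.
- **Percentile convention.** Cut points are the literal 20/30/40th sample
  percentiles (`numpy.quantile` with linear interpolation); the alternative
  reading (group proportions 20/30/40/10) was considered and rejected as
  inconsistent with cutting at three stated percentiles.
- **Monotonicity checking.** Estimated power is compared across the `d`
  grid allowing two combined standard errors of Monte Carlo slack per step,
  with the overall d = 0.2 → 0.8 increase required to exceed three combined
  standard errors; demanding strict pairwise significance would fail
  spuriously once power saturates near 1.
- **Binning convention.** Continuous phenotypes are binned with left-closed
  intervals: the level of `v` is the number of cut points `c ≤ v`, matching
  the blood-pressure convention (e.g. DBP = 90 with cuts 60/80/90 is level
  3). The simulation's percentile cuts use the opposite tie direction
  (ties to the lower level) because there the cuts are data-derived order
  statistics; with a continuous trait, ties have probability zero.

## Known limitations

- The test takes no covariates; confounded designs need residualisation
  before binning, outside this package's scope.
- Power degrades when causal effects point in opposing directions, since a
  single monotone score cannot represent them.
- Multi-allelic and sex-chromosome variants are rejected rather than
  handled; split multi-allelic records upstream.
- The permutation cost grows linearly in `A` and in the number of regions;
  no genome-wide parallelisation is built in beyond per-region iteration.
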