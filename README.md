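# ovrv — permutation gamma tests for ordinal rare-variant association

`ovrv` tests whether a group of rare genetic variants shows a monotone trend
association with an ordinal phenotype (for example a disease-severity grade,
or diastolic blood pressure binned into clinical levels). It is aimed at
statistical geneticists running region-based (gene-based) rare-variant
association scans where both the collapsed genotype and the phenotype are
ordered categorical variables.

## The method

For each subject the minor-allele counts `G_ij ∈ {0, 1, 2}` across the `m`
variants of a region are collapsed into a genetic score — by default the
number of variants at which the subject carries at least one minor allele,

    S_i = Σ_j 1(G_ij > 0),

optionally with per-variant weights or the raw allele-count (identity) link.
The distinct scores, sorted ascending, define an ordinal genotype variable
`G` with levels `0 … J−1`; the phenotype `Y` has levels `0 … I−1`. Their
association is measured by the Goodman–Kruskal gamma. With `C` and `D` the
total numbers of concordant and discordant subject pairs (pairs tied on
either variable count toward neither),

    γ̂ = (C − D) / (C + D),

the sample version of γ = (Π_c − Π_d)/(Π_c + Π_d). Because rare variants
leave the `I × J` cross-contingency table extremely sparse, the classical
normal approximation for γ̂ is unreliable; instead the null distribution is
estimated Fisher-style by recomputing γ̂ for `A` random permutations of the
phenotype vector, and the test reports the two-sided add-one permutation
p-value

    p = (1 + #{a : |γ̂⁽ᵃ⁾| ≥ |γ̂_obs|}) / (A + 1).

A built-in simulation module generates synthetic studies with the designed
statistical structure (Hardy–Weinberg genotypes with MAFs ~ U(0.001, 0.01),
a linear intermediate trait with a fixed causal pattern, percentile
discretization into four phenotype levels) to estimate type-I error and
power.

## Worked example

`examples/region_association_test.py` simulates a 500-subject region of 20
rare variants with a true increasing trend (effect magnitude d = 0.6) and
runs the test:

```
region of 20 rare variants, 500 subjects, effect magnitude d = 0.6
observed gamma = +0.2031 (C = 14101, D = 9341)
permutation p-value (A = 999) = 0.0230
```

Of the untied subject pairs, 14101 are concordant (the subject with the
higher carrier count also has the higher phenotype level) against 9341
discordant, giving γ̂ ≈ +0.20 — a modest increasing trend — which only 2.2%
of random phenotype permutations matched or exceeded in absolute value, so
the region is flagged at the 5% level. The other examples show the gamma
computation on a hand-checkable table and the type-I error / power
simulation; each prints a line explaining its numbers.

The same analysis runs from the shell on VCF or TSV inputs:

```sh
ovrv test --genotypes cohort.vcf --phenotypes dbp.tsv \
     --regions genes.tsv --cut-points 60,80,90 --seed 1
ovrv simulate --config sim.yaml --out rates.tsv
```

`--cut-points 60,80,90` reproduces the diastolic blood pressure convention
(DBP < 60 → level 0, 60 ≤ DBP < 80 → 1, 80 ≤ DBP < 90 → 2, DBP ≥ 90 → 3).

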