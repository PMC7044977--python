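"""Concordance counting and the gamma statistic on a small table.

Builds the cross-contingency table of an ordinal phenotype (rows) by an
ordinal genotype score (columns) and computes the Goodman-Kruskal gamma.
"""

from ovrv import OrdinalVector, build_contingency_table, gamma_statistic

phenotype = OrdinalVector.from_codes([0, 0, 0, 0, 1, 1, 1, 1, 1, 1])
score = OrdinalVector.from_codes([0, 0, 0, 1, 0, 0, 1, 1, 1, 1])

table = build_contingency_table(phenotype, score)
print("contingency table (phenotype x score):")
print(table.counts)

result = gamma_statistic(table)
print(f"concordant pairs C = {result.C}, discordant pairs D = {result.D}")
print(f"gamma = (C - D) / (C + D) = {result.gamma:+.4f}")

# gamma near +1 means subjects with higher scores tend to have higher
# phenotype levels; near -1 the trend is decreasing; near 0, no trend.
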