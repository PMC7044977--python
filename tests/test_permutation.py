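"""The permutation null, the empirical p-value and the full region test."""

import itertools

import numpy as np
import pytest

from ovrv.collapse import GenotypeMatrix, ScoreConfig
from ovrv.ordinal import GammaResult, OrdinalVector, build_contingency_table, gamma_statistic
from ovrv.permutation import (
    ecdf_estimate,
    empirical_pvalue,
    ov_rv_test,
    permutation_null,
)

from conftest import gamma_bruteforce


class TestPermutationNull:
    def test_constant_phenotype_gives_all_degenerate_zeros(self):
        y = OrdinalVector.from_codes([2] * 10)
        g = OrdinalVector.from_codes([0, 1] * 5)
        null = permutation_null(y, g, A=50, seed=0)
        assert np.all(null == 0.0)

    def test_two_distinct_subjects_force_unit_gammas(self):
        y = OrdinalVector.from_codes([0, 1])
        g = OrdinalVector.from_codes([0, 1])
        null = permutation_null(y, g, A=200, seed=1)
        assert set(np.unique(null)) <= {-1.0, 1.0}

    def test_reproducible_bit_for_bit(self):
        y = OrdinalVector.from_codes([0, 1, 2, 3, 0, 1, 2, 3])
        g = OrdinalVector.from_codes([0, 0, 1, 1, 0, 1, 0, 1])
        a = permutation_null(y, g, A=500, seed=42)
        b = permutation_null(y, g, A=500, seed=42)
        assert np.array_equal(a, b)

    def test_matches_exhaustive_enumeration_for_small_n(self):
        """The Monte Carlo null CDF at n = 5 agrees with the exact
        distribution over all 5! phenotype orderings."""
        y_codes = np.array([0, 0, 1, 2, 2])
        g_codes = np.array([0, 1, 0, 1, 1])
        exact = np.sort([
            gamma_bruteforce(np.array(p), g_codes)
            for p in itertools.permutations(y_codes)
        ])
        y = OrdinalVector.from_codes(y_codes)
        g = OrdinalVector.from_codes(g_codes)
        mc = np.sort(permutation_null(y, g, A=20_000, seed=9))
        grid = np.unique(exact)
        exact_cdf = np.searchsorted(exact, grid, side="right") / exact.size
        mc_cdf = np.searchsorted(mc, grid, side="right") / mc.size
        assert np.max(np.abs(exact_cdf - mc_cdf)) < 0.015

    def test_permuting_genotype_instead_gives_same_null_in_law(self):
        """Permuting either margin breaks the pairing the same way, so the
        two null distributions coincide (compared on n = 5 by enumeration)."""
        y_codes = np.array([0, 1, 1, 2, 3])
        g_codes = np.array([0, 0, 1, 1, 2])
        by_y = sorted(
            gamma_bruteforce(np.array(p), g_codes)
            for p in itertools.permutations(y_codes)
        )
        by_g = sorted(
            gamma_bruteforce(y_codes, np.array(p))
            for p in itertools.permutations(g_codes)
        )
        assert np.allclose(by_y, by_g)


class TestEcdf:
    def test_counts_at_and_below_x(self):
        assert ecdf_estimate(np.array([-0.5, 0.0, 0.5]), 0.0) == pytest.approx(2 / 3)

    def test_boundaries(self):
        null = np.array([-0.2, 0.1, 0.4])
        assert ecdf_estimate(null, -1.0) == 0.0
        assert ecdf_estimate(null, 0.4) == 1.0

    def test_median_of_odd_sample(self, rng):
        null = rng.normal(size=101)
        med = np.median(null)
        assert ecdf_estimate(null, med) == pytest.approx((101 + 1) / (2 * 101))

    def test_right_continuous_and_nondecreasing(self, rng):
        null = rng.choice([-0.5, 0.0, 0.5], size=200)
        xs = np.linspace(-1.2, 1.2, 97)
        vals = [ecdf_estimate(null, x) for x in xs]
        assert all(b >= a for a, b in zip(vals, vals[1:]))


class TestEmpiricalPvalue:
    def test_add_one_two_sided_count(self):
        obs = GammaResult(C=9, D=1, gamma=0.9, defined=True)
        assert empirical_pvalue(obs, np.array([0.1, -0.2, 0.05])) == 0.25

    def test_zero_observed_gamma_never_rejects(self):
        obs = GammaResult(C=5, D=5, gamma=0.0, defined=True)
        assert empirical_pvalue(obs, np.array([0.3, -0.1, 0.0, 0.9])) == 1.0

    def test_undefined_observed_returns_one(self):
        obs = GammaResult(C=0, D=0, gamma=0.0, defined=False)
        assert empirical_pvalue(obs, np.array([0.5, 0.7])) == 1.0


def hwe_matrix(rng, n=60, m=8, maf=0.3):
    counts = rng.binomial(2, maf, size=(n, m)).astype(float)
    return GenotypeMatrix(
        counts=counts,
        mafs=np.full(m, maf),
        variant_ids=tuple(f"v{j}" for j in range(m)),
    )


class TestOvRvTest:
    def test_perfectly_concordant_phenotype_attains_minimal_pvalue(self, rng):
        from ovrv.collapse import genetic_score, ordinal_encode

        g = hwe_matrix(rng)
        score = ordinal_encode(genetic_score(g, ScoreConfig(maf_threshold=0.5)))
        assert score.n_levels >= 3  # informative region
        result = ov_rv_test(
            score, g, ScoreConfig(maf_threshold=0.5), A=999, seed=4
        )
        assert result.observed.gamma == 1.0
        assert result.p_value == pytest.approx(1 / 1000)

    def test_monomorphic_region_is_degenerate_with_p_one(self):
        g = GenotypeMatrix(
            counts=np.zeros((12, 3)),
            mafs=np.full(3, 0.01),
            variant_ids=("a", "b", "c"),
        )
        y = OrdinalVector.from_codes([0, 1, 2, 3] * 3)
        result = ov_rv_test(y, g, A=99, seed=0)
        assert not result.observed.defined
        assert result.p_value == 1.0

    def test_empty_region_after_maf_filter_flags_and_reports_p_one(self, rng):
        g = hwe_matrix(rng, maf=0.3)
        y = OrdinalVector.from_codes(list(range(4)) * 15)
        result = ov_rv_test(y, g, ScoreConfig(maf_threshold=0.05), A=99, seed=0)
        assert result.empty_region
        assert result.p_value == 1.0

    def test_identical_inputs_and_seed_reproduce_bitwise(self, rng):
        g = hwe_matrix(rng)
        y = OrdinalVector.from_codes(list(rng.integers(0, 4, size=g.n_subjects)))
        cfg = ScoreConfig(maf_threshold=0.5)
        r1 = ov_rv_test(y, g, cfg, A=300, seed=77)
        r2 = ov_rv_test(y, g, cfg, A=300, seed=77)
        assert r1.p_value == r2.p_value
        assert np.array_equal(r1.null_gammas, r2.null_gammas)

    def test_pvalue_within_permutation_bounds(self, rng):
        g = hwe_matrix(rng)
        y = OrdinalVector.from_codes(list(rng.integers(0, 4, size=g.n_subjects)))
        result = ov_rv_test(y, g, ScoreConfig(maf_threshold=0.5), A=199, seed=5)
        assert 1 / 200 <= result.p_value <= 1.0
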