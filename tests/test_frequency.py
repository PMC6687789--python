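"""Contingency tables, chi-square with contributions, Monte-Carlo test."""

import itertools

import numpy as np
import pytest
from scipy import stats as sstats

from vmclust import (
    ContingencyTable,
    ValidationError,
    build_table,
    chi_square,
    frequency_report,
    monte_carlo_p,
)
from vmclust.datasets import load_shape_counts, load_shape_magnitude_counts


class TestBuildTable:
    def test_counts_and_ordering(self):
        pairs = [("boy1", "early_peak"), ("boy1", "early_peak"), ("girl1", "peak")]
        t = build_table(pairs)
        assert t.row_labels == ["boy1", "girl1"]
        assert t.col_labels == ["early_peak", "peak"]
        np.testing.assert_array_equal(t.counts, [[2, 0], [0, 1]])

    def test_grand_total_conservation(self, rng):
        pairs = [(f"g{rng.integers(3)}", f"c{rng.integers(4)}") for _ in range(137)]
        assert build_table(pairs).grand_total == 137

    def test_fixture_row_margins_match_cohort_sizes(self):
        t = load_shape_counts()
        assert t.row_totals.tolist() == [1512, 2502, 364, 419]
        assert t.grand_total == 4797

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            build_table([])


class TestChiSquare:
    def test_independence_gives_zero(self):
        t = ContingencyTable(["a", "b"], ["x", "y"], np.outer([40, 60], [30, 70]) // 100)
        r = chi_square(t)
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_asymptotic == pytest.approx(1.0)

    def test_two_by_two_closed_form(self):
        r = chi_square(ContingencyTable(["a", "b"], ["x", "y"], np.array([[10, 20], [20, 10]])))
        assert r.statistic == pytest.approx(20 / 3)
        assert r.df == 1

    def test_contributions_sum_to_statistic(self):
        t = load_shape_magnitude_counts()
        r = chi_square(t)
        assert r.contributions.sum() == pytest.approx(r.statistic, rel=1e-9)

    def test_expected_margins_match_observed(self):
        t = load_shape_counts()
        r = chi_square(t)
        np.testing.assert_allclose(r.expected.sum(axis=1), t.row_totals, rtol=1e-9)
        np.testing.assert_allclose(r.expected.sum(axis=0), t.col_totals, rtol=1e-9)

    def test_matches_scipy_chi2_contingency(self):
        t = load_shape_counts()
        r = chi_square(t)
        ref = sstats.chi2_contingency(t.counts, correction=False)
        assert r.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert r.p_asymptotic == pytest.approx(ref.pvalue, rel=1e-9)
        assert r.df == ref.dof

    def test_permutation_invariance(self, rng):
        t = load_shape_counts()
        rp = rng.permutation(4)
        cp = rng.permutation(6)
        permuted = ContingencyTable(
            [t.row_labels[i] for i in rp],
            [t.col_labels[j] for j in cp],
            t.counts[np.ix_(rp, cp)],
        )
        assert chi_square(permuted).statistic == pytest.approx(chi_square(t).statistic)

    def test_all_zero_column_errors_or_drops(self):
        counts = np.array([[5, 0, 3], [2, 0, 4]])
        t = ContingencyTable(["a", "b"], ["x", "y", "z"], counts)
        with pytest.raises(ValidationError):
            chi_square(t)
        r = chi_square(t, on_empty="drop")
        assert r.df == 1


class TestMonteCarlo:
    def test_independent_table_p_is_one(self):
        # an exactly independent table: counts equal the margin outer product / N
        t = ContingencyTable(["a", "b"], ["x", "y"], np.array([[12, 28], [18, 42]]))
        assert chi_square(t).statistic == pytest.approx(0.0, abs=1e-12)
        assert monte_carlo_p(t, n_sim=999, seed=0) == 1.0

    def test_margins_preserved_on_every_draw(self):
        t = load_shape_counts()
        sampler = sstats.random_table(t.row_totals, t.col_totals)
        sims = sampler.rvs(200, method="patefield", random_state=np.random.default_rng(0))
        np.testing.assert_array_equal(sims.sum(axis=2), np.tile(t.row_totals, (200, 1)))
        np.testing.assert_array_equal(sims.sum(axis=1), np.tile(t.col_totals, (200, 1)))

    def test_small_table_against_full_enumeration(self):
        """2x2 with margins (3,3)/(3,3): p matches exact conditional enumeration."""
        observed = ContingencyTable(["r1", "r2"], ["c1", "c2"], np.array([[3, 0], [0, 3]]))
        obs_stat = chi_square(observed).statistic
        # enumerate all tables with these margins (cell (0,0) = 0..3),
        # weighted by the multivariate hypergeometric probability
        p_exact = 0.0
        for a in range(4):
            tab = np.array([[a, 3 - a], [3 - a, a]])
            prob = (
                sstats.hypergeom.pmf(a, 6, 3, 3)
            )
            stat = ((tab - chi_square(observed).expected) ** 2 / chi_square(observed).expected).sum()
            if stat >= obs_stat - 1e-12:
                p_exact += prob
        p_mc = monte_carlo_p(observed, n_sim=10_000, seed=42)
        se = np.sqrt(p_exact * (1 - p_exact) / 10_000)
        assert abs(p_mc - p_exact) < 3 * se + 2e-4

    def test_agrees_with_asymptotic_on_well_populated_table(self, rng):
        counts = rng.integers(20, 80, size=(4, 6))
        t = ContingencyTable(list("abcd"), list("uvwxyz"), counts)
        r = chi_square(t)
        p_mc = monte_carlo_p(t, n_sim=20_000, seed=7)
        assert abs(p_mc - r.p_asymptotic) < 0.02 + 3 * np.sqrt(p_mc * (1 - p_mc) / 20_000)

    def test_reproducible_under_seed(self):
        t = load_shape_counts()
        assert monte_carlo_p(t, 999, seed=5) == monte_carlo_p(t, 999, seed=5)

    def test_n_sim_floor(self):
        t = load_shape_counts()
        with pytest.raises(ValidationError):
            monte_carlo_p(t, n_sim=10)


class TestFrequencyReport:
    def test_single_column_all_hundred(self):
        t = ContingencyTable(["a", "b"], ["x"], np.array([[5], [9]]))
        assert (frequency_report(t)["x"] == 100.0).all()

    def test_rows_sum_to_hundred(self):
        rep = frequency_report(load_shape_counts())
        np.testing.assert_allclose(rep.sum(axis=1), 100.0, rtol=1e-12)

    def test_zero_row_flagged_as_nan(self):
        t = ContingencyTable(["a", "b"], ["x", "y"], np.array([[0, 0], [3, 1]]))
        rep = frequency_report(t)
        assert rep.loc["a"].isna().all()
        assert rep.loc["b", "x"] == 75.0
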