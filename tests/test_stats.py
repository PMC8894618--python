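"""Exact 2x2 tests against independent oracles.

The implementation computes Fisher, chi-square and binomial quantities
from first principles (exact rationals, erfc identity); every routine is
checked here against an independent route: a factorial-based
hypergeometric enumeration, scipy's reference statistics, and numeric
integration of the chi-square density.
"""

from fractions import Fraction
from math import comb, factorial, isclose

import pytest
import scipy.stats
from hypothesis import given
from hypothesis import strategies as st

from degconcord.correspondence import ContingencyTable
from degconcord.errors import UndefinedMarginError
from degconcord.stats import (
    binomial_tail,
    chi2_sf_df1,
    fisher_exact_two_sided,
    pearson_chi2,
    run_all_tests,
)

PUBLISHED_TABLE = ContingencyTable(16, 4, 9, 11)


def fisher_oracle(a: int, b: int, c: int, d: int) -> Fraction:
    """Brute-force two-sided Fisher p: enumerate every 2x2 table with the
    observed margins and sum the point probabilities not exceeding the
    observed one.  Exact rationals throughout, factorial formula (a route
    independent of the implementation's comb-based pmf)."""

    def pmf(w, x, y, z) -> Fraction:
        n = w + x + y + z
        num = (
            factorial(w + x) * factorial(y + z) * factorial(w + y) * factorial(x + z)
        )
        den = factorial(n) * factorial(w) * factorial(x) * factorial(y) * factorial(z)
        return Fraction(num, den)

    p_obs = pmf(a, b, c, d)
    cutoff = p_obs * (1 + Fraction(1, 10**7))
    total = Fraction(0)
    for w in range(a + b + 1):
        x = a + b - w
        y = a + c - w
        z = d - a + w
        if x < 0 or y < 0 or z < 0:
            continue
        p = pmf(w, x, y, z)
        if p <= cutoff:
            total += p
    return total


TABLES = st.tuples(
    st.integers(0, 15), st.integers(0, 15), st.integers(0, 15), st.integers(0, 15)
).filter(lambda t: min(t[0] + t[1], t[2] + t[3], t[0] + t[2], t[1] + t[3]) > 0)


class TestFisher:
    def test_published_table(self):
        p = fisher_exact_two_sided(PUBLISHED_TABLE)
        assert isclose(p, 1609 / 33263, rel_tol=0, abs_tol=1e-15)
        assert round(p, 4) == 0.0484
        assert p <= 0.05

    def test_balanced_table_is_one(self):
        assert fisher_exact_two_sided(ContingencyTable(1, 1, 1, 1)) == 1.0

    @pytest.mark.parametrize("cells", [(0, 0, 1, 1), (1, 0, 1, 0), (0, 1, 0, 1)])
    def test_zero_margin_rejected(self, cells):
        with pytest.raises(UndefinedMarginError):
            fisher_exact_two_sided(ContingencyTable(*cells))

    @given(TABLES)
    def test_matches_enumeration_oracle(self, cells):
        p = fisher_exact_two_sided(ContingencyTable(*cells))
        assert abs(p - float(fisher_oracle(*cells))) <= 1e-12

    @given(TABLES)
    def test_matches_scipy(self, cells):
        a, b, c, d = cells
        expected = scipy.stats.fisher_exact([[a, b], [c, d]]).pvalue
        assert isclose(
            fisher_exact_two_sided(ContingencyTable(*cells)), expected, rel_tol=1e-9
        )


class TestPearsonChi2:
    def test_published_table_uncorrected(self):
        stat, p = pearson_chi2(PUBLISHED_TABLE)
        assert isclose(stat, 40 * (16 * 11 - 4 * 9) ** 2 / (20 * 20 * 25 * 15))
        assert round(stat, 4) == 5.2267
        assert round(p, 4) == 0.0222
        assert p <= 0.05

    def test_published_table_yates_closed_form(self):
        stat, _ = pearson_chi2(PUBLISHED_TABLE, yates=True)
        assert stat == pytest.approx(3.84, abs=1e-12)  # 40*120^2/150000

    @pytest.mark.parametrize("k", [1, 2, 5, 10])
    def test_independent_table_has_zero_statistic(self, k):
        stat, p = pearson_chi2(ContingencyTable(k, k, k, k))
        assert stat == 0.0
        assert p == 1.0

    @given(TABLES, st.booleans())
    def test_matches_scipy_contingency(self, cells, yates):
        a, b, c, d = cells
        stat, p = pearson_chi2(ContingencyTable(*cells), yates=yates)
        ref_stat, ref_p, _, _ = scipy.stats.chi2_contingency(
            [[a, b], [c, d]], correction=yates
        )
        assert isclose(stat, ref_stat, rel_tol=1e-12, abs_tol=1e-12)
        assert isclose(p, ref_p, rel_tol=1e-10, abs_tol=1e-12)

    @given(TABLES)
    def test_yates_never_exceeds_uncorrected(self, cells):
        t = ContingencyTable(*cells)
        assert pearson_chi2(t, yates=True)[0] <= pearson_chi2(t, yates=False)[0]

    @pytest.mark.parametrize("x", [0.0, 0.01, 0.5, 1.0, 2.5, 3.84, 5.2267, 10.0, 25.0])
    def test_sf_matches_scipy_chi2(self, x):
        assert isclose(
            chi2_sf_df1(x), scipy.stats.chi2.sf(x, df=1), rel_tol=1e-12, abs_tol=1e-300
        )


class TestBinomialTail:
    def test_published_domestic_tail(self):
        p = binomial_tail(16, 20, 0.5)
        assert p == 6196 / 1048576
        assert p <= 0.01

    def test_published_wild_tail(self):
        p = binomial_tail(11, 20, 0.5)
        assert p == 431910 / 1048576
        # symmetry identity: (1 - C(20,10)/2^20) / 2
        assert p == (1 - comb(20, 10) / 2**20) / 2
        assert p >= 0.4

    def test_whole_support(self):
        assert binomial_tail(0, 20, 0.5) == 1.0
        assert binomial_tail(0, 7, 0.123) == 1.0

    @given(st.integers(0, 30), st.integers(1, 30), st.floats(0.01, 0.99))
    def test_complement_identity_and_monotonicity(self, k, n, p0):
        k = min(k, n)
        upper = binomial_tail(k, n, p0)
        if k > 0:
            lower = sum(
                comb(n, j) * Fraction(p0) ** j * (1 - Fraction(p0)) ** (n - j)
                for j in range(0, k)
            )
            assert upper + float(lower) == pytest.approx(1.0, abs=1e-15)
            assert binomial_tail(k - 1, n, p0) >= upper

    @given(st.integers(1, 25), st.integers(0, 25))
    def test_matches_scipy_binomtest(self, n, k):
        k = min(k, n)
        ref = scipy.stats.binomtest(k, n, 0.5, alternative="greater").pvalue
        assert isclose(binomial_tail(k, n, 0.5), ref, rel_tol=1e-12)

    @pytest.mark.parametrize(
        ("k", "n", "p0"), [(-1, 10, 0.5), (11, 10, 0.5), (5, 10, 0.0), (5, 10, 1.0)]
    )
    def test_domain_errors(self, k, n, p0):
        with pytest.raises(ValueError):
            binomial_tail(k, n, p0)


class TestRunAllTests:
    def test_published_table_meets_all_reported_bounds(self):
        report = run_all_tests(PUBLISHED_TABLE)
        assert report.fisher_p <= 0.05
        assert report.chi2_p <= 0.05
        assert report.binom_p_domestic <= 0.01
        assert report.binom_p_wild >= 0.4
        assert report.chi2_yates_stat <= report.chi2_stat

    def test_perfectly_balanced_table(self):
        report = run_all_tests(ContingencyTable(10, 10, 10, 10))
        assert report.fisher_p == 1.0
        assert report.chi2_stat == 0.0
        expected_tie_tail = (1 + comb(20, 10) / 2**20) / 2
        assert report.binom_p_domestic == pytest.approx(expected_tie_tail, abs=1e-15)
        assert report.binom_p_wild == pytest.approx(expected_tie_tail, abs=1e-15)

    def test_zero_margin_propagates(self):
        with pytest.raises(UndefinedMarginError):
            run_all_tests(ContingencyTable(5, 5, 0, 0))

    @given(TABLES)
    def test_all_probabilities_in_unit_interval(self, cells):
        report = run_all_tests(ContingencyTable(*cells))
        for p in (
            report.fisher_p,
            report.chi2_p,
            report.chi2_yates_p,
            report.binom_p_domestic,
            report.binom_p_wild,
        ):
            assert 0.0 <= p <= 1.0
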