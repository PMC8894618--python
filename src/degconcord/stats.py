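"""Exact tests for the 2x2 lineage x effect table, from first principles.

Three tests are computed on the final contingency table:

* **Fisher's exact test**, two-sided by the point-probability rule: the
  p-value is the sum of hypergeometric probabilities, over all tables
  with the observed margins, of the tables whose point probability does
  not exceed that of the observed table.  Probabilities are exact
  rationals (``fractions.Fraction`` over integer binomial coefficients),
  so the sum involves no floating-point cancellation; a small relative
  cushion on the comparison guards the <= rule against ties that are
  exact in rational arithmetic but would be ambiguous in floats.

* **Pearson's chi-square test** on 1 degree of freedom, in the closed
  form N(ad - bc)^2 / (r1 r2 c1 c2), optionally with the Yates
  continuity correction (|ad - bc| reduced by N/2, floored at zero,
  before squaring).  The upper-tail probability of the chi-square(1) law
  is computed through the complementary error function identity
  p = erfc(sqrt(x/2)).

* **Exact binomial tail** per lineage: P(X >= k) under Binomial(n, p0),
  summed from exact binomial coefficients, with k the majority cell of
  the lineage's row and p0 = 1/2 — a one-sided sign test of whether a
  lineage's expression changes preferentially track one effect
  direction.

All three require every row and column margin to be positive; an empty
margin makes the tests undefined and raises.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from fractions import Fraction
from math import comb, erfc, sqrt
from pathlib import Path

from .correspondence import ContingencyTable
from .errors import UndefinedMarginError

#: Relative cushion on the point-probability comparison in the two-sided
#: Fisher rule: tables with pmf <= pmf_obs * (1 + FISHER_REL_TOL) are
#: included in the tail.
FISHER_REL_TOL = 1e-7


@dataclass(frozen=True)
class StatReport:
    """All test results for one 2x2 table."""

    fisher_p: float
    chi2_stat: float
    chi2_p: float
    chi2_yates_stat: float
    chi2_yates_p: float
    binom_p_domestic: float
    binom_p_wild: float

    def to_dict(self) -> dict:
        return {
            "fisher_p": self.fisher_p,
            "chi2_stat": self.chi2_stat,
            "chi2_p": self.chi2_p,
            "chi2_yates_stat": self.chi2_yates_stat,
            "chi2_yates_p": self.chi2_yates_p,
            "binom_p_domestic": self.binom_p_domestic,
            "binom_p_wild": self.binom_p_wild,
        }

    def to_json(self, table: ContingencyTable, path: str | Path) -> None:
        payload = {"contingency": table.to_dict(), "tests": self.to_dict()}
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _check_margins(t: ContingencyTable) -> None:
    if min(t.row_margins) == 0 or min(t.col_margins) == 0:
        raise UndefinedMarginError(
            f"2x2 tests are undefined on table {t.cells}: empty margin"
        )


def _hypergeom_pmf(a: int, r1: int, r2: int, c1: int) -> Fraction:
    """Exact probability of cell (1,1) == a given the margins."""
    return Fraction(comb(r1, a) * comb(r2, c1 - a), comb(r1 + r2, c1))


def fisher_exact_two_sided(t: ContingencyTable) -> float:
    """Two-sided Fisher exact p-value by the point-probability rule.

    Enumerates the full hypergeometric support of the observed margins
    in exact rational arithmetic.
    """
    _check_margins(t)
    a, b, c, d = t.cells
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = _hypergeom_pmf(a, r1, r2, c1)
    cutoff = p_obs * (1 + Fraction(FISHER_REL_TOL))
    total = Fraction(0)
    for x in range(lo, hi + 1):
        p = _hypergeom_pmf(x, r1, r2, c1)
        if p <= cutoff:
            total += p
    return float(min(total, Fraction(1)))


def chi2_sf_df1(x: float) -> float:
    """Upper-tail probability of the chi-square law with one degree of
    freedom, via p = erfc(sqrt(x/2))."""
    if x < 0:
        raise ValueError(f"chi-square statistic must be >= 0, got {x}")
    return erfc(sqrt(x / 2.0))


def pearson_chi2(t: ContingencyTable, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square statistic and p-value (df = 1) for a 2x2 table.

    With ``yates`` the continuity correction reduces |ad - bc| by N/2
    (floored at zero) before squaring, so the corrected statistic never
    exceeds the uncorrected one.
    """
    _check_margins(t)
    a, b, c, d = t.cells
    n = a + b + c + d
    r1, r2 = t.row_margins
    c1, c2 = t.col_margins
    delta = abs(a * d - b * c)
    if yates:
        delta = max(delta - n / 2.0, 0.0)
    stat = n * delta * delta / (r1 * r2 * c1 * c2)
    return stat, chi2_sf_df1(stat)


def binomial_tail(k: int, n: int, p0: float = 0.5) -> float:
    """Exact upper tail P(X >= k) under Binomial(n, p0).

    Summed from exact binomial coefficients with the null probability
    held as an exact rational, so P(X >= 0) is exactly 1 and the
    complementary identity P(X >= k) + P(X <= k-1) = 1 holds exactly.
    """
    if not (0 <= k <= n):
        raise ValueError(f"k must satisfy 0 <= k <= n, got k={k}, n={n}")
    if not (0.0 < p0 < 1.0):
        raise ValueError(f"null probability must lie in (0, 1), got {p0}")
    p = Fraction(p0)
    q = 1 - p
    total = sum(
        comb(n, j) * p**j * q ** (n - j) for j in range(k, n + 1)
    )
    return float(total)


def run_all_tests(t: ContingencyTable) -> StatReport:
    """Run all three tests on one table.

    Each lineage's binomial tail is one-sided on its majority cell:
    k = max of the two cells, n = their sum, p0 = 1/2.
    """
    _check_margins(t)
    fisher_p = fisher_exact_two_sided(t)
    chi2_stat, chi2_p = pearson_chi2(t, yates=False)
    yates_stat, yates_p = pearson_chi2(t, yates=True)
    n_dom = t.n_dom_decrease + t.n_dom_increase
    n_wild = t.n_wild_decrease + t.n_wild_increase
    return StatReport(
        fisher_p=fisher_p,
        chi2_stat=chi2_stat,
        chi2_p=chi2_p,
        chi2_yates_stat=yates_stat,
        chi2_yates_p=yates_p,
        binom_p_domestic=binomial_tail(
            max(t.n_dom_decrease, t.n_dom_increase), n_dom, 0.5
        ),
        binom_p_wild=binomial_tail(
            max(t.n_wild_decrease, t.n_wild_increase), n_wild, 0.5
        ),
    )
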