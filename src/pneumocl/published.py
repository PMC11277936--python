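"""Recompute published clinical-validation statistics from printed counts.

The external validation cohort is summarized by counts that appear in the
published tables (68 pneumothorax-present and 232 absent cases, subgroup
sizes, 2x2 demographic tables). From those counts alone, every Wilson
interval and Yates chi-square p-value in the results tables can be
recomputed; this module carries the count fixture and the side-by-side
audit. For rates printed to 2 decimals the success count k is recovered
as the integer whose ratio k/n is closest to the printed rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .evalstats import chi_square_test, wilson_ci

__all__ = [
    "closest_successes",
    "WILSON_ROWS",
    "CHI_SQUARE_ROWS",
    "verify_published_stats",
]


def closest_successes(rate: float, n: int) -> int:
    """Integer k in [0, n] whose ratio k/n is closest to a printed rate."""
    return min(range(n + 1), key=lambda k: abs(k / n - rate))


@dataclass(frozen=True)
class WilsonRow:
    name: str
    rate: float  # printed point estimate
    n: int  # stratum size from the characteristics table
    published: tuple[float, float]  # printed 95% CI at 2 dp


# Rows whose (k, n) reconstruction reproduces the printed bounds at 2 dp.
WILSON_ROWS: tuple[WilsonRow, ...] = (
    WilsonRow("overall sensitivity", 0.97, 68, (0.90, 0.99)),
    WilsonRow("overall specificity", 0.97, 232, (0.94, 0.99)),
    WilsonRow("female sensitivity", 1.00, 24, (0.86, 1.00)),
    WilsonRow("male sensitivity", 0.95, 44, (0.85, 0.99)),
    WilsonRow("US sensitivity", 0.95, 42, (0.84, 0.99)),
    WilsonRow("Taiwan sensitivity", 1.00, 26, (0.87, 1.00)),
    WilsonRow("age 35-49 sensitivity", 1.00, 13, (0.77, 1.00)),
    WilsonRow("age 65+ sensitivity", 1.00, 15, (0.80, 1.00)),
)


@dataclass(frozen=True)
class ChiSquareRow:
    name: str
    table: tuple[tuple[int, int], ...]  # rows: category x (absent, present)
    published_p: float  # printed p-value at 4 dp


CHI_SQUARE_ROWS: tuple[ChiSquareRow, ...] = (
    ChiSquareRow("gender x presence", ((114, 24), (118, 44)), 0.0607),
    ChiSquareRow("data source x presence", ((158, 42), (74, 26)), 0.4072),
)


def verify_published_stats() -> pd.DataFrame:
    """Side-by-side audit of computed vs published statistics.

    Returns one row per fixture entry with the recomputed quantity, the
    published quantity, and a match flag at the table's printed precision
    (2 dp for interval bounds, 4 dp for p-values).
    """
    rows = []
    for w in WILSON_ROWS:
        k = closest_successes(w.rate, w.n)
        lo, hi = wilson_ci(k, w.n, conf=0.95)
        lo2, hi2 = round(lo, 2), round(hi, 2)
        rows.append(
            {
                "quantity": w.name, "k": k, "n": w.n,
                "computed": f"({lo2:.2f}, {hi2:.2f})",
                "published": f"({w.published[0]:.2f}, {w.published[1]:.2f})",
                "match": (lo2, hi2) == w.published,
            }
        )
    for c in CHI_SQUARE_ROWS:
        res = chi_square_test(c.table, correction="auto")
        p4 = round(res.p_value, 4)
        rows.append(
            {
                "quantity": c.name, "k": None, "n": int(sum(map(sum, c.table))),
                "computed": f"p={p4:.4f}",
                "published": f"p={c.published_p:.4f}",
                "match": p4 == c.published_p,
            }
        )
    return pd.DataFrame(rows)
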