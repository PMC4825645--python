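"""Segregation goodness-of-fit tests and cohort summary tables.

Implements the Pearson chi-square test against a Mendelian ratio with two
expected-count conventions: EXACT fractional expecteds (the default for
new analyses), and PUBLISHED_INTEGER, where each expected count is rounded to
the nearest integer (repairing the largest cell so the total is
preserved), the convention used in the original screen's printed tables
(e.g. 281 split 1:2 as 94 and 187 rather than 93.67 and 187.33).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "Rounding",
    "GoodnessOfFitResult",
    "FamilySterileSummary",
    "expected_counts",
    "chi_square_gof",
    "segregation_test",
    "family_sterile_percent",
    "cohort_summary",
]

ALPHA = 0.05


class Rounding(str, enum.Enum):
    EXACT = "EXACT"
    PUBLISHED_INTEGER = "PUBLISHED_INTEGER"


@dataclass
class GoodnessOfFitResult:
    """A Pearson chi-square goodness-of-fit result.

    ``reject_null`` follows standard usage: True when the statistic
    exceeds the critical value, i.e. the observed counts deviate from the
    ratio more than chance allows.  ``consistent_with_ratio`` is its
    complement, the quantity a segregation analysis usually reports.
    """

    observed: list[int]
    expected: list[float]
    contributions: list[float] = field(init=False)
    chi_square: float = field(init=False)
    df: int = field(init=False)
    critical_value: float = field(init=False)
    reject_null: bool = field(init=False)

    def __post_init__(self) -> None:
        if len(self.observed) != len(self.expected):
            raise ValueError("observed and expected must have equal length")
        if any(e <= 0 for e in self.expected):
            raise ValueError("expected counts must be positive")
        self.contributions = [
            (o - e) ** 2 / e for o, e in zip(self.observed, self.expected)
        ]
        self.chi_square = float(sum(self.contributions))
        self.df = len(self.observed) - 1
        self.critical_value = float(sps.chi2.ppf(1 - ALPHA, self.df))
        self.reject_null = self.chi_square >= self.critical_value

    @property
    def consistent_with_ratio(self) -> bool:
        return not self.reject_null

    @property
    def p_value(self) -> float:
        return float(sps.chi2.sf(self.chi_square, self.df))

    def to_frame(self) -> pd.DataFrame:
        """Observed/expected/contribution table with a Total column."""
        return pd.DataFrame(
            {
                "Observed": self.observed + [sum(self.observed)],
                "Expected": self.expected + [sum(self.expected)],
                "(Obs-exp)^2/exp": self.contributions + [self.chi_square],
            },
            index=[f"class_{i}" for i in range(len(self.observed))] + ["Total"],
        )

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "expected": self.expected,
            "contributions": self.contributions,
            "chi_square": self.chi_square,
            "df": self.df,
            "critical_value": self.critical_value,
            "reject_null": self.reject_null,
            "consistent_with_ratio": self.consistent_with_ratio,
            "p_value": self.p_value,
        }


@dataclass
class FamilySterileSummary:
    """Per-family tallies of reared offspring of carrier parents."""

    family_id: str
    n_wildtype: int = 0
    n_star_plus: int = 0
    n_sterile: int = 0
    n_males: int = 0

    @property
    def percent_sterile_among_carrier_descended(self) -> float | None:
        return family_sterile_percent(self.n_sterile, self.n_star_plus)


def expected_counts(
    total: int,
    ratio: Sequence[float],
    rounding: Rounding | str = Rounding.EXACT,
) -> list[float]:
    """Split ``total`` across classes in proportion to ``ratio``.

    PUBLISHED_INTEGER rounds each expected count to the nearest integer, then
    adjusts the cell with the largest expectation so the rounded counts
    sum back to the total.
    """
    rounding = Rounding(rounding)
    if total <= 0:
        raise ValueError("total must be positive")
    if any(w <= 0 for w in ratio):
        raise ValueError("ratio weights must be positive")
    weights = np.asarray(ratio, dtype=float)
    exact = total * weights / weights.sum()
    if rounding is Rounding.EXACT:
        return [float(e) for e in exact]
    rounded = [int(round(e)) for e in exact]
    deficit = total - sum(rounded)
    if deficit:
        rounded[int(np.argmax(exact))] += deficit
    return [float(r) for r in rounded]


def chi_square_gof(
    observed: Sequence[int], expected: Sequence[float]
) -> GoodnessOfFitResult:
    """Pearson chi-square goodness of fit of observed vs expected counts."""
    return GoodnessOfFitResult(list(observed), list(expected))


def segregation_test(
    observed: Sequence[int],
    ratio: Sequence[float],
    rounding: Rounding | str = Rounding.EXACT,
) -> GoodnessOfFitResult:
    """Test observed class counts against a Mendelian ratio (e.g. 1:2, 3:1)."""
    total = int(sum(observed))
    return chi_square_gof(observed, expected_counts(total, ratio, rounding))


def family_sterile_percent(n_sterile: int, n_star_plus: int) -> float | None:
    """Percent of sterile fish among reared offspring of carrier parents:
    100 * s / (s + */+).  None (missing) when no such offspring exist."""
    if n_sterile < 0 or n_star_plus < 0:
        raise ValueError("counts must be nonnegative")
    denom = n_sterile + n_star_plus
    if denom == 0:
        return None
    return 100.0 * n_sterile / denom


def cohort_summary(
    records: pd.DataFrame,
    value_column: str,
    class_column: str,
    decimals: int | None = None,
) -> pd.DataFrame:
    """Sum / Mean / Range table of a count per classification class.

    ``records`` holds one row per individual with its class label and a
    numeric value (e.g. embryos scored).  Means are rounded to
    ``decimals`` when given; the Range row is formatted "lo-hi".
    """
    if records.empty:
        return pd.DataFrame(index=["Sum", "Mean", "Range"])
    out = {}
    groups = list(records.groupby(class_column, sort=False)) + [
        ("Total", records)
    ]
    for name, grp in groups:
        values = grp[value_column]
        mean = values.mean()
        if decimals is not None:
            mean = round(mean, decimals)
            if decimals == 0:
                mean = int(mean)
        out[name] = {
            "Sum": values.sum(),
            "Mean": mean,
            "Range": f"{values.min()}-{values.max()}",
        }
    return pd.DataFrame(out).reindex(["Sum", "Mean", "Range"])
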