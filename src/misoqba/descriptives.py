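"""Proportions, binomial confidence intervals, and frequency tables.

The default interval is the Wilson score interval without continuity
correction: inverting the score test gives

    (p̂ + z²/2n ± z·sqrt(p̂(1−p̂)/n + z²/4n²)) / (1 + z²/n)

which reproduces the published bounds of the primary effectiveness
endpoints at 1-decimal rounding.  Clopper–Pearson is available as an
alternative for small counts.

Percentages are rounded half-away-from-zero at one decimal, the
convention of the published tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional, Sequence

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

CI_METHODS = ("wilson", "clopper_pearson")
_SM_METHOD = {"wilson": "wilson", "clopper_pearson": "beta"}

POLICIES = ("missing_in_denominator", "missing_excluded")


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (5 rounds up in magnitude), as in the
    published tables, where Python's bankers rounding would differ."""
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(repr(x)).copy_abs().quantize(q, rounding=ROUND_HALF_UP)
    return float(d.copy_negate() if x < 0 else d)


def wilson_interval(numerator: int, denominator: int, alpha: float = 0.05):
    """Two-sided Wilson score interval (no continuity correction).

    Mirror-symmetric: ``wilson(x, n)`` reflects ``wilson(n-x, n)`` about
    0.5, and the lower bound is exactly 0 when ``numerator`` is 0.
    """
    _check_counts(numerator, denominator, alpha)
    lo, hi = proportion_confint(numerator, denominator, alpha=alpha, method="wilson")
    return float(lo), float(hi)


def clopper_pearson_interval(numerator: int, denominator: int, alpha: float = 0.05):
    """Exact (Clopper–Pearson) binomial interval."""
    _check_counts(numerator, denominator, alpha)
    lo, hi = proportion_confint(numerator, denominator, alpha=alpha, method="beta")
    return float(lo), float(hi)


def _check_counts(numerator, denominator, alpha):
    if denominator < 1:
        raise ValueError("denominator must be >= 1")
    if not 0 <= numerator <= denominator:
        raise ValueError("require 0 <= numerator <= denominator")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class EndpointResult:
    """A numerator/denominator proportion with its confidence interval."""

    numerator: int
    denominator: int
    proportion: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05
    method: str = "wilson"

    @property
    def percent(self) -> float:
        return round_half_away(100.0 * self.proportion, 1)

    def __str__(self) -> str:
        lo = round_half_away(100 * self.ci_low, 1)
        hi = round_half_away(100 * self.ci_high, 1)
        return (f"{self.numerator}/{self.denominator} = {self.percent}% "
                f"({100 * (1 - self.alpha):g}% CI, {lo}%-{hi}%)")


def proportion_ci(numerator: int, denominator: int, alpha: float = 0.05,
                  method: str = "wilson") -> EndpointResult:
    """Build an :class:`EndpointResult` for x successes out of n."""
    if method not in CI_METHODS:
        raise ValueError(f"unknown CI method {method!r}")
    fn = wilson_interval if method == "wilson" else clopper_pearson_interval
    lo, hi = fn(numerator, denominator, alpha)
    return EndpointResult(numerator, denominator, numerator / denominator,
                          lo, hi, alpha, method)


# ---------------------------------------------------------------------------
# Frequency tables


@dataclass
class FrequencyTable:
    """Labeled counts with percentages, optionally column-stratified.

    ``counts`` has one row per level of the row variable and one column per
    stratum (single column "all" when unstratified).  Percentages are
    computed against the policy denominator of each column.
    """

    row_variable: str
    counts: pd.DataFrame
    denominators: pd.Series
    policy: str = "missing_in_denominator"
    percentages: pd.DataFrame = field(init=False)

    def __post_init__(self):
        pct = 100.0 * self.counts.div(self.denominators, axis=1)
        self.percentages = pct.map(
            lambda v: round_half_away(v, 1) if pd.notna(v) else v)

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame: row level, stratum, count, percent."""
        cnt = self.counts.stack()
        pct = self.percentages.stack()
        out = pd.DataFrame({"count": cnt, "percent": pct}).reset_index()
        out.columns = [self.row_variable, "stratum", "count", "percent"]
        return out

    def to_text(self) -> str:
        """Aligned plain-text rendering ("count (percent)") per cell."""
        cols = list(self.counts.columns)
        body = []
        for lev in self.counts.index:
            cells = []
            for c in cols:
                n = self.counts.loc[lev, c]
                p = self.percentages.loc[lev, c]
                cells.append(f"{int(n)} ({p:.1f})" if pd.notna(p) else f"{int(n)}")
            body.append((str(lev), cells))
        hdr = [f"{c} (n={int(self.denominators[c])})" for c in cols]
        widths = [max(len(h), *(len(r[1][i]) for r in body)) for i, h in enumerate(hdr)]
        lw = max(len(self.row_variable), *(len(r[0]) for r in body))
        lines = [self.row_variable.ljust(lw) + "  " +
                 "  ".join(h.rjust(w) for h, w in zip(hdr, widths))]
        for lev, cells in body:
            lines.append(lev.ljust(lw) + "  " +
                         "  ".join(s.rjust(w) for s, w in zip(cells, widths)))
        return "\n".join(lines)


def tabulate(frame: pd.DataFrame, row_variable: str,
             strata: Optional[str] = None,
             policy: str = "missing_in_denominator",
             row_order: Optional[Sequence] = None) -> FrequencyTable:
    """Cross-tabulate a (derived) participant frame.

    With ``missing_in_denominator`` (descriptive default) missing values
    appear as a "missing" row and count toward column denominators; with
    ``missing_excluded`` (inferential default) they are dropped first.
    Invariant to record order.
    """
    if row_variable not in frame.columns:
        raise KeyError(f"unknown variable {row_variable!r}")
    if strata is not None and strata not in frame.columns:
        raise KeyError(f"unknown variable {strata!r}")
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}")

    col = frame[row_variable]
    if policy == "missing_excluded":
        keep = col.notna()
        frame, col = frame[keep], col[keep]
    else:
        col = col.astype(object).where(col.notna(), "missing")

    if frame.empty:
        counts = pd.DataFrame(columns=["all"], dtype=int)
        return FrequencyTable(row_variable, counts,
                              pd.Series({"all": pd.NA}), policy)

    if strata is None:
        tab = col.value_counts().to_frame("all")
    else:
        tab = pd.crosstab(col, frame[strata].astype(object))
    tab = tab.reindex(sorted(tab.index, key=str))  # mixed-type labels
    if row_order is not None:
        order = [r for r in row_order if r in tab.index]
        order += [r for r in tab.index if r not in order]
        tab = tab.loc[order]
    denoms = tab.sum(axis=0)
    return FrequencyTable(row_variable, tab.astype(int), denoms, policy)


def proportion_expelled_within(records, hours: float, alpha: float = 0.05,
                               method: str = "wilson") -> EndpointResult:
    """Proportion of the whole cohort with an observed expulsion within
    ``hours`` of the first dose.  Unobserved or missing expulsion times
    count as not-within; the denominator is all records."""
    if not hours > 0:
        raise ValueError("hours must be > 0")
    records = list(records)
    num = sum(1 for r in records
              if isinstance(r.time_to_expulsion_h, (int, float))
              and r.time_to_expulsion_h <= hours)
    return proportion_ci(num, len(records), alpha=alpha, method=method)
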