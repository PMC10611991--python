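"""Contingency-table tests for group comparisons.

Pearson chi-square of independence (no Yates correction by default) and
the Fisher exact test.  For 2x2 tables the Fisher p-value is the exact
two-sided probability-ordering p (sum of hypergeometric probabilities of
all tables with the observed margins whose point probability does not
exceed the observed table's).  For larger r x c tables an exact p is
computed by enumerating all tables with the observed margins when the
total count is small enough, falling back to Monte Carlo sampling of
margin-fixed tables otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

#: relative slack when comparing point probabilities for "at least as
#: extreme" — guards against floating-point ties
_REL_EPS = 1e-9

ALPHA = 0.05  # two-sided significance threshold used in reporting


@dataclass(frozen=True)
class ContingencyTable:
    """r x c nonnegative integer counts with labels."""

    counts: tuple
    row_labels: tuple = ()
    col_labels: tuple = ()

    @classmethod
    def from_array(cls, a, row_labels=None, col_labels=None) -> "ContingencyTable":
        arr = np.asarray(a)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError("need an r x c table with r >= 2 and c >= 2")
        if np.any(arr < 0):
            raise ValueError("counts must be nonnegative")
        if not np.all(arr == np.floor(arr)):
            raise ValueError("counts must be integers")
        arr = arr.astype(np.int64)
        if arr.sum() < 1:
            raise ValueError("table total must be >= 1")
        r, c = arr.shape
        rl = tuple(row_labels) if row_labels else tuple(f"r{i}" for i in range(r))
        cl = tuple(col_labels) if col_labels else tuple(f"c{j}" for j in range(c))
        return cls(tuple(map(tuple, arr.tolist())), rl, cl)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.int64)


@dataclass(frozen=True)
class TestResult:
    method: str                      # chi2 | fisher_exact | fisher_mc
    p_value: float
    statistic: Optional[float] = None
    df: Optional[int] = None
    n_mc: Optional[int] = None
    seed: Optional[int] = None

    @property
    def significant(self) -> bool:
        """Two-sided p below the conventional 0.05 threshold."""
        return self.p_value < ALPHA


def chi2_independence(table: ContingencyTable, yates: bool = False) -> TestResult:
    """Pearson chi-square test of independence.

    No continuity correction by default; ``df = (r-1)(c-1)``; upper-tail
    p-value.  Rejects tables with a zero row or column margin (expected
    counts undefined).
    """
    a = table.array
    if np.any(a.sum(axis=0) == 0) or np.any(a.sum(axis=1) == 0):
        raise ValueError("zero margin: expected counts undefined")
    res = stats.chi2_contingency(a, correction=yates)
    return TestResult(method="chi2", p_value=float(res.pvalue),
                      statistic=float(res.statistic), df=int(res.dof))


def fisher_exact(table: ContingencyTable, mc_threshold: int = 10_000,
                 n_mc: int = 1_000_000, seed: int = 0) -> TestResult:
    """Fisher exact test, two-sided by probability ordering.

    2x2 tables use the exact hypergeometric computation.  r x c tables
    with total count <= ``mc_threshold`` are enumerated exactly over all
    tables sharing the observed margins; larger tables get a Monte Carlo
    p from ``n_mc`` margin-fixed draws (add-one estimator), with the seed
    recorded in the result.
    """
    a = table.array
    if a.shape == (2, 2):
        p = float(stats.fisher_exact(a, alternative="two-sided").pvalue)
        return TestResult(method="fisher_exact", p_value=min(p, 1.0))
    if a.sum() <= mc_threshold:
        p = _exact_rxc(a)
        return TestResult(method="fisher_exact", p_value=p)
    p = _mc_rxc(a, n_mc=n_mc, seed=seed)
    return TestResult(method="fisher_mc", p_value=p, n_mc=n_mc, seed=seed)


# ---------------------------------------------------------------------------
# r x c exact enumeration


def _log_table_prob(a: np.ndarray, lgn: float, lg_margins: float) -> float:
    from scipy.special import gammaln
    return lg_margins - lgn - gammaln(a + 1.0).sum()


def _exact_rxc(a: np.ndarray) -> float:
    """Exact two-sided p for an r x c table: total probability of all
    tables with the observed margins whose probability is <= observed."""
    from scipy.special import gammaln

    rows = a.sum(axis=1)
    cols = a.sum(axis=0)
    n = int(a.sum())
    lg_margins = gammaln(rows + 1.0).sum() + gammaln(cols + 1.0).sum()
    lgn = gammaln(n + 1.0)
    lp_obs = _log_table_prob(a, lgn, lg_margins)
    cutoff = lp_obs + np.log1p(_REL_EPS)

    r, c = a.shape
    p_total = 0.0
    cell_lg = gammaln(np.arange(n + 2, dtype=float) + 1.0)  # log k! lookup

    def rec(i: int, col_rem: np.ndarray, lp_partial: float):
        nonlocal p_total
        if i == r - 1:
            # last row is forced by the remaining column margins
            lp = lp_partial - cell_lg[col_rem].sum()
            if lp <= cutoff:
                p_total += np.exp(lp)
            return
        ri = rows[i]
        row_cells = np.zeros(c, dtype=np.int64)

        def fill(j: int, rem: int, lp_row: float):
            if j == c - 1:
                if rem > col_rem[c - 1]:
                    return
                row_cells[j] = rem
                rec(i + 1, col_rem - row_cells, lp_row - cell_lg[rem])
                row_cells[j] = 0
                return
            hi = min(rem, col_rem[j])
            for k in range(hi + 1):
                row_cells[j] = k
                fill(j + 1, rem - k, lp_row - cell_lg[k])
            row_cells[j] = 0

        fill(0, int(ri), lp_partial)

    rec(0, cols.copy(), lg_margins - lgn)
    return float(min(p_total, 1.0))


def _mc_rxc(a: np.ndarray, n_mc: int, seed: int) -> float:
    """Monte Carlo two-sided p from margin-fixed random tables."""
    from scipy.special import gammaln

    rows = a.sum(axis=1)
    cols = a.sum(axis=0)
    n = int(a.sum())
    lg_margins = gammaln(rows + 1.0).sum() + gammaln(cols + 1.0).sum()
    lgn = gammaln(n + 1.0)
    lp_obs = _log_table_prob(a, lgn, lg_margins)
    cutoff = lp_obs + np.log1p(_REL_EPS)

    rng = np.random.default_rng(seed)
    rt = stats.random_table(rows, cols)
    hits = 0
    chunk = 50_000
    done = 0
    while done < n_mc:
        m = min(chunk, n_mc - done)
        draws = rt.rvs(size=m, random_state=rng)
        lps = lg_margins - lgn - gammaln(draws + 1.0).sum(axis=(1, 2))
        hits += int(np.count_nonzero(lps <= cutoff))
        done += m
    return (hits + 1) / (n_mc + 1)


# ---------------------------------------------------------------------------
# Convenience


def care_seeking_table(n_sought_warning: int, n_warning: int,
                       n_sought_no_warning: int, n_no_warning: int) -> ContingencyTable:
    """2x2 table of ever-sought-care by warning-sign status."""
    return ContingencyTable.from_array(
        [[n_sought_warning, n_warning - n_sought_warning],
         [n_sought_no_warning, n_no_warning - n_sought_no_warning]],
        row_labels=("warning_sign", "no_warning_sign"),
        col_labels=("sought_care", "did_not_seek_care"),
    )


def table_from_frame(frame, row_variable: str, col_variable: str,
                     policy: str = "missing_excluded") -> ContingencyTable:
    """Cross-tabulate two columns of a derived frame into a test-ready
    table; missing categories are dropped before testing by default."""
    import pandas as pd

    sub = frame[[row_variable, col_variable]]
    if policy == "missing_excluded":
        sub = sub.dropna()
    tab = pd.crosstab(sub[row_variable].astype(object),
                      sub[col_variable].astype(object))
    return ContingencyTable.from_array(
        tab.to_numpy(), row_labels=tab.index.tolist(),
        col_labels=tab.columns.tolist())
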