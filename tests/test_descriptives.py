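"""Wilson intervals against a score-equation root-finding oracle, rounding,
and frequency-table behaviour."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq
from scipy.stats import norm

from misoqba import (
    proportion_ci, round_half_away, tabulate, wilson_interval,
    clopper_pearson_interval, proportion_expelled_within,
)


def wilson_by_root_finding(x, n, alpha=0.05):
    """Independent oracle: invert the score test numerically.

    The bounds are the roots p of (p_hat - p)^2 = z^2 p(1-p)/n.
    """
    z = norm.ppf(1 - alpha / 2)
    p_hat = x / n

    def g(p):
        return (p_hat - p) ** 2 - z * z * p * (1 - p) / n

    # at the boundaries p_hat itself is a root of g, so bracket away from it
    lo = 0.0 if x == 0 else brentq(g, 1e-15, p_hat * (1 - 1e-12), xtol=1e-14)
    hi = (1.0 if x == n
          else brentq(g, p_hat + (1 - p_hat) * 1e-12, 1 - 1e-15, xtol=1e-14))
    return lo, hi


@pytest.mark.parametrize("n", [1, 2, 3, 5, 10, 37, 100, 250, 637, 1000])
def test_wilson_matches_root_finder_sweep(n):
    step = max(1, n // 25)
    for x in range(0, n + 1, step):
        lo, hi = wilson_interval(x, n)
        olo, ohi = wilson_by_root_finding(x, n)
        assert math.isclose(lo, olo, abs_tol=1e-10)
        assert math.isclose(hi, ohi, abs_tol=1e-10)


@settings(max_examples=150, deadline=None, derandomize=True)
@given(st.integers(1, 1000), st.data())
def test_wilson_matches_root_finder_property(n, data):
    x = data.draw(st.integers(0, n))
    lo, hi = wilson_interval(x, n)
    olo, ohi = wilson_by_root_finding(x, n)
    assert abs(lo - olo) < 1e-10 and abs(hi - ohi) < 1e-10


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.integers(1, 500), st.data())
def test_wilson_mirror_symmetry(n, data):
    x = data.draw(st.integers(0, n))
    lo, hi = wilson_interval(x, n)
    lo2, hi2 = wilson_interval(n - x, n)
    assert math.isclose(lo, 1 - hi2, abs_tol=1e-12)
    assert math.isclose(hi, 1 - lo2, abs_tol=1e-12)


def test_published_primary_bounds_at_one_decimal():
    for (x, n), want in (((625, 637), (96.7, 98.9)),
                         ((605, 635), (93.3, 96.7))):
        lo, hi = wilson_interval(x, n)
        assert (round_half_away(100 * lo, 1),
                round_half_away(100 * hi, 1)) == want


def test_zero_numerator_lower_bound_exact():
    assert wilson_interval(0, 10)[0] == 0.0


def test_degenerate_inputs_rejected():
    with pytest.raises(ValueError):
        wilson_interval(1, 0)
    with pytest.raises(ValueError):
        wilson_interval(5, 3)
    with pytest.raises(ValueError):
        proportion_ci(1, 2, method="jeffreys")


def test_clopper_pearson_contains_wilson_center():
    res = proportion_ci(625, 637, method="clopper_pearson")
    assert res.ci_low <= res.proportion <= res.ci_high
    assert clopper_pearson_interval(0, 10)[0] == 0.0


def test_round_half_away():
    assert round_half_away(0.25, 1) == 0.3
    assert round_half_away(-0.25, 1) == -0.3
    assert round_half_away(85.44, 1) == 85.4
    assert round_half_away(2.5, 0) == 3.0


# ---------------------------------------------------------------------------
# tabulate


def test_tabulate_reference_effectiveness(ref_frame):
    tab = tabulate(ref_frame, "eff_last")
    assert tab.counts.loc["complete_no_procedure", "all"] == 625
    assert tab.percentages.loc["complete_no_procedure", "all"] == 98.1
    assert int(tab.denominators["all"]) == 637


def test_tabulate_stratified_denominators(ref_frame):
    tab = tabulate(ref_frame, "eff_last", strata="duration_weeks")
    assert int(tab.denominators["lt7"]) == 317
    assert int(tab.denominators["12to16"]) == 23


def test_percentages_sum_to_100_with_missing_policy(ref_frame):
    for var in ("eff_last", "warning_sign", "education"):
        tab = tabulate(ref_frame, var, policy="missing_in_denominator")
        assert abs(tab.percentages["all"].sum() - 100.0) <= 0.2


def test_missing_excluded_drops_missing_row(ref_frame):
    tab = tabulate(ref_frame, "education", policy="missing_excluded")
    assert "missing" not in tab.counts.index
    assert int(tab.denominators["all"]) == 632  # 5 missing education


def test_tabulate_invariant_to_record_order(ref_frame):
    shuffled = ref_frame.sample(frac=1.0, random_state=7).reset_index(drop=True)
    a = tabulate(ref_frame, "eff_last", strata="regimen")
    b = tabulate(shuffled, "eff_last", strata="regimen")
    assert a.counts.equals(b.counts)


def test_tabulate_unknown_variable_echoed(ref_frame):
    with pytest.raises(KeyError, match="nonexistent"):
        tabulate(ref_frame, "nonexistent")


def test_empty_cohort_no_division_by_zero(ref_frame):
    tab = tabulate(ref_frame.iloc[0:0], "eff_last")
    assert tab.counts.empty


# ---------------------------------------------------------------------------
# expulsion-time filter


def test_expelled_within_24h_reference(ref_cohort):
    res = proportion_expelled_within(ref_cohort, 24.0)
    assert (res.numerator, res.denominator) == (544, 637)
    assert res.percent == 85.4


def test_expelled_within_infinity_counts_all_observed(ref_cohort):
    res = proportion_expelled_within(ref_cohort, math.inf)
    observed = sum(1 for r in ref_cohort
                   if isinstance(r.time_to_expulsion_h, (int, float)))
    assert res.numerator == observed == 588  # 637 - 48 unnoticed - 1 missing


def test_expelled_requires_positive_hours(ref_cohort):
    with pytest.raises(ValueError):
        proportion_expelled_within(ref_cohort, 0)
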