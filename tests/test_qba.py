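"""Quantitative bias analysis: closed forms, identities, monotonicity,
and the seeding contract."""

import numpy as np
import pytest

from misoqba import (
    BiasParameters, misclassification_correct, point, run_qba,
    selection_adjust, uniform, trapezoidal, beta,
)
from misoqba.qba import Dist, with_seed


# ---------------------------------------------------------------------------
# closed-form primitives


@pytest.mark.parametrize("p_obs_n,se,sp,expected", [
    ((95, 100), 0.98, 0.90, (0.95 - 0.10) / 0.88),   # 0.96590909...
    ((95, 100), 1.0, 1.0, 0.95),                      # identity
    ((584, 592), 1.0, 0.9, (584 / 592 - 0.1) / 0.9),
])
def test_misclassification_closed_form(p_obs_n, se, sp, expected):
    x, n = p_obs_n
    assert misclassification_correct(x, n, se, sp) == pytest.approx(
        expected, abs=1e-12)


def test_misclassification_impossible_pair_flagged_by_range():
    # observed 99% cannot arise from Se=0.95 even if everyone is complete
    val = misclassification_correct(99, 100, 0.95, 1.0)
    assert val > 1.0


def test_misclassification_uninformative_rejected():
    with pytest.raises(ValueError, match="se \\+ sp"):
        misclassification_correct(50, 100, 0.5, 0.5)


def test_selection_adjust_hand_computed():
    # 90 complete / 10 incomplete followed; attendance 0.95 vs 0.50
    got = selection_adjust(90, 10, 0.95, 0.50)
    assert got == pytest.approx((90 / 0.95) / (90 / 0.95 + 10 / 0.50),
                                abs=1e-12)
    assert got == pytest.approx(0.825688, abs=1e-6)


def test_selection_equal_attendance_is_identity():
    assert selection_adjust(90, 10, 0.8, 0.8) == pytest.approx(0.9)


def test_selection_single_class():
    assert selection_adjust(50, 0, 0.9, 0.5) == 1.0
    assert selection_adjust(0, 50, 0.9, 0.5) == 0.0


def test_selection_zero_attendance_rejected():
    with pytest.raises(ValueError):
        selection_adjust(10, 5, 0.0, 0.5)


# ---------------------------------------------------------------------------
# distributions


def test_distribution_samples_stay_in_support():
    rng = np.random.default_rng(0)
    for d in (point(0.7), uniform(0.2, 0.9), beta(5, 2),
              trapezoidal(0.5, 0.6, 0.8, 0.95)):
        x = d.sample(rng, 10_000)
        lo, hi = d.support()
        assert np.all(x >= lo - 1e-12) and np.all(x <= hi + 1e-12)


def test_trapezoidal_mean_matches_theory():
    a, b, c, d = 0.5, 0.6, 0.8, 0.95
    x = trapezoidal(a, b, c, d).sample(np.random.default_rng(1), 200_000)
    # mean of a trapezoidal distribution
    want = (d**2 + c**2 + c*d - a**2 - b**2 - a*b) / (3 * (d + c - a - b))
    assert x.mean() == pytest.approx(want, abs=2e-3)


def test_invalid_distributions_rejected():
    with pytest.raises(ValueError, match="support"):
        Dist("uniform", (-0.1, 0.5)).validate("se_dist")
    with pytest.raises(ValueError, match="family"):
        Dist("cauchy", (0.0,)).validate("se_dist")
    with pytest.raises(ValueError, match="trapezoidal"):
        trapezoidal(0.5, 0.9, 0.8, 1.0).validate("se_dist")


# ---------------------------------------------------------------------------
# the Monte Carlo engine


def test_null_bias_identity_recovers_crude():
    """Point masses at Se=Sp=1 with equal attendance leave only the
    binomial random-error step; the median sits at the crude estimate."""
    params = BiasParameters(se_dist=point(1.0), sp_dist=point(1.0),
                            attend_given_complete=point(0.9),
                            attend_given_incomplete=point(0.9),
                            n_iter=50_000, seed=5)
    res = run_qba(584, 592, 637, params)
    crude = 584 / 592
    assert res.point_estimate == pytest.approx(crude, abs=0.002)
    assert res.n_discarded == 0
    assert res.sim_low <= res.point_estimate <= res.sim_high


def test_single_iteration_bit_reproducible():
    params = BiasParameters(se_dist=uniform(0.95, 1.0), sp_dist=uniform(0.8, 1.0),
                            n_iter=1, seed=77)
    r1 = run_qba(600, 620, 637, params, keep_trace=True)
    r2 = run_qba(600, 620, 637, params, keep_trace=True)
    assert r1.trace.tolist() == r2.trace.tolist()
    assert r1.point_estimate == r2.point_estimate


def test_specificity_monotonicity():
    """Lowering a point-mass Sp strictly lowers the corrected proportion
    for fixed p_obs > 1 - sp; the Monte Carlo median follows, up to the
    1/n quantization of the binomial error step."""
    last_corr, last_est = None, None
    for sp in (1.0, 0.95, 0.9, 0.85):
        corr = misclassification_correct(584, 592, 1.0, sp)
        params = BiasParameters(se_dist=point(1.0), sp_dist=point(sp),
                                n_iter=20_000, seed=3)
        est = run_qba(584, 592, 637, params).point_estimate
        if last_corr is not None:
            assert corr < last_corr           # strict, closed form
            assert est <= last_est + 1 / 637  # quantized median follows
        last_corr, last_est = corr, est


def test_widening_priors_never_narrows_interval():
    def width(params):
        r = run_qba(584, 592, 637, params)
        return r.sim_high - r.sim_low

    for seed in (0, 1, 2):
        narrow = BiasParameters(se_dist=point(1.0), sp_dist=point(0.9),
                                attend_given_complete=point(0.95),
                                attend_given_incomplete=point(0.7),
                                n_iter=30_000, seed=seed)
        wide = BiasParameters(se_dist=point(1.0), sp_dist=uniform(0.8, 1.0),
                              attend_given_complete=uniform(0.9, 1.0),
                              attend_given_incomplete=uniform(0.5, 0.9),
                              n_iter=30_000, seed=seed)
        assert width(wide) >= width(narrow) - 1e-4


def test_impossible_draws_discarded_and_counted():
    # Se uniform(0.9, 1.0) with p_obs ~ 0.9865: draws below p_obs are
    # impossible, roughly (0.9865-0.9)/0.1 of them
    params = BiasParameters(se_dist=uniform(0.9, 1.0), sp_dist=point(1.0),
                            n_iter=20_000, seed=13)
    res = run_qba(584, 592, 637, params)
    assert res.n_kept + res.n_discarded == 20_000
    frac = res.n_discarded / 20_000
    assert 0.8 < frac < 0.92


def test_truncate_policy_keeps_all_informative_draws():
    params = BiasParameters(se_dist=uniform(0.9, 1.0), sp_dist=point(1.0),
                            n_iter=20_000, seed=13,
                            impossible_draw_policy="truncate")
    res = run_qba(584, 592, 637, params)
    assert res.n_discarded == 0


def test_all_draws_impossible_raises():
    params = BiasParameters(se_dist=point(0.9), sp_dist=point(1.0),
                            n_iter=100, seed=0)
    with pytest.raises(RuntimeError, match="incompatible"):
        run_qba(636, 637, 637, params)


def test_parameter_recovery_from_synthetic_truth():
    """Generate a cohort with known Se/Sp and outcome-dependent attrition;
    running the bias analysis with point-mass priors at the true values
    recovers the generator's true effectiveness."""
    from misoqba import default_paper_config, derive_frame, generate
    from dataclasses import replace as dc_replace

    se, sp, ac, ai = 0.97, 0.85, 0.95, 0.60
    cfg = default_paper_config(n=20_000, seed=2024)
    cfg.selfreport_sensitivity = se
    cfg.selfreport_specificity = sp
    cfg.fu1_attendance_prob = 1.0
    cfg.fu2_attendance_prob = {"complete": ac, "incomplete": ai}
    cfg.intervention_probs = {"complete": 0.0, "incomplete": 0.0}
    cfg.true_completion_prob = {d: {r: 0.9 for r in ("endorsed_3x800", "other")}
                                for d in cfg.duration_probs}
    records, truth = generate(cfg)
    p_true = truth["true_complete"].mean()

    frame = derive_frame(records)
    followed = frame[frame["fu2_attended"]]
    observed_pos = int((followed["eff_fu2"] == "complete_no_procedure").sum())

    params = BiasParameters(se_dist=point(se), sp_dist=point(sp),
                            attend_given_complete=point(ac),
                            attend_given_incomplete=point(ai),
                            n_iter=50_000, seed=9)
    res = run_qba(observed_pos, len(followed), len(records), params)
    assert res.point_estimate == pytest.approx(p_true, abs=0.01)


def test_seed_copy_helper():
    p = BiasParameters(seed=1)
    assert with_seed(p, 9).seed == 9 and p.seed == 1
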