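"""Synthetic-cohort generator: reproducibility, calibration, and the
closed-form behaviour of its noise channels."""

import numpy as np
import pytest

from misoqba import (
    ConfigError, default_paper_config, effectiveness_counts, generate,
    noise_free, records_to_frame,
)
from misoqba.synth import CohortConfig


def crude_last(records):
    c = effectiveness_counts(records, "last_recorded")
    return c["complete_no_procedure"] / len(records)


def test_bit_identical_for_same_config_and_seed(tmp_path):
    cfg = default_paper_config(seed=123)
    r1, t1 = generate(cfg)
    r2, t2 = generate(cfg)
    assert records_to_frame(r1).equals(records_to_frame(r2))
    assert t1.equals(t2)


def test_different_seeds_differ():
    r1, _ = generate(default_paper_config(seed=1))
    r2, _ = generate(default_paper_config(seed=2))
    assert not records_to_frame(r1).equals(records_to_frame(r2))


def test_invalid_configs_rejected_with_field_named():
    with pytest.raises(ConfigError, match="n"):
        cfg = default_paper_config()
        cfg.n = 0
        generate(cfg)
    with pytest.raises(ConfigError, match="site_probs"):
        cfg = default_paper_config()
        cfg.site_probs = {"nigeria": 0.7, "argentina": 0.7}
        generate(cfg)
    with pytest.raises(ConfigError, match="selfreport_sensitivity"):
        cfg = default_paper_config()
        cfg.selfreport_sensitivity = 0.0
        generate(cfg)
    with pytest.raises(ConfigError, match="true_completion_prob"):
        CohortConfig(**{**default_paper_config().__dict__,
                        "true_completion_prob": {}}).validate()


def test_noise_free_observed_equals_truth():
    """With Se = Sp = 1, full attendance and no interventions, the crude
    observed effectiveness is exactly the hidden truth proportion."""
    cfg = noise_free(default_paper_config(seed=9))
    records, truth = generate(cfg)
    assert crude_last(records) == pytest.approx(truth["true_complete"].mean())


def test_truth_never_in_observed_file(tmp_path):
    from misoqba.synth import write_cohort

    cfg = default_paper_config(seed=2)
    write_cohort(cfg, tmp_path / "obs.csv", tmp_path / "truth.csv")
    header = (tmp_path / "obs.csv").read_text().splitlines()[0]
    assert "true_complete" not in header
    truth_header = (tmp_path / "truth.csv").read_text().splitlines()[0]
    assert truth_header == "participant_id,true_complete"


def test_misclassification_bias_matches_closed_form():
    """With Se < 1, Sp = 1 and no other noise, the observed crude
    effectiveness under-estimates truth by (1 - Se) * p in expectation."""
    se = 0.9
    cfg = noise_free(default_paper_config(n=40_000, seed=31))
    cfg.selfreport_sensitivity = se
    records, truth = generate(cfg)
    p_true = truth["true_complete"].mean()
    bias = p_true - crude_last(records)
    # binomial MC error at n=40k is ~0.0015; allow 4 sigma
    assert bias == pytest.approx((1 - se) * p_true, abs=0.006)


def test_default_config_margins_probabilities_sum_to_one():
    cfg = default_paper_config()
    for name in ("site_probs", "duration_probs", "regimen_probs",
                 "time_to_expulsion_dist"):
        assert sum(getattr(cfg, name).values()) == pytest.approx(1.0, abs=1e-9)


def test_default_config_calibration_margins():
    """Mean counts over repeated seeds match the configured margins
    (site 591/45/1, duration 317/205/92/23, regimen 532/105) within
    4 standard errors of the replicate mean."""
    n_rep = 60
    sums = {}
    for s in range(n_rep):
        records, _ = generate(default_paper_config(seed=s))
        for r in records:
            for key in ((("site", r.site)), ("duration", r.duration_weeks),
                        ("regimen", r.regimen)):
                sums[key] = sums.get(key, 0) + 1
    expected = {("site", "nigeria"): 591, ("site", "southeast_asia"): 45,
                ("site", "argentina"): 1,
                ("duration", "lt7"): 317, ("duration", "7to_lt9"): 205,
                ("duration", "9to_lt12"): 92, ("duration", "12to16"): 23,
                ("regimen", "endorsed_3x800"): 532, ("regimen", "other"): 105}
    for key, want in expected.items():
        got = sums.get(key, 0) / n_rep
        p = want / 637
        se_mean = np.sqrt(637 * p * (1 - p) / n_rep)
        assert abs(got - want) <= 4 * se_mean + 1e-9, (key, got, want)


def test_default_config_crude_effectiveness_near_calibrated_truth():
    """Crude last-recorded effectiveness stays within 3 percentage points
    of the configured 98.1% across seeds."""
    vals = [crude_last(generate(default_paper_config(seed=s))[0])
            for s in range(25)]
    assert all(abs(v - 0.981) < 0.03 for v in vals)


def test_attrition_is_outcome_dependent():
    """Participants with truly incomplete abortions miss the 3-week
    interview more often, and ~45/637 are lost overall."""
    lost_inc, lost_com, n_inc, n_com, lost = 0, 0, 0, 0, []
    for s in range(40):
        records, truth = generate(default_paper_config(seed=100 + s))
        tr = truth["true_complete"].to_numpy()
        att = np.array([r.fu2_attended for r in records])
        lost_inc += int((~att & ~tr).sum()); n_inc += int((~tr).sum())
        lost_com += int((~att & tr).sum()); n_com += int(tr.sum())
        lost.append(int((~att).sum()))
    assert lost_inc / n_inc > lost_com / n_com
    assert abs(np.mean(lost) - 45) < 10


def test_yaml_config_round_trip(tmp_path):
    cfg = default_paper_config(seed=17)
    cfg.to_yaml(tmp_path / "cfg.yaml")
    back = CohortConfig.from_yaml(tmp_path / "cfg.yaml")
    assert back == cfg
    r1, _ = generate(cfg)
    r2, _ = generate(back)
    assert records_to_frame(r1).equals(records_to_frame(r2))
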