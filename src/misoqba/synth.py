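"""Seeded synthetic-cohort generator.

Emulates the data-generating process the analysis assumes: a latent true
abortion-completion status per participant (probability set per
pregnancy-duration bin and regimen), an observed self-report drawn from
the truth through sensitivity/specificity channels, follow-up attendance
drawn conditionally on the truth (differential loss to follow-up), and
the symptom/care-seeking/physical-experience fields drawn from configured
marginal or conditional frequencies.

Truth is returned separately from the observed records and is never
written into the observed record file, so misclassification-recovery
tests have a gold standard the real study lacks.

Reproducibility contract: output is bit-identical for identical
(config, seed), and each record field draws from its own named
random-number substream, so adding a new field does not perturb draws
for existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .records import (
    ParticipantRecord, SITES, AGE_GROUPS, EDUCATION, DURATION_BINS,
    REGIMENS, SIDE_EFFECTS, NOT_OBSERVED, write_records,
)

# hour bins for time to expulsion: (label, low, high); sampled uniformly
# within the bin since only binned frequencies are published
EXPULSION_BINS = (
    ("not_observed", None, None),
    ("lt8", 1.0, 8.0),
    ("8to12", 8.0, 12.0),
    ("12to16", 12.0, 16.0),
    ("16to24", 16.0, 24.0),
    ("gt24", 24.0, 48.0),
)

# integer-day bins for bleeding durations
_DAY_BINS = {"0": (0, 0), "1to3": (1, 3), "4to6": (4, 6), "7to9": (7, 9),
             "ge10": (10, 14)}
_CRAMP_BINS = {"0": (0.0, 0.0), "lt1": (0.5, 0.5), "1to2": (1.0, 2.0),
               "3": (3.0, 3.0), "ge4": (4.0, 6.0)}


class ConfigError(ValueError):
    """Invalid generator configuration; the message names the field."""


@dataclass
class CohortConfig:
    """Generator configuration.

    All `_probs` vectors must sum to 1 (tolerance 1e-9).
    ``true_completion_prob`` maps duration bin -> regimen -> probability of
    a truly complete abortion without procedural need.
    ``selfreport_sensitivity`` (Se) is P(report complete | truly complete);
    ``selfreport_specificity`` (Sp) is P(report not-complete-or-unsure |
    truly not complete).  ``fu2_attendance_prob`` is keyed by true outcome
    ("complete"/"incomplete") — the differential-loss channel.
    """

    n: int = 637
    seed: int = 0
    site_probs: dict = field(default_factory=dict)
    duration_probs: dict = field(default_factory=dict)
    regimen_probs: dict = field(default_factory=dict)
    age_probs: dict = field(default_factory=dict)
    education_probs: dict = field(default_factory=dict)
    prior_attempt_probs: dict = field(default_factory=dict)
    true_completion_prob: dict = field(default_factory=dict)
    selfreport_sensitivity: float = 1.0
    selfreport_specificity: float = 1.0
    fu1_attendance_prob: float = 1.0
    fu2_attendance_prob: dict = field(default_factory=lambda: {"complete": 1.0,
                                                               "incomplete": 1.0})
    intervention_probs: dict = field(default_factory=lambda: {"complete": 0.0,
                                                              "incomplete": 0.0})
    warning_sign_probs: dict = field(default_factory=dict)
    adverse_event_probs: dict = field(default_factory=dict)
    care_seeking_prob: dict = field(default_factory=lambda: {"warning": 0.0,
                                                             "no_warning": 0.0})
    time_to_expulsion_dist: dict = field(default_factory=dict)
    bleeding_days_dist: dict = field(default_factory=dict)
    heavy_bleeding_days_dist: dict = field(default_factory=dict)
    cramping_days_dist: dict = field(default_factory=dict)
    side_effect_probs: dict = field(default_factory=dict)
    pain_prob: float = 0.9

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        if self.n < 1:
            raise ConfigError("n: must be >= 1")
        for name in ("site_probs", "duration_probs", "regimen_probs",
                     "age_probs", "education_probs", "prior_attempt_probs",
                     "time_to_expulsion_dist", "bleeding_days_dist",
                     "heavy_bleeding_days_dist", "cramping_days_dist"):
            vec = getattr(self, name)
            if not vec:
                raise ConfigError(f"{name}: empty probability vector")
            vals = np.asarray(list(vec.values()), dtype=float)
            if np.any(vals < 0):
                raise ConfigError(f"{name}: negative probability")
            if abs(vals.sum() - 1.0) > 1e-9:
                raise ConfigError(f"{name}: probabilities sum to {vals.sum()!r}, not 1")
        for name in ("selfreport_sensitivity", "selfreport_specificity"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigError(f"{name}: must lie in (0, 1]")
        if not 0 < self.fu1_attendance_prob <= 1:
            raise ConfigError("fu1_attendance_prob: must lie in (0, 1]")
        for k in ("complete", "incomplete"):
            if not 0 <= self.fu2_attendance_prob.get(k, -1) <= 1:
                raise ConfigError(f"fu2_attendance_prob[{k}]: must lie in [0, 1]")
            if not 0 <= self.intervention_probs.get(k, -1) <= 1:
                raise ConfigError(f"intervention_probs[{k}]: must lie in [0, 1]")
        for d in DURATION_BINS:
            for r in REGIMENS:
                p = self.true_completion_prob.get(d, {}).get(r)
                if p is None or not 0 <= p <= 1:
                    raise ConfigError(f"true_completion_prob[{d}][{r}]: "
                                      "missing or outside [0, 1]")
        for sign, cond in self.warning_sign_probs.items():
            for k in ("complete", "incomplete"):
                if not 0 <= cond.get(k, -1) <= 1:
                    raise ConfigError(f"warning_sign_probs[{sign}][{k}]: outside [0, 1]")
        for ev, p in self.adverse_event_probs.items():
            if not 0 <= p <= 1:
                raise ConfigError(f"adverse_event_probs[{ev}]: outside [0, 1]")
        for k in ("warning", "no_warning"):
            if not 0 <= self.care_seeking_prob.get(k, -1) <= 1:
                raise ConfigError(f"care_seeking_prob[{k}]: outside [0, 1]")

    # -- persistence -------------------------------------------------------

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        data = yaml.safe_load(Path(path).read_text())
        cfg = cls(**data)
        cfg.validate()
        return cfg


# ---------------------------------------------------------------------------
# Named substreams — fixed registry; append only, never reorder

_STREAMS = (
    "site", "duration", "regimen", "age", "education", "prior_attempt",
    "truth", "report_fu1", "report_fu2", "fu1_attend", "fu2_attend",
    "intervention", "warning_signs", "adverse_events", "care_seeking",
    "expulsion", "bleeding", "heavy_bleeding", "cramping", "side_effects",
    "pain", "fu_days", "confirmation",
)


def _rng(seed: int, stream: str) -> np.random.Generator:
    idx = _STREAMS.index(stream)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(idx,)))


def _choice(rng: np.random.Generator, keys_probs: dict, n: int) -> np.ndarray:
    keys = list(keys_probs.keys())
    probs = np.asarray(list(keys_probs.values()), dtype=float)
    probs = probs / probs.sum()
    return rng.choice(np.asarray(keys, dtype=object), size=n, p=probs)


def generate(config: CohortConfig):
    """Generate a synthetic cohort.

    Returns ``(records, truth)`` where ``records`` is a list of
    :class:`ParticipantRecord` and ``truth`` is a DataFrame with columns
    ``participant_id`` and ``true_complete`` — the hidden gold standard.
    """
    config.validate()
    n, seed = config.n, config.seed

    site = _choice(_rng(seed, "site"), config.site_probs, n)
    duration = _choice(_rng(seed, "duration"), config.duration_probs, n)
    regimen = _choice(_rng(seed, "regimen"), config.regimen_probs, n)
    age = _choice(_rng(seed, "age"), config.age_probs, n)
    edu = _choice(_rng(seed, "education"), config.education_probs, n)
    prior = _choice(_rng(seed, "prior_attempt"), config.prior_attempt_probs, n)

    p_true = np.array([config.true_completion_prob[d][r]
                       for d, r in zip(duration, regimen)])
    truth = _rng(seed, "truth").random(n) < p_true

    se, sp = config.selfreport_sensitivity, config.selfreport_specificity
    p_report = np.where(truth, se, 1.0 - sp)
    rep1 = _rng(seed, "report_fu1").random(n) < p_report
    rep2 = _rng(seed, "report_fu2").random(n) < p_report

    fu1_att = _rng(seed, "fu1_attend").random(n) < config.fu1_attendance_prob
    p_att2 = np.where(truth, config.fu2_attendance_prob["complete"],
                      config.fu2_attendance_prob["incomplete"])
    fu2_att = _rng(seed, "fu2_attend").random(n) < p_att2
    fu2_att |= ~fu1_att  # every participant completes at least one follow-up

    p_interv = np.where(truth, config.intervention_probs["complete"],
                        config.intervention_probs["incomplete"])
    interv = _rng(seed, "intervention").random(n) < p_interv

    ws_rng = _rng(seed, "warning_signs")
    sign_draws = {}
    for sign, cond in sorted(config.warning_sign_probs.items()):
        p = np.where(truth, cond["complete"], cond["incomplete"])
        sign_draws[sign] = ws_rng.random(n) < p
    any_sign = np.zeros(n, dtype=bool)
    for v in sign_draws.values():
        any_sign |= v

    ae_rng = _rng(seed, "adverse_events")
    ae_draws = {ev: ae_rng.random(n) < p
                for ev, p in sorted(config.adverse_event_probs.items())}

    p_seek = np.where(any_sign, config.care_seeking_prob["warning"],
                      config.care_seeking_prob["no_warning"])
    seek = _rng(seed, "care_seeking").random(n) < p_seek

    exp_rng = _rng(seed, "expulsion")
    exp_bin = _choice(exp_rng, config.time_to_expulsion_dist, n)
    bin_bounds = {lab: (lo, hi) for lab, lo, hi in EXPULSION_BINS}
    exp_u = exp_rng.random(n)
    expulsion = []
    for lab, u in zip(exp_bin, exp_u):
        lo, hi = bin_bounds[lab]
        expulsion.append(NOT_OBSERVED if lo is None else round(lo + u * (hi - lo), 2))

    def days(stream, dist, bins, integer=True):
        rng = _rng(seed, stream)
        lab = _choice(rng, dist, n)
        u = rng.random(n)
        out = []
        for la, uu in zip(lab, u):
            lo, hi = bins[la]
            v = lo + uu * (hi - lo)
            out.append(int(round(v)) if integer else round(v, 1))
        return out

    bleeding = days("bleeding", config.bleeding_days_dist, _DAY_BINS)
    heavy = days("heavy_bleeding", config.heavy_bleeding_days_dist, _DAY_BINS)
    cramp = days("cramping", config.cramping_days_dist, _CRAMP_BINS, integer=False)

    se_rng = _rng(seed, "side_effects")
    se_draws = {s: se_rng.random(n) < config.side_effect_probs.get(s, 0.0)
                for s in SIDE_EFFECTS}
    pain = _rng(seed, "pain").random(n) < config.pain_prob

    d_rng = _rng(seed, "fu_days")
    fu1_days = d_rng.integers(7, 13, n)
    fu2_days = d_rng.integers(21, 27, n)

    records = []
    for i in range(n):
        records.append(ParticipantRecord(
            participant_id=f"S{i:05d}",
            site=str(site[i]),
            age_group=str(age[i]),
            education=None if edu[i] == "missing" else str(edu[i]),
            prior_attempt=None if prior[i] == "missing" else str(prior[i]),
            pregnancy_confirmation=frozenset({"test"}),
            duration_weeks=str(duration[i]),
            regimen=str(regimen[i]),
            fu1_status=("complete" if rep1[i] else "not_complete_or_unsure")
                        if fu1_att[i] else None,
            fu1_days=int(fu1_days[i]) if fu1_att[i] else None,
            fu2_status=("complete" if rep2[i] else "not_complete_or_unsure")
                        if fu2_att[i] else None,
            fu2_days=int(fu2_days[i]) if fu2_att[i] else None,
            fu2_attended=bool(fu2_att[i]),
            procedural_intervention="mva" if interv[i] else "none",
            intervention_timing="fu2_window" if interv[i] else None,
            heavy_bleeding_2pads_2h=bool(sign_draws.get("heavy_bleeding_2pads_2h",
                                                        np.zeros(n, bool))[i]),
            unrelieved_pain=bool(sign_draws.get("unrelieved_pain",
                                                np.zeros(n, bool))[i]),
            fever_gt38_24h=bool(sign_draws.get("fever_gt38_24h",
                                               np.zeros(n, bool))[i]),
            foul_discharge=bool(sign_draws.get("foul_discharge",
                                               np.zeros(n, bool))[i]),
            iv_fluids=bool(ae_draws.get("iv_fluids", np.zeros(n, bool))[i]),
            transfusion=bool(ae_draws.get("transfusion", np.zeros(n, bool))[i]),
            overnight_stay=bool(ae_draws.get("overnight_stay", np.zeros(n, bool))[i]),
            sought_care=bool(seek[i]),
            care_facility="clinic_hospital" if seek[i] else None,
            care_reasons=frozenset({"confirm_completion"}) if seek[i] else frozenset(),
            time_to_expulsion_h=expulsion[i],
            bleeding_days=bleeding[i],
            heavy_bleeding_days=heavy[i],
            cramping_days=cramp[i],
            pain=bool(pain[i]),
            side_effects=frozenset(s for s, v in se_draws.items() if v[i]),
        ))

    truth_df = pd.DataFrame({
        "participant_id": [r.participant_id for r in records],
        "true_complete": truth,
    })
    return records, truth_df


def write_cohort(config: CohortConfig, records_path, truth_path=None):
    """Generate and write the observed CSV (and, separately, the truth CSV).

    The truth file never shares columns with the observed file beyond the
    participant id.
    """
    records, truth = generate(config)
    write_records(records, records_path)
    if truth_path is not None:
        truth.to_csv(truth_path, index=False)
    return records, truth


# ---------------------------------------------------------------------------
# Default configuration matched to the published margins


def default_paper_config(n: int = 637, seed: int = 0) -> CohortConfig:
    """Configuration whose marginal expectations match the published
    cohort: site mix 591/45/1, duration mix 317/205/92/23, regimen mix
    532/105, true completion set to the stratum effectiveness rates, and
    follow-up attendance tuned so ~45 of 637 miss the 3-week interview,
    more often when the abortion is truly incomplete.

    Warning-sign and adverse-event probabilities conditional on a truly
    incomplete abortion are not identifiable from published margins; the
    values here are unanchored defaults chosen to reproduce the observed
    marginal prevalences (~8% any warning sign, ~1% any adverse event).
    """
    d = 637.0
    # duration x regimen completion probabilities consistent with the
    # printed stratum rates (duration margins 99.4/97.6/97.8/87.0 and the
    # endorsed/other split 99.4/91.4)
    completion = {
        "lt7": {"endorsed_3x800": 0.997, "other": 0.97},
        "7to_lt9": {"endorsed_3x800": 0.99, "other": 0.93},
        "9to_lt12": {"endorsed_3x800": 0.99, "other": 0.95},
        "12to16": {"endorsed_3x800": 0.93, "other": 0.80},
    }
    return CohortConfig(
        n=n,
        seed=seed,
        site_probs={"nigeria": 591 / d, "southeast_asia": 45 / d, "argentina": 1 / d},
        duration_probs={"lt7": 317 / d, "7to_lt9": 205 / d,
                        "9to_lt12": 92 / d, "12to16": 23 / d},
        regimen_probs={"endorsed_3x800": 532 / d, "other": 105 / d},
        age_probs={"lt20": 23 / d, "20to24": 157 / d, "25to29": 227 / d,
                   "30to34": 119 / d, "ge35": 111 / d},
        education_probs={"primary": 13 / d, "secondary": 263 / d,
                         "more_than_secondary": 356 / d, "missing": 5 / d},
        prior_attempt_probs={"no": 600 / d, "yes": 35 / d, "missing": 2 / d},
        true_completion_prob=completion,
        selfreport_sensitivity=0.99,
        selfreport_specificity=0.95,
        fu1_attendance_prob=635 / d,
        # E[missed fu2] = p*(1-a_c) + (1-p)*(1-a_i) ~ 45/637 at p ~ 0.984
        fu2_attendance_prob={"complete": 0.933, "incomplete": 0.70},
        intervention_probs={"complete": 0.002, "incomplete": 0.05},
        warning_sign_probs={
            "heavy_bleeding_2pads_2h": {"complete": 0.019, "incomplete": 0.15},
            "unrelieved_pain": {"complete": 0.030, "incomplete": 0.20},
            "fever_gt38_24h": {"complete": 0.005, "incomplete": 0.05},
            "foul_discharge": {"complete": 0.033, "incomplete": 0.15},
        },
        adverse_event_probs={"iv_fluids": 6 / d, "overnight_stay": 3 / d,
                             "transfusion": 0.0},
        care_seeking_prob={"warning": 23 / 52, "no_warning": 126 / 584},
        time_to_expulsion_dist={"not_observed": 48 / 636, "lt8": 79 / 636,
                                "8to12": 311 / 636, "12to16": 96 / 636,
                                "16to24": 58 / 636, "gt24": 44 / 636},
        bleeding_days_dist={"0": 3 / 636, "1to3": 182 / 636, "4to6": 300 / 636,
                            "7to9": 89 / 636, "ge10": 62 / 636},
        heavy_bleeding_days_dist={"0": 25 / d, "1to3": 557 / d, "4to6": 43 / d,
                                  "7to9": 9 / d, "ge10": 3 / d},
        cramping_days_dist={"0": 12 / 635, "lt1": 212 / 635, "1to2": 296 / 635,
                            "3": 61 / 635, "ge4": 54 / 635},
        side_effect_probs={"nausea": 335 / d, "fever": 232 / d, "diarrhea": 181 / d,
                           "chills": 161 / d, "vomiting": 89 / d,
                           "itchiness_hives": 22 / d, "difficulty_breathing": 1 / d,
                           "facial_numbness": 6 / d, "sweaty_hands": 4 / d},
        pain_prob=591 / d,
    )


def noise_free(config: CohortConfig) -> CohortConfig:
    """Copy of ``config`` with all observation channels switched off
    (Se = Sp = 1, full attendance, no interventions): the observed crude
    effectiveness then equals the hidden truth exactly."""
    return replace(
        config,
        selfreport_sensitivity=1.0,
        selfreport_specificity=1.0,
        fu1_attendance_prob=1.0,
        fu2_attendance_prob={"complete": 1.0, "incomplete": 1.0},
        intervention_probs={"complete": 0.0, "incomplete": 0.0},
    )
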