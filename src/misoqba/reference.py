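"""Synthetic reference cohort reconstructed from published margins.

Builds, by deterministic constrained assignment (no sampling), a cohort of
637 participant records whose marginal and key joint counts match the
published tables of the source study: follow-up structure (635 one-week
interviews, 592 three-week interviews, 45 carried forward), effectiveness
classes overall and by pregnancy-duration stratum and regimen, warning-sign
and adverse-event counts, care-seeking cross-tabulations, time-to-expulsion
bins, bleeding/cramping durations and side-effect frequencies.

The individual rows are synthetic: joint cells the study never printed
(e.g., exactly which regimen each non-complete outcome belongs to beyond
the published subgroup totals, or which stratum each care seeker is in)
are fixed by arbitrary-but-deterministic rules.  Only the published
margins are meaningful.

Archetype codes used in construction (per duration stratum):

==== ======================================================================
A    both follow-ups, complete at both
B    both follow-ups, not-complete/unsure at 1 week, complete at 3 weeks
C1   complete at both, procedural intervention in the 1-week window
C2   complete at both, procedural intervention in the 3-week window
D    not-complete/unsure at both follow-ups
E    3-week follow-up only (missed the 1-week interview)
F    1-week follow-up only, complete (carried forward)
G    1-week follow-up only, not complete or unsure
H    1-week follow-up only, outcome answer missing (the one participant
     with missing outcome and safety data)
==== ======================================================================
"""

from __future__ import annotations

from .records import ParticipantRecord, NOT_OBSERVED

_SIGN = {"b": "heavy_bleeding_2pads_2h", "p": "unrelieved_pain",
         "f": "fever_gt38_24h", "d": "foul_discharge"}

# stratum -> ordered archetype blocks (code, count)
_BLOCKS = {
    "lt7": (("A", 286), ("B", 10), ("C1", 1), ("D", 1), ("F", 19)),
    "7to_lt9": (("A", 178), ("B", 6), ("C2", 1), ("D", 3), ("E", 1),
                ("F", 15), ("G", 1)),
    "9to_lt12": (("A", 79), ("B", 5), ("F", 6), ("G", 1), ("H", 1)),
    "12to16": (("A", 19), ("C2", 1), ("E", 1), ("F", 1), ("G", 1)),
}
_STRATA = tuple(_BLOCKS)

# 3-week class for the two fu2-only (E) participants
_E_CLASS = {"7to_lt9": "complete", "12to16": "not_complete_or_unsure"}

# intervention type for the C2 rows (the C1 row is an MVA)
_C2_TYPE = {"7to_lt9": "mva", "12to16": "dc"}

# stratum-local row indices on the non-endorsed regimen; everyone else
# uses the endorsed 3x800 regimen (totals 532 endorsed / 105 other,
# duration cross 281/166/71/14 vs 36/39/21/9, non-complete split 3 vs 9)
_OTHER_REGIMEN = {
    "lt7": {297, *range(251, 286)},
    "7to_lt9": {184, 186, 187, 204, *range(143, 178)},
    "9to_lt12": {90, 91, *range(60, 79)},
    "12to16": {20, 21, 22, *range(13, 19)},
}

# stratum-local index -> warning-sign codes (52 participants with at least
# one sign; component counts 14/21/4/23 with the printed per-stratum
# margins; overlaps make components sum to 62)
_WARNINGS = {
    "lt7": dict(enumerate(
        ["b", "b", "b", "b", "p", "p", "p", "p", "f",
         "d", "d", "d", "d", "d", "d", "d", "d", "bp", "dp", "df"])),
    "7to_lt9": {184: "p", **dict(enumerate(
        ["b", "b", "b", "p", "p", "p", "p", "p", "p", "p", "p",
         "d", "d", "d", "d", "d", "d", "d", "bp", "pd", "pd"]))},
    "9to_lt12": dict(enumerate(
        ["b", "b", "p", "d", "bp", "bd", "pd", "fd"])),
    "12to16": {19: "b", 0: "f"},
}

# stratum-local index -> adverse-event markers (6 IV fluids, 3 overnight,
# 0 transfusions, per-stratum 1/3/0/2 and 1/1/0/1)
_ADVERSE = {
    "lt7": {100: ("iv_fluids", "overnight_stay")},
    "7to_lt9": {0: ("iv_fluids", "overnight_stay"), 1: ("iv_fluids",),
                100: ("iv_fluids",)},
    "9to_lt12": {},
    "12to16": {19: ("iv_fluids", "overnight_stay"), 0: ("iv_fluids",)},
}

# the participant with missing outcome and safety data (archetype H)
_MISSING_SAFETY = ("9to_lt12", 91)
# rows with missing cramping duration and side-effect data
_MISSING_SYMPTOMS = (("7to_lt9", 203), ("12to16", 22))

# care seekers: 23 of the 52 with a warning sign, 126 of the 584 without
# (ever sought care 149).  Special rows lead each list so facility and
# treatment assignment puts procedures/IV fluids where the event flags are.
_W_SEEKERS = ([("7to_lt9", 184), ("7to_lt9", 0), ("7to_lt9", 1),
               ("12to16", 19), ("12to16", 0)]
              + [("lt7", i) for i in range(8)]
              + [("7to_lt9", i) for i in range(2, 9)]
              + [("9to_lt12", i) for i in range(3)])
_NW_SEEKERS = ([("lt7", 296), ("lt7", 100), ("7to_lt9", 100)]
               + [("lt7", i) for i in range(20, 78)]
               + [("7to_lt9", i) for i in range(21, 60)]
               + [("9to_lt12", i) for i in range(8, 28)]
               + [("12to16", i) for i in range(1, 7)])

# per-stratum counts over the representative values of each physical-
# experience variable, applied in row order (missing rows skipped)
_EXPULSION_VALUES = (NOT_OBSERVED, 6.0, 10.0, 14.0, 20.0, 30.0)
_EXPULSION = {"lt7": (26, 36, 157, 52, 28, 18),
              "7to_lt9": (11, 25, 102, 31, 22, 14),
              "9to_lt12": (7, 16, 42, 11, 6, 9),
              "12to16": (4, 2, 10, 2, 2, 3)}
_BLEED_VALUES = (0, 2, 5, 8, 12)
_BLEEDING = {"lt7": (1, 96, 155, 45, 20), "7to_lt9": (1, 53, 93, 30, 28),
             "9to_lt12": (0, 25, 44, 11, 11), "12to16": (1, 8, 8, 3, 3)}
_HEAVY_VALUES = (0, 2, 5, 8, 11)
_HEAVY = {"lt7": (20, 273, 23, 1, 0), "7to_lt9": (1, 179, 16, 7, 2),
          "9to_lt12": (2, 86, 3, 0, 1), "12to16": (2, 19, 1, 1, 0)}
_CRAMP_VALUES = (0.0, 0.5, 1.5, 3.0, 4.0)
_CRAMPING = {"lt7": (7, 110, 154, 28, 18), "7to_lt9": (3, 59, 95, 20, 27),
             "9to_lt12": (2, 32, 40, 11, 7), "12to16": (0, 11, 7, 2, 2)}

# side effects: (per-stratum count of "no side effects", then
# {effect: (start, stop)} half-open ranges over the remaining eligible
# rows in order)
_SE_NONE = {"lt7": 52, "7to_lt9": 19, "9to_lt12": 7, "12to16": 0}
_SE_RANGES = {
    "lt7": {"nausea": (0, 156), "fever": (155, 265), "diarrhea": (50, 128),
            "chills": (100, 171), "vomiting": (0, 41),
            "itchiness_hives": (41, 49), "facial_numbness": (49, 51),
            "sweaty_hands": (51, 52)},
    "7to_lt9": {"nausea": (0, 111), "fever": (115, 185),
                "diarrhea": (111, 180), "chills": (60, 118),
                "vomiting": (30, 59), "itchiness_hives": (0, 6),
                "facial_numbness": (6, 9), "sweaty_hands": (9, 12),
                "difficulty_breathing": (12, 13)},
    "9to_lt12": {"nausea": (0, 54), "fever": (42, 84), "diarrhea": (10, 38),
                 "chills": (30, 57), "vomiting": (0, 14),
                 "itchiness_hives": (14, 19), "facial_numbness": (19, 20)},
    "12to16": {"nausea": (0, 14), "fever": (12, 22), "diarrhea": (0, 6),
               "chills": (6, 11), "vomiting": (11, 16),
               "itchiness_hives": (16, 19)},
}
_PAIN_FALSE = {"lt7": 16, "7to_lt9": 16, "9to_lt12": 10, "12to16": 3}

_FU1_DAYS = (7, 8, 9, 9, 10, 12)
_FU2_DAYS = (21, 22, 23, 23, 24, 26)


def _spread(counts, values):
    out = []
    for c, v in zip(counts, values):
        out.extend([v] * c)
    return out


def _skeleton(stratum):
    """Per-stratum row dicts carrying the follow-up/outcome skeleton."""
    rows = []
    for code, count in _BLOCKS[stratum]:
        for _ in range(count):
            r = {"archetype": code, "fu1_status": None, "fu1_attended": True,
                 "fu2_status": None, "fu2_attended": False,
                 "intervention": "none", "timing": None}
            if code in ("A", "C1", "C2"):
                r.update(fu1_status="complete", fu2_status="complete",
                         fu2_attended=True)
                if code == "C1":
                    r.update(intervention="mva", timing="fu1_window")
                elif code == "C2":
                    r.update(intervention=_C2_TYPE[stratum],
                             timing="fu2_window")
            elif code == "B":
                r.update(fu1_status="not_complete_or_unsure",
                         fu2_status="complete", fu2_attended=True)
            elif code == "D":
                r.update(fu1_status="not_complete_or_unsure",
                         fu2_status="not_complete_or_unsure",
                         fu2_attended=True)
            elif code == "E":
                r.update(fu1_attended=False, fu2_status=_E_CLASS[stratum],
                         fu2_attended=True)
            elif code == "F":
                r.update(fu1_status="complete")
            elif code == "G":
                r.update(fu1_status="not_complete_or_unsure")
            # H: attended fu1 but the outcome answer is missing
            rows.append(r)
    return rows


def reference_cohort() -> list:
    """Build the 637-record reference cohort.

    Deterministic: repeated calls return identical records.
    """
    strata = {s: _skeleton(s) for s in _STRATA}

    for s, rows in strata.items():
        # regimen
        other = _OTHER_REGIMEN[s]
        for i, r in enumerate(rows):
            r["regimen"] = "other" if i in other else "endorsed_3x800"
        # warning signs and adverse events
        for i, r in enumerate(rows):
            r["signs"] = frozenset(_SIGN[c] for c in _WARNINGS[s].get(i, ""))
            r["adverse"] = frozenset(_ADVERSE[s].get(i, ()))
            r["safety_missing"] = False
            r["symptoms_missing"] = False
        # physical-experience variables, in row order
        miss_safety = [i for (ms, i) in [_MISSING_SAFETY] if ms == s]
        miss_sympt = [i for (ms, i) in _MISSING_SYMPTOMS if ms == s]
        for i in miss_safety:
            rows[i]["safety_missing"] = True
        for i in miss_sympt:
            rows[i]["symptoms_missing"] = True

        elig = [r for i, r in enumerate(rows) if i not in miss_safety]
        for r, v in zip(elig, _spread(_EXPULSION[s], _EXPULSION_VALUES)):
            r["expulsion"] = v
        for r, v in zip(elig, _spread(_BLEEDING[s], _BLEED_VALUES)):
            r["bleeding"] = v
        for r, v in zip(rows, _spread(_HEAVY[s], _HEAVY_VALUES)):
            r["heavy"] = v
        celig = [r for i, r in enumerate(rows) if i not in miss_sympt]
        for r, v in zip(celig, _spread(_CRAMPING[s], _CRAMP_VALUES)):
            r["cramping"] = v
        # side effects: exclude symptom-missing rows and the safety-missing
        # row, put the "none reported" block at the end
        selig = [r for i, r in enumerate(rows)
                 if i not in miss_sympt and i not in miss_safety]
        n_none = _SE_NONE[s]
        active = selig[:len(selig) - n_none] if n_none else selig
        for r in selig:
            r["side_effects"] = set()
        for eff, (a, b) in _SE_RANGES[s].items():
            for r in active[a:b]:
                r["side_effects"].add(eff)
        # pain: last k rows (excluding the safety-missing row) report none
        pelig = [r for i, r in enumerate(rows) if i not in miss_safety]
        for r in pelig:
            r["pain"] = True
        for r in pelig[len(pelig) - _PAIN_FALSE[s]:]:
            r["pain"] = False

    # care seeking -------------------------------------------------------
    for s, rows in strata.items():
        for r in rows:
            r["sought"] = False
    for s, i in _W_SEEKERS + _NW_SEEKERS:
        strata[s][i]["sought"] = True

    def seekers(pairs):
        return [strata[s][i] for s, i in pairs]

    nw, w = seekers(_NW_SEEKERS), seekers(_W_SEEKERS)
    _assign_care(nw, w)

    # demographics, assigned by position within each regimen group -------
    ordered = [r for s in _STRATA for r in strata[s]]
    endorsed = [r for r in ordered if r["regimen"] == "endorsed_3x800"]
    others = [r for r in ordered if r["regimen"] == "other"]
    _assign_demographics(endorsed, others)

    for j, r in enumerate(ordered):
        r["route"] = "sublingual" if j < 626 else "other"
        r["source"] = "pharmacy" if j < 471 else "other"

    # materialize --------------------------------------------------------
    records = []
    j = 0
    for s in _STRATA:
        for r in strata[s]:
            fu1_att = r["fu1_attended"]
            sm = r["safety_missing"]
            records.append(ParticipantRecord(
                participant_id=f"R{j:04d}",
                site=r["site"],
                age_group=r["age_group"],
                education=r["education"],
                prior_attempt=r["prior_attempt"],
                pregnancy_confirmation=r["confirmation"],
                duration_weeks=s,
                regimen=r["regimen"],
                route=r["route"],
                source=r["source"],
                fu1_status=r["fu1_status"],
                fu1_days=_FU1_DAYS[j % 6] if fu1_att else None,
                fu2_status=r["fu2_status"],
                fu2_days=_FU2_DAYS[j % 6] if r["fu2_attended"] else None,
                fu2_attended=r["fu2_attended"],
                procedural_intervention=r["intervention"],
                intervention_timing=r["timing"],
                heavy_bleeding_2pads_2h=None if sm else "heavy_bleeding_2pads_2h" in r["signs"],
                unrelieved_pain=None if sm else "unrelieved_pain" in r["signs"],
                fever_gt38_24h=None if sm else "fever_gt38_24h" in r["signs"],
                foul_discharge=None if sm else "foul_discharge" in r["signs"],
                iv_fluids=None if sm else "iv_fluids" in r["adverse"],
                transfusion=None if sm else "transfusion" in r["adverse"],
                overnight_stay=None if sm else "overnight_stay" in r["adverse"],
                sought_care=r["sought"],
                care_facility=r.get("facility"),
                care_reasons=frozenset(r.get("reasons", ())),
                care_treatments=frozenset(r.get("treatments", ())),
                disclosure=r.get("disclosure"),
                time_to_expulsion_h=r.get("expulsion"),
                bleeding_days=r.get("bleeding"),
                heavy_bleeding_days=r["heavy"],
                cramping_days=r.get("cramping"),
                pain=r.get("pain"),
                side_effects=(frozenset(r["side_effects"])
                              if "side_effects" in r else None),
            ))
            j += 1
    return records


def _ranges(people, spec):
    """Apply {key: (start, stop, field)} positional assignments."""
    for value, (a, b), fld in spec:
        for r in people[a:b]:
            if fld == "treatments":
                r.setdefault("treatments", set()).add(value)
            elif fld == "reasons":
                r.setdefault("reasons", set()).add(value)
            else:
                r[fld] = value


def _assign_care(nw, w):
    """Facility, reasons, treatments and disclosure for the 126 care
    seekers without and 23 with warning signs, matching the published
    cross-tabulated counts.  The lists are ordered with the procedural-
    intervention and IV-fluid rows first."""
    _ranges(nw, [
        ("clinic_hospital", (0, 64), "facility"),
        ("pharmacy_lab", (64, 124), "facility"),
        ("other", (124, 126), "facility"),
        ("confirm_completion", (0, 120), "reasons"),
        ("symptom_concern", (118, 122), "reasons"),
        ("other", (122, 126), "reasons"),
        ("mva", (0, 1), "treatments"),
        ("iv_fluids", (1, 3), "treatments"),
        ("overnight_stay", (1, 2), "treatments"),
        ("observation", (3, 4), "treatments"),
        ("additional_misoprostol", (4, 6), "treatments"),
        ("antibiotics", (6, 8), "treatments"),
        ("pain_medication", (8, 11), "treatments"),
        ("other_medications", (11, 16), "treatments"),
        ("ultrasound", (4, 29), "treatments"),
        ("no_treatment", (29, 126), "treatments"),
        ("did_not_tell", (0, 104), "disclosure"),
        ("said_miscarriage", (104, 108), "disclosure"),
        ("told_them", (108, 119), "disclosure"),
        ("suspected_or_found_out", (119, 121), "disclosure"),
        ("other", (121, 123), "disclosure"),
    ])
    _ranges(w, [
        ("clinic_hospital", (0, 15), "facility"),
        ("pharmacy_lab", (15, 23), "facility"),
        ("confirm_completion", (0, 13), "reasons"),
        ("symptom_concern", (9, 21), "reasons"),
        ("other", (21, 23), "reasons"),
        ("mva", (0, 1), "treatments"),
        ("iv_fluids", (1, 5), "treatments"),
        ("overnight_stay", (1, 2), "treatments"),
        ("dc", (3, 4), "treatments"),
        ("overnight_stay", (3, 4), "treatments"),
        ("observation", (5, 7), "treatments"),
        ("antibiotics", (5, 14), "treatments"),
        ("pain_medication", (7, 16), "treatments"),
        ("other_medications", (10, 18), "treatments"),
        ("ultrasound", (11, 20), "treatments"),
        ("no_treatment", (20, 23), "treatments"),
        ("did_not_tell", (0, 11), "disclosure"),
        ("said_miscarriage", (11, 12), "disclosure"),
        ("told_them", (12, 18), "disclosure"),
        ("suspected_or_found_out", (18, 20), "disclosure"),
        ("other", (20, 22), "disclosure"),
    ])


def _assign_demographics(endorsed, others):
    """Site, age, education, prior attempts and pregnancy confirmation,
    by position within regimen groups (the published table crosses these
    only with regimen)."""
    _ranges(endorsed, [
        ("argentina", (0, 1), "site"),
        ("nigeria", (1, 532), "site"),
        ("lt20", (0, 17), "age_group"),
        ("20to24", (17, 140), "age_group"),
        ("25to29", (140, 328), "age_group"),
        ("30to34", (328, 434), "age_group"),
        ("ge35", (434, 532), "age_group"),
        ("primary", (0, 11), "education"),
        ("secondary", (11, 237), "education"),
        ("more_than_secondary", (237, 532), "education"),
        ("no", (0, 514), "prior_attempt"),
        ("yes", (514, 532), "prior_attempt"),
    ])
    _ranges(others, [
        ("southeast_asia", (0, 45), "site"),
        ("nigeria", (45, 105), "site"),
        ("lt20", (0, 6), "age_group"),
        ("20to24", (6, 40), "age_group"),
        ("25to29", (40, 79), "age_group"),
        ("30to34", (79, 92), "age_group"),
        ("ge35", (92, 105), "age_group"),
        ("primary", (0, 2), "education"),
        ("secondary", (2, 39), "education"),
        ("more_than_secondary", (39, 100), "education"),
        (None, (100, 105), "education"),
        ("no", (0, 86), "prior_attempt"),
        ("yes", (86, 103), "prior_attempt"),
        (None, (103, 105), "prior_attempt"),
    ])
    # pregnancy confirmation (select-all: 617 tests, 22 ultrasounds,
    # 1 missed period, 1 bimanual exam, 4 overlaps)
    for i, r in enumerate(endorsed):
        if i < 525:
            r["confirmation"] = frozenset({"test"})
        elif i < 528:
            r["confirmation"] = frozenset({"test", "ultrasound"})
        elif i == 528:
            r["confirmation"] = frozenset({"missed_period"})
        else:
            r["confirmation"] = frozenset({"ultrasound"})
    for i, r in enumerate(others):
        if i < 88:
            r["confirmation"] = frozenset({"test"})
        elif i == 88:
            r["confirmation"] = frozenset({"test", "ultrasound"})
        elif i < 104:
            r["confirmation"] = frozenset({"ultrasound"})
        else:
            r["confirmation"] = frozenset({"bimanual"})
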