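"""Analysis-endpoint derivation.

Effectiveness is abortion completion *without* procedural intervention
(manual vacuum aspiration or dilation & curettage/evacuation), classified
from the harmonized self-report at each follow-up.  The last-recorded
follow-up carries the 1-week outcome forward for participants who missed
the 3-week interview.

Safety endpoints are OR-composites: any of four warning signs
(heavy bleeding >2 pads/h for >2 h, unrelieved pain, fever >38 C for
>24 h, foul discharge) and any of three adverse-event markers (IV fluids,
transfusion, overnight hospital stay), each measured across both
follow-ups.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Iterable, Optional

import pandas as pd

from .records import ParticipantRecord, WARNING_SIGNS, ADVERSE_EVENTS

log = logging.getLogger(__name__)

TIMEPOINTS = ("fu1", "fu2", "last_recorded")

#: the four effectiveness classes, in reporting order
EFFECTIVENESS_CLASSES = (
    "complete_no_procedure",
    "complete_with_procedure",
    "not_complete_or_unsure",
    "missing",
)


def _intervention_by(record: ParticipantRecord, timepoint: str) -> bool:
    """Did a procedural intervention occur on or before `timepoint`?"""
    if record.procedural_intervention == "none":
        return False
    timing = record.intervention_timing
    if timepoint == "fu1":
        if timing == "fu2_window":
            log.info(
                "participant %s: intervention in fu2 window ignored for fu1",
                record.participant_id,
            )
            return False
        return True
    return True  # fu2 / last_recorded: either window counts


def classify_effectiveness(record: ParticipantRecord, timepoint: str) -> str:
    """Classify one participant's effectiveness outcome at a time point.

    Precedence: a procedural intervention combined with a self-report of
    completion is "complete_with_procedure" (interventions override the
    self-assessment); a completion report with no intervention is
    "complete_no_procedure"; a report of not-complete-or-unsure keeps its
    own class regardless of intervention (this cell is never printed in
    the source tables — classified by self-report and logged); anything
    else is "missing".

    ``last_recorded`` uses the 3-week classification when that follow-up
    was attended, otherwise the 1-week classification (carry-forward).
    """
    if timepoint not in TIMEPOINTS:
        raise ValueError(f"unknown timepoint {timepoint!r}; expected one of {TIMEPOINTS}")
    if timepoint == "last_recorded":
        return classify_effectiveness(record, "fu2" if record.fu2_attended else "fu1")

    status = record.fu1_status if timepoint == "fu1" else record.fu2_status
    intervened = _intervention_by(record, timepoint)
    if status == "complete":
        return "complete_with_procedure" if intervened else "complete_no_procedure"
    if status == "not_complete_or_unsure":
        if intervened:
            log.info(
                "participant %s: intervention with 'not complete or unsure' "
                "self-report at %s; classified by self-report",
                record.participant_id, timepoint,
            )
        return "not_complete_or_unsure"
    return "missing"


def composite_warning_sign(record: ParticipantRecord) -> Optional[bool]:
    """True iff any of the four warning signs was reported.

    Returns ``None`` (missing) only when all four component fields are
    missing; such participants remain in published denominators.
    """
    vals = [getattr(record, f) for f in WARNING_SIGNS]
    if all(v is None for v in vals):
        return None
    return any(bool(v) for v in vals if v is not None)


def composite_adverse_event(record: ParticipantRecord) -> Optional[bool]:
    """True iff any adverse-event marker (IV fluids, transfusion,
    overnight stay) was reported; ``None`` if all three are missing."""
    vals = [getattr(record, f) for f in ADVERSE_EVENTS]
    if all(v is None for v in vals):
        return None
    return any(bool(v) for v in vals if v is not None)


# ---------------------------------------------------------------------------
# Cohort-level conveniences


def attended(record: ParticipantRecord, timepoint: str) -> bool:
    """Whether the participant contributes to the time point's denominator:
    fu1/fu2 require the respective interview; last_recorded includes
    everyone with at least one follow-up."""
    if timepoint == "fu1":
        return record.fu1_status is not None or record.fu1_days is not None or (
            not record.fu2_attended
        )
    if timepoint == "fu2":
        return record.fu2_attended
    if timepoint == "last_recorded":
        return True
    raise ValueError(f"unknown timepoint {timepoint!r}")


def effectiveness_counts(records: Iterable[ParticipantRecord], timepoint: str) -> Counter:
    """Counts of the four effectiveness classes among the time point's
    attendees (fu1: 1-week attendees; fu2: 3-week attendees; last_recorded:
    everyone)."""
    c = Counter({k: 0 for k in EFFECTIVENESS_CLASSES})
    for rec in records:
        if attended(rec, timepoint):
            c[classify_effectiveness(rec, timepoint)] += 1
    return c


def derive_frame(records: Iterable[ParticipantRecord]) -> pd.DataFrame:
    """One row per participant with raw fields plus derived endpoint columns
    (``eff_fu1``/``eff_fu2``/``eff_last``, composite flags, attendance).

    Missing composites are left as ``pd.NA`` so tabulation policies can
    decide denominator handling.
    """
    records = list(records)
    rows = []
    for rec in records:
        ws = composite_warning_sign(rec)
        ae = composite_adverse_event(rec)
        rows.append({
            "participant_id": rec.participant_id,
            "site": rec.site,
            "age_group": rec.age_group,
            "education": rec.education,
            "prior_attempt": rec.prior_attempt,
            "duration_weeks": rec.duration_weeks,
            "regimen": rec.regimen,
            "route": rec.route,
            "source": rec.source,
            "fu1_attended": attended(rec, "fu1"),
            "fu2_attended": rec.fu2_attended,
            "eff_fu1": classify_effectiveness(rec, "fu1") if attended(rec, "fu1") else pd.NA,
            "eff_fu2": classify_effectiveness(rec, "fu2") if rec.fu2_attended else pd.NA,
            "eff_last": classify_effectiveness(rec, "last_recorded"),
            "warning_sign": pd.NA if ws is None else ws,
            "adverse_event": pd.NA if ae is None else ae,
            "sought_care": rec.sought_care,
            "care_facility": rec.care_facility,
            "time_to_expulsion_h": rec.time_to_expulsion_h,
            "bleeding_days": rec.bleeding_days,
            "heavy_bleeding_days": rec.heavy_bleeding_days,
            "cramping_days": rec.cramping_days,
            "pain": rec.pain,
        })
    return pd.DataFrame(rows)
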