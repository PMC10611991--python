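"""Participant data model and delimited-file I/O.

One :class:`ParticipantRecord` per enrolled participant, carrying baseline
characteristics, per-follow-up self-reported outcome fields, symptom and
care-seeking fields.  Enum-like fields are stored as lowercase string
tokens; missing values are ``None`` (empty cells on disk).  Set-valued
fields (pregnancy confirmation methods, care-seeking reasons, treatments,
side effects) are serialized as ``;``-joined token lists.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

# ---------------------------------------------------------------------------
# Controlled vocabularies

SITES = ("argentina", "nigeria", "southeast_asia")
AGE_GROUPS = ("lt20", "20to24", "25to29", "30to34", "ge35")
EDUCATION = ("primary", "secondary", "more_than_secondary")
YES_NO = ("yes", "no")
CONFIRMATION = ("test", "missed_period", "ultrasound", "bimanual")
DURATION_BINS = ("lt7", "7to_lt9", "9to_lt12", "12to16")
REGIMENS = ("endorsed_3x800", "other")
ROUTES = ("sublingual", "other")
SOURCES = ("pharmacy", "other")
FU_STATUS = ("complete", "not_complete_or_unsure")
INTERVENTIONS = ("none", "mva", "dc")
INTERVENTION_TIMING = ("fu1_window", "fu2_window")
WARNING_SIGNS = (
    "heavy_bleeding_2pads_2h",
    "unrelieved_pain",
    "fever_gt38_24h",
    "foul_discharge",
)
ADVERSE_EVENTS = ("iv_fluids", "transfusion", "overnight_stay")
CARE_FACILITIES = ("clinic_hospital", "pharmacy_lab", "other")
CARE_REASONS = ("confirm_completion", "symptom_concern", "other")
CARE_TREATMENTS = (
    "observation",
    "additional_misoprostol",
    "antibiotics",
    "pain_medication",
    "other_medications",
    "mva",
    "dc",
    "ultrasound",
    "iv_fluids",
    "transfusion",
    "overnight_stay",
    "no_treatment",
)
DISCLOSURE = (
    "did_not_tell",
    "said_miscarriage",
    "told_them",
    "suspected_or_found_out",
    "other",
)
SIDE_EFFECTS = (
    "nausea",
    "fever",
    "diarrhea",
    "chills",
    "vomiting",
    "itchiness_hives",
    "difficulty_breathing",
    "facial_numbness",
    "sweaty_hands",
)

#: sentinel for expulsion never observed (products of conception not noticed)
NOT_OBSERVED = "not_observed"


@dataclass
class ParticipantRecord:
    """A single enrolled participant.

    ``fu1_status`` / ``fu2_status`` hold the harmonized binary self-report
    ("complete" vs "not_complete_or_unsure"); ``None`` means the follow-up
    was missed or the answer is missing.  ``time_to_expulsion_h`` is hours
    from the first dose, :data:`NOT_OBSERVED` if products of conception
    were never noticed, or ``None`` if missing.
    """

    participant_id: str
    site: str = "nigeria"
    age_group: Optional[str] = None
    education: Optional[str] = None
    prior_attempt: Optional[str] = None
    pregnancy_confirmation: frozenset = frozenset()
    duration_weeks: str = "lt7"
    regimen: str = "endorsed_3x800"
    route: str = "sublingual"
    source: str = "pharmacy"
    fu1_status: Optional[str] = None
    fu1_days: Optional[int] = None
    fu2_status: Optional[str] = None
    fu2_days: Optional[int] = None
    fu2_attended: bool = False
    procedural_intervention: str = "none"
    intervention_timing: Optional[str] = None
    heavy_bleeding_2pads_2h: Optional[bool] = False
    unrelieved_pain: Optional[bool] = False
    fever_gt38_24h: Optional[bool] = False
    foul_discharge: Optional[bool] = False
    iv_fluids: Optional[bool] = False
    transfusion: Optional[bool] = False
    overnight_stay: Optional[bool] = False
    sought_care: bool = False
    care_facility: Optional[str] = None
    care_reasons: frozenset = frozenset()
    care_treatments: frozenset = frozenset()
    disclosure: Optional[str] = None
    time_to_expulsion_h: Optional[object] = None  # float | NOT_OBSERVED | None
    bleeding_days: Optional[float] = None
    heavy_bleeding_days: Optional[float] = None
    cramping_days: Optional[float] = None
    pain: Optional[bool] = None
    side_effects: Optional[frozenset] = field(default_factory=frozenset)

    def validate(self) -> list:
        """Return a list of invariant-violation messages (empty if valid)."""
        errs = []

        def chk(value, vocab, name, nullable=True):
            if value is None:
                if not nullable:
                    errs.append(f"{name}: missing not allowed")
            elif value not in vocab:
                errs.append(f"{name}: unknown token {value!r}")

        chk(self.site, SITES, "site", nullable=False)
        chk(self.age_group, AGE_GROUPS, "age_group")
        chk(self.education, EDUCATION, "education")
        chk(self.prior_attempt, YES_NO, "prior_attempt")
        chk(self.duration_weeks, DURATION_BINS, "duration_weeks", nullable=False)
        chk(self.regimen, REGIMENS, "regimen", nullable=False)
        chk(self.route, ROUTES, "route")
        chk(self.source, SOURCES, "source")
        chk(self.fu1_status, FU_STATUS, "fu1_status")
        chk(self.fu2_status, FU_STATUS, "fu2_status")
        chk(self.procedural_intervention, INTERVENTIONS, "procedural_intervention",
            nullable=False)
        chk(self.intervention_timing, INTERVENTION_TIMING, "intervention_timing")
        chk(self.care_facility, CARE_FACILITIES, "care_facility")
        chk(self.disclosure, DISCLOSURE, "disclosure")
        for tok in self.pregnancy_confirmation:
            chk(tok, CONFIRMATION, "pregnancy_confirmation")
        for tok in self.care_reasons:
            chk(tok, CARE_REASONS, "care_reasons")
        for tok in self.care_treatments:
            chk(tok, CARE_TREATMENTS, "care_treatments")
        for tok in (self.side_effects or ()):
            chk(tok, SIDE_EFFECTS, "side_effects")
        if not self.fu2_attended and self.fu2_status is not None:
            errs.append("fu2_attended is false but fu2_status is recorded")
        if self.procedural_intervention != "none" and self.intervention_timing is None:
            errs.append("procedural_intervention set without intervention_timing")
        if isinstance(self.time_to_expulsion_h, (int, float)) and self.time_to_expulsion_h < 0:
            errs.append("time_to_expulsion_h: negative")
        for name in ("bleeding_days", "heavy_bleeding_days", "cramping_days"):
            v = getattr(self, name)
            if v is not None and v < 0:
                errs.append(f"{name}: negative")
        return errs


class RecordValidationError(ValueError):
    """Raised after a full validation pass; carries per-row diagnostics."""

    def __init__(self, diagnostics):
        self.diagnostics = diagnostics
        lines = [f"row {i}: {msg}" for i, msgs in diagnostics for msg in msgs]
        super().__init__(
            f"{len(diagnostics)} invalid record(s):\n" + "\n".join(lines)
        )


def validate_records(records: Iterable[ParticipantRecord]) -> None:
    """Validate every record; raise :class:`RecordValidationError` listing
    all offending rows (full pass, not fail-on-first)."""
    diagnostics = []
    for i, rec in enumerate(records):
        errs = rec.validate()
        if errs:
            diagnostics.append((i, errs))
    if diagnostics:
        raise RecordValidationError(diagnostics)


# ---------------------------------------------------------------------------
# Serialization

_SET_FIELDS = {"pregnancy_confirmation", "care_reasons", "care_treatments",
               "side_effects"}
_BOOL_FIELDS = {"fu2_attended", "sought_care", "pain",
                *WARNING_SIGNS, *ADVERSE_EVENTS}
_INT_FIELDS = {"fu1_days", "fu2_days"}
_FLOAT_FIELDS = {"bleeding_days", "heavy_bleeding_days", "cramping_days"}

FIELD_NAMES = tuple(f.name for f in dc_fields(ParticipantRecord))


def _cell(rec: ParticipantRecord, name: str) -> str:
    v = getattr(rec, name)
    if v is None:
        return ""
    if name in _SET_FIELDS:
        # an empty set is a real observation ("none reported") and must not
        # collapse into the missing empty cell
        return ";".join(sorted(v)) if v else "none"
    if name in _BOOL_FIELDS:
        return "true" if v else "false"
    return str(v)


def _parse(name: str, cell: str):
    if cell == "":
        return None
    if name in _SET_FIELDS:
        return frozenset() if cell == "none" else frozenset(cell.split(";"))
    if name in _BOOL_FIELDS:
        if cell not in ("true", "false"):
            raise ValueError(f"{name}: expected true/false, got {cell!r}")
        return cell == "true"
    if name in _INT_FIELDS:
        return int(cell)
    if name in _FLOAT_FIELDS:
        return float(cell)
    if name == "time_to_expulsion_h":
        return cell if cell == NOT_OBSERVED else float(cell)
    return cell


def write_records(records: Iterable[ParticipantRecord], path) -> None:
    """Write records to CSV (one row per participant, empty cell = missing)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(FIELD_NAMES)
        for rec in records:
            w.writerow([_cell(rec, n) for n in FIELD_NAMES])


def read_records(path, validate: bool = True) -> list:
    """Read a participant CSV written by :func:`write_records`.

    With ``validate=True`` (default) a full validation pass runs and a
    :class:`RecordValidationError` lists every bad row at once.
    """
    path = Path(path)
    out = []
    with path.open(newline="") as fh:
        r = csv.reader(fh)
        header = next(r)
        unknown = set(header) - set(FIELD_NAMES)
        if unknown:
            raise ValueError(f"unknown columns: {sorted(unknown)}")
        for row in r:
            kw = {name: _parse(name, cell) for name, cell in zip(header, row)}
            for sf in _SET_FIELDS - {"side_effects"}:
                if kw.get(sf) is None:
                    kw[sf] = frozenset()
            out.append(ParticipantRecord(**kw))
    if validate:
        validate_records(out)
    return out


def records_to_frame(records: Iterable[ParticipantRecord]) -> pd.DataFrame:
    """Flatten records to a DataFrame (sets become ;-joined strings)."""
    rows = [{n: _cell(r, n) for n in FIELD_NAMES} for r in records]
    df = pd.DataFrame(rows, columns=list(FIELD_NAMES))
    return df.replace({"": None})


DATA_DICTIONARY = {
    "participant_id": "opaque identifier",
    "site": f"study site, one of {SITES}",
    "age_group": f"age band, one of {AGE_GROUPS}",
    "education": f"highest education, one of {EDUCATION}",
    "prior_attempt": "prior attempt to end this pregnancy (yes/no)",
    "pregnancy_confirmation": f";-joined subset of {CONFIRMATION}",
    "duration_weeks": f"pregnancy duration bin at first dose, one of {DURATION_BINS}",
    "regimen": "endorsed_3x800 = 3 doses of 800 ug misoprostol 3 h apart; else other",
    "route": f"administration route, one of {ROUTES}",
    "source": f"where misoprostol was obtained, one of {SOURCES}",
    "fu1_status": "self-report at ~1-week follow-up (complete / not_complete_or_unsure); empty = missed/missing",
    "fu1_days": "days from first dose to first follow-up",
    "fu2_status": "self-report at ~3-week follow-up",
    "fu2_days": "days from first dose to second follow-up",
    "fu2_attended": "completed the 3-week follow-up (true/false)",
    "procedural_intervention": f"one of {INTERVENTIONS}",
    "intervention_timing": "follow-up window in which the procedure occurred",
    "heavy_bleeding_2pads_2h": "warning sign: bleeding soaking >2 pads/h for >2 h",
    "unrelieved_pain": "warning sign: pain not relieved by analgesics",
    "fever_gt38_24h": "warning sign: fever >38 C for >24 h",
    "foul_discharge": "warning sign: foul-smelling vaginal discharge",
    "iv_fluids": "adverse-event marker: received intravenous fluids",
    "transfusion": "adverse-event marker: received blood transfusion",
    "overnight_stay": "adverse-event marker: overnight hospital stay",
    "sought_care": "ever sought follow-up health care",
    "care_facility": f"one of {CARE_FACILITIES}",
    "care_reasons": f";-joined subset of {CARE_REASONS}",
    "care_treatments": f";-joined subset of {CARE_TREATMENTS}",
    "disclosure": "whether the clinician was told about the self-managed abortion",
    "time_to_expulsion_h": "hours from first dose to expulsion; 'not_observed' if never noticed",
    "bleeding_days": "days of any bleeding",
    "heavy_bleeding_days": "days of heavy bleeding",
    "cramping_days": "days of cramping (0.5 = under one day)",
    "pain": "experienced abortion-related pain",
    "side_effects": f";-joined subset of {SIDE_EFFECTS}; empty set = none reported",
}


def write_data_dictionary(path) -> None:
    """Emit the column-by-column data dictionary as CSV."""
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["field", "description"])
        for k in FIELD_NAMES:
            w.writerow([k, DATA_DICTIONARY[k]])
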