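"""Core record types for post-operative encounter data.

A :class:`VisitRecord` is the unit of labeling: one hospital encounter with
its demographics, timestamped medication administrations, administrative
codes, ventilation duration, emergency-department day offsets and clinical
notes.  All timestamps are integer day offsets relative to admission
(day 0); the source regime is de-identified, so no calendar dates exist.

Synthetic administrative codes carry an explicit semantic tag embedded in
the code string, ``SYN:<tag>:<number>`` (e.g. ``SYN:respiratory_failure:3``),
replacing real ICD/CPT code lists.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional

from .errors import RecordValidationError

#: semantic tags the synthetic code system can carry
CODE_TAGS = frozenset(
    {
        "respiratory_failure",
        "sepsis",
        "myocardial_infarction",
        "cardiovascular",
        "cerebrovascular",
        "prolonged_vent",
        "qualifying_procedure",
        "other",
    }
)


def make_code(tag: str, number: int) -> str:
    if tag not in CODE_TAGS:
        raise ValueError(f"unknown code tag {tag!r}")
    return f"SYN:{tag}:{number}"


def code_tag(code: str) -> Optional[str]:
    """Return the semantic tag of a synthetic code, or None if unparseable."""
    parts = code.split(":")
    if len(parts) == 3 and parts[0] == "SYN" and parts[1] in CODE_TAGS:
        return parts[1]
    return None


@dataclass(frozen=True)
class MedAdmin:
    """One medication administration event."""

    drug: str
    route: str
    day: int


@dataclass(frozen=True)
class Note:
    """One clinical note (title, author role, day offset, free text)."""

    title: str
    author_role: str
    day: int
    text: str


@dataclass
class VisitRecord:
    visit_id: str
    patient_id: str
    age: int
    gender: str
    surgery_day: int
    qualifying_procedure: bool
    ahrq_flag: bool
    ed_visit_days: frozenset = field(default_factory=frozenset)
    diagnosis_codes: list = field(default_factory=list)
    procedure_codes: list = field(default_factory=list)
    vent_days: int = 0
    med_admins: list = field(default_factory=list)  # list[MedAdmin]
    notes: list = field(default_factory=list)  # list[Note]

    def validate(self) -> None:
        if self.vent_days < 0:
            raise RecordValidationError(f"{self.visit_id}: vent_days < 0")
        if self.surgery_day is None:
            raise RecordValidationError(f"{self.visit_id}: missing surgery_day")
        for n in self.notes:
            if n.day < 0:
                raise RecordValidationError(
                    f"{self.visit_id}: note day offset {n.day} outside encounter span"
                )

    # ---- JSON-lines serialization ------------------------------------
    def to_json_obj(self) -> dict:
        d = asdict(self)
        d["ed_visit_days"] = sorted(self.ed_visit_days)
        d["med_admins"] = [[m.drug, m.route, m.day] for m in self.med_admins]
        d["notes"] = [[n.title, n.author_role, n.day, n.text] for n in self.notes]
        return d

    @classmethod
    def from_json_obj(cls, d: dict) -> "VisitRecord":
        return cls(
            visit_id=d["visit_id"],
            patient_id=d["patient_id"],
            age=d["age"],
            gender=d["gender"],
            surgery_day=d["surgery_day"],
            qualifying_procedure=d["qualifying_procedure"],
            ahrq_flag=d["ahrq_flag"],
            ed_visit_days=frozenset(d["ed_visit_days"]),
            diagnosis_codes=list(d["diagnosis_codes"]),
            procedure_codes=list(d["procedure_codes"]),
            vent_days=d["vent_days"],
            med_admins=[MedAdmin(*m) for m in d["med_admins"]],
            notes=[Note(*n) for n in d["notes"]],
        )


@dataclass(frozen=True)
class LatentTruth:
    """Ground-truth outcome for one synthetic visit.

    Stands in for manual adjudication; only evaluation and diagnostics may
    see it — labeling and label-model fitting never do.
    """

    visit_id: str
    oird: bool


def write_visits_jsonl(visits: Iterable[VisitRecord], path) -> None:
    with open(path, "w") as fh:
        for v in visits:
            fh.write(json.dumps(v.to_json_obj(), separators=(",", ":")) + "\n")


def read_visits_jsonl(path) -> list:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(VisitRecord.from_json_obj(json.loads(line)))
    return out


def write_truth_jsonl(truth: Iterable[LatentTruth], path) -> None:
    with open(path, "w") as fh:
        for t in truth:
            fh.write(
                json.dumps({"visit_id": t.visit_id, "oird": t.oird}, separators=(",", ":"))
                + "\n"
            )


def read_truth_jsonl(path) -> list:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                d = json.loads(line)
                out.append(LatentTruth(d["visit_id"], bool(d["oird"])))
    return out
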