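"""The 14 expert labeling functions (LFs) for OIRD and LF diagnostics.

Each LF inspects one :class:`~oirdlab.types.VisitRecord` — its medication
administrations, administrative codes, ventilation duration and note text —
and votes ``1`` (case), ``0`` (control) or ``-1`` (abstain).  The LFs are a
lexicon-driven rule engine: every keyword family is configurable through
:class:`~oirdlab.lexicons.LexiconSet`.

Decision table (Yes-branch / No-branch on the question each LF asks):

======  ==============================================================
LF1     received naloxone?  no -> 0; yes and an effectiveness keyword
        within ``window`` tokens of a naloxone mention in a note -> 1;
        an ineffectiveness keyword so placed -> 0; neither -> abstain.
        Effectiveness takes precedence when both occur.
LF2     naloxone-ineffectiveness keyword count > effectiveness count
        -> 0; any keywords otherwise -> 1; none -> abstain.
LF3     mechanical ventilation >= 4 days -> 0; else abstain.
LF4     respiratory-failure diagnosis code and ventilation >= 1 day
        -> 0; else abstain.
LF5     no note titled "Respiratory Care" -> 0; else abstain.
LF6     narcotic-overdose keywords -> 1; else abstain.
LF7     hypoxia keywords within ``window`` tokens of opioid/narcotic
        terms in the same note -> 1; else abstain.
LF8     decreasing-opioids keywords -> 1; else abstain.
LF9     holding-opioids keywords -> 1; else abstain.
LF10    no-pain-meds keywords -> 0; else abstain.
LF11    altered-mental-status keywords: with a confounding diagnosis
        code (e.g. sepsis) -> abstain; without -> 1; none -> abstain.
LF12    pinpoint-pupils keywords -> 1; else abstain.
LF13    "no acute events" phrase: with acute-event keywords anywhere in
        the visit -> abstain; without -> 0; phrase absent -> abstain.
LF14    no OIRD-support keywords anywhere -> 0; any present -> abstain.
======  ==============================================================

No general negation detection is applied beyond the phrase lists above;
that is a documented limitation of the rule engine.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np

from .errors import OirdlabError
from .lexicons import LexiconSet
from .textmatch import spans_within, tokenize
from .types import VisitRecord, code_tag

ABSTAIN, NO, YES = -1, 0, 1
VOTE_VALUES = (ABSTAIN, NO, YES)

LF_IDS = [f"LF{i}" for i in range(1, 15)]

RESPIRATORY_CARE_TITLE = "respiratory care"


def proximity_match(text, lex_a, lex_b, window):
    """Re-exported from :mod:`oirdlab.textmatch` (LF1/LF7 primitive)."""
    from .textmatch import proximity_match as _pm

    return _pm(text, lex_a, lex_b, window)


class VisitScan:
    """One-pass tokenization + lexicon scan of all notes of a visit.

    Shared by the LF engine and by feature extraction so each note is
    tokenized exactly once.
    """

    __slots__ = ("visit", "note_hits", "counts")

    def __init__(self, visit: VisitRecord, lexicons: LexiconSet):
        self.visit = visit
        index = lexicons.index
        self.note_hits = []  # per note: dict lexicon name -> list of spans
        counts: Dict[str, int] = {}
        for note in visit.notes:
            hits = index.scan(tokenize(note.text))
            self.note_hits.append(hits)
            for name, spans in hits.items():
                counts[name] = counts.get(name, 0) + len(spans)
        self.counts = counts

    def count(self, name: str) -> int:
        return self.counts.get(name, 0)

    def any_proximity(self, name_a: str, name_b: str, window: int) -> bool:
        for hits in self.note_hits:
            a = hits.get(name_a)
            if not a:
                continue
            b = hits.get(name_b)
            if b and spans_within(a, b, window):
                return True
        return False


def _naloxone_given(visit: VisitRecord, lexicons: LexiconSet, parenteral_only: bool) -> bool:
    drugs = {d.lower() for d in lexicons.naloxone_drugs}
    for m in visit.med_admins:
        if m.drug.lower() in drugs:
            if not parenteral_only or m.route.lower() in ("iv", "im", "sc", "parenteral"):
                return True
    return False


def _visit_code_tags(visit: VisitRecord) -> set:
    tags = set()
    for c in visit.diagnosis_codes:
        t = code_tag(c)
        if t:
            tags.add(t)
    for c in visit.procedure_codes:
        t = code_tag(c)
        if t:
            tags.add(t)
    return tags


def _diag_code_tags(visit: VisitRecord) -> set:
    return {t for t in (code_tag(c) for c in visit.diagnosis_codes) if t}


def evaluate_lf(
    visit: VisitRecord,
    lf_id: str,
    lexicons: LexiconSet,
    scan: Optional[VisitScan] = None,
    parenteral_only: bool = False,
) -> int:
    """Evaluate one labeling function on one visit.

    ``scan`` may be passed to reuse a precomputed :class:`VisitScan`.
    """
    if lf_id not in LF_IDS:
        raise OirdlabError(f"unknown labeling function id {lf_id!r}")
    if scan is None:
        scan = VisitScan(visit, lexicons)
    w = lexicons.window

    if lf_id == "LF1":
        if not _naloxone_given(visit, lexicons, parenteral_only):
            return NO
        if scan.any_proximity("naloxone_effective", "naloxone_drugs", w):
            return YES
        if scan.any_proximity("naloxone_ineffective", "naloxone_drugs", w):
            return NO
        return ABSTAIN

    if lf_id == "LF2":
        eff = scan.count("naloxone_effective")
        ineff = scan.count("naloxone_ineffective")
        if ineff > eff:
            return NO
        if eff + ineff > 0:
            return YES
        return ABSTAIN

    if lf_id == "LF3":
        return NO if visit.vent_days >= 4 else ABSTAIN

    if lf_id == "LF4":
        if "respiratory_failure" in _diag_code_tags(visit) and visit.vent_days >= 1:
            return NO
        return ABSTAIN

    if lf_id == "LF5":
        for note in visit.notes:
            if " ".join(note.title.lower().split()) == RESPIRATORY_CARE_TITLE:
                return ABSTAIN
        return NO

    if lf_id == "LF6":
        return YES if scan.count("narcotic_overdose") > 0 else ABSTAIN

    if lf_id == "LF7":
        return YES if scan.any_proximity("hypoxia", "opioid_terms", w) else ABSTAIN

    if lf_id == "LF8":
        return YES if scan.count("decreasing_opioids") > 0 else ABSTAIN

    if lf_id == "LF9":
        return YES if scan.count("holding_opioids") > 0 else ABSTAIN

    if lf_id == "LF10":
        return NO if scan.count("no_pain_meds") > 0 else ABSTAIN

    if lf_id == "LF11":
        if scan.count("altered_mental_status") == 0:
            return ABSTAIN
        confounders = set(lexicons.confounding_diagnosis_tags)
        if _visit_code_tags(visit) & confounders:
            return ABSTAIN
        return YES

    if lf_id == "LF12":
        return YES if scan.count("pinpoint_pupils") > 0 else ABSTAIN

    if lf_id == "LF13":
        if scan.count("no_acute_events_phrase") == 0:
            return ABSTAIN
        if scan.count("acute_event_terms") > 0:
            return ABSTAIN
        return NO

    if lf_id == "LF14":
        return NO if scan.count("oird_support_terms") == 0 else ABSTAIN

    raise AssertionError("unreachable")


@dataclass
class LabelMatrix:
    """m visits x n LFs of integer votes in {-1, 0, 1}."""

    visit_ids: List[str]
    lf_ids: List[str]
    votes: np.ndarray  # (m, n) int8

    def __post_init__(self):
        self.votes = np.asarray(self.votes, dtype=np.int8)
        if self.votes.shape != (len(self.visit_ids), len(self.lf_ids)):
            raise OirdlabError("label matrix shape does not match id lists")
        if not np.isin(self.votes, VOTE_VALUES).all():
            raise OirdlabError("label matrix entries must be in {-1, 0, 1}")

    @property
    def m(self) -> int:
        return len(self.visit_ids)

    @property
    def n(self) -> int:
        return len(self.lf_ids)

    def row(self, visit_id: str) -> np.ndarray:
        return self.votes[self.visit_ids.index(visit_id)]

    def subset(self, visit_ids: Sequence[str]) -> "LabelMatrix":
        pos = {v: i for i, v in enumerate(self.visit_ids)}
        idx = [pos[v] for v in visit_ids]
        return LabelMatrix(list(visit_ids), list(self.lf_ids), self.votes[idx])

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["visit_id"] + self.lf_ids)
            for vid, row in zip(self.visit_ids, self.votes):
                wr.writerow([vid] + [int(x) for x in row])

    @classmethod
    def from_csv(cls, path) -> "LabelMatrix":
        with open(path, newline="") as fh:
            rd = csv.reader(fh)
            header = next(rd)
            lf_ids = header[1:]
            visit_ids, rows = [], []
            for rec in rd:
                visit_ids.append(rec[0])
                rows.append([int(x) for x in rec[1:]])
        return cls(visit_ids, lf_ids, np.array(rows, dtype=np.int8))


def build_label_matrix(
    visits: Sequence[VisitRecord],
    lexicons: LexiconSet,
    parenteral_only: bool = False,
) -> LabelMatrix:
    """Evaluate all 14 LFs on every visit (deterministic)."""
    if not visits:
        raise OirdlabError("cannot build a label matrix from zero visits")
    votes = np.empty((len(visits), len(LF_IDS)), dtype=np.int8)
    for i, visit in enumerate(visits):
        scan = VisitScan(visit, lexicons)
        for j, lf_id in enumerate(LF_IDS):
            votes[i, j] = evaluate_lf(visit, lf_id, lexicons, scan, parenteral_only)
    return LabelMatrix([v.visit_id for v in visits], list(LF_IDS), votes)


@dataclass
class LFDiagnostics:
    """Per-LF coverage / overlap / conflict and (optional) empirical accuracy."""

    lf_ids: List[str]
    coverage: Dict[str, float]
    overlap: Dict[str, float]
    conflict: Dict[str, float]
    empirical_accuracy: Dict[str, Optional[float]]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "coverage": [self.coverage[l] for l in self.lf_ids],
                "overlap": [self.overlap[l] for l in self.lf_ids],
                "conflict": [self.conflict[l] for l in self.lf_ids],
                "empirical_accuracy": [self.empirical_accuracy[l] for l in self.lf_ids],
            },
            index=self.lf_ids,
        )


def lf_diagnostics(
    matrix: LabelMatrix, reference: Optional[Mapping[str, int]] = None
) -> LFDiagnostics:
    """Coverage, overlap, conflict and (against ``reference``) accuracy.

    * coverage — fraction of visits with a non-abstain vote;
    * overlap — fraction where the LF and at least one other LF vote;
    * conflict — fraction where another non-abstain vote disagrees;
    * empirical_accuracy — fraction of the LF's non-abstain votes matching
      the reference labels, over referenced visits only; ``None`` when the
      LF abstains on every referenced visit.
    """
    V = matrix.votes
    m = matrix.m
    obs = V != ABSTAIN
    n_obs_per_visit = obs.sum(axis=1)
    coverage, overlap, conflict, acc = {}, {}, {}, {}
    for j, lf in enumerate(matrix.lf_ids):
        oj = obs[:, j]
        coverage[lf] = float(oj.sum()) / m
        others = oj & (n_obs_per_visit >= 2)
        overlap[lf] = float(others.sum()) / m
        disagree = 0
        if others.any():
            rows = np.where(others)[0]
            vj = V[rows, j]
            for r, v in zip(rows, vj):
                other_votes = V[r][obs[r]]
                if np.any(other_votes != v):
                    disagree += 1
        conflict[lf] = float(disagree) / m
        acc[lf] = None

    if reference is not None:
        pos = {vid: i for i, vid in enumerate(matrix.visit_ids)}
        ref_rows = [(pos[vid], y) for vid, y in reference.items() if vid in pos]
        for j, lf in enumerate(matrix.lf_ids):
            n_votes = correct = 0
            for r, y in ref_rows:
                v = V[r, j]
                if v != ABSTAIN:
                    n_votes += 1
                    correct += int(v == y)
            acc[lf] = (correct / n_votes) if n_votes else None

    return LFDiagnostics(list(matrix.lf_ids), coverage, overlap, conflict, acc)
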