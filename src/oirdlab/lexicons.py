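"""Keyword lexicons driving the labeling functions and note features.

The published decision table gives only example terms for each keyword
family; the full lists are an editorial choice here, shipped as defaults and
overridable from a YAML file (one list per name, plus the proximity
``window``).  All matching is case-insensitive after whitespace
normalization (see :mod:`oirdlab.textmatch`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from typing import Dict, List, Optional

import yaml

from .errors import ConfigError
from .textmatch import LexiconIndex

_DEFAULTS: Dict[str, List[str]] = {
    "naloxone_drugs": ["naloxone", "narcan"],
    "naloxone_effective": ["improved", "well", "alert", "responsive", "arousable"],
    "naloxone_ineffective": ["no response", "lack", "without", "unresponsive"],
    "narcotic_overdose": ["narcotic overdose", "opioid overdose", "oversedation"],
    "hypoxia": ["hypoxia", "hypoxic", "desaturation", "desaturated", "spo2"],
    "opioid_terms": ["opioid", "opioids", "narcotic", "narcotics", "opiate", "opiates"],
    "decreasing_opioids": [
        "decreasing opioids",
        "decreased opioids",
        "weaning opioids",
        "reduced opioid dose",
    ],
    "holding_opioids": ["holding opioids", "held opioids", "hold opioids", "opioids held"],
    "no_pain_meds": ["no pain medication", "no pain meds", "declined pain medication"],
    "altered_mental_status": ["altered mental status", "somnolent", "obtunded", "lethargic"],
    "pinpoint_pupils": ["pinpoint pupils", "miosis", "pupils pinpoint"],
    "no_acute_events_phrase": ["no acute events"],
    "acute_event_terms": ["rapid response", "altered mental status"],
    "confounding_diagnosis_tags": ["sepsis", "myocardial_infarction"],
}

#: lexicons whose union forms the default OIRD-support list
_SUPPORT_UNION = (
    "hypoxia",
    "acute_event_terms",
    "pinpoint_pupils",
    "narcotic_overdose",
    "altered_mental_status",
)

_LIST_FIELDS = list(_DEFAULTS) + ["oird_support_terms"]


@dataclass
class LexiconSet:
    naloxone_drugs: List[str] = field(default_factory=lambda: list(_DEFAULTS["naloxone_drugs"]))
    naloxone_effective: List[str] = field(
        default_factory=lambda: list(_DEFAULTS["naloxone_effective"])
    )
    naloxone_ineffective: List[str] = field(
        default_factory=lambda: list(_DEFAULTS["naloxone_ineffective"])
    )
    narcotic_overdose: List[str] = field(
        default_factory=lambda: list(_DEFAULTS["narcotic_overdose"])
    )
    hypoxia: List[str] = field(default_factory=lambda: list(_DEFAULTS["hypoxia"]))
    opioid_terms: List[str] = field(default_factory=lambda: list(_DEFAULTS["opioid_terms"]))
    decreasing_opioids: List[str] = field(
        default_factory=lambda: list(_DEFAULTS["decreasing_opioids"])
    )
    holding_opioids: List[str] = field(
        default_factory=lambda: list(_DEFAULTS["holding_opioids"])
    )
    no_pain_meds: List[str] = field(default_factory=lambda: list(_DEFAULTS["no_pain_meds"]))
    altered_mental_status: List[str] = field(
        default_factory=lambda: list(_DEFAULTS["altered_mental_status"])
    )
    pinpoint_pupils: List[str] = field(
        default_factory=lambda: list(_DEFAULTS["pinpoint_pupils"])
    )
    no_acute_events_phrase: List[str] = field(
        default_factory=lambda: list(_DEFAULTS["no_acute_events_phrase"])
    )
    acute_event_terms: List[str] = field(
        default_factory=lambda: list(_DEFAULTS["acute_event_terms"])
    )
    #: None -> union of hypoxia/acute events/pinpoint pupils/overdose/AMS
    oird_support_terms: Optional[List[str]] = None
    confounding_diagnosis_tags: List[str] = field(
        default_factory=lambda: list(_DEFAULTS["confounding_diagnosis_tags"])
    )
    window: int = 10

    def __post_init__(self):
        if self.oird_support_terms is None:
            union: List[str] = []
            for name in _SUPPORT_UNION:
                for t in getattr(self, name):
                    if t not in union:
                        union.append(t)
            self.oird_support_terms = union
        self.validate()
        self._index = None

    def validate(self) -> None:
        if self.window < 1:
            raise ConfigError("window", "must be >= 1")
        for f in _LIST_FIELDS:
            if not getattr(self, f):
                raise ConfigError(f, "lexicon list must be non-empty")

    # ---- scanning ----------------------------------------------------
    #: names scanned in note text (code-tag lists excluded)
    SCAN_NAMES = (
        "naloxone_drugs",
        "naloxone_effective",
        "naloxone_ineffective",
        "narcotic_overdose",
        "hypoxia",
        "opioid_terms",
        "decreasing_opioids",
        "holding_opioids",
        "no_pain_meds",
        "altered_mental_status",
        "pinpoint_pupils",
        "no_acute_events_phrase",
        "acute_event_terms",
        "oird_support_terms",
    )

    @property
    def index(self) -> LexiconIndex:
        if self._index is None:
            self._index = LexiconIndex({n: getattr(self, n) for n in self.SCAN_NAMES})
        return self._index

    # ---- serialization ----------------------------------------------
    def to_dict(self) -> dict:
        d = {f: getattr(self, f) for f in _LIST_FIELDS}
        d["confounding_diagnosis_tags"] = list(self.confounding_diagnosis_tags)
        d["window"] = self.window
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "LexiconSet":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "LexiconSet":
        known = {f.name for f in dc_fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(sorted(unknown)[0], "unknown lexicon field")
        return cls(**d)


def default_lexicons() -> LexiconSet:
    return LexiconSet()
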