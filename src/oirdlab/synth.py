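"""Synthetic post-operative EHR cohort generator with latent OIRD truth.

The generator emulates the study regime the pipeline was designed for: a
large surgical cohort with a rare (~1%) outcome, an administrative flag
that is a poor proxy for truth, and heterogeneous per-visit content
(medication administrations, administrative codes, ventilation duration and
clinical notes) from which each of the 14 labeling functions derives its
vote.

Votes are *planted*: for every configured LF the generator first samples
the vote the LF should emit (so that, among non-abstaining visits, the vote
agrees with the latent truth with the configured accuracy), then assembles
note text, medication rows and codes that make the rule engine reproduce
exactly that vote.  Note text is built from sentence templates into which
lexicon keywords (or nothing) are injected, so the regex/token path of the
labeling module is exercised end-to-end rather than simulated.

Sampling scheme
---------------
Let ``a`` be the planted accuracy, ``p`` the planted propensity
(P(non-abstain)) and ``pi`` the outcome prevalence.

* Two-sided LFs (LF1, LF2) vote on any visit with probability ``p`` and
  vote in the direction of the truth with probability ``a``.
* One-sided LFs emit a single non-abstain value ``v`` (e.g. LF6 only ever
  votes "case").  Their accuracy is then P(y = v | vote), which forces
  class-conditional firing rates ``P(vote | y=v) = a*p/P(y=v)`` and
  ``P(vote | y!=v) = (1-a)*p/P(y!=v)``.  Configurations for which these
  exceed 1 are rejected with a :class:`~oirdlab.errors.ConfigError`.
* LF13 and LF14 abstain whenever keywords injected for *other* LFs are
  present, so their firing rates are additionally renormalized by the
  empirically measured fraction of eligible visits per class; when the
  forced-abstention mass exceeds the planted budget the rate clamps at 1
  and the realized accuracy drifts slightly above the planted value.

LF2's abstention is likewise impossible on visits where LF1 placed
naloxone-effectiveness keywords; its direction (hence accuracy) is still
sampled freely, and its firing rate off the forced set is deflated
analytically so the marginal propensity stays close to the configured one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .errors import ConfigError
from .types import LatentTruth, MedAdmin, Note, VisitRecord, make_code

LF_IDS = [f"LF{i}" for i in range(1, 15)]

TWO_SIDED = ("LF1", "LF2")
CASE_SIDED = ("LF6", "LF7", "LF8", "LF9", "LF11", "LF12")
CONTROL_SIDED = ("LF3", "LF4", "LF5", "LF10", "LF13", "LF14")

#: study-condition defaults: planted accuracy per LF
DEFAULT_LF_ACCURACY: Dict[str, float] = {
    "LF1": 0.98,
    "LF2": 0.80,
    "LF3": 0.97,
    "LF4": 0.96,
    "LF5": 0.992,
    "LF6": 0.90,
    "LF7": 0.85,
    "LF8": 0.70,
    "LF9": 0.70,
    "LF10": 0.90,
    "LF11": 0.72,
    "LF12": 0.92,
    "LF13": 0.97,
    "LF14": 0.985,
}

#: study-condition defaults: planted propensity (P(non-abstain)) per LF
DEFAULT_LF_PROPENSITY: Dict[str, float] = {
    "LF1": 0.995,
    "LF2": 0.25,
    "LF3": 0.04,
    "LF4": 0.03,
    "LF5": 0.95,
    "LF6": 0.006,
    "LF7": 0.006,
    "LF8": 0.006,
    "LF9": 0.006,
    "LF10": 0.02,
    "LF11": 0.008,
    "LF12": 0.004,
    "LF13": 0.10,
    "LF14": 0.45,
}

# fraction of LF1 control votes realized through the naloxone-ineffective
# note path (the rest carry no naloxone administration at all)
_LF1_INEFF_FRAC = 0.02
# fraction of LF11 abstentions realized as AMS keywords + confounding code
_LF11_CONFOUND_FRAC = 0.10
# fraction of acute-keyword visits that also receive the "no acute events"
# phrase (exercising LF13's abstain branch)
_LF13_PHRASE_ON_ACUTE = 0.30
# background rapid-response mention rates (case, control)
_RR_BG = (0.08, 0.01)
# background code rates
_BG_CARDIO, _BG_CEREBRO, _BG_SEPSIS, _BG_MI = 0.15, 0.05, 0.03, 0.02
_BG_VENT = 0.02  # short ventilation without respiratory-failure code

# ---------------------------------------------------------------------------
# sentence templates.  Every template is lexicon-clean except for the
# keywords it deliberately injects; tests assert this against the default
# LexiconSet.
# ---------------------------------------------------------------------------
BENIGN_TEMPLATES = [
    "patient resting comfortably vital signs stable plan continue current care",
    "tolerating diet and ambulating in hallway pain controlled on oral regimen",
    "incision clean dry and intact staples to be removed at follow up",
    "physical therapy session completed patient making steady progress toward discharge",
]
TPL_LF1_EFFECTIVE = (
    "narcan administered for low respirations patient subsequently improved and alert"
)
TPL_LF1_INEFFECTIVE = "naloxone given with no response noted"
TPL_LF2_EFF_EXTRA = "family states patient much improved overnight"
TPL_LF2_INEFF_HEAVY = (
    "nursing reports lack of alertness and no response to stimuli overall without improvement"
)
TPL_LF6 = "clinical picture concerning for narcotic overdose requiring intervention"
TPL_LF7 = "patient noted to be hypoxic shortly after narcotic dose with oxygen applied"
TPL_LF8 = "plan includes decreasing opioids given ongoing sedation concerns"
TPL_LF9 = "team recommends holding opioids until respiratory status clears"
TPL_LF10 = "patient required no pain medication today"
TPL_LF11 = "patient with altered mental status and somnolent this morning"
TPL_LF12 = "exam notable for pinpoint pupils bilaterally"
TPL_LF13 = "overnight summary documents no acute events"
TPL_RR = "rapid response team evaluated patient transient concern resolved"
TPL_DESAT = "brief desaturation on ambulation resolved with rest"
TPL_RESP_CARE = "chest physiotherapy and incentive spirometry administered"

_OPIOID_DRUGS = ["oxycodone", "morphine", "hydromorphone", "tramadol"]
_NOTE_TITLES = ["Progress Note", "Physician Note", "Discharge Summary"]


@dataclass
class SynthConfig:
    """Configuration of one synthetic cohort.

    ``lf_accuracy`` / ``lf_propensity`` map LF ids to planted values; an LF
    omitted from ``lf_accuracy`` receives no targeted content (its votes
    then follow from whatever the other LFs inject).
    """

    n_visits: int = 2000
    prevalence: float = 0.01
    ahrq_flag_rate: float = 0.015
    ahrq_sensitivity: float = 0.15
    ahrq_ppv: Optional[float] = 0.10
    lf_accuracy: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LF_ACCURACY))
    lf_propensity: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LF_PROPENSITY)
    )
    visits_per_patient_mean: float = 1.17
    gender_other_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_visits < 1:
            raise ConfigError("n_visits", "must be >= 1")
        for name in ("prevalence", "ahrq_flag_rate", "ahrq_sensitivity", "gender_other_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(name, f"probability {v} outside [0, 1]")
        if self.ahrq_ppv is not None and not (0.0 < self.ahrq_ppv <= 1.0):
            raise ConfigError("ahrq_ppv", f"must be in (0, 1] or None, got {self.ahrq_ppv}")
        if self.visits_per_patient_mean < 1.0:
            raise ConfigError("visits_per_patient_mean", "must be >= 1")
        for lf, a in self.lf_accuracy.items():
            if lf not in LF_IDS:
                raise ConfigError(f"lf_accuracy[{lf}]", "unknown LF id")
            if not (0.5 < a < 1.0):
                raise ConfigError(f"lf_accuracy[{lf}]", f"accuracy {a} not in (0.5, 1)")
        for lf, p in self.lf_propensity.items():
            if lf not in LF_IDS:
                raise ConfigError(f"lf_propensity[{lf}]", "unknown LF id")
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"lf_propensity[{lf}]", f"propensity {p} outside [0, 1]")
        missing = set(self.lf_accuracy) - set(self.lf_propensity)
        if missing:
            raise ConfigError(
                f"lf_propensity[{sorted(missing)[0]}]", "configured accuracy but no propensity"
            )
        self._validate_feasibility()
        if self.ahrq_ppv is not None:
            self._ahrq_fpr()  # raises when infeasible

    def _validate_feasibility(self) -> None:
        pi1, pi0 = self.prevalence, 1.0 - self.prevalence
        for lf in self.lf_accuracy:
            a, p = self.lf_accuracy[lf], self.lf_propensity[lf]
            if lf in TWO_SIDED:
                continue
            pi_v = pi1 if lf in CASE_SIDED else pi0
            if a * p > pi_v + 1e-12:
                raise ConfigError(
                    f"lf_propensity[{lf}]",
                    f"planted accuracy {a} x propensity {p} exceeds the "
                    f"probability mass {pi_v} of the voted class at "
                    f"prevalence {self.prevalence}",
                )
            if (1.0 - a) * p > (1.0 - pi_v) + 1e-12:
                raise ConfigError(
                    f"lf_propensity[{lf}]",
                    "planted error mass exceeds the opposite class probability",
                )

    def _ahrq_fpr(self) -> float:
        pi1, pi0 = self.prevalence, 1.0 - self.prevalence
        sens, ppv = self.ahrq_sensitivity, self.ahrq_ppv
        if pi0 == 0 or ppv == 0:
            raise ConfigError("ahrq_ppv", "degenerate prevalence/ppv combination")
        fpr = sens * pi1 * (1.0 - ppv) / (ppv * pi0)
        if fpr > 1.0:
            raise ConfigError(
                "ahrq_ppv", f"implied false-positive rate {fpr:.3f} exceeds 1"
            )
        return fpr


def balanced_benchmark_config(n_visits: int = 5000, seed: int = 0) -> SynthConfig:
    """Parameter-recovery benchmark: balanced prevalence, planted accuracies
    spread over [0.6, 0.95], moderate propensities so every LF casts enough
    votes for its empirical accuracy to concentrate."""
    acc = {
        "LF1": 0.90,
        "LF2": 0.75,
        "LF3": 0.80,
        "LF4": 0.70,
        "LF5": 0.85,
        "LF6": 0.90,
        "LF7": 0.85,
        "LF8": 0.65,
        "LF9": 0.60,
        "LF10": 0.70,
        "LF11": 0.75,
        "LF12": 0.95,
        "LF13": 0.80,
        "LF14": 0.90,
    }
    prop = {
        "LF1": 0.90,
        "LF2": 0.30,
        "LF3": 0.30,
        "LF4": 0.30,
        "LF5": 0.50,
        "LF6": 0.25,
        "LF7": 0.25,
        "LF8": 0.25,
        "LF9": 0.25,
        "LF10": 0.30,
        "LF11": 0.25,
        "LF12": 0.20,
        "LF13": 0.20,
        "LF14": 0.20,
    }
    return SynthConfig(
        n_visits=n_visits,
        prevalence=0.5,
        ahrq_sensitivity=0.6,
        ahrq_ppv=0.7,
        lf_accuracy=acc,
        lf_propensity=prop,
        seed=seed,
    )


def expected_lf_accuracies(config: SynthConfig) -> Dict[str, float]:
    """Planted accuracies exactly as configured (oracle for recovery tests)."""
    config.validate()
    return dict(config.lf_accuracy)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _two_sided_votes(rng, y, a, p, n):
    """Vote array in {-1,0,1}: vote w.p. p, direction = truth w.p. a."""
    votes = np.full(n, -1, dtype=np.int8)
    cast = rng.random(n) < p
    correct = rng.random(n) < a
    direction = np.where(correct, y, ~y)
    votes[cast] = direction[cast].astype(np.int8)
    return votes


def _one_sided_fire(rng, y, a, p, pi1, side_case, n, elig=None):
    """Boolean firing array for a one-sided LF honouring (a, p) marginals.

    ``elig`` restricts firing to eligible visits; rates are renormalized by
    the empirical eligible mass per class and clamped at 1.
    """
    pi0 = 1.0 - pi1
    if side_case:
        joint_y1, joint_y0 = a * p, (1.0 - a) * p
    else:
        joint_y1, joint_y0 = (1.0 - a) * p, a * p
    if elig is None:
        mass_y1, mass_y0 = pi1, pi0
        elig = np.ones(n, dtype=bool)
    else:
        mass_y1 = np.count_nonzero(elig & y) / n
        mass_y0 = np.count_nonzero(elig & ~y) / n
    q1 = min(1.0, joint_y1 / mass_y1) if mass_y1 > 0 else 0.0
    q0 = min(1.0, joint_y0 / mass_y0) if mass_y0 > 0 else 0.0
    return elig & (rng.random(n) < np.where(y, q1, q0))


def _assign_patients(rng, n, mean) -> List[int]:
    """Visit -> patient index, drawing per-patient visit counts."""
    owners: List[int] = []
    pid = 0
    while len(owners) < n:
        extra = rng.poisson(mean - 1.0) if mean > 1.0 else 0
        owners.extend([pid] * (1 + extra))
        pid += 1
    return owners[:n]


def generate_cohort(config: SynthConfig) -> Tuple[List[VisitRecord], List[LatentTruth]]:
    """Generate ``config.n_visits`` visits plus their latent truth.

    Deterministic for a fixed config (byte-identical JSON-lines output).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_visits
    pi1 = config.prevalence
    acc, prop = config.lf_accuracy, config.lf_propensity

    y = rng.random(n) < pi1

    def has(lf):
        return lf in acc

    # ---- AHRQ flag (independent of note content) ---------------------
    u = rng.random(n)
    if config.ahrq_ppv is None:
        flag = u < config.ahrq_flag_rate
    else:
        fpr = config._ahrq_fpr()
        flag = np.where(y, u < config.ahrq_sensitivity, u < fpr)

    # ---- pass A: independent LF vote targets -------------------------
    # LF1 (two-sided; control votes mostly = no naloxone at all)
    if has("LF1"):
        lf1 = _two_sided_votes(rng, y, acc["LF1"], prop["LF1"], n)
    else:
        lf1 = np.zeros(n, dtype=np.int8)  # no naloxone ever -> votes control
    ineff_path = (lf1 == 0) & (rng.random(n) < _LF1_INEFF_FRAC) if has("LF1") else np.zeros(n, bool)

    # LF2 (two-sided, forced to vote where LF1 injected keywords)
    forced2 = (lf1 == 1) | ineff_path
    if has("LF2"):
        a2, p2 = acc["LF2"], prop["LF2"]
        if has("LF1"):
            a1, p1 = acc["LF1"], prop["LF1"]
            f1 = p1 * a1 + _LF1_INEFF_FRAC * p1 * (1 - a1)
            f0 = p1 * (1 - a1) + _LF1_INEFF_FRAC * p1 * a1
        else:
            f1 = f0 = 0.0
        q1 = max(0.0, (p2 - f1) / (1.0 - f1)) if f1 < 1 else 0.0
        q0 = max(0.0, (p2 - f0) / (1.0 - f0)) if f0 < 1 else 0.0
        cast2 = forced2 | (rng.random(n) < np.where(y, q1, q0))
        correct2 = rng.random(n) < a2
        lf2 = np.full(n, -1, dtype=np.int8)
        lf2[cast2] = np.where(correct2, y, ~y)[cast2].astype(np.int8)
    else:
        # keywords from LF1 still imply a vote; keep it consistent
        lf2 = np.full(n, -1, dtype=np.int8)
        lf2[lf1 == 1] = 1
        lf2[ineff_path] = 0

    fire: Dict[str, np.ndarray] = {}
    for lf in ("LF3", "LF4", "LF5", "LF10", "LF13", "LF14"):
        fire[lf] = np.zeros(n, dtype=bool)
    for lf in CASE_SIDED:
        fire[lf] = np.zeros(n, dtype=bool)
    for lf in ("LF3", "LF4", "LF5", "LF10"):
        if has(lf):
            fire[lf] = _one_sided_fire(rng, y, acc[lf], prop[lf], pi1, False, n)
    for lf in CASE_SIDED:
        if has(lf):
            fire[lf] = _one_sided_fire(rng, y, acc[lf], prop[lf], pi1, True, n)

    # LF5 fires -> *no* respiratory-care note; abstain -> note present
    resp_care_note = ~fire["LF5"] if has("LF5") else np.zeros(n, dtype=bool)

    # LF11 abstain branch: AMS keywords + confounding diagnosis code
    lf11_confound = (
        (~fire["LF11"]) & (rng.random(n) < _LF11_CONFOUND_FRAC)
        if has("LF11")
        else np.zeros(n, dtype=bool)
    )
    ams_present = fire["LF11"] | lf11_confound

    # background content
    rr_bg = rng.random(n) < np.where(y, _RR_BG[0], _RR_BG[1])
    bg_cardio = rng.random(n) < _BG_CARDIO
    bg_cerebro = rng.random(n) < _BG_CEREBRO
    # confounding codes never co-occur with an LF11 case vote
    bg_sepsis = (rng.random(n) < _BG_SEPSIS) & ~fire["LF11"]
    bg_mi = (rng.random(n) < _BG_MI) & ~fire["LF11"]
    bg_vent = rng.random(n) < _BG_VENT

    # ---- pass B: eligibility-adjusted LFs ----------------------------
    has_acute = ams_present | rr_bg
    if has("LF13"):
        fire["LF13"] = _one_sided_fire(
            rng, y, acc["LF13"], prop["LF13"], pi1, False, n, elig=~has_acute
        )
    phrase_on_acute = has_acute & (rng.random(n) < _LF13_PHRASE_ON_ACUTE)

    has_support = fire["LF6"] | fire["LF7"] | fire["LF12"] | ams_present | rr_bg
    if has("LF14"):
        fire["LF14"] = _one_sided_fire(
            rng, y, acc["LF14"], prop["LF14"], pi1, False, n, elig=~has_support
        )
        desat_note = ~has_support & ~fire["LF14"]
    else:
        desat_note = np.zeros(n, dtype=bool)

    # ---- demographics & structured fields ----------------------------
    owners = _assign_patients(rng, n, config.visits_per_patient_mean)
    ages = np.clip(np.round(rng.normal(60, 15, n)), 18, 95).astype(int)
    gu = rng.random(n)
    other = config.gender_other_rate
    genders = np.where(gu < other, "X", np.where(gu < other + (1 - other) / 2, "F", "M"))
    surgery_day = rng.choice([0, 1, 2], size=n, p=[0.7, 0.2, 0.1])
    ed_present = rng.random(n) < 0.06
    ed_days_draw = rng.integers(-2, 6, size=(n, 2))
    ed_two = rng.random(n) < 0.3

    vent = np.zeros(n, dtype=int)
    vent[fire["LF3"]] = rng.integers(4, 13, size=int(fire["LF3"].sum()))
    m4 = fire["LF4"] & ~fire["LF3"]
    vent[m4] = rng.integers(1, 4, size=int(m4.sum()))
    mbg = bg_vent & ~fire["LF3"] & ~fire["LF4"]
    vent[mbg] = rng.integers(1, 3, size=int(mbg.sum()))

    nalox_needed = (lf1 == 1) | (lf1 == -1) | ineff_path
    nalox_oral = rng.random(n) < 0.10
    n_benign = 1 + (rng.random(n) < 0.6).astype(int)
    code_nums = rng.integers(1, 40, size=(n, 8))
    day_draws = rng.integers(0, 1 << 30, size=(n, 10))
    tmpl_draws = rng.integers(0, 1 << 30, size=(n, 4))
    n_opioid = 1 + rng.integers(0, 3, size=n)

    sepsis_vs_mi = rng.random(n) < 0.5  # for the LF11 confounder branch

    visits: List[VisitRecord] = []
    truths: List[LatentTruth] = []
    width = len(str(n))
    for i in range(n):
        vid = f"V{i:0{width}d}"
        los = int(max(5, vent[i] + 2, surgery_day[i] + 3))
        dd = day_draws[i]
        td = tmpl_draws[i]

        def day(k):
            return int(dd[k % 10] % (los + 1))

        notes: List[Note] = []
        meds: List[MedAdmin] = []
        dx: List[str] = []
        px: List[str] = [make_code("qualifying_procedure", int(code_nums[i, 0]))]

        for b in range(n_benign[i]):
            notes.append(
                Note(
                    _NOTE_TITLES[td[b % 4] % len(_NOTE_TITLES)],
                    "physician",
                    day(b),
                    BENIGN_TEMPLATES[(td[b % 4] + b) % len(BENIGN_TEMPLATES)],
                )
            )

        for k in range(int(n_opioid[i])):
            meds.append(
                MedAdmin(_OPIOID_DRUGS[(td[0] + k) % len(_OPIOID_DRUGS)], "oral", day(2 + k))
            )
        if nalox_needed[i]:
            route = "oral" if nalox_oral[i] else "IV"
            meds.append(MedAdmin("naloxone", route, day(3)))

        if lf1[i] == 1:
            notes.append(Note("Physician Note", "physician", day(4), TPL_LF1_EFFECTIVE))
        elif ineff_path[i]:
            notes.append(Note("Physician Note", "physician", day(4), TPL_LF1_INEFFECTIVE))

        if lf2[i] == 1 and lf1[i] != 1:
            notes.append(Note("Progress Note", "physician", day(5), TPL_LF2_EFF_EXTRA))
        elif lf2[i] == 0 and has("LF2"):
            # needs ineff count > eff count; the heavy template always wins
            if not ineff_path[i] or lf1[i] == 1:
                notes.append(Note("Progress Note", "nurse practitioner", day(5), TPL_LF2_INEFF_HEAVY))

        if fire["LF4"][i]:
            dx.append(make_code("respiratory_failure", int(code_nums[i, 1])))
        if vent[i] >= 4:
            px.append(make_code("prolonged_vent", int(code_nums[i, 2])))
        if resp_care_note[i]:
            notes.append(Note("Respiratory Care", "respiratory therapist", day(6), TPL_RESP_CARE))
        if fire["LF6"][i]:
            notes.append(Note("Physician Note", "physician", day(7), TPL_LF6))
        if fire["LF7"][i]:
            notes.append(Note("Progress Note", "physician", day(7), TPL_LF7))
        if fire["LF8"][i]:
            notes.append(Note("Progress Note", "physician", day(8), TPL_LF8))
        if fire["LF9"][i]:
            notes.append(Note("Progress Note", "physician", day(8), TPL_LF9))
        if fire["LF10"][i]:
            notes.append(Note("Progress Note", "nurse practitioner", day(9), TPL_LF10))
        if ams_present[i]:
            notes.append(Note("Physician Note", "physician", day(7), TPL_LF11))
        if lf11_confound[i]:
            tag = "sepsis" if sepsis_vs_mi[i] else "myocardial_infarction"
            dx.append(make_code(tag, int(code_nums[i, 3])))
        if fire["LF12"][i]:
            notes.append(Note("Physician Note", "physician", day(7), TPL_LF12))
        if fire["LF13"][i] or phrase_on_acute[i]:
            notes.append(Note("Progress Note", "physician", day(8), TPL_LF13))
        if rr_bg[i]:
            notes.append(Note("Progress Note", "physician", day(7), TPL_RR))
        if desat_note[i]:
            notes.append(Note("Progress Note", "physician", day(9), TPL_DESAT))

        if bg_cardio[i]:
            dx.append(make_code("cardiovascular", int(code_nums[i, 4])))
        if bg_cerebro[i]:
            dx.append(make_code("cerebrovascular", int(code_nums[i, 5])))
        if bg_sepsis[i]:
            dx.append(make_code("sepsis", int(code_nums[i, 6])))
        if bg_mi[i]:
            dx.append(make_code("myocardial_infarction", int(code_nums[i, 7])))
        dx.append(make_code("other", int(code_nums[i, 0])))

        ed: set = set()
        if ed_present[i]:
            ed.add(int(ed_days_draw[i, 0]))
            if ed_two[i]:
                ed.add(int(ed_days_draw[i, 1]))

        visits.append(
            VisitRecord(
                visit_id=vid,
                patient_id=f"P{owners[i]:0{width}d}",
                age=int(ages[i]),
                gender=str(genders[i]),
                surgery_day=int(surgery_day[i]),
                qualifying_procedure=True,
                ahrq_flag=bool(flag[i]),
                ed_visit_days=frozenset(ed),
                diagnosis_codes=dx,
                procedure_codes=px,
                vent_days=int(vent[i]),
                med_admins=meds,
                notes=notes,
            )
        )
        truths.append(LatentTruth(vid, bool(y[i])))

    return visits, truths
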