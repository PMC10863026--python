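from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

from oirdlab import LexiconSet, SynthConfig, generate_cohort
from oirdlab.synth import balanced_benchmark_config
from oirdlab.types import MedAdmin, Note, VisitRecord

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def lexicons() -> LexiconSet:
    return LexiconSet()


@pytest.fixture(scope="session")
def fixture_paths():
    return DATA_DIR / "fixture_visits.jsonl", DATA_DIR / "fixture_truth.jsonl"


@pytest.fixture(scope="session")
def small_cohort():
    """Default study conditions at modest scale."""
    cfg = SynthConfig(n_visits=400, seed=42)
    visits, truths = generate_cohort(cfg)
    return cfg, visits, truths


@pytest.fixture(scope="session")
def benchmark_cohort_10k():
    """Balanced parameter-recovery benchmark at n=10,000."""
    cfg = balanced_benchmark_config(n_visits=10000, seed=3)
    visits, truths = generate_cohort(cfg)
    return cfg, visits, truths


def make_visit(
    visit_id="V1",
    patient_id="P1",
    age=60,
    gender="F",
    surgery_day=0,
    ahrq_flag=False,
    ed_visit_days=(),
    diagnosis_codes=(),
    procedure_codes=(),
    vent_days=0,
    meds=(),
    notes=(),
) -> VisitRecord:
    """Hand-crafted visit for decision-table and partitioning tests.

    ``meds`` items: (drug, route, day); ``notes`` items: (title, role, day, text).
    """
    return VisitRecord(
        visit_id=visit_id,
        patient_id=patient_id,
        age=age,
        gender=gender,
        surgery_day=surgery_day,
        qualifying_procedure=True,
        ahrq_flag=ahrq_flag,
        ed_visit_days=frozenset(ed_visit_days),
        diagnosis_codes=list(diagnosis_codes),
        procedure_codes=list(procedure_codes),
        vent_days=vent_days,
        med_admins=[MedAdmin(*m) for m in meds],
        notes=[Note(*n) for n in notes],
    )


def truth_array(truths) -> np.ndarray:
    return np.array([t.oird for t in truths], dtype=int)
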