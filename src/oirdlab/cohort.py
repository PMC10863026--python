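"""Cohort filtering, Train/Dev/Val/Test partitioning and enrichment.

The partitioning mirrors the study design: a random patient subset forms
the test candidate pool (standing in for the subset of patients whose
records had been designated for held-out review); every administratively
flagged visit in that pool plus a random unflagged sample becomes the Test
Set; development and validation sets are drawn from the remainder with
flagged:unflagged oversampling; everything else is Training.  Patient
disjointness is enforced only between Test and the non-test sets — visits
of test patients that were not themselves sampled are excluded outright and
recorded in the partition history.

Iterative enrichment moves the k highest-probability training visits into
Dev/Val (alternating, so dev receives ranks 1, 3, 5, ...), emulating the
review loop that hunts rare cases among the top generative probabilities.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

from .errors import ConfigError, OirdlabError, RecordValidationError
from .types import VisitRecord

SETS = ("training", "development", "validation", "test")
EXCLUDED = "excluded"


def elective_proxy_filter(visits: Sequence[VisitRecord]) -> List[VisitRecord]:
    """Drop visits whose qualifying surgery fell on an ED-visit day.

    Elective status is unavailable in a de-identified regime; same-day ED
    contact is the proxy for an emergent (non-elective) procedure.  Order
    is preserved and the input is not modified.
    """
    missing = [v.visit_id for v in visits if v.surgery_day is None]
    if missing:
        raise RecordValidationError(f"missing surgery_day for visits: {missing}")
    return [v for v in visits if v.surgery_day not in v.ed_visit_days]


@dataclass
class PartitionConfig:
    test_pool_fraction: float = 0.05  # fraction of patients eligible for Test
    test_flagged_take_all: bool = True
    test_unflagged_sample: int = 500
    dev_size: int = 50
    val_size: int = 50
    oversample_ratio: Tuple[int, int] = (2, 1)  # flagged : unflagged
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.test_pool_fraction <= 1.0):
            raise ConfigError("test_pool_fraction", "must be in (0, 1]")
        for name in ("test_unflagged_sample", "dev_size", "val_size"):
            if getattr(self, name) < 0:
                raise ConfigError(name, "must be non-negative")
        a, b = self.oversample_ratio
        if a <= 0 or b <= 0:
            raise ConfigError("oversample_ratio", "both ratio parts must be positive")


@dataclass
class Partition:
    """Visit-id -> set assignment plus an append-only enrichment history."""

    assignment: Dict[str, str] = field(default_factory=dict)
    history: List[Tuple[int, str, str]] = field(default_factory=list)  # (round, vid, dest)

    def ids_in(self, which: str) -> List[str]:
        return [v for v, s in self.assignment.items() if s == which]

    def counts(self) -> Dict[str, int]:
        out = {s: 0 for s in SETS}
        for s in self.assignment.values():
            out[s] += 1
        return out

    def copy(self) -> "Partition":
        return Partition(dict(self.assignment), list(self.history))

    def to_csv(self, path) -> None:
        rounds = {}
        for rnd, vid, dest in self.history:
            rounds[vid] = rnd
        with open(path, "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["visit_id", "set", "round_assigned"])
            for vid, s in self.assignment.items():
                wr.writerow([vid, s, rounds.get(vid, 0)])
            for rnd, vid, dest in self.history:
                if dest == EXCLUDED:
                    wr.writerow([vid, EXCLUDED, rnd])

    @classmethod
    def from_csv(cls, path) -> "Partition":
        part = cls()
        with open(path, newline="") as fh:
            rd = csv.DictReader(fh)
            for rec in rd:
                vid, s, rnd = rec["visit_id"], rec["set"], int(rec["round_assigned"])
                if s == EXCLUDED:
                    part.history.append((rnd, vid, EXCLUDED))
                else:
                    part.assignment[vid] = s
                    if rnd > 0:
                        part.history.append((rnd, vid, s))
        part.history.sort()
        return part


def assign_partitions(visits: Sequence[VisitRecord], config: PartitionConfig) -> Partition:
    """Partition the cohort into training/development/validation/test."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    ids = [v.visit_id for v in visits]
    if len(set(ids)) != len(ids):
        raise RecordValidationError("duplicate visit ids in cohort")

    patients = sorted({v.patient_id for v in visits})
    n_pool = max(1, int(round(config.test_pool_fraction * len(patients))))
    pool_patients = set(rng.choice(patients, size=n_pool, replace=False))

    pool = [v for v in visits if v.patient_id in pool_patients]
    pool_flagged = [v.visit_id for v in pool if v.ahrq_flag]
    pool_unflagged = [v.visit_id for v in pool if not v.ahrq_flag]

    test_ids: List[str] = []
    if config.test_flagged_take_all:
        test_ids.extend(pool_flagged)
        unflagged_pool = pool_unflagged
    else:
        unflagged_pool = [v.visit_id for v in pool]
    k = config.test_unflagged_sample
    if k > len(unflagged_pool):
        raise OirdlabError(
            f"test_unflagged_sample={k} exceeds the {len(unflagged_pool)} "
            "unflagged visits available in the test pool"
        )
    test_ids.extend(rng.choice(unflagged_pool, size=k, replace=False).tolist())
    test_set = set(test_ids)

    part = Partition()
    for vid in test_ids:
        part.assignment[vid] = "test"

    # patient disjointness: non-test visits of test patients are excluded
    by_id = {v.visit_id: v for v in visits}
    test_patients = {by_id[vid].patient_id for vid in test_ids}
    remaining: List[VisitRecord] = []
    for v in visits:
        if v.visit_id in test_set:
            continue
        if v.patient_id in test_patients:
            part.history.append((0, v.visit_id, EXCLUDED))
        else:
            remaining.append(v)

    a, b = config.oversample_ratio
    flagged = [v.visit_id for v in remaining if v.ahrq_flag]
    unflagged = [v.visit_id for v in remaining if not v.ahrq_flag]
    rng.shuffle(flagged)
    rng.shuffle(unflagged)

    def draw(size: int, which: str) -> List[str]:
        n_f = (size * a) // (a + b)
        n_u = size - n_f
        if n_f > len(flagged):
            raise OirdlabError(
                f"{which}: need {n_f} flagged visits but only {len(flagged)} remain"
            )
        if n_u > len(unflagged):
            raise OirdlabError(
                f"{which}: need {n_u} unflagged visits but only {len(unflagged)} remain"
            )
        out = [flagged.pop() for _ in range(n_f)] + [unflagged.pop() for _ in range(n_u)]
        return out

    for vid in draw(config.dev_size, "development set"):
        part.assignment[vid] = "development"
    for vid in draw(config.val_size, "validation set"):
        part.assignment[vid] = "validation"
    for vid in flagged + unflagged:
        part.assignment[vid] = "training"
    return part


def enrich_top_k(
    partition: Partition, probabilities: Mapping[str, float], k: int
) -> Partition:
    """Move the k highest-probability training visits to dev/val.

    Alternating assignment in descending probability order (development
    receives ranks 1, 3, 5, ...); ties at the cutoff break by ascending
    visit_id.  Returns a new Partition; the input is unchanged.
    """
    if k % 2 != 0:
        raise OirdlabError(f"k must be even, got {k}")
    training = [vid for vid, s in partition.assignment.items() if s == "training"]
    if k > len(training):
        raise OirdlabError(f"k={k} exceeds training size {len(training)}")
    missing = [vid for vid in training if vid not in probabilities]
    if missing:
        raise OirdlabError(
            f"probabilities missing for {len(missing)} training visits "
            f"(e.g. {missing[:3]})"
        )
    out = partition.copy()
    if k == 0:
        return out
    ranked = sorted(training, key=lambda vid: (-probabilities[vid], vid))
    rnd = max((r for r, _, _ in partition.history), default=0) + 1
    for rank, vid in enumerate(ranked[:k]):
        dest = "development" if rank % 2 == 0 else "validation"
        out.assignment[vid] = dest
        out.history.append((rnd, vid, dest))
    return out
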