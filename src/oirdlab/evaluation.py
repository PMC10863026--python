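"""Confusion-matrix metrics, rank AUC, the joint-threshold rule and the
cross-approach comparison table.

Metric conventions: proportions are reported at 3 decimals; a metric whose
denominator is zero is *undefined* and reported as missing, never coerced
to 0 — with the single convention that F1 = 0 whenever tp = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .errors import OirdlabError
from .labeling import LabelMatrix
from .label_model import majority_vote


@dataclass(frozen=True)
class ContingencyTable:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise OirdlabError("contingency counts must be non-negative")
        if self.total < 1:
            raise OirdlabError("contingency table must contain at least one count")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricsReport:
    """One comparison-table row; ``None`` marks an undefined metric."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    accuracy: Optional[float]
    f1: Optional[float]
    auc: Optional[float] = None

    def rounded(self, ndigits: int = 3) -> "MetricsReport":
        def r(x):
            return None if x is None else round(x, ndigits)

        return MetricsReport(
            r(self.sensitivity), r(self.specificity), r(self.ppv),
            r(self.accuracy), r(self.f1), r(self.auc),
        )

    def as_dict(self) -> Dict[str, Optional[float]]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "accuracy": self.accuracy,
            "auc": self.auc,
            "f1": self.f1,
        }


def metrics_from_confusion(t: ContingencyTable) -> MetricsReport:
    """Sensitivity/specificity/PPV/accuracy/F1 from a confusion table."""
    sens = t.tp / (t.tp + t.fn) if (t.tp + t.fn) else None
    spec = t.tn / (t.tn + t.fp) if (t.tn + t.fp) else None
    ppv = t.tp / (t.tp + t.fp) if (t.tp + t.fp) else None
    acc = (t.tp + t.tn) / t.total
    if t.tp == 0:
        f1: Optional[float] = 0.0
    elif sens is None or ppv is None or (sens + ppv) == 0:
        f1 = None
    else:
        f1 = 2 * ppv * sens / (ppv + sens)
    return MetricsReport(sens, spec, ppv, acc, f1)


def f1_harmonic(sensitivity: float, ppv: float) -> float:
    """Harmonic mean of sensitivity and PPV, by convention 0 when both are 0."""
    for name, v in (("sensitivity", sensitivity), ("ppv", ppv)):
        if not (0.0 <= v <= 1.0):
            raise OirdlabError(f"{name} {v} outside [0, 1]")
    if sensitivity == 0 and ppv == 0:
        return 0.0
    return 2 * sensitivity * ppv / (sensitivity + ppv)


def auc_rank(truth: Sequence[int], scores: Sequence[float]) -> Optional[float]:
    """Mann-Whitney rank AUC with midrank tie handling:
    P(score_case > score_control) + 0.5 P(equal).  ``None`` (undefined)
    when only one class is present."""
    truth = np.asarray(truth)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(truth)) < 2:
        return None
    return float(roc_auc_score(truth, scores))


def joint_threshold_rule(
    p_gen: float, p_disc: float, t_gen: float = 0.8, t_disc: float = 0.7
) -> bool:
    """Case iff the generative AND discriminative probabilities strictly
    exceed their thresholds."""
    return (p_gen > t_gen) and (p_disc > t_disc)


def _confusion(truth: np.ndarray, pred: np.ndarray) -> ContingencyTable:
    return ContingencyTable(
        tp=int(np.sum((truth == 1) & (pred == 1))),
        fp=int(np.sum((truth == 0) & (pred == 1))),
        fn=int(np.sum((truth == 1) & (pred == 0))),
        tn=int(np.sum((truth == 0) & (pred == 0))),
    )


def _row(truth: np.ndarray, pred: np.ndarray, scores: np.ndarray) -> MetricsReport:
    rep = metrics_from_confusion(_confusion(truth, pred))
    rep.auc = auc_rank(truth, scores)
    return rep


def comparison_table(
    truth: Mapping[str, int],
    lf_matrix: Optional[LabelMatrix],
    gen_probs: Mapping[str, float],
    disc_probs: Mapping[str, Mapping[str, float]],
    ahrq_flags: Mapping[str, bool],
    t_gen: float = 0.8,
    t_disc: float = 0.7,
    binarize: float = 0.5,
) -> pd.DataFrame:
    """Metrics rows for every phenotyping approach, on a shared visit set.

    Rows: LF majority vote, generative model (binarized at ``binarize``),
    each discriminative variant in ``disc_probs``, the joint-threshold rule
    (generative AND first discriminative variant above their thresholds),
    and the administrative-flag baseline.  Binary-output approaches use
    their predictions as two-valued scores for AUC.
    """
    ids = sorted(truth)
    for name, mapping in [("gen_probs", gen_probs), ("ahrq_flags", ahrq_flags)] + [
        (f"disc_probs[{k}]", v) for k, v in disc_probs.items()
    ]:
        diff = [i for i in ids if i not in mapping]
        if diff:
            raise OirdlabError(f"{name} missing visit ids: {diff[:5]} ({len(diff)} total)")
    y = np.array([truth[i] for i in ids], dtype=int)
    rows: Dict[str, MetricsReport] = {}

    if lf_matrix is not None:
        sub = lf_matrix.subset(ids)
        mv = np.array([majority_vote(r) for r in sub.votes], dtype=int)
        rows["majority_vote"] = _row(y, mv, mv.astype(float))

    pg = np.array([gen_probs[i] for i in ids], dtype=float)
    rows["generative"] = _row(y, (pg >= binarize).astype(int), pg)

    first_disc = None
    for name, probs in disc_probs.items():
        pd_ = np.array([probs[i] for i in ids], dtype=float)
        if first_disc is None:
            first_disc = pd_
        rows[f"discriminative_{name}"] = _row(y, (pd_ >= binarize).astype(int), pd_)

    if first_disc is not None:
        joint = ((pg > t_gen) & (first_disc > t_disc)).astype(int)
        rows["joint_threshold"] = _row(y, joint, joint.astype(float))

    fl = np.array([1 if ahrq_flags[i] else 0 for i in ids], dtype=int)
    rows["ahrq_flag"] = _row(y, fl, fl.astype(float))

    table = pd.DataFrame(
        {name: rep.rounded().as_dict() for name, rep in rows.items()}
    ).T
    table.index.name = "approach"
    return table[["sensitivity", "specificity", "ppv", "accuracy", "auc", "f1"]]
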