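"""Feature extraction and the certainty-weighted discriminative classifier.

The discriminative stage generalizes beyond the labeling functions: it is
trained on features computed *directly from the source visits* (never from
LF votes or label-model state), using the generative model's probabilistic
labels as its outcome.  Each training row is weighted by the certainty of
its probabilistic label, |p - 0.5|, so records the label model is unsure
about barely influence the fit; manually adjudicated records can replace
the probabilistic label and always carry the maximum certainty weight 0.5.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .errors import ConfigError, OirdlabError
from .labeling import VisitScan, _naloxone_given
from .lexicons import LexiconSet
from .textmatch import find_occurrences, tokenize
from .types import VisitRecord, code_tag

#: fixed feature column order (gender one-hot columns are appended after
#: these, one per level observed in the cohort, sorted)
BASE_COLUMNS = [
    "age",
    "code_respiratory_failure",
    "code_prolonged_vent",
    "code_sepsis",
    "code_cardiovascular",
    "code_cerebrovascular",
    "naloxone_given",
    "kw_naloxone_effective",
    "kw_naloxone_ineffective",
    "kw_narcotic_overdose",
    "kw_no_pain_meds",
    "kw_decreasing_opioids",
    "kw_holding_opioids",
    "kw_acute_event",
    "kw_altered_mental_status",
    "kw_pinpoint_pupils",
    "kw_hypoxia",
    "resp_therapist_note_count",
    "rapid_response_mentions",
]

_KW_MAP = {
    "kw_naloxone_effective": "naloxone_effective",
    "kw_naloxone_ineffective": "naloxone_ineffective",
    "kw_narcotic_overdose": "narcotic_overdose",
    "kw_no_pain_meds": "no_pain_meds",
    "kw_decreasing_opioids": "decreasing_opioids",
    "kw_holding_opioids": "holding_opioids",
    "kw_acute_event": "acute_event_terms",
    "kw_altered_mental_status": "altered_mental_status",
    "kw_pinpoint_pupils": "pinpoint_pupils",
    "kw_hypoxia": "hypoxia",
}

_RESP_THERAPIST_ROLES = {"respiratory therapist", "respiratory therapy"}


def extract_features(visit: VisitRecord, lexicons: LexiconSet) -> Dict[str, object]:
    """Deterministic per-visit feature mapping (pure; source data only).

    Returns a plain dict keyed by :data:`BASE_COLUMNS` plus ``gender``
    (categorical level, encoded later at the table level).
    """
    scan = VisitScan(visit, lexicons)
    tags = set()
    for c in visit.diagnosis_codes + visit.procedure_codes:
        t = code_tag(c)
        if t:
            tags.add(t)
    rr = 0
    for note in visit.notes:
        rr += len(find_occurrences(tokenize(note.text), ["rapid response"]))
    feats: Dict[str, object] = {
        "age": visit.age,
        "code_respiratory_failure": "respiratory_failure" in tags,
        "code_prolonged_vent": "prolonged_vent" in tags,
        "code_sepsis": "sepsis" in tags,
        "code_cardiovascular": "cardiovascular" in tags,
        "code_cerebrovascular": "cerebrovascular" in tags,
        "naloxone_given": _naloxone_given(visit, lexicons, parenteral_only=False),
        "resp_therapist_note_count": sum(
            1 for nt in visit.notes if nt.author_role.lower() in _RESP_THERAPIST_ROLES
        ),
        "rapid_response_mentions": rr,
        "gender": visit.gender,
    }
    for col, lex in _KW_MAP.items():
        feats[col] = scan.count(lex)
    return feats


def features_frame(visits: Sequence[VisitRecord], lexicons: LexiconSet) -> pd.DataFrame:
    """Feature table for a cohort, indexed by visit_id, with gender one-hot
    encoded over the levels observed in this cohort."""
    rows = [extract_features(v, lexicons) for v in visits]
    df = pd.DataFrame(rows, index=[v.visit_id for v in visits])
    levels = sorted(df["gender"].unique())
    for lev in levels:
        df[f"gender_{lev}"] = (df["gender"] == lev).astype(int)
    df = df.drop(columns=["gender"])
    cols = BASE_COLUMNS + [f"gender_{lev}" for lev in levels]
    df = df[cols]
    bool_cols = df.select_dtypes(bool).columns
    df[bool_cols] = df[bool_cols].astype(int)
    df.index.name = "visit_id"
    return df


@dataclass
class TrainingLabels:
    """Per-visit binary label, certainty weight and provenance."""

    frame: pd.DataFrame  # index visit_id; columns label, weight, source

    def __post_init__(self):
        need = {"label", "weight", "source"}
        if not need <= set(self.frame.columns):
            raise OirdlabError(f"training labels need columns {sorted(need)}")


def build_training_labels(
    p_gen: Mapping[str, float],
    manual: Optional[Mapping[str, int]] = None,
    use_weights: bool = True,
    use_manual: bool = True,
    threshold: float = 0.5,
    manual_weight: float = 0.5,
) -> TrainingLabels:
    """Merge probabilistic and manual labels into weighted training rows.

    Generative rows: label = 1 iff p >= threshold, weight = |p - 0.5| (or
    1.0 when ``use_weights`` is off).  A manual label, when present and
    ``use_manual`` is on, overrides the probabilistic one and carries the
    maximum certainty weight.
    """
    manual = manual or {}
    ids, labels, weights, sources = [], [], [], []
    for vid, p in p_gen.items():
        if not (0.0 <= p <= 1.0):
            raise OirdlabError(f"probability {p} for visit {vid} outside [0, 1]")
        if use_manual and vid in manual:
            lab, w, src = int(manual[vid]), manual_weight, "manual"
        else:
            lab, w, src = int(p >= threshold), abs(p - 0.5), "generative"
        ids.append(vid)
        labels.append(lab)
        weights.append(w if use_weights else 1.0)
        sources.append(src)
    if use_manual:
        for vid, lab in manual.items():
            if vid not in p_gen:
                ids.append(vid)
                labels.append(int(lab))
                weights.append(manual_weight if use_weights else 1.0)
                sources.append("manual")
    frame = pd.DataFrame(
        {"label": labels, "weight": weights, "source": sources}, index=ids
    )
    frame.index.name = "visit_id"
    return TrainingLabels(frame)


@dataclass
class ClassifierSpec:
    algorithm: str = "random_forest"  # "random_forest" | "logistic_baseline"
    grid: List[Dict] = field(
        default_factory=lambda: [
            {"n_estimators": 100, "max_depth": None, "min_samples_leaf": 1, "class_weight": None},
            {"n_estimators": 100, "max_depth": 12, "min_samples_leaf": 2, "class_weight": "balanced"},
        ]
    )
    seed: int = 0

    def validate(self) -> None:
        if self.algorithm not in ("random_forest", "logistic_baseline"):
            raise ConfigError("algorithm", f"unknown algorithm {self.algorithm!r}")
        if not self.grid:
            raise ConfigError("grid", "hyperparameter grid must be non-empty")


def _make_estimator(spec: ClassifierSpec, hyper: Dict):
    if spec.algorithm == "random_forest":
        return RandomForestClassifier(
            n_estimators=hyper.get("n_estimators", 100),
            max_depth=hyper.get("max_depth"),
            min_samples_leaf=hyper.get("min_samples_leaf", 1),
            class_weight=hyper.get("class_weight"),
            random_state=spec.seed,
            n_jobs=1,
        )
    return LogisticRegression(
        C=hyper.get("C", 1.0), max_iter=2000, random_state=spec.seed
    )


@dataclass
class FittedClassifier:
    spec: ClassifierSpec
    hyper: Dict
    estimator: object
    feature_columns: List[str]

    def predict_proba(self, X: pd.DataFrame) -> pd.Series:
        proba = self.estimator.predict_proba(X[self.feature_columns].to_numpy())
        classes = list(self.estimator.classes_)
        col = classes.index(1) if 1 in classes else int(np.argmax(classes))
        return pd.Series(proba[:, col], index=X.index, name="probability")


def train_classifier(
    X: pd.DataFrame,
    labels: TrainingLabels,
    spec: ClassifierSpec,
    hyper: Optional[Dict] = None,
) -> FittedClassifier:
    """Fit the specified algorithm with per-sample certainty weights."""
    spec.validate()
    lab = labels.frame.loc[labels.frame.index.intersection(X.index)]
    missing = labels.frame.index.difference(X.index)
    if len(missing):
        raise OirdlabError(f"feature rows missing for labeled visits (e.g. {list(missing[:3])})")
    Xa = X.loc[lab.index]
    y = lab["label"].to_numpy()
    if len(np.unique(y)) < 2:
        raise OirdlabError(
            "training labels contain a single class; cannot fit a classifier"
        )
    hy = hyper if hyper is not None else spec.grid[0]
    est = _make_estimator(spec, hy)
    est.fit(Xa.to_numpy(), y, sample_weight=lab["weight"].to_numpy())
    return FittedClassifier(spec, hy, est, list(X.columns))


def _f1_binary(y_true, y_pred) -> float:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0


def nested_cv(
    X: pd.DataFrame,
    labels: TrainingLabels,
    spec: ClassifierSpec,
    folds_outer: int = 10,
    folds_inner: int = 3,
) -> Tuple[List[Dict], Dict]:
    """Nested cross-validation with a manual grid search.

    Inner folds select the hyperparameter set by F1 (at a 0.5 cut); each
    outer fold reports F1, AUC and mean squared error against its held-out
    labels.  Returns the per-outer-fold reports and the hyperparameter set
    chosen most often across outer folds (ties break by grid order).
    """
    from .evaluation import auc_rank

    spec.validate()
    lab = labels.frame.loc[X.index.intersection(labels.frame.index)]
    Xa = X.loc[lab.index]
    y = lab["label"].to_numpy()
    w = lab["weight"].to_numpy()
    minority = int(min(Counter(y).values(), default=0))
    if minority < folds_outer:
        raise OirdlabError(
            f"minority class has {minority} members; fewer than {folds_outer} "
            "outer folds — reduce the fold count"
        )
    outer = StratifiedKFold(n_splits=folds_outer, shuffle=True, random_state=spec.seed)
    Xn = Xa.to_numpy()
    reports: List[Dict] = []
    for fold, (tr, te) in enumerate(outer.split(Xn, y)):
        best_hy, best_f1 = None, -1.0
        inner_ok = min(Counter(y[tr]).values()) >= folds_inner
        for gi, hy in enumerate(spec.grid):
            if not inner_ok:
                best_hy = spec.grid[0]
                break
            inner = StratifiedKFold(
                n_splits=folds_inner, shuffle=True, random_state=spec.seed + 1
            )
            f1s = []
            for itr, ite in inner.split(Xn[tr], y[tr]):
                est = _make_estimator(spec, hy)
                est.fit(Xn[tr][itr], y[tr][itr], sample_weight=w[tr][itr])
                pred = est.predict(Xn[tr][ite])
                f1s.append(_f1_binary(y[tr][ite], pred))
            mean_f1 = float(np.mean(f1s))
            if mean_f1 > best_f1 + 1e-12:
                best_f1, best_hy = mean_f1, hy
        est = _make_estimator(spec, best_hy)
        est.fit(Xn[tr], y[tr], sample_weight=w[tr])
        classes = list(est.classes_)
        col = classes.index(1) if 1 in classes else 0
        p = est.predict_proba(Xn[te])[:, col]
        reports.append(
            {
                "fold": fold,
                "hyper": best_hy,
                "f1": _f1_binary(y[te], (p >= 0.5).astype(int)),
                "auc": auc_rank(y[te], p),
                "mse": float(np.mean((p - y[te]) ** 2)),
            }
        )
    freq = Counter(spec.grid.index(r["hyper"]) for r in reports)
    final_idx = max(freq, key=lambda i: (freq[i], -i))
    return reports, spec.grid[final_idx]
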