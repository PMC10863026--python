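"""Feature extraction and the certainty-weighted classifier."""

import numpy as np
import pandas as pd
import pytest

from oirdlab import (
    ClassifierSpec,
    build_training_labels,
    extract_features,
    features_frame,
    nested_cv,
    train_classifier,
)
from oirdlab.errors import OirdlabError

from .conftest import make_visit

FAST_RF = ClassifierSpec(
    grid=[{"n_estimators": 20, "max_depth": 8, "min_samples_leaf": 1, "class_weight": None}],
    seed=0,
)


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------
def test_resp_therapist_note_count(lexicons):
    v = make_visit(
        notes=[
            ("Respiratory Care", "respiratory therapist", 1, "treatment"),
            ("Respiratory Care", "respiratory therapist", 2, "treatment"),
            ("Progress Note", "physician", 2, "stable"),
        ]
    )
    assert extract_features(v, lexicons)["resp_therapist_note_count"] == 2


def test_naloxone_given_indicator(lexicons):
    assert extract_features(make_visit(), lexicons)["naloxone_given"] is False
    v = make_visit(meds=[("Narcan", "IV", 1)])
    assert extract_features(v, lexicons)["naloxone_given"] is True


def test_rapid_response_mentions_counted_by_independent_scan(lexicons):
    text = "rapid response called and later a second rapid response occurred"
    v = make_visit(notes=[("N", "md", 1, text)])
    feats = extract_features(v, lexicons)
    assert feats["rapid_response_mentions"] == text.lower().count("rapid response") == 2


def test_feature_extraction_is_pure(lexicons, small_cohort):
    _, visits, _ = small_cohort
    v = visits[7]
    assert extract_features(v, lexicons) == extract_features(v, lexicons)


def test_features_frame_layout(lexicons, small_cohort):
    _, visits, _ = small_cohort
    df = features_frame(visits[:30], lexicons)
    assert df.index.name == "visit_id"
    assert df.shape[0] == 30
    assert df.columns[0] == "age"
    gender_cols = [c for c in df.columns if c.startswith("gender_")]
    assert gender_cols and (df[gender_cols].sum(axis=1) == 1).all()
    assert (df.drop(columns=["age"]).to_numpy() >= 0).all()


def test_keyword_counts_sum_across_notes(lexicons):
    v = make_visit(
        notes=[
            ("N", "md", 1, "patient improved today"),
            ("N", "md", 2, "family agrees patient improved and alert"),
        ]
    )
    assert extract_features(v, lexicons)["kw_naloxone_effective"] == 3


# ---------------------------------------------------------------------------
# training labels
# ---------------------------------------------------------------------------
def test_training_label_arithmetic():
    labels = build_training_labels({"a": 0.9, "b": 0.5, "c": 0.2}, manual={})
    f = labels.frame
    assert f.loc["a", "label"] == 1 and f.loc["a", "weight"] == pytest.approx(0.4)
    assert f.loc["b", "label"] == 1 and f.loc["b", "weight"] == 0.0
    assert f.loc["c", "label"] == 0 and f.loc["c", "weight"] == pytest.approx(0.3)
    assert (f["source"] == "generative").all()


def test_manual_label_overrides_with_max_weight():
    labels = build_training_labels({"a": 0.2}, manual={"a": 1})
    row = labels.frame.loc["a"]
    assert row["label"] == 1 and row["weight"] == 0.5 and row["source"] == "manual"


def test_sensitivity_toggles():
    p, manual = {"a": 0.2}, {"a": 1}
    no_manual = build_training_labels(p, manual, use_manual=False)
    assert no_manual.frame.loc["a", "label"] == 0
    unweighted = build_training_labels(p, manual, use_weights=False)
    assert unweighted.frame.loc["a", "weight"] == 1.0


def test_probability_out_of_range_rejected():
    with pytest.raises(OirdlabError, match="outside"):
        build_training_labels({"a": 1.2})


# ---------------------------------------------------------------------------
# classifier
# ---------------------------------------------------------------------------
def _separable_data(n=200, seed=0):
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < 0.3).astype(int)
    X = pd.DataFrame(
        {
            "signal": y * 2.0 + rng.normal(0, 0.1, n),
            "noise": rng.normal(0, 1, n),
        },
        index=[f"V{i}" for i in range(n)],
    )
    return X, y


def test_separable_training_f1_is_one():
    X, y = _separable_data()
    labels = build_training_labels({v: float(t) for v, t in zip(X.index, y)})
    # p in {0,1} -> all weights 0.5
    clf = train_classifier(X, labels, FAST_RF)
    pred = (clf.predict_proba(X) >= 0.5).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    assert 2 * tp / (2 * tp + fp + fn) == 1.0


def test_same_seed_reproduces_probabilities():
    X, y = _separable_data()
    labels = build_training_labels({v: float(t) for v, t in zip(X.index, y)})
    p1 = train_classifier(X, labels, FAST_RF).predict_proba(X)
    p2 = train_classifier(X, labels, FAST_RF).predict_proba(X)
    pd.testing.assert_series_equal(p1, p2)


def test_zero_weight_rows_have_no_influence():
    """Refit-and-compare oracle on the logistic baseline: appending a
    duplicated row with weight zero leaves every prediction unchanged."""
    X, y = _separable_data(n=120, seed=1)
    spec = ClassifierSpec(algorithm="logistic_baseline", grid=[{"C": 1.0}], seed=0)
    base = build_training_labels({v: float(t) for v, t in zip(X.index, y)})
    p_base = train_classifier(X, base, spec).predict_proba(X)

    dup = X.iloc[[0]].rename(index={X.index[0]: "DUP"})
    X2 = pd.concat([X, dup])
    frame = base.frame.copy()
    frame.loc["DUP"] = {"label": 1 - frame.iloc[0]["label"], "weight": 0.0, "source": "generative"}
    from oirdlab.discriminative import TrainingLabels

    p_aug = train_classifier(X2, TrainingLabels(frame), spec).predict_proba(X)
    assert np.allclose(p_base.to_numpy(), p_aug.to_numpy(), atol=1e-8)


def test_single_class_labels_raise():
    X, _ = _separable_data(n=50)
    labels = build_training_labels({v: 0.9 for v in X.index})
    with pytest.raises(OirdlabError, match="single class"):
        train_classifier(X, labels, FAST_RF)


# ---------------------------------------------------------------------------
# nested cross-validation
# ---------------------------------------------------------------------------
def test_nested_cv_structure_and_determinism():
    X, y = _separable_data(n=300, seed=2)
    labels = build_training_labels({v: float(t) for v, t in zip(X.index, y)})
    spec = ClassifierSpec(
        grid=[
            {"n_estimators": 10, "max_depth": 4, "min_samples_leaf": 1, "class_weight": None},
            {"n_estimators": 10, "max_depth": None, "min_samples_leaf": 2, "class_weight": None},
        ],
        seed=3,
    )
    reports, final = nested_cv(X, labels, spec, folds_outer=10, folds_inner=3)
    assert len(reports) == 10
    assert all({"fold", "hyper", "f1", "auc", "mse"} <= set(r) for r in reports)
    assert final in spec.grid
    reports2, final2 = nested_cv(X, labels, spec, folds_outer=10, folds_inner=3)
    assert final2 == final
    assert [r["f1"] for r in reports2] == [r["f1"] for r in reports]


def test_nested_cv_single_hyper_chosen_every_fold():
    X, y = _separable_data(n=250, seed=4)
    labels = build_training_labels({v: float(t) for v, t in zip(X.index, y)})
    reports, final = nested_cv(X, labels, FAST_RF, folds_outer=10, folds_inner=3)
    assert final == FAST_RF.grid[0]
    assert all(r["hyper"] == FAST_RF.grid[0] for r in reports)


def test_nested_cv_minority_smaller_than_folds_errors():
    X, _ = _separable_data(n=60, seed=5)
    y = np.zeros(60, int)
    y[:4] = 1
    labels = build_training_labels({v: float(t) for v, t in zip(X.index, y)})
    with pytest.raises(OirdlabError, match="folds"):
        nested_cv(X, labels, FAST_RF, folds_outer=10, folds_inner=3)


def test_certainty_weighting_helps_with_noisy_uncertain_labels():
    """Corrupt a third of the probabilistic labels but keep them close to
    0.5: the weighted fit should match or beat the unweighted fit on a
    clean validation set in most replicates."""
    wins = ties = 0
    reps = 20
    for seed in range(reps):
        rng = np.random.default_rng(100 + seed)
        n = 400
        y = (rng.random(n) < 0.4).astype(int)
        X = pd.DataFrame(
            {
                "s1": y + rng.normal(0, 0.6, n),
                "s2": y * 0.8 + rng.normal(0, 0.8, n),
                "noise": rng.normal(0, 1, n),
            },
            index=[f"V{i}" for i in range(n)],
        )
        corrupt = rng.random(n) < 1 / 3
        p_gen = np.where(corrupt, np.where(y == 1, 0.45, 0.55), np.where(y == 1, 0.95, 0.05))
        probs = {v: float(p) for v, p in zip(X.index, p_gen)}
        tr = X.index[: n // 2]
        va = X.index[n // 2 :]
        y_va = y[n // 2 :]
        spec = ClassifierSpec(
            grid=[{"n_estimators": 30, "max_depth": 6, "min_samples_leaf": 1, "class_weight": None}],
            seed=seed,
        )
        f1s = {}
        for use_w in (True, False):
            labels = build_training_labels({v: probs[v] for v in tr}, use_weights=use_w)
            clf = train_classifier(X.loc[tr], labels, spec)
            pred = (clf.predict_proba(X.loc[va]) >= 0.5).astype(int).to_numpy()
            tp = int(((pred == 1) & (y_va == 1)).sum())
            fp = int(((pred == 1) & (y_va == 0)).sum())
            fn = int(((pred == 0) & (y_va == 1)).sum())
            f1s[use_w] = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
        if f1s[True] > f1s[False]:
            wins += 1
        elif f1s[True] == f1s[False]:
            ties += 1
    assert wins + ties > reps / 2, (wins, ties)
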