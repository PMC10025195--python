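"""Weighted-average ensemble: LOOCV protocol, weights, scoring, selection."""

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from tugait.ensemble import (
    COMPONENTS,
    ComponentProbabilityMatrix,
    EnsembleWeights,
    ModelSpec,
    TrainedEnsemble,
    classify,
    ensemble_score,
    fit_component_models,
    fit_weights,
    loocv_component_probabilities,
    predict_test,
    run_model_selection,
)
from tugait.errors import DegenerateFoldError, SchemaError
from tugait.selection import FeatureGroup, mann_whitney_screen

from conftest import gaussian_feature_table


def make_table(n_per_class, shifts=(1.2, 1.8, 1.0, 0.8), seed=0):
    """One feature per component with the given PD shifts (SD units)."""
    effects = {
        f"feat_{c}": (c, s) for c, s in zip(COMPONENTS, shifts)
    }
    return gaussian_feature_table(n_per_class, effects, seed=seed)


def full_group(table, name="FG_I"):
    return FeatureGroup(name=name, features=list(table.feature_names), provenance={})


def test_loocv_matches_explicit_refit_oracle():
    """The LOOCV matrix equals a brute-force loop that refits a fresh
    scaler+forest for every held-out subject."""
    table = make_table(4, seed=1)
    spec = ModelSpec(base_model="RF", feature_group="FG_I", seed=3, rf_n_estimators=50)
    got = loocv_component_probabilities(table, full_group(table), spec).probs

    y = table.labels.to_numpy()
    for j, component in enumerate(COMPONENTS):
        feats = [f for f in table.feature_names if table.components[f] == component]
        x = table.data[feats].to_numpy()
        for i in range(len(y)):
            mask = np.ones(len(y), dtype=bool)
            mask[i] = False
            oracle = Pipeline(
                [
                    ("scale", StandardScaler()),
                    ("clf", RandomForestClassifier(n_estimators=50, random_state=3)),
                ]
            )
            oracle.fit(x[mask], y[mask])
            k = list(oracle.classes_).index("PD")
            expected = oracle.predict_proba(x[i : i + 1])[0, k]
            assert got.iloc[i, j] == pytest.approx(expected, abs=1e-12)


def test_separable_cohort_probabilities_on_correct_side():
    table = make_table(12, shifts=(6.0, 6.0, 6.0, 6.0), seed=2)
    spec = ModelSpec(base_model="SVM", feature_group="FG_I", seed=0)
    probs = loocv_component_probabilities(table, full_group(table), spec).probs
    is_pd = (table.labels == "PD").to_numpy()
    for j in range(4):
        assert np.all(probs.to_numpy()[is_pd, j] > 0.5)
        assert np.all(probs.to_numpy()[~is_pd, j] < 0.5)


def test_uninformative_features_give_prior_probabilities():
    table = make_table(10, shifts=(0, 0, 0, 0), seed=3)
    table.data[:] = 1.0  # identical subjects
    spec = ModelSpec(base_model="RF", feature_group="FG_I", seed=0, rf_n_estimators=50)
    probs = loocv_component_probabilities(table, full_group(table), spec).probs
    assert np.all(np.abs(probs.to_numpy() - 0.5) < 0.2)


def test_single_class_fold_raises():
    table = make_table(2, seed=4)
    table = type(table)(
        data=table.data.iloc[:3],
        labels=table.labels.iloc[:3],
        components=table.components,
    )
    spec = ModelSpec(base_model="RF", feature_group="FG_I", seed=0, rf_n_estimators=10)
    with pytest.raises(DegenerateFoldError):
        loocv_component_probabilities(table, full_group(table), spec)
    # a calibrated SVM needs enough subjects per class for its internal folds
    svm = ModelSpec(base_model="SVM", feature_group="FG_I", seed=0)
    with pytest.raises(DegenerateFoldError):
        loocv_component_probabilities(make_table(3, seed=4), full_group(table), svm)


def _probs_frame(n, columns_dict):
    idx = [f"S{i}" for i in range(n)]
    return ComponentProbabilityMatrix(
        probs=pd.DataFrame(columns_dict, index=idx)[list(COMPONENTS)],
        provenance="loocv",
    )


def test_weights_favor_the_informative_component():
    rng = np.random.default_rng(0)
    n = 120
    labels = pd.Series(
        ["PD"] * (n // 2) + ["ET"] * (n // 2), index=[f"S{i}" for i in range(n)]
    )
    informative = np.clip(
        0.5 + 0.35 * np.where(labels == "PD", 1, -1) + 0.1 * rng.normal(size=n), 0, 1
    )
    noise = lambda: np.clip(rng.uniform(0, 1, size=n), 0, 1)  # noqa: E731
    probs = _probs_frame(
        n,
        {
            "standing": noise(),
            "straight_walk": informative,
            "turning": noise(),
            "sitting": noise(),
        },
    )
    w = fit_weights(probs, labels)
    assert w.weights["straight_walk"] == max(w.weights.values())
    arr = w.as_array()
    assert arr.sum() == pytest.approx(1.0)
    assert np.all(arr >= 0) and np.all(arr <= 1)


def test_weights_fall_back_to_equal_when_nothing_informative():
    rng = np.random.default_rng(1)
    n = 60
    labels = pd.Series(
        ["PD"] * 30 + ["ET"] * 30, index=[f"S{i}" for i in range(n)]
    )
    anti = np.clip(0.5 - 0.3 * np.where(labels == "PD", 1, -1), 0, 1)
    probs = _probs_frame(n, {c: anti for c in COMPONENTS})
    with pytest.warns(UserWarning, match="equal weights"):
        w = fit_weights(probs, labels)
    assert np.allclose(w.as_array(), 0.25)


def weights_of(values):
    return EnsembleWeights(
        weights=dict(zip(COMPONENTS, values)),
        coefficients=dict(zip(COMPONENTS, values)),
        intercept=0.0,
    )


def test_ensemble_score_arithmetic_and_decision_rule():
    w = weights_of([0.5, 0.3, 0.1, 0.1])
    p = ensemble_score(np.array([0.9, 0.8, 0.7, 0.6]), w)
    assert p == pytest.approx(0.82)
    assert classify(p) == "PD"
    # tie at exactly 0.5 is classified ET (strict inequality)
    assert classify(ensemble_score(np.full(4, 0.5), weights_of([0.25] * 4))) == "ET"
    assert classify(ensemble_score(np.array([1, 0, 0, 0.0]), weights_of([0.25] * 4))) == "ET"


def test_score_monotone_in_probabilities():
    w = weights_of([0.4, 0.3, 0.2, 0.1])
    base = np.array([0.2, 0.4, 0.6, 0.8])
    assert ensemble_score(base + 0.1, w) >= ensemble_score(base, w)


def test_predict_with_degenerate_weights_tracks_single_component():
    table = make_table(10, seed=5)
    spec = ModelSpec(base_model="SVM", feature_group="FG_I", seed=0)
    models, feats = fit_component_models(table, full_group(table), spec)
    trained = TrainedEnsemble(
        spec=spec,
        group=full_group(table),
        weights=weights_of([0.0, 1.0, 0.0, 0.0]),
        component_models=models,
        component_features=feats,
    )
    scored = predict_test(trained, table)
    np.testing.assert_allclose(scored["P"], scored["straight_walk"], atol=1e-12)


def test_no_leakage_test_subjects_scored_independently():
    train = make_table(10, seed=6)
    test_a = make_table(5, seed=7)
    test_b = type(test_a)(
        data=test_a.data.iloc[:4],
        labels=test_a.labels.iloc[:4],
        components=test_a.components,
    )
    spec = ModelSpec(base_model="SVM", feature_group="FG_I", seed=0)
    models, feats = fit_component_models(train, full_group(train), spec)
    probs = loocv_component_probabilities(train, full_group(train), spec)
    w = fit_weights(probs, train.labels)
    trained = TrainedEnsemble(spec, full_group(train), w, models, feats)
    sa = predict_test(trained, test_a)
    sb = predict_test(trained, test_b)
    # removing a test subject changes nothing for the others
    np.testing.assert_allclose(
        sa.loc[sb.index, "P"].to_numpy(), sb["P"].to_numpy(), atol=1e-12
    )


def test_predict_missing_feature_raises_schema_error():
    train = make_table(6, seed=8)
    spec = ModelSpec(base_model="SVM", feature_group="FG_I", seed=0)
    models, feats = fit_component_models(train, full_group(train), spec)
    trained = TrainedEnsemble(
        spec, full_group(train), weights_of([0.25] * 4), models, feats
    )
    broken = type(train)(
        data=train.data.drop(columns=["feat_turning"]),
        labels=train.labels,
        components=train.components,
    )
    with pytest.raises(SchemaError):
        predict_test(trained, broken)


def test_model_selection_reports_all_six_combinations():
    table = make_table(6, shifts=(1.5, 1.5, 1.5, 1.5), seed=9)
    groups = {
        name: FeatureGroup(name=name, features=list(table.feature_names), provenance={})
        for name in ("FG_I", "FG_II", "FG_III")
    }
    result = run_model_selection(table, groups, seed=0, rf_n_estimators=20)
    assert len(result.report) == 6
    assert set(result.report["model"]) == {"SVM", "RF"}


def test_model_selection_null_cohort_near_chance():
    """Without signal, LOOCV ensemble accuracy stays near chance (the
    in-sample logistic weighting contributes a known optimistic bias,
    bounded here)."""
    table = make_table(30, shifts=(0, 0, 0, 0), seed=9)
    groups = {
        name: FeatureGroup(name=name, features=list(table.feature_names), provenance={})
        for name in ("FG_I", "FG_III")
    }
    result = run_model_selection(table, groups, base_models=("SVM",), seed=0)
    assert result.report["accuracy"].between(0.25, 0.78).all()


def test_model_selection_prefers_group_with_signal():
    table = make_table(12, shifts=(1.5, 2.0, 1.2, 1.0), seed=10)
    noise_only = mann_whitney_screen(table, alpha=1.1)
    groups = {
        "FG_I": FeatureGroup(
            name="FG_I", features=list(table.feature_names), provenance={}
        ),
        "FG_II": FeatureGroup(name="FG_II", features=[], provenance={}),
        "FG_III": FeatureGroup(
            name="FG_III", features=list(table.feature_names), provenance={}
        ),
    }
    result = run_model_selection(
        table, groups, base_models=("SVM",), seed=0
    )
    assert result.best[1] in ("FG_I", "FG_III")  # the empty group cannot win
    del noise_only
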