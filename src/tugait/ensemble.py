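"""Weighted-average ensemble classification over the four TUG components.

For one feature group, four base classifiers (SVM or random forest) are
trained on the component-specific features (standing, straight walk,
turning, sitting). Under leave-one-out cross-validation each held-out
subject receives four PD probabilities; a logistic regression of the label
on those probabilities supplies the component weights (coefficients
clipped at zero and normalized to sum to one; the intercept is kept as
metadata only). The ensemble score is the weighted average
P = Σ w_c · p_c, and the subject is classified PD iff P > 0.5 (a tie goes
to ET). Test subjects are scored with component models refit on the full
training split and the training-derived weights — nothing test-derived
feeds back into the models or weights.

Base-model defaults: SVM with RBF kernel, C = 1, scaled gamma, features
z-scored inside every fold with training-fold statistics, probabilities
from the built-in Platt calibration; RF with 500 trees, probabilities as
class-vote fractions.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import DegenerateFoldError, SchemaError
from .metrics import MetricsReport, compute_metrics, confusion
from .parameters import FeatureTable
from .selection import FeatureGroup

log = logging.getLogger(__name__)

COMPONENTS = ("standing", "straight_walk", "turning", "sitting")


@dataclasses.dataclass
class ModelSpec:
    base_model: str  # "SVM" | "RF"
    feature_group: str  # "FG_I" | "FG_II" | "FG_III"
    seed: int = 0
    svm_c: float = 1.0
    rf_n_estimators: int = 500

    def __post_init__(self) -> None:
        if self.base_model not in ("SVM", "RF"):
            raise ValueError(f"unknown base model {self.base_model!r}")

    def make(self) -> Pipeline:
        if self.base_model == "SVM":
            # Platt-calibrated RBF SVM (sigmoid calibration on internal
            # stratified folds, single final model)
            clf = CalibratedClassifierCV(
                SVC(kernel="rbf", C=self.svm_c, gamma="scale", random_state=self.seed),
                method="sigmoid",
                cv=StratifiedKFold(n_splits=3, shuffle=True, random_state=self.seed),
                ensemble=False,
            )
        else:
            clf = RandomForestClassifier(
                n_estimators=self.rf_n_estimators, random_state=self.seed
            )
        return Pipeline([("scale", StandardScaler()), ("clf", clf)])


@dataclasses.dataclass
class ComponentProbabilityMatrix:
    """Per-subject, per-component PD probabilities."""

    probs: pd.DataFrame  # index subject_id, columns COMPONENTS
    provenance: str  # "loocv" | "test"

    def __post_init__(self) -> None:
        if list(self.probs.columns) != list(COMPONENTS):
            raise SchemaError(f"columns must be {COMPONENTS}")
        vals = self.probs.to_numpy()
        if np.any((vals < 0) | (vals > 1)):
            raise SchemaError("probabilities must lie in [0, 1]")


@dataclasses.dataclass
class EnsembleWeights:
    weights: dict[str, float]  # component -> weight, >=0, sum 1
    coefficients: dict[str, float]  # raw logistic coefficients (metadata)
    intercept: float

    def __post_init__(self) -> None:
        w = np.array([self.weights[c] for c in COMPONENTS])
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise SchemaError("weights must be non-negative and sum to 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.weights[c] for c in COMPONENTS])


def _component_features(
    table: FeatureTable, group: FeatureGroup, component: str
) -> list[str]:
    return [f for f in group.features if table.components[f] == component]


def _clean_matrix(table: FeatureTable, features: list[str]) -> np.ndarray:
    """Feature matrix with per-column median imputation of NaNs."""
    x = table.data[features].to_numpy(dtype=float)
    for j in range(x.shape[1]):
        col = x[:, j]
        bad = ~np.isfinite(col)
        if bad.any():
            med = np.nanmedian(col)
            col[bad] = 0.0 if not np.isfinite(med) else med
    return x


def loocv_component_probabilities(
    train_table: FeatureTable, group: FeatureGroup, spec: ModelSpec
) -> ComponentProbabilityMatrix:
    """LOOCV PD probabilities: one row per training subject, one column per
    component; the held-out subject never influences the fold's scaler or
    classifier. Components with no features in the group emit a constant
    0.5 with a warning.
    """
    y = train_table.labels.to_numpy()
    n = len(y)
    if len(set(y)) < 2 or n < 3:
        raise DegenerateFoldError("training table needs both classes and n >= 3")
    min_class = min(np.sum(y == c) for c in set(y))
    if spec.base_model == "SVM" and min_class - 1 < 3:
        # Platt calibration needs 3 stratified folds inside every LOOCV fold
        raise DegenerateFoldError(
            "calibrated SVM needs >= 4 training subjects per class"
        )
    out = np.full((n, len(COMPONENTS)), 0.5)
    for j, component in enumerate(COMPONENTS):
        feats = _component_features(train_table, group, component)
        if not feats:
            log.warning(
                "component %s has no features in %s; emitting 0.5", component, group.name
            )
            continue
        x = _clean_matrix(train_table, feats)
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            if len(set(y[mask])) < 2:
                raise DegenerateFoldError(
                    f"single-class training fold when holding out subject {i}"
                )
            model = spec.make()
            model.fit(x[mask], y[mask])
            k = list(model.classes_).index("PD")
            out[i, j] = model.predict_proba(x[i : i + 1])[0, k]
    return ComponentProbabilityMatrix(
        probs=pd.DataFrame(out, index=train_table.data.index, columns=COMPONENTS),
        provenance="loocv",
    )


def fit_weights(probs: ComponentProbabilityMatrix, labels: pd.Series) -> EnsembleWeights:
    """Logistic-regression-derived component weights on the simplex.

    The label is regressed on the four LOOCV probabilities (light ridge
    penalty, so perfect separation cannot break the fit); coefficients are
    clipped at zero and normalized to sum to one. If no coefficient is
    positive, equal weights are used with a warning.
    """
    x = probs.probs.to_numpy()
    y = (labels.loc[probs.probs.index].to_numpy() == "PD").astype(int)
    lr = LogisticRegression(C=100.0, solver="lbfgs", max_iter=1000)
    lr.fit(x, y)
    coef = lr.coef_[0]
    clipped = np.clip(coef, 0.0, None)
    if clipped.sum() <= 0:
        warnings.warn("no positive logistic coefficient; falling back to equal weights")
        w = np.full(len(COMPONENTS), 1.0 / len(COMPONENTS))
    else:
        w = clipped / clipped.sum()
    return EnsembleWeights(
        weights=dict(zip(COMPONENTS, w.tolist())),
        coefficients=dict(zip(COMPONENTS, coef.tolist())),
        intercept=float(lr.intercept_[0]),
    )


def ensemble_score(row: np.ndarray | pd.Series, weights: EnsembleWeights) -> float:
    """P = Σ w_c · p_c over the four components."""
    if isinstance(row, pd.Series):
        row = row[list(COMPONENTS)].to_numpy()
    return float(np.dot(np.asarray(row, dtype=float), weights.as_array()))


def classify(p_val: float) -> str:
    """Decision rule: PD iff P > 0.5 (tie classified ET)."""
    return "PD" if p_val > 0.5 else "ET"


@dataclasses.dataclass
class TrainedEnsemble:
    spec: ModelSpec
    group: FeatureGroup
    weights: EnsembleWeights
    component_models: dict[str, Pipeline | None]
    component_features: dict[str, list[str]]


def fit_component_models(
    train_table: FeatureTable, group: FeatureGroup, spec: ModelSpec
) -> tuple[dict[str, Pipeline | None], dict[str, list[str]]]:
    """Refit the four component models on the full training split."""
    models: dict[str, Pipeline | None] = {}
    feats_of: dict[str, list[str]] = {}
    y = train_table.labels.to_numpy()
    for component in COMPONENTS:
        feats = _component_features(train_table, group, component)
        feats_of[component] = feats
        if not feats:
            models[component] = None
            continue
        model = spec.make()
        model.fit(_clean_matrix(train_table, feats), y)
        models[component] = model
    return models, feats_of


def predict_test(
    trained: TrainedEnsemble, test_table: FeatureTable
) -> pd.DataFrame:
    """Score test subjects: P = Σ w_c · p_c with training-derived weights.

    Returns a frame with the four component probabilities, P and the
    predicted class per subject.
    """
    missing = [
        f
        for feats in trained.component_features.values()
        for f in feats
        if f not in test_table.data.columns
    ]
    if missing:
        raise SchemaError(f"test table lacks features: {sorted(set(missing))}")
    n = len(test_table.data)
    probs = np.full((n, len(COMPONENTS)), 0.5)
    for j, component in enumerate(COMPONENTS):
        model = trained.component_models[component]
        feats = trained.component_features[component]
        if model is None or not feats:
            continue
        x = _clean_matrix(test_table, feats)
        k = list(model.classes_).index("PD")
        probs[:, j] = model.predict_proba(x)[:, k]
    frame = pd.DataFrame(probs, index=test_table.data.index, columns=COMPONENTS)
    frame["P"] = frame[list(COMPONENTS)].to_numpy() @ trained.weights.as_array()
    frame["prediction"] = [classify(p) for p in frame["P"]]
    return frame


def evaluate_probabilities(
    probs: ComponentProbabilityMatrix,
    weights: EnsembleWeights,
    labels: pd.Series,
) -> tuple[MetricsReport, pd.Series]:
    """Ensemble metrics from a probability matrix and weights."""
    p_val = pd.Series(
        probs.probs[list(COMPONENTS)].to_numpy() @ weights.as_array(),
        index=probs.probs.index,
        name="P",
    )
    y = labels.loc[p_val.index]
    preds = [classify(p) for p in p_val]
    cm = confusion(list(y), preds)
    return compute_metrics(cm, scores=p_val.to_numpy(), labels=y.to_numpy()), p_val


@dataclasses.dataclass
class ModelSelectionResult:
    report: pd.DataFrame  # one row per model x feature-group combination
    best: tuple[str, str]  # (base_model, feature_group)
    loocv: dict[tuple[str, str], ComponentProbabilityMatrix]
    weights: dict[tuple[str, str], EnsembleWeights]


def run_model_selection(
    train_table: FeatureTable,
    groups: dict[str, FeatureGroup],
    base_models: tuple[str, ...] = ("SVM", "RF"),
    seed: int = 0,
    rf_n_estimators: int = 500,
) -> ModelSelectionResult:
    """Evaluate every base-model × feature-group combination by LOOCV.

    The best combination is chosen by accuracy, ties broken by kappa and
    then AUC.
    """
    rows = []
    loocv: dict[tuple[str, str], ComponentProbabilityMatrix] = {}
    weights: dict[tuple[str, str], EnsembleWeights] = {}
    for base in base_models:
        for gname, group in groups.items():
            spec = ModelSpec(
                base_model=base,
                feature_group=gname,
                seed=seed,
                rf_n_estimators=rf_n_estimators,
            )
            probs = loocv_component_probabilities(train_table, group, spec)
            w = fit_weights(probs, train_table.labels)
            report, _ = evaluate_probabilities(probs, w, train_table.labels)
            loocv[(base, gname)] = probs
            weights[(base, gname)] = w
            rows.append(
                {
                    "model": base,
                    "feature_group": gname,
                    **report.as_dict(),
                    **{f"w_{c}": w.weights[c] for c in COMPONENTS},
                }
            )
    report = pd.DataFrame(rows)
    order = report.sort_values(
        ["accuracy", "kappa", "auc"], ascending=False, kind="mergesort"
    )
    best_row = order.iloc[0]
    best = (str(best_row["model"]), str(best_row["feature_group"]))
    return ModelSelectionResult(report=report, best=best, loocv=loocv, weights=weights)
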