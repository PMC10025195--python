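"""End-to-end orchestration: simulate → segment → extract → select → train.

Every stage reads and writes plain-text artifacts under the output
directory, and the whole run is reproducible bit-for-bit from the config
and master seed. Stage failures are re-raised as :class:`StageError`
carrying the stage name and artifact context.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

from .ensemble import (
    ModelSelectionResult,
    ModelSpec,
    TrainedEnsemble,
    evaluate_probabilities,
    fit_component_models,
    predict_test,
    run_model_selection,
)
from .errors import StageError, TugaitError
from .metrics import compute_metrics, confusion
from .parameters import FeatureTable, compute_parameters
from .segmentation import segment_tug, write_segments_tsv
from .selection import select_feature_groups, write_groups_csv
from .synthetic import CohortConfig, CohortSubject, iter_cohort

log = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    cohort: CohortConfig
    outdir: str = "tugait_run"
    seed: int = 0
    alpha: float = 0.05
    folds: int = 5
    auc_threshold: float = 0.6
    rho_max: float = 0.9
    base_models: tuple[str, ...] = ("SVM", "RF")
    rf_n_estimators: int = 500
    log_level: str = "INFO"

    def validate(self) -> None:
        self.cohort.validate()
        if not (0 < self.alpha < 1):
            raise TugaitError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort_raw = raw.pop("cohort", {})
        cohort = CohortConfig(
            **{
                k: v
                for k, v in cohort_raw.items()
                if k in {f.name for f in dataclasses.fields(CohortConfig)}
                and k not in ("pd_profile", "et_profile")
            }
        )
        cfg = cls(cohort=cohort, **raw)
        cfg.cohort.seed = cfg.seed
        return cfg


@dataclasses.dataclass
class RunReport:
    artifacts: dict[str, str]
    loocv_metrics: pd.DataFrame  # 6 rows: model x feature group
    test_metrics: pd.DataFrame  # 1 row: selected model on the test split
    best: tuple[str, str]


def extract_cohort_features(
    subjects: Iterable[CohortSubject],
    segments_path: Path | None = None,
) -> FeatureTable:
    """Segment every recording and compute its feature vector."""
    rows = []
    seg_frames = []
    for subj in subjects:
        seg = segment_tug(subj.recording)
        fv = compute_parameters(subj.recording, seg)
        rows.append((subj.recording.subject_id, subj.label, subj.split, fv))
        if segments_path is not None:
            seg_frames.append((subj.recording.subject_id, seg))
    if segments_path is not None:
        import io

        parts = []
        for sid, seg in seg_frames:
            buf = io.StringIO()
            write_segments_tsv(sid, seg, buf)
            parts.append(buf.getvalue() if not parts else buf.getvalue().split("\n", 1)[1])
        segments_path.write_text("".join(parts))
    return FeatureTable.from_subjects(rows)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run the full study protocol and write every artifact to disk."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def stage(name: str):
        log.info("stage %s", name)
        return time.time()

    # --- simulate + segment + extract -------------------------------------
    t0 = stage("simulate/extract")
    try:
        config.cohort.seed = config.seed
        table = extract_cohort_features(
            iter_cohort(config.cohort), segments_path=outdir / "segments.tsv"
        )
        table.to_csv(outdir / "features.csv")
        artifacts["features"] = str(outdir / "features.csv")
        artifacts["segments"] = str(outdir / "segments.tsv")
    except TugaitError as exc:
        raise StageError("simulate/extract", exc, str(outdir)) from exc
    log.info("extracted %d subjects in %.1f s", len(table.data), time.time() - t0)

    # --- feature selection (training split only) ---------------------------
    stage("select")
    try:
        train = table.subset("train")
        test = table.subset("test")
        groups = select_feature_groups(
            train,
            alpha=config.alpha,
            rho_max=config.rho_max,
            folds=config.folds,
            auc_threshold=config.auc_threshold,
            seed=config.seed,
        )
        write_groups_csv(groups, train, outdir / "feature_groups.csv")
        artifacts["feature_groups"] = str(outdir / "feature_groups.csv")
    except TugaitError as exc:
        raise StageError("select", exc, artifacts.get("features", "")) from exc

    # --- model selection by LOOCV ------------------------------------------
    stage("train")
    try:
        selection = run_model_selection(
            train,
            groups,
            base_models=config.base_models,
            seed=config.seed,
            rf_n_estimators=config.rf_n_estimators,
        )
        selection.report.to_csv(outdir / "loocv_metrics.csv", index=False)
        artifacts["loocv_metrics"] = str(outdir / "loocv_metrics.csv")
    except TugaitError as exc:
        raise StageError("train", exc, artifacts.get("feature_groups", "")) from exc

    # --- independent test evaluation ---------------------------------------
    stage("evaluate")
    try:
        base, gname = selection.best
        spec = ModelSpec(
            base_model=base,
            feature_group=gname,
            seed=config.seed,
            rf_n_estimators=config.rf_n_estimators,
        )
        models, feats = fit_component_models(train, groups[gname], spec)
        trained = TrainedEnsemble(
            spec=spec,
            group=groups[gname],
            weights=selection.weights[selection.best],
            component_models=models,
            component_features=feats,
        )
        scored = predict_test(trained, test)
        scored.to_csv(outdir / "test_predictions.csv")
        cm = confusion(list(test.labels), list(scored["prediction"]))
        report = compute_metrics(
            cm, scores=scored["P"].to_numpy(), labels=test.labels.to_numpy()
        )
        test_metrics = pd.DataFrame(
            [{"model": base, "feature_group": gname, **report.as_dict()}]
        )
        test_metrics.to_csv(outdir / "test_metrics.csv", index=False)
        artifacts["test_metrics"] = str(outdir / "test_metrics.csv")
        weight_rows = [
            {"model": b, "feature_group": g, "component": c, "weight": w.weights[c]}
            for (b, g), w in selection.weights.items()
            for c in w.weights
        ]
        pd.DataFrame(weight_rows).to_csv(outdir / "component_weights.csv", index=False)
        artifacts["component_weights"] = str(outdir / "component_weights.csv")
    except TugaitError as exc:
        raise StageError("evaluate", exc, artifacts.get("loocv_metrics", "")) from exc

    run_report = RunReport(
        artifacts=artifacts,
        loocv_metrics=selection.report,
        test_metrics=test_metrics,
        best=selection.best,
    )
    with open(outdir / "run_report.json", "w") as fh:
        json.dump(
            {
                "artifacts": artifacts,
                "best_model": list(selection.best),
                "seed": config.seed,
                "test_metrics": test_metrics.iloc[0].to_dict(),
            },
            fh,
            indent=1,
        )
    return run_report


def dump_config_yaml(config: PipelineConfig, path: str | Path) -> None:
    cohort = {
        "n_pd": config.cohort.n_pd,
        "n_et": config.cohort.n_et,
        "seed": config.cohort.seed,
        "train_fraction": config.cohort.train_fraction,
    }
    body = dataclasses.asdict(config)
    body["cohort"] = cohort
    body["base_models"] = list(config.base_models)
    with open(path, "w") as fh:
        yaml.safe_dump(body, fh)
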