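"""End-to-end pipeline and model persistence.

``run_pipeline`` chains the stages — curate, featurize, train both
ensembles under 10-fold CV, tune the classification cutoff on the
out-of-fold sweep, assemble the cascade, and screen the held-out split —
and writes every artifact (curated table, descriptor cache, model archive,
sweep CSV, metric report JSON, run manifest) into an output directory.
Re-running with the same manifest reproduces predictions bit-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import joblib
import numpy as np
import pandas as pd

from . import __version__
from .cascade import (
    DEFAULT_REG_CUTOFF,
    CascadeModel,
    build_cascade,
    evaluate_screen,
    screen,
)
from .chem import (
    CLASS_BOUNDARY,
    CuratedDataset,
    deduplicate,
    labels_for,
    read_molecules_csv,
    split,
    subset,
    write_molecules_csv,
)
from .descriptors import Preprocessor, compute_descriptors
from .metrics import classification_report, regression_report
from .modeling import (
    CrossValConfig,
    EnsembleModel,
    train_classifier_ensemble,
    train_regressor_ensemble,
)
from .tuning import (
    PIPELINE_GRID,
    RULE_MAX_PRECISION,
    RULE_MIN_THRESHOLD_FP_MAX,
    select_cutoff,
    sweep,
    write_sweep_csv,
)

logger = logging.getLogger(__name__)

ARCHIVE_FORMAT_VERSION = 1


@dataclass
class PipelineConfig:
    """Everything a run needs; defaults follow the standard protocol
    (10 folds, 85% class boundary, 90% stage-2 cutoff, the reference
    threshold grid, at most one false positive at the tuned cutoff)."""

    input_table: str | None = None  # None -> synthetic benchmark
    output_dir: str = "hiascreen_run"
    cv_folds: int = 10
    seed: int = 0
    test_fraction: float = 0.3
    threshold_grid: tuple[float, ...] = PIPELINE_GRID
    fp_max: int = 1
    reg_cutoff: float = DEFAULT_REG_CUTOFF
    class_boundary: float = CLASS_BOUNDARY
    fit_on: str = "train"  # "train" (leakage-safe) or "all"

    def __post_init__(self):
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.fit_on not in ("train", "all"):
            raise ValueError("fit_on must be 'train' or 'all'")


# ---------------------------------------------------------------------------
# Model archive


def save_model_archive(
    path,
    cascade: CascadeModel,
    preprocessor: Preprocessor,
    extra_manifest: dict | None = None,
) -> None:
    """Persist a cascade + preprocessor as a versioned directory archive."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": ARCHIVE_FORMAT_VERSION,
        "package_version": __version__,
        "clf_cutoff": cascade.clf_cutoff,
        "reg_cutoff": cascade.reg_cutoff,
        "classifier_members": cascade.classifier.member_names,
        "classifier_weights": cascade.classifier.weights.tolist(),
        "regressor_members": cascade.regressor.member_names,
        "regressor_weights": cascade.regressor.weights.tolist(),
    }
    if extra_manifest:
        manifest.update(extra_manifest)
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (path / "preprocessor.json").write_text(json.dumps(preprocessor.to_dict()))
    joblib.dump(cascade.classifier.members, path / "classifier_members.joblib")
    joblib.dump(cascade.regressor.members, path / "regressor_members.joblib")


def load_model_archive(path) -> tuple[CascadeModel, Preprocessor, dict]:
    """Load a cascade archive; predictions round-trip bit-identically."""
    path = Path(path)
    manifest_file = path / "manifest.json"
    if not manifest_file.exists():
        raise FileNotFoundError(f"{path} is not a model archive (no manifest.json)")
    manifest = json.loads(manifest_file.read_text())
    version = manifest.get("format_version")
    if version != ARCHIVE_FORMAT_VERSION:
        raise ValueError(
            f"unsupported archive format version {version!r} "
            f"(expected {ARCHIVE_FORMAT_VERSION})"
        )
    for needed in ("preprocessor.json", "classifier_members.joblib",
                   "regressor_members.joblib"):
        if not (path / needed).exists():
            raise ValueError(f"corrupted archive: missing {needed}")
    preprocessor = Preprocessor.from_dict(
        json.loads((path / "preprocessor.json").read_text())
    )
    clf_members = joblib.load(path / "classifier_members.joblib")
    reg_members = joblib.load(path / "regressor_members.joblib")
    classifier = EnsembleModel(
        task="classification",
        member_names=manifest["classifier_members"],
        members=clf_members,
        weights=np.asarray(manifest["classifier_weights"]),
    )
    regressor = EnsembleModel(
        task="regression",
        member_names=manifest["regressor_members"],
        members=reg_members,
        weights=np.asarray(manifest["regressor_weights"]),
    )
    cascade = build_cascade(
        classifier, manifest["clf_cutoff"], regressor, manifest["reg_cutoff"]
    )
    return cascade, preprocessor, manifest


# ---------------------------------------------------------------------------
# Pipeline


@dataclass
class PipelineResult:
    dataset: CuratedDataset
    assignment: object
    cascade: CascadeModel
    preprocessor: Preprocessor
    sweep_table: object
    selection: object
    metrics: dict
    decisions: list
    output_dir: Path


def _load_or_simulate(config: PipelineConfig) -> CuratedDataset:
    if config.input_table is None:
        from .synth import GeneratorConfig, generate_molecules, simulate_hia

        records = generate_molecules(141, seed=config.seed)
        records = simulate_hia(records, GeneratorConfig(seed=config.seed))
        return deduplicate(records)
    records = read_molecules_csv(config.input_table)
    missing = [r.id for r in records if r.hia_percent is None]
    if missing:
        raise ValueError(
            f"curation: input rows without an HIA value: {missing[:10]}"
        )
    return deduplicate(records)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("stage curate")
    dataset = _load_or_simulate(config)
    write_molecules_csv(out / "curated.csv", dataset.records)

    assignment = split(dataset, test_fraction=config.test_fraction, seed=config.seed)
    train_ds = subset(dataset, assignment.train_ids)
    test_ds = subset(dataset, assignment.test_ids)

    logger.info("stage featurize (%d molecules)", len(dataset))
    matrix = compute_descriptors(dataset.records)
    matrix.to_csv(out / "descriptors.csv")
    train_matrix = matrix.loc[list(assignment.train_ids)]
    test_matrix = matrix.loc[list(assignment.test_ids)]

    pre = Preprocessor()
    pre.fit(matrix if config.fit_on == "all" else train_matrix)
    X_train = pre.transform(train_matrix)
    X_test = pre.transform(test_matrix)

    y_train_hia = train_ds.hia_array()
    y_test_hia = test_ds.hia_array()
    y_train = labels_for(train_ds, config.class_boundary)
    y_test = labels_for(test_ds, config.class_boundary)

    cv = CrossValConfig(k=config.cv_folds, seed=config.seed, stratified=True)
    logger.info("stage train: classifier ensemble")
    clf, clf_oof = train_classifier_ensemble(X_train, y_train, cv)
    logger.info("stage train: regressor ensemble")
    cv_reg = CrossValConfig(k=config.cv_folds, seed=config.seed, stratified=False)
    reg, reg_oof = train_regressor_ensemble(X_train, y_train_hia, cv_reg)

    logger.info("stage tune")
    table = sweep(clf_oof.values, y_train, config.threshold_grid)
    try:
        selection = select_cutoff(table, RULE_MIN_THRESHOLD_FP_MAX, config.fp_max)
    except ValueError:
        logger.warning(
            "no grid threshold leaves <= %d false positives; falling back to "
            "the max-precision rule", config.fp_max,
        )
        selection = select_cutoff(table, RULE_MAX_PRECISION)
    write_sweep_csv(out / "sweep.csv", table)

    cascade = build_cascade(clf, selection.threshold, reg, config.reg_cutoff)
    save_model_archive(
        out / "model_archive",
        cascade,
        pre,
        extra_manifest={
            "seed": config.seed,
            "cv_folds": config.cv_folds,
            "fit_on": config.fit_on,
            "train_ids": list(assignment.train_ids),
            "test_ids": list(assignment.test_ids),
        },
    )

    logger.info("stage screen (test split, %d molecules)", len(test_ds))
    decisions = screen(cascade, X_test, ids=test_ds.ids())
    report = evaluate_screen(decisions, y_test)

    from .modeling import predict_proba, predict_value

    metrics = {
        "classification": {
            "cv": classification_report(y_train, clf_oof.values, 0.5),
            "test": classification_report(
                y_test, predict_proba(clf, X_test), 0.5
            ),
        },
        "regression": {
            "cv": regression_report(y_train_hia, reg_oof.values),
            "test": regression_report(y_test_hia, predict_value(reg, X_test)),
        },
        "tuned_threshold": selection.threshold,
        "screening": asdict(report),
    }
    (out / "metrics.json").write_text(json.dumps(metrics, indent=2))

    decisions_df = pd.DataFrame(
        [
            {
                "id": d.molecule_id,
                "stage": d.stage,
                "probability": d.probability,
                "predicted_hia": d.predicted_hia,
                "selected": d.selected,
            }
            for d in decisions
        ]
    )
    decisions_df.to_csv(out / "screening.csv", index=False)

    manifest = {
        "package_version": __version__,
        "config": {
            **{k: v for k, v in asdict(config).items()},
            "threshold_grid": list(config.threshold_grid),
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return PipelineResult(
        dataset=dataset,
        assignment=assignment,
        cascade=cascade,
        preprocessor=pre,
        sweep_table=table,
        selection=selection,
        metrics=metrics,
        decisions=decisions,
        output_dir=out,
    )
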