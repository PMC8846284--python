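"""Pipeline configuration, orchestration, and reporting.

:func:`run_pipeline` chains the whole framework on synthetic phantoms:
simulate -> segment -> register -> subregions -> extract -> classify ->
importance -> report.  Every random draw flows from the single global
seed through named per-stage, per-subject substreams (see
:func:`cftpet.core.derive_seed`), so two runs with equal configs are
bit-identical in all CSV/JSON outputs.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .core import DIAGNOSES, derive_seed
from .phantom import (
    CohortManifest,
    GroupProfile,
    PhantomSpec,
    default_profiles,
    default_spec,
    generate_cohort,
    generate_subject,
)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All stage configs in one document, validated before any stage runs."""

    seed: int = 0
    grid: int = 64
    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"PD": 50, "MSA": 37, "PSP": 20, "NC": 22}
    )
    noise_sd: float = 0.05
    segmentation_backend: str = "atlas"  # atlas | learned | truth
    segmentation_train: dict = field(
        default_factory=lambda: {"n_train": 6, "epochs": 12}
    )
    registration: dict = field(default_factory=dict)
    subregion_seed: int = 0
    feature_set: str = "striatum+midbrain"
    sor_formula: str = "sbr"
    include_asymmetry: bool = False
    classifier: dict = field(default_factory=dict)
    importance: dict = field(default_factory=dict)
    run_strategies: bool = True

    _REQUIRED = ("seed", "grid", "segmentation_backend", "feature_set")

    def __post_init__(self) -> None:
        if self.segmentation_backend not in ("atlas", "learned", "truth"):
            raise ValueError(
                "config field 'segmentation_backend' must be atlas|learned|truth"
            )
        if self.grid % 4:
            raise ValueError("config field 'grid' must be divisible by 4")
        from .features import FEATURE_SETS

        if self.feature_set not in FEATURE_SETS:
            raise ValueError(f"config field 'feature_set' must be one of {FEATURE_SETS}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        for req in cls._REQUIRED:
            if req not in raw:
                raise ValueError(f"config is missing required field '{req}'")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))


def _build_segmenter(config: PipelineConfig, spec: PhantomSpec, log: dict):
    """Atlas or learned segmenter trained on dedicated phantoms (never
    cohort subjects)."""
    from .segmentation import atlas_model, train_segmenter

    profiles = default_profiles()
    if config.segmentation_backend == "truth":
        return None
    if config.segmentation_backend == "atlas":
        ref_spec = replace(spec, noise_sd=0.0, mri_noise_sd=0.0)
        seed = derive_seed(config.seed, "atlas-reference")
        mri, _, truth = generate_subject(ref_spec, profiles["NC"], seed)
        log["atlas_reference_seed"] = seed
        return atlas_model(mri, truth)
    n_train = int(config.segmentation_train.get("n_train", 6))
    pairs = []
    groups = list(profiles)
    for i in range(n_train):
        seed = derive_seed(config.seed, "segtrain", i)
        mri, _, truth = generate_subject(spec, profiles[groups[i % len(groups)]], seed)
        pairs.append((mri, truth))
    tcfg = dict(config.segmentation_train)
    tcfg["seed"] = derive_seed(config.seed, "segmenter")
    log["segmenter_train_seed"] = tcfg["seed"]
    return train_segmenter(pairs, tcfg)


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Run the full framework end-to-end; returns the run directory.

    The run directory contains the cohort manifest and volumes, the
    feature table, classification results, importance tables, a metrics
    report and a machine-readable provenance log.  Any stage failure
    aborts with the stage name; partial outputs are retained.
    """
    from .classification import (
        ClassifierConfig,
        binary_tasks,
        feature_matrix,
        loocv,
        run_strategy,
    )
    from .evaluation import metrics_from_matrix
    from .features import cohort_feature_table, group_summary
    from .importance import contribution_map, feature_contributions
    from .subregions import build_subregion_map

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance: dict = {
        "version": _version,
        "config": asdict(config),
        "stages": {},
    }
    stage = "configure"
    try:
        spec = default_spec(config.grid, noise_sd=config.noise_sd)

        stage = "simulate"
        t0 = time.time()
        manifest = generate_cohort(
            out / "cohort",
            spec=spec,
            n_per_group=config.n_per_group,
            seed=derive_seed(config.seed, "cohort"),
        )
        provenance["stages"]["simulate"] = {
            "n_subjects": len(manifest),
            "seconds": round(time.time() - t0, 2),
        }

        stage = "segment"
        t0 = time.time()
        seg_log: dict = {}
        segmenter = _build_segmenter(config, spec, seg_log)
        seg_log["seconds"] = round(time.time() - t0, 2)
        provenance["stages"]["segment"] = seg_log

        stage = "extract"
        t0 = time.time()
        feat_cfg = {
            "feature_set": config.feature_set,
            "sor_formula": config.sor_formula,
            "subregion_seed": config.subregion_seed,
            "registration": config.registration,
        }
        table = cohort_feature_table(manifest, segmenter, feat_cfg)
        if len(table) < len(manifest):
            failed = [f[0] for f in table.attrs.get("failures", [])]
            provenance["stages"]["extract_failures"] = failed
        from .features import write_feature_table

        write_feature_table(table, out / "features.csv")
        group_summary(table).to_csv(out / "group_summary.csv", index=False)
        provenance["stages"]["extract"] = {"seconds": round(time.time() - t0, 2)}

        stage = "classify"
        t0 = time.time()
        clf_cfg = ClassifierConfig(
            **{**config.classifier, "seed": derive_seed(config.seed, "classifier")}
        )
        patients = table[table["group"].isin(DIAGNOSES)]
        X, y = feature_matrix(patients, config.feature_set, config.include_asymmetry)
        multi = loocv(X, y, clf_cfg)
        multi.to_frame().to_csv(out / "multiclass_predictions.csv", index=False)
        cm = multi.confusion()
        cm.to_csv(out / "confusion_matrix.csv")
        report = metrics_from_matrix(cm)
        binaries = binary_tasks(X, y, clf_cfg)
        report.auc = {d: auc for d, (res, auc) in binaries.items()}
        report.save_json(out / "metrics.json")
        report.as_percent_table().to_csv(out / "metrics_percent.csv", index=False)
        strategy_acc = {}
        if config.run_strategies and (patients["stage"] != "NA").all():
            for sid in (1, 2, 3, 4):
                res = run_strategy(patients, sid, clf_cfg, config.feature_set)
                res.to_frame().to_csv(out / f"strategy{sid}_predictions.csv", index=False)
                strategy_acc[sid] = res.accuracy
        provenance["stages"]["classify"] = {
            "seconds": round(time.time() - t0, 2),
            "multiclass_accuracy": multi.accuracy,
            "strategy_accuracy": strategy_acc,
        }

        stage = "importance"
        t0 = time.time()
        Xs, ys = feature_matrix(patients, "striatum")
        imp_cfg = {**config.importance, "seed": derive_seed(config.seed, "importance")}
        imp = feature_contributions(Xs, ys, imp_cfg)
        imp.save(out / "importance")
        from .core import save_volume
        from .phantom import build_truth_labels

        submap = build_subregion_map(build_truth_labels(spec), seed=config.subregion_seed)
        save_volume(contribution_map(submap, imp), out / "contribution_map.nii.gz")
        provenance["stages"]["importance"] = {"seconds": round(time.time() - t0, 2)}
    except Exception as exc:
        provenance["failed_stage"] = stage
        provenance["error"] = str(exc)
        (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return out
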