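"""End-to-end orchestration: simulate -> extract -> stability -> model -> evaluate.

A single JSON config drives the run; one master seed is fanned out per
stage, every artifact is checksummed into a run manifest, and re-running
with the same config and seed reproduces identical checksums for all
deterministic stages.

Two cohort modes are supported: ``panel`` simulates per-setting feature
tables directly (fast; known ICC ground truth), ``imaging`` builds phantom
volumes, degrades them per acquisition setting, and extracts features.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .evaluation import CVPlan, generalizability_summary, run_cv
from .features import ExtractionConfig, extract_all
from .preprocess import PreprocessSpec
from .settings import DEFAULT_GROUP_PLAN, REFERENCE_SETTING_ID, SETTINGS
from .stability import (
    SettingGroupPlan,
    category_summary,
    intersect_categories,
    joint_partition,
    records_to_frame,
    stability_by_group,
)
from .synthetic import PanelSpec, PhantomSpec, apply_setting, make_phantom_cohort, simulate_feature_panel

logger = logging.getLogger("radstab.pipeline")

_DEFAULTS: dict[str, Any] = {
    "mode": "panel",
    "seed": 0,
    "out_dir": "radstab_run",
    "icc_thresholds": {"stable": 0.8, "unstable": 0.4},
    "n_select": 20,
    "cv_folds": 5,
    "n_test": None,          # default: 20% of subjects
    "settings": [s.setting_id for s in SETTINGS],
    "panel": {},             # PanelSpec overrides
    "cohort": {},            # PhantomSpec overrides
    "extraction": {},        # ExtractionConfig overrides
}

_KNOWN_KEYS = set(_DEFAULTS)


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    mode: str
    seed: int
    out_dir: Path
    stable_threshold: float
    unstable_threshold: float
    n_select: int
    cv_folds: int
    n_test: int | None
    settings: list[str]
    panel: dict
    cohort: dict
    extraction: dict
    raw: dict = field(default_factory=dict)


def validate_config(source: str | Path | Mapping[str, Any]) -> PipelineConfig:
    """Schema-check a JSON config (path or mapping) and fill defaults."""
    if isinstance(source, (str, Path)):
        path = Path(source)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        data = json.loads(path.read_text())
    else:
        data = dict(source)
    unknown = set(data) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    merged = {**_DEFAULTS, **data}
    thr = {**_DEFAULTS["icc_thresholds"], **merged["icc_thresholds"]}
    lo, hi = thr["unstable"], thr["stable"]
    if not (0 < lo < hi < 1):
        raise ConfigError(f"ICC thresholds must satisfy 0 < unstable < stable < 1, got {lo}, {hi}")
    if merged["mode"] not in ("panel", "imaging"):
        raise ConfigError(f"mode must be 'panel' or 'imaging', got {merged['mode']!r}")
    if REFERENCE_SETTING_ID not in merged["settings"]:
        raise ConfigError(f"settings must include the reference {REFERENCE_SETTING_ID}")
    return PipelineConfig(
        mode=merged["mode"],
        seed=int(merged["seed"]),
        out_dir=Path(merged["out_dir"]),
        stable_threshold=float(hi),
        unstable_threshold=float(lo),
        n_select=int(merged["n_select"]),
        cv_folds=int(merged["cv_folds"]),
        n_test=merged["n_test"],
        settings=list(merged["settings"]),
        panel=dict(merged["panel"]),
        cohort=dict(merged["cohort"]),
        extraction=dict(merged["extraction"]),
        raw=merged,
    )


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    checksums: dict[str, str]
    timestamps: dict[str, float]

    def to_json(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.12g")


def _simulate_tables(cfg: PipelineConfig) -> dict[str, pd.DataFrame]:
    if cfg.mode == "panel":
        spec = PanelSpec(**{"n_subjects": 200, "n_features": 40,
                            "seed": cfg.seed,
                            "setting_ids": tuple(cfg.settings),
                            **cfg.panel})
        return simulate_feature_panel(spec)
    cohort_kwargs = {"n_nodules": 24, "seed": cfg.seed, **cfg.cohort}
    cohort = make_phantom_cohort(PhantomSpec(**cohort_kwargs))
    ex_kwargs = dict(cfg.extraction)
    pre = PreprocessSpec(**ex_kwargs.pop("preprocess", {}))
    ex = ExtractionConfig(preprocess=pre, **{k: tuple(v) if isinstance(v, list) else v
                                             for k, v in ex_kwargs.items()})
    tables: dict[str, pd.DataFrame] = {}
    for sid in cfg.settings:
        rows = []
        for nod in cohort:
            variant = apply_setting(nod, sid)
            feats = extract_all(variant.volume, variant.mask, ex)
            rows.append({"nodule_id": nod.nodule_id, "setting_id": sid,
                         "label": nod.label, **feats})
        tables[sid] = pd.DataFrame(rows)
        logger.info("stage=extract setting=%s nodules=%d features=%d",
                    sid, len(rows), len(rows[0]) - 3)
    return tables


def run_pipeline(config: PipelineConfig | str | Path | Mapping[str, Any]) -> RunManifest:
    """Execute all stages and write artifacts + manifest under ``out_dir``.

    Any stage failure aborts with the stage name; partial outputs are kept
    next to a ``FAILED_<stage>`` marker file.
    """
    cfg = config if isinstance(config, PipelineConfig) else validate_config(config)
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out / "run.log")
    logger.addHandler(log_handler)
    logger.setLevel(logging.INFO)

    checksums: dict[str, str] = {}
    timestamps: dict[str, float] = {}
    stage = "init"

    def record(path: Path) -> None:
        checksums[path.name] = _sha256(path)

    try:
        stage = "simulate"
        timestamps[stage] = time.time()
        logger.info("stage=%s event=start mode=%s seed=%d", stage, cfg.mode, cfg.seed)
        tables = _simulate_tables(cfg)
        feat_dir = out / "features"
        feat_dir.mkdir(exist_ok=True)
        for sid, df in tables.items():
            p = feat_dir / f"features_{sid}.csv"
            _write_csv(df, p)
            checksums[f"features/{p.name}"] = _sha256(p)

        stage = "stability"
        timestamps[stage] = time.time()
        plan_groups = {
            name: tuple(s for s in ids if s in tables)
            for name, ids in DEFAULT_GROUP_PLAN.groups.items()
        }
        plan_groups = {n: ids for n, ids in plan_groups.items()
                       if len(ids) >= 2 and REFERENCE_SETTING_ID in ids}
        group_records = {}
        if plan_groups:
            plan = SettingGroupPlan(groups=plan_groups)
            group_records = stability_by_group(
                tables, plan, cfg.stable_threshold, cfg.unstable_threshold)
            rec_df = records_to_frame(group_records)
            p = out / "icc_records.csv"
            _write_csv(rec_df, p)
            record(p)
            if len(plan_groups) >= 2:
                venn = {}
                for cat in ("stable", "unstable"):
                    _, counts = intersect_categories(group_records, cat)
                    venn[cat] = counts
                p = out / "venn_counts.json"
                p.write_text(json.dumps(venn, indent=2, sort_keys=True))
                record(p)
        partition, joint_records = joint_partition(
            tables, cfg.settings, cfg.stable_threshold, cfg.unstable_threshold)
        p = out / "icc_joint.csv"
        _write_csv(records_to_frame({"all_settings": joint_records}), p)
        record(p)
        logger.info("stage=%s event=done stable=%d intermediate=%d unstable=%d",
                    stage, len(partition.stable), len(partition.intermediate),
                    len(partition.unstable))

        stage = "split"
        timestamps[stage] = time.time()
        ref = tables[REFERENCE_SETTING_ID]
        n_sub = len(ref)
        n_test = cfg.n_test if cfg.n_test is not None else max(4, n_sub // 5)
        rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 101)))
        labels = ref["label"].to_numpy()
        test_idx: list[int] = []
        for lab in np.unique(labels):
            idx = np.flatnonzero(labels == lab)
            take = int(round(n_test * len(idx) / n_sub))
            test_idx.extend(rng.choice(idx, size=min(take, len(idx)), replace=False))
        test_ids = set(ref.iloc[sorted(test_idx)]["nodule_id"])
        trainval = ref[~ref["nodule_id"].isin(test_ids)].reset_index(drop=True)
        test_tables = {sid: df[df["nodule_id"].isin(test_ids)].reset_index(drop=True)
                       for sid, df in tables.items()}

        stage = "evaluate"
        timestamps[stage] = time.time()
        plan = CVPlan(n_folds=cfg.cv_folds, seed=cfg.seed, n_select=cfg.n_select)
        report = run_cv(trainval, test_tables, partition, plan)
        p = out / "cv_report.csv"
        _write_csv(report.metrics, p)
        record(p)
        p = out / "comparisons.csv"
        _write_csv(report.comparisons, p)
        record(p)

        stage = "models"
        timestamps[stage] = time.time()
        # Final per-stratum models refit on the full training-validation
        # cohort, serialized for reuse.
        from .classifier import train_stratum_model
        feat_cols = [c for c in trainval.columns
                     if c not in ("nodule_id", "setting_id", "label")]
        y = (trainval["label"] == "malignant").astype(int).to_numpy()
        model_dir = out / "models"
        model_dir.mkdir(exist_ok=True)
        for label in plan.strata:
            feats = sorted(partition.stratum(label) & set(feat_cols))
            if not feats:
                continue
            model = train_stratum_model(trainval, y, feats, stratum_label=label,
                                        n_select=cfg.n_select)
            p = model_dir / f"model_{label}.json"
            model.to_json(p)
            checksums[f"models/{p.name}"] = _sha256(p)

        stage = "summary"
        timestamps[stage] = time.time()
        summary = {
            "fold_means": report.fold_means().to_dict(orient="records"),
            "generalizability": generalizability_summary(report)
            .to_dict(orient="records"),
            "stability_summary": {
                g: category_summary(recs) for g, recs in group_records.items()
            },
        }
        p = out / "summary.json"
        p.write_text(json.dumps(summary, indent=2, sort_keys=True, default=float))
        record(p)

        config_hash = hashlib.sha256(
            json.dumps(cfg.raw, sort_keys=True, default=str).encode()).hexdigest()
        manifest = RunManifest(config_hash=config_hash, seed=cfg.seed,
                               version=__version__, checksums=checksums,
                               timestamps=timestamps)
        manifest.to_json(out / "manifest.json")
        logger.info("stage=done artifacts=%d", len(checksums))
        return manifest
    except Exception as exc:
        (out / f"FAILED_{stage}").write_text(f"{type(exc).__name__}: {exc}\n")
        logger.error("stage=%s event=failed error=%s", stage, exc)
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
    finally:
        logger.removeHandler(log_handler)
        log_handler.close()
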