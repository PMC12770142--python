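"""Metrics, paired tests and cross-validated model comparison.

Implements the evaluation protocol of the stability study: fivefold
stratified cross-validation over seven stability-stratum models, external
evaluation on ten reconstruction-variant test sets, DeLong tests on paired
AUCs and McNemar tests on paired sensitivity/specificity, and the
generalizability summary (AUC range across test settings per model).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .classifier import (
    STRATUM_LABELS,
    FirthModel,
    apply_stratum_model,
    train_stratum_model,
)
from .stability import StabilityPartition

METRIC_NAMES = ("auc", "accuracy", "sensitivity", "specificity", "gmean", "f1")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(labels: np.ndarray, predictions: np.ndarray) -> ConfusionCounts:
    labels = np.asarray(labels).astype(int)
    predictions = np.asarray(predictions).astype(int)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must have the same length")
    return ConfusionCounts(
        tp=int(np.sum((labels == 1) & (predictions == 1))),
        fp=int(np.sum((labels == 0) & (predictions == 1))),
        tn=int(np.sum((labels == 0) & (predictions == 0))),
        fn=int(np.sum((labels == 1) & (predictions == 0))),
    )


def gmean(sensitivity: float, specificity: float) -> float:
    """G-mean = sqrt(sensitivity x specificity)."""
    return float(np.sqrt(sensitivity * specificity))


def balanced_accuracy(sensitivity: float, specificity: float) -> float:
    """Accuracy under balanced classes: (sensitivity + specificity) / 2."""
    return (sensitivity + specificity) / 2.0


def auc_score(labels: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney (midrank) AUC; errors on single-class labels."""
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined for single-class labels")
    return float(roc_auc_score(labels, scores))


def metrics_row(labels: np.ndarray, predictions: np.ndarray,
                scores: np.ndarray) -> dict[str, float]:
    """AUC, accuracy, sensitivity, specificity, G-mean and F1 for one
    evaluation.  F1 = 2TP / (2TP + FP + FN)."""
    c = confusion(labels, predictions)
    sens = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else np.nan
    spec = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else np.nan
    f1_den = 2 * c.tp + c.fp + c.fn
    return {
        "auc": auc_score(labels, scores),
        "accuracy": (c.tp + c.tn) / c.n,
        "sensitivity": sens,
        "specificity": spec,
        "gmean": gmean(sens, spec),
        "f1": 2 * c.tp / f1_den if f1_den else np.nan,
    }


# ---------------------------------------------------------------------------
# DeLong test for paired AUCs
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus per-positive (V10) and per-negative (V01) placement values."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    r_all = _midrank(np.concatenate([pos, neg]))
    r_pos = _midrank(pos)
    r_neg = _midrank(neg)
    auc = (r_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    return float(auc), v10, v01


@dataclass(frozen=True)
class DeLongResult:
    auc_a: float
    auc_b: float
    p_value: float
    z: float
    zero_variance: bool = False


def delong_test(scores_a: np.ndarray, scores_b: np.ndarray,
                labels: np.ndarray) -> DeLongResult:
    """Two-sided paired DeLong test for AUC_a = AUC_b on shared cases.

    Uses the structural-component (placement value) covariance estimate;
    zero variance of the difference yields p = 1 with a flag.
    """
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("DeLong test requires both classes present")
    auc_a, v10_a, v01_a = _placements(np.asarray(scores_a, float), labels)
    auc_b, v10_b, v01_b = _placements(np.asarray(scores_b, float), labels)
    m, n = len(v10_a), len(v01_a)
    if m < 2 or n < 2:  # placement covariance needs >= 2 of each class
        return DeLongResult(auc_a, auc_b, 1.0, 0.0, zero_variance=True)
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1)
    s = s10 / m + s01 / n
    var = s[0, 0] + s[1, 1] - 2 * s[0, 1]
    if var <= 0:
        return DeLongResult(auc_a, auc_b, 1.0, 0.0, zero_variance=True)
    z = (auc_a - auc_b) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return DeLongResult(auc_a, auc_b, float(p), float(z))


# ---------------------------------------------------------------------------
# McNemar test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class McNemarResult:
    b: int
    c: int
    p_value: float
    exact: bool
    no_discordance: bool = False


def mcnemar_test(correct_a: np.ndarray, correct_b: np.ndarray) -> McNemarResult:
    """Two-sided McNemar test on paired correctness indicators.

    Exact binomial when the discordant count b + c < 25, otherwise
    chi-square with continuity correction; b + c = 0 gives p = 1, flagged.
    """
    correct_a = np.asarray(correct_a).astype(bool)
    correct_b = np.asarray(correct_b).astype(bool)
    if correct_a.shape != correct_b.shape:
        raise ValueError("paired vectors must have the same length")
    b = int(np.sum(correct_a & ~correct_b))
    c = int(np.sum(~correct_a & correct_b))
    if b + c == 0:
        return McNemarResult(b, c, 1.0, exact=True, no_discordance=True)
    if b + c < 25:
        p = stats.binomtest(b, b + c, 0.5).pvalue
        return McNemarResult(b, c, float(p), exact=True)
    chi2 = (abs(b - c) - 1) ** 2 / (b + c)
    return McNemarResult(b, c, float(stats.chi2.sf(chi2, df=1)), exact=False)


# ---------------------------------------------------------------------------
# Cross-validation orchestration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CVPlan:
    n_folds: int = 5
    seed: int = 0
    n_select: int = 20
    reference_setting: str = "S2"
    strata: tuple[str, ...] = STRATUM_LABELS


@dataclass
class CVReport:
    """Per-fold/model/dataset metrics plus pairwise model comparisons."""

    metrics: pd.DataFrame
    comparisons: pd.DataFrame
    skipped: list[dict] = field(default_factory=list)

    def fold_means(self) -> pd.DataFrame:
        """Fivefold-mean metrics per (model, dataset), Table-3 style."""
        return (self.metrics.groupby(["model", "dataset"], sort=False)
                [list(METRIC_NAMES)].mean().reset_index())


def _encode_labels(series: pd.Series) -> np.ndarray:
    return (series.to_numpy() == "malignant").astype(int)


def run_cv(trainval: pd.DataFrame,
           test_tables: Mapping[str, pd.DataFrame],
           partition: StabilityPartition,
           plan: CVPlan = CVPlan()) -> CVReport:
    """Fivefold stratified CV of the stability-stratum models.

    ``trainval`` is the reference-setting feature table of the development
    cohort (columns: nodule_id, setting_id, label, features); each entry of
    ``test_tables`` holds the same held-out nodules under one acquisition
    setting.  Normalization, MRMR selection and Firth coefficients are fit
    on each fold's training part only.  Comparisons (DeLong on AUC, McNemar
    on sensitivity/specificity) are computed per fold on the validation set
    and the reference test set.
    """
    feat_cols = [c for c in trainval.columns
                 if c not in ("nodule_id", "setting_id", "label")]
    y_all = _encode_labels(trainval["label"])
    skf = StratifiedKFold(n_splits=plan.n_folds, shuffle=True, random_state=plan.seed)

    rows: list[dict] = []
    comps: list[dict] = []
    skipped: list[dict] = []
    for fold, (tr_idx, va_idx) in enumerate(skf.split(trainval, y_all)):
        tr, va = trainval.iloc[tr_idx], trainval.iloc[va_idx]
        y_tr, y_va = y_all[tr_idx], y_all[va_idx]

        models: dict[str, FirthModel] = {}
        for label in plan.strata:
            feats = sorted(partition.stratum(label) & set(feat_cols))
            if not feats:
                skipped.append({"fold": fold, "model": label,
                                "reason": "empty feature stratum"})
                continue
            models[label] = train_stratum_model(
                tr, y_tr, feats, stratum_label=label, n_select=plan.n_select)

        eval_sets: dict[str, tuple[pd.DataFrame, np.ndarray]] = {
            "train": (tr, y_tr), "valid": (va, y_va)}
        for sid, df in test_tables.items():
            eval_sets[f"test_{sid}"] = (df, _encode_labels(df["label"]))

        fold_scores: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for label, model in models.items():
            for ds_name, (df, y) in eval_sets.items():
                prob, pred = apply_stratum_model(model, df)
                fold_scores[(label, ds_name)] = (y, prob, pred)
                rows.append({"fold": fold, "model": label, "dataset": ds_name,
                             **metrics_row(y, pred, prob)})

        compare_on = ["valid", f"test_{plan.reference_setting}"]
        for ds_name in compare_on:
            for a, b in combinations(models, 2):
                if (a, ds_name) not in fold_scores or (b, ds_name) not in fold_scores:
                    continue
                y, pa, preda = fold_scores[(a, ds_name)]
                _, pb, predb = fold_scores[(b, ds_name)]
                dl = delong_test(pa, pb, y)
                pos, neg = y == 1, y == 0
                mc_sens = mcnemar_test(preda[pos] == 1, predb[pos] == 1)
                mc_spec = mcnemar_test(preda[neg] == 0, predb[neg] == 0)
                comps.append({
                    "fold": fold, "dataset": ds_name, "model_a": a, "model_b": b,
                    "auc_a": dl.auc_a, "auc_b": dl.auc_b,
                    "delong_p": dl.p_value,
                    "mcnemar_sens_p": mc_sens.p_value,
                    "mcnemar_spec_p": mc_spec.p_value,
                    "significant": dl.p_value < 0.05,
                })

    return CVReport(metrics=pd.DataFrame(rows), comparisons=pd.DataFrame(comps),
                    skipped=skipped)


def generalizability_summary(report: CVReport,
                             setting_ids: Sequence[str] | None = None
                             ) -> pd.DataFrame:
    """Min / max / range of fivefold-mean AUC across the test settings.

    The model with the smallest range (most consistent across
    reconstruction variants) is flagged.
    """
    means = report.fold_means()
    test = means[means["dataset"].str.startswith("test_")].copy()
    if setting_ids is not None:
        keep = {f"test_{s}" for s in setting_ids}
        test = test[test["dataset"].isin(keep)]
    rows = []
    for model, grp in test.groupby("model", sort=False):
        aucs = grp["auc"].to_numpy()
        rows.append({"model": model, "auc_min": aucs.min(), "auc_max": aucs.max(),
                     "auc_range": aucs.max() - aucs.min(),
                     "n_test_sets": len(aucs)})
    out = pd.DataFrame(rows)
    out["smallest_range"] = out["auc_range"] == out["auc_range"].min()
    return out
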