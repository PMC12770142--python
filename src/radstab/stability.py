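"""Feature stability across acquisition settings via ICC(A,1).

Agreement of one feature across reconstruction variants is scored with the
single-rating, absolute-agreement, two-way mixed-effects intraclass
correlation (McGraw & Wong ICC(A,1)): subjects are nodules, "raters" are
acquisition settings.  Absolute agreement penalises systematic per-setting
offsets, not just rank disagreement.  Features are stratified at the
conventional 0.8 / 0.4 thresholds into stable / intermediate / unstable.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .settings import DEFAULT_GROUP_PLAN, SettingGroupPlan

STABLE_THRESHOLD = 0.8
UNSTABLE_THRESHOLD = 0.4

CATEGORIES = ("stable", "intermediate", "unstable")


@dataclass(frozen=True)
class ICCRecord:
    feature_name: str
    icc: float
    category: str
    degenerate: bool = False


@dataclass
class StabilityPartition:
    """Disjoint stable / intermediate / unstable feature-name sets."""

    stable: frozenset[str]
    intermediate: frozenset[str]
    unstable: frozenset[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        sets = (self.stable, self.intermediate, self.unstable)
        for a, b in combinations(sets, 2):
            if a & b:
                raise ValueError("stability categories must be disjoint")

    @property
    def universe(self) -> frozenset[str]:
        return self.stable | self.intermediate | self.unstable

    def stratum(self, label: str) -> frozenset[str]:
        """Feature set for a model stratum: FULL, S, I, U, SI, SU or UI."""
        parts = {
            "FULL": self.universe,
            "S": self.stable,
            "I": self.intermediate,
            "U": self.unstable,
            "SI": self.stable | self.intermediate,
            "SU": self.stable | self.unstable,
            "UI": self.unstable | self.intermediate,
        }
        if label not in parts:
            raise KeyError(f"unknown stratum label {label!r}")
        return frozenset(parts[label])


def anova_mean_squares(ratings: np.ndarray) -> tuple[float, float, float]:
    """Two-way ANOVA mean squares (rows = subjects, columns = raters).

    Returns (MSR, MSC, MSE): subject, rater and residual mean squares.
    """
    ratings = np.asarray(ratings, dtype=np.float64)
    n, k = ratings.shape
    if n < 2 or k < 2:
        raise ValueError("ratings matrix must be at least 2 x 2")
    if not np.all(np.isfinite(ratings)):
        raise ValueError("ratings matrix contains non-finite cells")
    grand = ratings.mean()
    row_means = ratings.mean(axis=1)
    col_means = ratings.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((ratings - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    return (ss_rows / (n - 1), ss_cols / (k - 1), ss_err / ((n - 1) * (k - 1)))


def icc_a1(ratings: np.ndarray, feature_name: str = "") -> ICCRecord:
    """Single-rating absolute-agreement two-way mixed-effects ICC.

    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)).

    A matrix with zero total variance has no defined agreement: the record
    is flagged degenerate and categorised unstable (a feature constant
    across subjects carries no discriminative signal).  Negative estimates
    (bounded below by -1/(k-1)) are retained as computed.
    """
    ratings = np.asarray(ratings, dtype=np.float64)
    n, k = ratings.shape
    if ((ratings - ratings.mean()) ** 2).sum() == 0.0:
        return ICCRecord(feature_name, np.nan, "unstable", degenerate=True)
    msr, msc, mse = anova_mean_squares(ratings)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        return ICCRecord(feature_name, np.nan, "unstable", degenerate=True)
    icc = (msr - mse) / denom
    return ICCRecord(feature_name, float(icc), categorize(icc))


def categorize(icc: float,
               stable_threshold: float = STABLE_THRESHOLD,
               unstable_threshold: float = UNSTABLE_THRESHOLD) -> str:
    """Stability stratum of an ICC value; boundaries are inclusive:
    icc >= 0.8 -> stable, icc <= 0.4 -> unstable, otherwise intermediate."""
    if np.isnan(icc):
        return "unstable"
    if icc >= stable_threshold:
        return "stable"
    if icc <= unstable_threshold:
        return "unstable"
    return "intermediate"


def ratings_matrix(tables: Mapping[str, pd.DataFrame], feature: str,
                   setting_ids: Sequence[str]) -> np.ndarray:
    """Assemble the subjects x settings matrix of one feature.

    Tables must share nodule_ids; subjects with any missing cell are
    dropped (complete-case policy)."""
    cols = []
    base_ids = tables[setting_ids[0]]["nodule_id"].to_numpy()
    for sid in setting_ids:
        if sid not in tables:
            raise KeyError(f"missing feature table for setting {sid!r}")
        df = tables[sid]
        if not np.array_equal(df["nodule_id"].to_numpy(), base_ids):
            df = df.set_index("nodule_id").loc[base_ids].reset_index()
        cols.append(df[feature].to_numpy(dtype=np.float64))
    mat = np.column_stack(cols)
    complete = np.all(np.isfinite(mat), axis=1)
    return mat[complete]


def feature_columns(df: pd.DataFrame) -> list[str]:
    meta = {"nodule_id", "setting_id", "label"}
    return [c for c in df.columns if c not in meta]


def stability_by_group(tables: Mapping[str, pd.DataFrame],
                       plan: SettingGroupPlan = DEFAULT_GROUP_PLAN,
                       stable_threshold: float = STABLE_THRESHOLD,
                       unstable_threshold: float = UNSTABLE_THRESHOLD,
                       ) -> dict[str, list[ICCRecord]]:
    """Per-group ICC records for every feature.

    For each named group (slice thickness, matrix, kernel, transmission)
    the ratings matrix uses only that group's settings, isolating the
    impact of one reconstruction factor.
    """
    first = next(iter(tables.values()))
    feats = feature_columns(first)
    out: dict[str, list[ICCRecord]] = {}
    for group, sids in plan.groups.items():
        missing = [s for s in sids if s not in tables]
        if missing:
            raise KeyError(f"group {group!r}: missing feature tables for {missing}")
        records = []
        for f in feats:
            mat = ratings_matrix(tables, f, sids)
            if mat.shape[0] < 2:
                records.append(ICCRecord(f, np.nan, "unstable", degenerate=True))
                continue
            rec = icc_a1(mat, f)
            cat = ("unstable" if rec.degenerate
                   else categorize(rec.icc, stable_threshold, unstable_threshold))
            records.append(ICCRecord(f, rec.icc, cat, rec.degenerate))
        out[group] = records
    return out


def category_summary(records: Iterable[ICCRecord]) -> dict[str, dict[str, float]]:
    records = list(records)
    n = len(records)
    out = {}
    for cat in CATEGORIES:
        count = sum(r.category == cat for r in records)
        out[cat] = {"count": count, "fraction": count / n if n else np.nan}
    return out


def intersect_categories(groups: Mapping[str, Sequence[ICCRecord]],
                         category: str) -> tuple[frozenset[str], dict[str, int]]:
    """Features in ``category`` under ALL groups, plus Venn region counts.

    Region keys are '+'-joined sorted group names; counts cover every
    non-empty combination (2^G - 1 regions), i.e. features in exactly that
    set of groups.
    """
    names = sorted(groups)
    universes = [frozenset(r.feature_name for r in groups[g]) for g in names]
    if len(set(universes)) != 1:
        raise ValueError("groups cover different feature universes")
    member: dict[str, frozenset[str]] = {
        g: frozenset(r.feature_name for r in groups[g] if r.category == category)
        for g in names
    }
    inter_all = frozenset.intersection(*member.values())
    counts: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = frozenset.intersection(*(member[g] for g in combo))
            outside = frozenset.union(
                frozenset(), *(member[g] for g in names if g not in combo))
            counts["+".join(combo)] = len(inside - outside)
    return inter_all, counts


def partition_from_records(records: Sequence[ICCRecord],
                           provenance: str = "") -> StabilityPartition:
    by_cat = {c: frozenset(r.feature_name for r in records if r.category == c)
              for c in CATEGORIES}
    return StabilityPartition(stable=by_cat["stable"],
                              intermediate=by_cat["intermediate"],
                              unstable=by_cat["unstable"],
                              provenance=provenance)


def joint_partition(tables: Mapping[str, pd.DataFrame],
                    setting_ids: Sequence[str] | None = None,
                    stable_threshold: float = STABLE_THRESHOLD,
                    unstable_threshold: float = UNSTABLE_THRESHOLD,
                    ) -> tuple[StabilityPartition, list[ICCRecord]]:
    """Stratify features by ICC across a set of settings jointly."""
    if setting_ids is None:
        setting_ids = list(tables)
    feats = feature_columns(next(iter(tables.values())))
    records = []
    for f in feats:
        mat = ratings_matrix(tables, f, list(setting_ids))
        if mat.shape[0] < 2:
            records.append(ICCRecord(f, np.nan, "unstable", degenerate=True))
            continue
        rec = icc_a1(mat, f)
        cat = ("unstable" if rec.degenerate
               else categorize(rec.icc, stable_threshold, unstable_threshold))
        records.append(ICCRecord(f, rec.icc, cat, rec.degenerate))
    part = partition_from_records(records, provenance=f"joint:{','.join(setting_ids)}")
    return part, records


def records_to_frame(groups: Mapping[str, Sequence[ICCRecord]]) -> pd.DataFrame:
    rows = [
        {"feature": r.feature_name, "group": g, "icc": r.icc,
         "category": r.category, "degenerate_flag": r.degenerate}
        for g, recs in groups.items() for r in recs
    ]
    return pd.DataFrame(rows)
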