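"""Stability-stratified malignancy classifiers.

Training recipe: z-score normalization (parameters learned on training data
only), greedy minimum-redundancy-maximum-relevance (MRMR) selection of the
top 20 features, then logistic regression fitted by maximising the
Firth/Jeffreys-penalized log-likelihood

    l*(b) = l(b) + 1/2 log det(X' W X),   W = diag(pi (1 - pi)),

via iteratively reweighted least squares on the bias-adjusted responses
y_i + h_i (1/2 - pi_i) (h_i = hat-matrix diagonals), capped at 100
iterations.  The penalty guarantees finite coefficients even under complete
separation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special

STRATUM_LABELS = ("FULL", "S", "U", "I", "SI", "SU", "UI")


# ---------------------------------------------------------------------------
# Z-score normalization
# ---------------------------------------------------------------------------

@dataclass
class NormalizationParams:
    """Per-feature training mean/sd; zero-sd features are dropped on apply."""

    feature_names: list[str]
    mean: np.ndarray
    sd: np.ndarray
    dropped: list[str] = field(default_factory=list)

    @property
    def kept(self) -> list[str]:
        return [f for f in self.feature_names if f not in set(self.dropped)]


def zscore_fit(train: pd.DataFrame, features: Sequence[str]) -> NormalizationParams:
    features = list(features)
    x = train[features].to_numpy(dtype=np.float64)
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    dropped = [f for f, s in zip(features, sd) if s == 0]
    return NormalizationParams(features, mean, sd, dropped)


def zscore_apply(params: NormalizationParams, table: pd.DataFrame) -> pd.DataFrame:
    """Transform with the training parameters (never refit on new data)."""
    keep_idx = [i for i, f in enumerate(params.feature_names)
                if f not in set(params.dropped)]
    feats = [params.feature_names[i] for i in keep_idx]
    x = table[feats].to_numpy(dtype=np.float64)
    z = (x - params.mean[keep_idx]) / params.sd[keep_idx]
    return pd.DataFrame(z, columns=feats, index=table.index)


# ---------------------------------------------------------------------------
# MRMR feature selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionResult:
    features: list[str]
    scores: list[float]


def _f_statistic(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """One-way ANOVA F of each column against the binary label."""
    x0, x1 = x[y == 0], x[y == 1]
    n0, n1 = len(x0), len(x1)
    n = n0 + n1
    grand = x.mean(axis=0)
    ss_between = n0 * (x0.mean(axis=0) - grand) ** 2 + n1 * (x1.mean(axis=0) - grand) ** 2
    ss_within = ((x0 - x0.mean(axis=0)) ** 2).sum(axis=0) + \
                ((x1 - x1.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ss_between / 1.0 / (ss_within / (n - 2))
    return np.where(ss_within > 0, f, np.inf)


def mrmr_select(x: pd.DataFrame, y: np.ndarray, m: int = 20) -> SelectionResult:
    """Greedy forward MRMR with the difference criterion.

    Relevance is the label F-statistic mapped to correlation units,
    sqrt(F / (F + n - 2)) — the absolute point-biserial correlation — so it
    is commensurate with the redundancy term, the mean absolute Pearson
    correlation with already-selected features.  Ties break on column
    order, making selection deterministic.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    feats = list(x.columns)
    if not feats:
        raise ValueError("no candidate features")
    if m > len(feats):
        m = len(feats)
    arr = x.to_numpy(dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)

    f_stat = _f_statistic(arr, y)
    n_obs = len(arr)
    with np.errstate(invalid="ignore"):
        relevance = np.where(np.isfinite(f_stat),
                             np.sqrt(f_stat / (f_stat + n_obs - 2)), 1.0)

    sd = arr.std(axis=0, ddof=0)
    safe = np.where(sd > 0, sd, 1.0)
    zs = (arr - arr.mean(axis=0)) / safe
    corr_cache = np.zeros((len(feats), 0))

    selected: list[int] = []
    scores: list[float] = []
    remaining = np.ones(len(feats), dtype=bool)
    for _ in range(m):
        if corr_cache.shape[1]:
            redundancy = np.abs(corr_cache).mean(axis=1)
        else:
            redundancy = np.zeros(len(feats))
        crit = np.where(remaining, relevance - redundancy, -np.inf)
        j = int(np.argmax(crit))  # argmax takes the first max: column-order tie-break
        selected.append(j)
        scores.append(float(crit[j]))
        remaining[j] = False
        new_corr = (zs * zs[:, [j]]).mean(axis=0) * (sd[j] > 0)
        corr_cache = np.column_stack([corr_cache, new_corr])
    return SelectionResult([feats[j] for j in selected], scores)


# ---------------------------------------------------------------------------
# Firth-penalized logistic regression
# ---------------------------------------------------------------------------

@dataclass
class FirthModel:
    feature_names: list[str]
    coef: np.ndarray  # [intercept, b_1 .. b_p]
    converged: bool
    n_iter: int
    final_score_norm: float
    stratum_label: str = "FULL"
    normalization: NormalizationParams | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature_names": self.feature_names,
            "coef": self.coef.tolist(),
            "converged": self.converged,
            "n_iter": self.n_iter,
            "final_score_norm": self.final_score_norm,
            "stratum_label": self.stratum_label,
        }
        if self.normalization is not None:
            payload["normalization"] = {
                "feature_names": self.normalization.feature_names,
                "mean": self.normalization.mean.tolist(),
                "sd": self.normalization.sd.tolist(),
                "dropped": self.normalization.dropped,
            }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "FirthModel":
        d = json.loads(Path(path).read_text())
        norm = None
        if "normalization" in d:
            nd = d["normalization"]
            norm = NormalizationParams(nd["feature_names"], np.array(nd["mean"]),
                                       np.array(nd["sd"]), nd["dropped"])
        return cls(d["feature_names"], np.array(d["coef"]), d["converged"],
                   d["n_iter"], d["final_score_norm"], d["stratum_label"], norm)


def firth_penalized_loglik(beta: np.ndarray, x: np.ndarray, y: np.ndarray,
                           penalty_weight: float = 1.0) -> float:
    """log L(beta) + w/2 log det(X' W X) with an intercept column prepended."""
    xd = np.column_stack([np.ones(len(x)), x])
    eta = xd @ beta
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    pi = 1.0 / (1.0 + np.exp(-eta))
    w = pi * (1 - pi)
    info = xd.T @ (xd * w[:, None])
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -np.inf
    return ll + 0.5 * penalty_weight * logdet


def _drop_collinear(x: np.ndarray, names: list[str], tol: float = 1e-8
                    ) -> tuple[np.ndarray, list[str], list[str]]:
    """QR-based removal of later duplicated/collinear columns."""
    xd = np.column_stack([np.ones(len(x)), x])
    q, r = np.linalg.qr(xd)
    diag = np.abs(np.diag(r))  # length min(n, p+1): excess columns get dropped
    scale = diag.max() if diag.size else 1.0
    keep = np.zeros(xd.shape[1], dtype=bool)
    keep[:len(diag)] = diag > tol * scale
    keep[0] = True  # intercept always stays
    kept_idx = [i - 1 for i in range(1, xd.shape[1]) if keep[i]]
    dropped = [names[i - 1] for i in range(1, xd.shape[1]) if not keep[i]]
    return x[:, kept_idx], [names[i] for i in kept_idx], dropped


def firth_fit(x: np.ndarray | pd.DataFrame, y: np.ndarray,
              max_iter: int = 100, tol: float = 1e-6,
              stratum_label: str = "FULL",
              penalty_weight: float = 1.0) -> FirthModel:
    """Fit Firth-penalized logistic regression by IRLS with step-halving.

    Stops when the penalized-score norm drops below ``tol`` or after
    ``max_iter`` iterations (a non-converged model is returned flagged, not
    raised).  ``penalty_weight`` = 0 is a diagnostic mode recovering the
    plain MLE on non-separable data.
    """
    if isinstance(x, pd.DataFrame):
        names = list(x.columns)
        x = x.to_numpy(dtype=np.float64)
    else:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 1:
            x = x[:, None]
        names = [f"x{i}" for i in range(x.shape[1])]
    y = np.asarray(y, dtype=np.float64)
    uniq = np.unique(y)
    if not np.all(np.isin(uniq, [0.0, 1.0])):
        raise ValueError("y must be binary 0/1")

    x, names, _dropped = _drop_collinear(x, names)
    xd = np.column_stack([np.ones(len(x)), x])
    n, p = xd.shape
    beta = np.zeros(p)

    def score_and_info(b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        eta = np.clip(xd @ b, -30, 30)
        pi = 1.0 / (1.0 + np.exp(-eta))
        w = pi * (1 - pi)
        info = xd.T @ (xd * w[:, None])
        # hat diagonals of the weighted design: h_i = w_i x_i info^{-1} x_i'
        sol = np.linalg.solve(info, xd.T)
        h = w * np.einsum("ij,ji->i", xd, sol)
        adj = y + penalty_weight * h * (0.5 - pi) - pi
        return xd.T @ adj, info, pi

    obj = firth_penalized_loglik(beta, x, y, penalty_weight)
    score, info, _ = score_and_info(beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        step = np.linalg.solve(info, score)
        # step-halving on the penalized objective
        new_beta, new_obj = beta + step, firth_penalized_loglik(beta + step, x, y,
                                                                penalty_weight)
        halves = 0
        while new_obj < obj - 1e-12 and halves < 25:
            step *= 0.5
            new_beta = beta + step
            new_obj = firth_penalized_loglik(new_beta, x, y, penalty_weight)
            halves += 1
        beta, obj = new_beta, new_obj
        score, info, _ = score_and_info(beta)
        if np.linalg.norm(score) < tol:
            converged = True
            break

    return FirthModel(
        feature_names=names,
        coef=beta,
        converged=converged,
        n_iter=it,
        final_score_norm=float(np.linalg.norm(score)),
        stratum_label=stratum_label,
    )


def predict(model: FirthModel, x: np.ndarray | pd.DataFrame,
            threshold: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Logistic probabilities and hard labels (positive iff p >= threshold)."""
    if isinstance(x, pd.DataFrame):
        missing = [f for f in model.feature_names if f not in x.columns]
        extra = [c for c in x.columns if c not in model.feature_names]
        if missing:
            raise ValueError(f"missing features {missing}; extra {extra}")
        x = x[model.feature_names].to_numpy(dtype=np.float64)
    else:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 1:
            x = x[:, None]
        if x.shape[1] != len(model.feature_names):
            raise ValueError(
                f"expected {len(model.feature_names)} features, got {x.shape[1]}"
            )
    eta = model.coef[0] + x @ model.coef[1:]
    prob = special.expit(eta)
    return prob, (prob >= threshold).astype(int)


def train_stratum_model(train: pd.DataFrame, y: np.ndarray,
                        features: Sequence[str], stratum_label: str,
                        n_select: int = 20, max_iter: int = 100,
                        tol: float = 1e-6) -> FirthModel:
    """Normalize -> MRMR -> Firth on one feature stratum; returns the model
    with its normalization parameters attached for later application."""
    norm = zscore_fit(train, features)
    z = zscore_apply(norm, train)
    if z.shape[1] == 0:
        raise ValueError(f"stratum {stratum_label!r}: no usable features")
    sel = mrmr_select(z, y, m=n_select)
    model = firth_fit(z[sel.features], y, max_iter=max_iter, tol=tol,
                      stratum_label=stratum_label)
    model.normalization = norm
    return model


def apply_stratum_model(model: FirthModel, table: pd.DataFrame,
                        threshold: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    if model.normalization is None:
        raise ValueError("model carries no normalization parameters")
    z = zscore_apply(model.normalization, table)
    return predict(model, z[model.feature_names], threshold=threshold)
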