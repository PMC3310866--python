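"""Logistic-regression models of interface amino-acid preferences.

One model is trained per amino-acid type: the binary experimental preference
deltaW at the held-out position is predicted from the (X, Y, Z) scores via

    pW = sigmoid(x*X + y*Y + z*Z + a),    deltapW = 1  iff  pW >= t_i

with the four weights fitted by leave-one-out over the contact positions
(train on all positions except the one being predicted) and the per-type
threshold t_i chosen to maximize the Matthews correlation coefficient of the
pooled leave-one-out predictions.  Five tunable parameters per model keep the
fit honest with ~23 training rows per fold.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression, LogisticRegression

from .aminoacids import AA1

__all__ = [
    "FoldModel",
    "EvaluationSummary",
    "fit_logistic",
    "loo_train_predict",
    "optimize_thresholds",
    "predict_binary",
    "evaluate",
    "report_position",
    "rank_amino_acids",
    "rank_of_native",
    "ranking_distribution",
    "random_baseline",
    "mcc",
]

FEATURES = ("X", "Y", "Z")
_CLIP = 1e-9


@dataclass
class FoldModel:
    """Weights of one trained fold, on z-scored features."""

    coef: tuple[float, float, float]
    intercept: float
    feature_mean: tuple[float, float, float]
    feature_std: tuple[float, float, float]
    degenerate: bool = False

    def predict(self, features: np.ndarray) -> np.ndarray:
        f = np.atleast_2d(np.asarray(features, dtype=float))
        std = np.where(np.asarray(self.feature_std) > 0, self.feature_std, 1.0)
        z = (f - np.asarray(self.feature_mean)) / std
        z[:, np.asarray(self.feature_std) <= 0] = 0.0
        logit = z @ np.asarray(self.coef) + self.intercept
        return 1.0 / (1.0 + np.exp(-np.clip(logit, -500, 500)))

    def to_dict(self) -> dict:
        return asdict(self)


def fit_logistic(
    features: np.ndarray, labels: np.ndarray, l2: float = 1e-6, tol: float = 1e-8
) -> FoldModel:
    """Deterministic L2-regularized logistic fit on z-scored features.

    Degenerate folds (all labels identical) fall back to an intercept-only
    model at the clipped label mean.
    """
    f = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels, dtype=int).ravel()
    if f.shape[0] != y.shape[0]:
        raise ValueError("features and labels disagree in length")
    if f.shape[0] < 1:
        raise ValueError("at least 1 row is required")
    if not np.all(np.isfinite(f)):
        bad = np.argwhere(~np.isfinite(f))[0]
        raise ValueError(f"non-finite feature at row {bad[0]}, column {bad[1]}")
    mean = f.mean(axis=0)
    std = f.std(axis=0)
    scale = np.where(std > 0, std, 1.0)
    z = (f - mean) / scale
    z[:, std <= 0] = 0.0
    if len(np.unique(y)) < 2:
        p = float(np.clip(y.mean(), _CLIP, 1.0 - _CLIP))
        return FoldModel(coef=(0.0, 0.0, 0.0),
                         intercept=math.log(p / (1.0 - p)),
                         feature_mean=tuple(mean), feature_std=tuple(std),
                         degenerate=True)
    clf = LogisticRegression(C=1.0 / max(l2, 1e-12), tol=tol, solver="lbfgs",
                             max_iter=10_000)
    clf.fit(z, y)
    return FoldModel(coef=tuple(float(c) for c in clf.coef_[0]),
                     intercept=float(clf.intercept_[0]),
                     feature_mean=tuple(float(v) for v in mean),
                     feature_std=tuple(float(v) for v in std))


def _fit_w_regression(features: np.ndarray, w: np.ndarray) -> tuple:
    """Least-squares alternative: fit min-max-rescaled W directly."""
    lo, hi = float(np.min(w)), float(np.max(w))
    span = hi - lo if hi > lo else 1.0
    target = (np.asarray(w, dtype=float) - lo) / span
    reg = LinearRegression().fit(np.atleast_2d(features), target)
    return reg, lo, span


def loo_train_predict(
    score_table: pd.DataFrame,
    preference_table: pd.DataFrame,
    positions=None,
    objective: str = "binary",
    l2: float = 1e-6,
    tol: float = 1e-8,
) -> pd.DataFrame:
    """Leave-one-out activations pW for every (position, type).

    For each amino-acid type the model predicting position j is trained on
    the rows of all other positions for that type; the position order is
    irrelevant.  ``objective`` is ``binary`` (logistic on deltaW, default) or
    ``w_regression`` (least squares on min-max-rescaled W, clipped to [0,1]).
    """
    if objective not in ("binary", "w_regression"):
        raise ValueError(f"unknown objective {objective!r}")
    merged = score_table.merge(
        preference_table[[c for c in ("position", "aa", "W", "deltaW")
                          if c in preference_table.columns]],
        on=["position", "aa"], how="inner")
    if positions is None:
        positions = list(dict.fromkeys(merged["position"]))
    positions = [str(p) for p in positions]
    merged = merged[merged["position"].astype(str).isin(positions)]
    rows = []
    for aa in sorted(merged["aa"].unique()):
        sub = merged[merged["aa"] == aa].set_index(merged.loc[merged["aa"] == aa,
                                                              "position"].astype(str))
        missing = set(positions) - set(sub.index)
        if missing:
            raise ValueError(f"type {aa}: no rows for positions {sorted(missing)}")
        feats = sub.loc[positions, list(FEATURES)].to_numpy(float)
        labels = sub.loc[positions, "deltaW"].to_numpy(int) if "deltaW" in sub else None
        w_vals = sub.loc[positions, "W"].to_numpy(float) if "W" in sub else None
        for j, pos in enumerate(positions):
            train = [k for k in range(len(positions)) if k != j]
            if not train:
                raise ValueError("leave-one-out needs at least 2 positions")
            if objective == "binary":
                model = fit_logistic(feats[train], labels[train], l2=l2, tol=tol)
                pw = float(model.predict(feats[j:j + 1])[0])
            else:
                reg, lo, span = _fit_w_regression(feats[train], w_vals[train])
                pw = float(np.clip(reg.predict(feats[j:j + 1])[0], 0.0, 1.0))
            row = {"position": pos, "aa": aa, "pW": pw}
            for name, val in zip(FEATURES, feats[j]):
                row[name] = val
            if labels is not None:
                row["deltaW"] = int(labels[j])
            if w_vals is not None:
                row["W"] = float(w_vals[j])
            rows.append(row)
    return pd.DataFrame(rows)


def mcc(tp: int, fp: int, tn: int, fn: int) -> float:
    """Matthews correlation coefficient; 0 when the denominator vanishes."""
    denom = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / denom


def optimize_thresholds(predictions: pd.DataFrame) -> pd.DataFrame:
    """Per-type thresholds t_i maximizing the MCC of the pooled leave-one-out
    activations.

    Candidates are the midpoints of consecutive sorted unique pW values plus
    {0, 1}; ties in MCC break toward the larger threshold.  Types with only
    one label class get the degenerate default t = 0.5.
    """
    rows = []
    for aa, grp in predictions.groupby("aa", sort=True):
        pw = grp["pW"].to_numpy(float)
        labels = grp["deltaW"].to_numpy(int)
        if len(np.unique(labels)) < 2:
            rows.append({"aa": aa, "t": 0.5, "mcc": 0.0, "degenerate": True})
            continue
        uniq = np.unique(pw)
        candidates = np.concatenate([[0.0], (uniq[:-1] + uniq[1:]) / 2.0, [1.0]])
        best_t, best_mcc = 0.5, -np.inf
        for t in candidates:
            pred = (pw >= t).astype(int)
            tp = int(np.sum((pred == 1) & (labels == 1)))
            fp = int(np.sum((pred == 1) & (labels == 0)))
            tn = int(np.sum((pred == 0) & (labels == 0)))
            fn = int(np.sum((pred == 0) & (labels == 1)))
            m = mcc(tp, fp, tn, fn)
            if m > best_mcc or (m == best_mcc and t > best_t):
                best_t, best_mcc = float(t), m
        rows.append({"aa": aa, "t": best_t, "mcc": best_mcc, "degenerate": False})
    return pd.DataFrame(rows)


def predict_binary(pw, t):
    """deltapW = 1 iff pW >= t (boundary counts as positive)."""
    return (np.asarray(pw, dtype=float) >= np.asarray(t, dtype=float)).astype(int)


@dataclass
class EvaluationSummary:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n if self.n else 0.0

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else 0.0

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 0.0

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else 0.0

    @property
    def mcc(self) -> float:
        return mcc(self.tp, self.fp, self.tn, self.fn)

    def as_dict(self) -> dict:
        return {"TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn,
                "accuracy": self.accuracy, "specificity": self.specificity,
                "recall": self.recall, "precision": self.precision,
                "MCC": self.mcc}


def evaluate(predicted, observed) -> EvaluationSummary:
    """Confusion summary of binary predictions against binary labels."""
    pred = np.asarray(predicted, dtype=int).ravel()
    obs = np.asarray(observed, dtype=int).ravel()
    if pred.size == 0:
        raise ValueError("empty input")
    if pred.shape != obs.shape:
        raise ValueError("shape mismatch")
    return EvaluationSummary(
        tp=int(np.sum((pred == 1) & (obs == 1))),
        fp=int(np.sum((pred == 1) & (obs == 0))),
        tn=int(np.sum((pred == 0) & (obs == 0))),
        fn=int(np.sum((pred == 0) & (obs == 1))),
    )


def report_position(
    predictions: pd.DataFrame, thresholds: pd.DataFrame, position
) -> dict:
    """Per-position report mirroring the published comparison tables.

    ``experimental``: types with positive experimental preference, sorted by
    W descending.  ``predicted``: predicted-positive types sorted by the
    activation margin pW - t descending (ties alphabetical).  ``true_positive``
    marks the intersection.
    """
    sub = predictions[predictions["position"].astype(str) == str(position)].copy()
    if sub.empty:
        raise KeyError(f"position {position} not in predictions")
    sub = sub.merge(thresholds[["aa", "t"]], on="aa", how="left")
    sub["margin"] = sub["pW"] - sub["t"]
    exp = sub[sub["deltaW"] == 1].sort_values(["W", "aa"],
                                              ascending=[False, True])
    pred = sub[sub["pW"] >= sub["t"]].sort_values(["margin", "aa"],
                                                  ascending=[False, True])
    exp_types = list(exp["aa"])
    pred_types = list(pred["aa"])
    return {
        "position": str(position),
        "experimental": [(r.aa, float(r.W)) for r in exp.itertuples()],
        "predicted": [(r.aa, float(r.margin)) for r in pred.itertuples()],
        "true_positive": sorted(set(exp_types) & set(pred_types)),
    }


def rank_amino_acids(activations: pd.Series) -> pd.Series:
    """Ranks 1..20 by activation (pW - t) descending, ties alphabetical."""
    s = activations.reindex(sorted(activations.index))
    order = sorted(s.index, key=lambda aa: (-s[aa], aa))
    return pd.Series({aa: r + 1 for r, aa in enumerate(order)}, name="rank")


def rank_of_native(
    predictions: pd.DataFrame, thresholds: pd.DataFrame, native: dict
) -> pd.DataFrame:
    """Per-position predicted rank of the native (crystal-structure) residue."""
    merged = predictions.merge(thresholds[["aa", "t"]], on="aa", how="left")
    merged["margin"] = merged["pW"] - merged["t"]
    rows = []
    for pos, grp in merged.groupby("position", sort=False):
        key = str(pos)
        if key not in {str(k) for k in native}:
            continue
        aa_native = {str(k): v for k, v in native.items()}[key]
        ranks = rank_amino_acids(grp.set_index("aa")["margin"])
        rows.append({"position": key, "native": aa_native,
                     "rank": int(ranks[aa_native])})
    return pd.DataFrame(rows)


def ranking_distribution(ranks: pd.DataFrame, n_types: int = 20) -> pd.DataFrame:
    """Percentage of positions at each rank 1..n per interface class.

    ``ranks`` needs columns ``rank`` and ``interface_class``; the uniform
    reference is 100/n per rank.
    """
    rows = []
    for cls, grp in ranks.groupby("interface_class", sort=True):
        hist = np.zeros(n_types)
        for r in grp["rank"]:
            hist[int(r) - 1] += 1
        pct = 100.0 * hist / hist.sum()
        for r in range(n_types):
            rows.append({"interface_class": cls, "rank": r + 1,
                         "percent": pct[r]})
    return pd.DataFrame(rows)


def random_baseline(
    n_positions: int, n_types: int, mean_positives: float, k_predicted: float
) -> dict:
    """Closed-form expected metrics for a random predictor marking k of n
    types positive per position when m are truly positive.

    E[TP] = k m / n per position (hypergeometric mean); the other confusion
    cells follow, and the metrics are ratios of expectations.
    """
    n = float(n_types)
    m = float(mean_positives)
    k = float(k_predicted)
    if not (0 <= m <= n and 0 <= k <= n):
        raise ValueError("mean_positives and k_predicted must lie in [0, n_types]")
    if n_positions < 1:
        raise ValueError("n_positions must be >= 1")
    tp = k * m / n
    fp = k - tp
    fn = m - tp
    tn = n - m - k + tp
    return {
        "accuracy": (tp + tn) / n,
        "precision": tp / k if k > 0 else 0.0,
        "recall": tp / m if m > 0 else 0.0,
        "specificity": tn / (n - m) if n > m else 0.0,
    }


def save_models(path: str, thresholds: pd.DataFrame, config: dict) -> None:
    """Serialize thresholds and run configuration as JSON."""
    payload = {"thresholds": thresholds.to_dict(orient="records"),
               "config": config}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
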