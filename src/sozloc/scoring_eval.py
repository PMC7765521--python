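"""Segment classification, channel scoring and evaluation.

Two segment classifiers are supported:

* ``svm_rbf`` — an RBF-kernel support vector machine whose decision values are
  mapped to probabilities by a Platt (paired-sigmoid) calibration fit on the
  training data.
* ``gbdt`` — a LightGBM gradient-boosted decision-tree ensemble emitting
  native class probabilities (the default; 200 trees, 31 leaves, learning
  rate 0.1).

Features are standardized with statistics fit on the *original* (pre-ADASYN)
training rows and the same transform is reused for validation and test rows,
so synthetic rows never shift the scale.  Hard segment decisions use the 0.5
probability threshold.  Segment metrics (focal = positive)::

    Sen = 100 * TP / (TP + FN)        Spe = 100 * TN / (TN + FP)
    F1  = TP / (TP + 0.5 * (FP + FN))

A channel's score is the arithmetic mean of its test-segment probabilities;
channels are ranked descending.  The channel-level ROC-AUC sweeps thresholds
over the distinct channel scores and integrates sensitivity over false
positive rate with the trapezoid rule — the channel, not the segment, is the
statistical unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler

from .balancing import adasyn
from .errors import ConfigurationError

__all__ = [
    "DEFAULT_SVM_PARAMS",
    "DEFAULT_GBDT_PARAMS",
    "Scorer",
    "SegmentMetrics",
    "train_classifier",
    "train_balanced",
    "score_segments",
    "segment_metrics",
    "f1_score_binary",
    "channel_scores",
    "channel_auc",
]

DEFAULT_SVM_PARAMS: Mapping = {"C": 1.0, "gamma": "scale"}
DEFAULT_GBDT_PARAMS: Mapping = {
    "n_estimators": 200,
    "num_leaves": 31,
    "learning_rate": 0.1,
    "max_bin": 63,
    "min_child_samples": 20,
    "force_col_wise": True,
    "deterministic": True,
    "verbosity": -1,
    "n_jobs": 1,
}


@dataclass
class Scorer:
    """A fitted segment scorer: optional standardizer + probabilistic model."""

    model: object
    scaler: StandardScaler | None = None
    n_features: int = 0
    threshold: float = 0.5

    def _transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"feature layout mismatch: scorer expects {self.n_features} columns, "
                f"got {X.shape[1] if X.ndim == 2 else 'non-2D'}"
            )
        return self.scaler.transform(X) if self.scaler is not None else X

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Focal-class probability per row, in [0, 1]."""
        Xt = self._transform(X)
        # lightgbm's sklearn wrapper registers synthetic feature names even for
        # ndarray fits and then warns on every ndarray predict; feed it a frame
        # with those names to keep the round trip silent
        names = getattr(self.model, "feature_names_in_", None)
        if names is not None:
            Xt = pd.DataFrame(Xt, columns=list(names))
        return self.model.predict_proba(Xt)[:, 1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Hard 0/1 decisions at the probability threshold."""
        return (self.predict_proba(X) >= self.threshold).astype(np.int64)


def _build_model(kind: str, hyper: Mapping | None, seed: int):
    if kind in ("svm", "svm_rbf"):
        from sklearn.calibration import CalibratedClassifierCV
        from sklearn.svm import SVC

        params = dict(DEFAULT_SVM_PARAMS)
        params.update(hyper or {})
        base = SVC(kernel="rbf", random_state=seed, **params)
        # Platt paired-sigmoid calibration of the SVM decision values
        return CalibratedClassifierCV(base, method="sigmoid", cv=3, ensemble=False)
    if kind in ("gbdt", "lgbm", "lightgbm"):
        from lightgbm import LGBMClassifier

        params = dict(DEFAULT_GBDT_PARAMS)
        params.update(hyper or {})
        return LGBMClassifier(random_state=seed, **params)
    raise ConfigurationError(f"unknown classifier kind: {kind!r}")


def train_classifier(
    X: np.ndarray,
    y: np.ndarray,
    kind: str = "gbdt",
    hyper: Mapping | None = None,
    seed: int = 0,
    scaler: StandardScaler | None = None,
) -> Scorer:
    """Fit a probabilistic segment classifier on (already balanced) rows."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y).astype(np.int64).ravel()
    if np.unique(y).size < 2:
        raise ValueError("training needs both classes present")
    Xs = scaler.transform(X) if scaler is not None else X
    model = _build_model(kind, hyper, seed)
    model.fit(Xs, y)
    return Scorer(model=model, scaler=scaler, n_features=X.shape[1])


def train_balanced(
    X: np.ndarray,
    y: np.ndarray,
    kind: str = "gbdt",
    hyper: Mapping | None = None,
    seed: int = 0,
    adasyn_k: int = 5,
    adasyn_beta: float = 1.0,
    standardize: bool = True,
) -> Scorer:
    """Standardize (fit on original rows), ADASYN-balance, then train."""
    X = np.asarray(X, dtype=np.float64)
    scaler = StandardScaler().fit(X) if standardize else None
    Xs = scaler.transform(X) if scaler is not None else X
    balanced = adasyn(Xs, y, k_neighbors=adasyn_k, beta=adasyn_beta, seed=seed,
                      standardize=False)  # rows are already on a common scale
    scorer = train_classifier(balanced.X, balanced.y, kind=kind, hyper=hyper, seed=seed)
    scorer.scaler = scaler
    scorer.n_features = X.shape[1]
    return scorer


def score_segments(
    scorer: Scorer,
    X: np.ndarray,
    channels: Sequence[str],
    indices: Sequence[int],
    labels: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Score every test segment; one row per (channel, segment_index)."""
    proba = scorer.predict_proba(X)
    frame = pd.DataFrame(
        {"channel": list(channels), "segment_index": list(indices), "score": proba}
    )
    if labels is not None:
        frame["label"] = np.asarray(labels).astype(np.int64)
    return frame


@dataclass(frozen=True)
class SegmentMetrics:
    """Confusion counts and the derived segment-level metrics.

    ``sensitivity``/``specificity`` are percentages; each is None when its
    denominator is empty (no positive / no negative segments).
    """

    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: float | None = field(init=False)
    specificity: float | None = field(init=False)
    f1: float | None = field(init=False)

    def __post_init__(self) -> None:
        pos, neg = self.tp + self.fn, self.tn + self.fp
        object.__setattr__(self, "sensitivity", 100.0 * self.tp / pos if pos else None)
        object.__setattr__(self, "specificity", 100.0 * self.tn / neg if neg else None)
        denom = self.tp + 0.5 * (self.fp + self.fn)
        object.__setattr__(self, "f1", self.tp / denom if denom > 0 else None)

    def to_dict(self) -> dict:
        return {
            "TP": self.tp, "FN": self.fn, "TN": self.tn, "FP": self.fp,
            "sensitivity_percent": self.sensitivity,
            "specificity_percent": self.specificity,
            "f1": self.f1,
        }


def segment_metrics(predictions, labels) -> SegmentMetrics:
    """Confusion counts with focal (SOZ-channel) segments as the positive class."""
    pred = np.asarray(predictions).astype(np.int64).ravel()
    lab = np.asarray(labels).astype(np.int64).ravel()
    if pred.shape != lab.shape:
        raise ValueError("predictions and labels must be aligned")
    tp = int(((pred == 1) & (lab == 1)).sum())
    fn = int(((pred == 0) & (lab == 1)).sum())
    tn = int(((pred == 0) & (lab == 0)).sum())
    fp = int(((pred == 1) & (lab == 0)).sum())
    return SegmentMetrics(tp, fn, tn, fp)


def f1_score_binary(predictions, labels) -> float | None:
    """F1 = TP / (TP + 0.5 (FP + FN)); None when the denominator is zero."""
    return segment_metrics(predictions, labels).f1


def channel_scores(segment_score_table: pd.DataFrame) -> pd.DataFrame:
    """Average each channel's segment scores; rank 1 = highest mean score.

    Input needs columns ``channel``, ``score`` and (optionally) ``label``.
    Channels without any test segment simply do not appear.
    """
    cols = {"channel", "score"}
    if not cols.issubset(segment_score_table.columns):
        raise ValueError(f"segment score table needs columns {sorted(cols)}")
    agg: dict = {"mean_score": ("score", "mean")}
    if "label" in segment_score_table.columns:
        agg["label"] = ("label", "first")
    table = segment_score_table.groupby("channel", sort=False).agg(**agg).reset_index()
    order = np.argsort(-table["mean_score"].to_numpy(), kind="stable")
    ranks = np.empty(len(table), dtype=np.int64)
    ranks[order] = np.arange(1, len(table) + 1)
    table["rank"] = ranks
    return table


def channel_auc(table: pd.DataFrame) -> float:
    """Channel-level ROC-AUC by explicit threshold sweep + trapezoid rule.

    ``table`` needs ``mean_score`` and binary ``label`` columns with both
    classes present.  Sensitivity and FPR are computed at every distinct score
    (prediction: score >= threshold) plus sentinels at (0,0) and (1,1); tied
    scores produce a diagonal ROC segment, so ties count one half.
    """
    scores = np.asarray(table["mean_score"], dtype=np.float64)
    labels = np.asarray(table["label"]).astype(np.int64)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ConfigurationError("channel AUC needs both SOZ and non-SOZ channels")
    sen = [0.0]
    fpr = [0.0]
    for thr in np.sort(np.unique(scores))[::-1]:
        pred = scores >= thr
        sen.append(float((pred & (labels == 1)).sum()) / n_pos)
        fpr.append(float((pred & (labels == 0)).sum()) / n_neg)
    return float(np.trapezoid(sen, fpr))
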