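"""Mutual-information scoring of subbands and features, and the joint

(J, K) grid search.

Training features are organised as a tensor ``(H, N, D)`` where ``H`` stacks
all training segments of all channels, ``N`` is the subband count and ``D``
the feature count.  For every (subband, feature) column the mutual information
with the binary segment label is estimated by the bin method: the feature is
discretized into equal-width bins over its observed training range and

    MI = sum_{b,c} p(b, c) * ln[ p(b, c) / (p(b) p(c)) ]

in natural log, clipped at zero.  Subbands are ranked by the mean MI over
features, features by the mean MI over subbands (both descending, stable
ties).  The grid search then evaluates, for every (j, k), a classifier trained
on the top-j subbands x top-k features (class-balanced first) and picks the
(J, K) with the best validation F1; ties prefer the smallest K, then the
smallest J (parsimony).

The selected feature layout is subband-major: the columns of the final matrix
are ``[band lambda(1) features I(1..K), band lambda(2) features I(1..K), ...]``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .errors import ConfigurationError
from .scoring_eval import f1_score_binary

logger = logging.getLogger(__name__)

__all__ = [
    "MIScores",
    "SelectionResult",
    "mi_score",
    "mi_score_matrix",
    "rank_subbands",
    "rank_features",
    "build_feature_matrix",
    "grid_search",
]

DEFAULT_MI_BINS = 10


@dataclass(frozen=True)
class MIScores:
    """MI score per (subband, feature): array of shape (N, D), all >= 0."""

    scores: np.ndarray

    @property
    def n_subbands(self) -> int:
        return self.scores.shape[0]

    @property
    def n_features(self) -> int:
        return self.scores.shape[1]


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of ranking + grid search.

    ``lambda_order`` / ``i_order`` are 0-based subband / feature indices in
    descending mean-MI order; ``J`` / ``K`` are the chosen counts;
    ``f1_grid[j-1, k-1]`` holds the validation F1 of each grid cell (None when
    the search was skipped).
    """

    mi: MIScores
    lambda_order: np.ndarray
    i_order: np.ndarray
    J: int
    K: int
    f1_grid: np.ndarray | None

    def to_dict(self) -> dict:
        return {
            "lambda_order": [int(i) + 1 for i in self.lambda_order],
            "i_order": [int(i) + 1 for i in self.i_order],
            "J": int(self.J),
            "K": int(self.K),
            "mi_scores": self.mi.scores.tolist(),
            "f1_grid": None if self.f1_grid is None else self.f1_grid.tolist(),
        }


def mi_score(feature_column, labels, n_bins: int = DEFAULT_MI_BINS) -> float:
    """Binned mutual information (nats) between one feature and the labels."""
    x = np.asarray(feature_column, dtype=np.float64)
    y = np.asarray(labels)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("feature column and labels must be 1-D and aligned")
    classes = np.unique(y)
    if classes.size < 2:
        raise ConfigurationError("MI needs both classes present")
    lo, hi = x.min(), x.max()
    if lo == hi:
        return 0.0  # constant feature carries no information
    # equal-width bins over the observed range; right edge inclusive
    bins = np.clip(((x - lo) * (n_bins / (hi - lo))).astype(np.int64), 0, n_bins - 1)
    H = x.size
    mi = 0.0
    p_bin = np.bincount(bins, minlength=n_bins) / H
    for c in classes:
        mask = y == c
        p_c = mask.mean()
        joint = np.bincount(bins[mask], minlength=n_bins) / H
        nz = joint > 0
        mi += float((joint[nz] * np.log(joint[nz] / (p_bin[nz] * p_c))).sum())
    return max(mi, 0.0)


def mi_score_matrix(tensor: np.ndarray, labels, n_bins: int = DEFAULT_MI_BINS) -> MIScores:
    """MI of every (subband, feature) column of an (H, N, D) training tensor."""
    H, N, D = tensor.shape
    scores = np.empty((N, D))
    for n in range(N):
        for d in range(D):
            scores[n, d] = mi_score(tensor[:, n, d], labels, n_bins)
    return MIScores(scores)


def _descending_stable(means: np.ndarray) -> np.ndarray:
    # stable sort on negated values keeps original order among ties
    return np.argsort(-means, kind="stable")


def rank_subbands(scores: MIScores) -> tuple[np.ndarray, np.ndarray]:
    """Mean MI per subband, sorted descending.  Returns (order, sorted means)."""
    means = scores.scores.mean(axis=1)
    order = _descending_stable(means)
    return order, means[order]


def rank_features(scores: MIScores) -> tuple[np.ndarray, np.ndarray]:
    """Mean MI per feature, sorted descending.  Returns (order, sorted means)."""
    means = scores.scores.mean(axis=0)
    order = _descending_stable(means)
    return order, means[order]


def build_feature_matrix(
    tensor: np.ndarray,
    lambda_order: Sequence[int],
    i_order: Sequence[int],
    j: int,
    k: int,
) -> np.ndarray:
    """Select top-j subbands x top-k features and flatten subband-major."""
    bands = np.asarray(lambda_order[:j])
    feats = np.asarray(i_order[:k])
    sub = tensor[:, bands][:, :, feats]  # (H, j, k)
    return sub.reshape(tensor.shape[0], j * k)


def grid_search(
    train_tensor: np.ndarray,
    train_labels: np.ndarray,
    val_tensor: np.ndarray,
    val_labels: np.ndarray,
    lambda_order: np.ndarray,
    i_order: np.ndarray,
    trainer: Callable[[np.ndarray, np.ndarray], object],
    mi: MIScores,
) -> SelectionResult:
    """Exhaustive search over (j, k) in {1..N} x {1..D} maximizing validation F1.

    ``trainer(X, y)`` must return a fitted scorer with a ``predict`` method
    producing hard 0/1 segment decisions (the trainer owns standardization and
    class balancing, re-run per cell on that cell's feature subset).  A cell
    where training fails scores 0 and is logged.  Ties prefer smallest K, then
    smallest J.
    """
    if np.unique(val_labels).size < 2:
        raise ConfigurationError("grid search needs both classes in the validation set")
    N, D = len(lambda_order), len(i_order)
    grid = np.zeros((N, D))
    best = (-1.0, None)
    for k in range(1, D + 1):
        for j in range(1, N + 1):
            Xtr = build_feature_matrix(train_tensor, lambda_order, i_order, j, k)
            Xva = build_feature_matrix(val_tensor, lambda_order, i_order, j, k)
            try:
                scorer = trainer(Xtr, train_labels)
                pred = scorer.predict(Xva)
                f1 = f1_score_binary(pred, val_labels)
                f1 = 0.0 if f1 is None else f1
            except Exception:  # noqa: BLE001 - a failing cell must not kill the search
                logger.warning("grid cell (j=%d, k=%d) failed; scored 0", j, k, exc_info=True)
                warnings.warn(f"grid cell (j={j}, k={k}) failed; scored 0", stacklevel=2)
                f1 = 0.0
            grid[j - 1, k - 1] = f1
            # iteration order (k outer, j inner) + strict '>' implements the
            # smallest-K-then-smallest-J tie rule
            if f1 > best[0]:
                best = (f1, (j, k))
    J, K = best[1]
    return SelectionResult(mi, np.asarray(lambda_order), np.asarray(i_order), J, K, grid)
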