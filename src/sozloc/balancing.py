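"""Adaptive synthetic (ADASYN) oversampling of the minority (focal) class.

Focal (SOZ-channel) segments are the minority in any clinical montage.  ADASYN
generates synthetic minority rows along segments between a minority row and one
of its minority neighbors, allocating more synthetics to minority rows whose
neighborhoods are dominated by the majority class (the "hard" rows):

1. ``G = beta * (J_in - I_in)`` synthetics in total (majority minus minority
   count; ``beta = 1`` balances exactly).
2. For each minority row, the fraction of majority points among its k nearest
   neighbors (Euclidean, over all rows) gives its density ratio; ratios are
   normalized and multiplied by G, with a largest-remainder rounding so the
   total is exactly G (hence ``I_in + Ĩ_in = J_in`` holds exactly at beta=1).
3. Each synthetic row is ``x_i + u * (x_z - x_i)`` with u ~ U[0, 1] and x_z a
   random one of the row's k nearest *minority* neighbors.

Neighbor distances are computed on standardized copies by default because
subband features differ in scale by orders of magnitude; synthetic rows are
interpolated in the original feature space (the convex combination is the same
in either space).  All randomness is governed by the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .errors import BalancingError

__all__ = ["BalancedTrainingSet", "adasyn"]


@dataclass(frozen=True)
class BalancedTrainingSet:
    """Original rows plus synthetic minority rows.

    ``X``/``y`` hold the full balanced set: original rows first (input order
    preserved), synthetic rows appended.  ``n_original``/``n_synthetic`` give
    the split point; ``minority_label`` is the oversampled class.
    """

    X: np.ndarray
    y: np.ndarray
    n_original: int
    n_synthetic: int
    minority_label: int

    @property
    def class_counts(self) -> dict[int, int]:
        values, counts = np.unique(self.y, return_counts=True)
        return {int(v): int(c) for v, c in zip(values, counts)}


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights`` (sums exactly)."""
    raw = weights * total
    base = np.floor(raw).astype(np.int64)
    short = total - int(base.sum())
    if short > 0:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:short]] += 1
    return base


def adasyn(
    features: np.ndarray,
    labels: np.ndarray,
    k_neighbors: int = 5,
    beta: float = 1.0,
    seed: int = 0,
    standardize: bool = True,
) -> BalancedTrainingSet:
    """Oversample the minority class; deterministic under a fixed seed.

    Raises :class:`BalancingError` when fewer than two minority rows exist.
    Already-balanced input is returned unchanged.  ``k_neighbors`` is reduced
    (with a warning) when it reaches the sample count.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels).astype(np.int64).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("features must be (n_rows, n_cols) aligned with labels")
    if not 0 < beta <= 1:
        raise ValueError(f"beta must be in (0, 1], got {beta}")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise BalancingError(f"need exactly two classes, got {classes.size}")
    minority = int(classes[np.argmin(counts)])
    i_in, j_in = int(counts.min()), int(counts.max())
    if i_in == j_in:
        return BalancedTrainingSet(X, y, X.shape[0], 0, minority)
    if i_in < 2:
        raise BalancingError(f"minority class has {i_in} row(s); ADASYN needs at least 2")

    k = k_neighbors
    if k >= X.shape[0]:
        k = X.shape[0] - 1
        warnings.warn(
            f"k_neighbors={k_neighbors} >= sample count {X.shape[0]}; reduced to {k}",
            stacklevel=2,
        )

    Z = X
    if standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        Z = (X - mu) / sd

    min_mask = y == minority
    Z_min = Z[min_mask]
    X_min = X[min_mask]

    G = int(round(beta * (j_in - i_in)))
    rng = np.random.default_rng(seed)

    # density ratio: majority fraction among each minority row's k-NN (all rows)
    nn_all = NearestNeighbors(n_neighbors=k + 1).fit(Z)
    idx = nn_all.kneighbors(Z_min, return_distance=False)[:, 1:]  # drop self
    ratios = (y[idx] != minority).mean(axis=1)
    if ratios.sum() == 0.0:
        ratios = np.ones_like(ratios)  # isolated minority cluster: uniform allocation
    weights = ratios / ratios.sum()
    alloc = _largest_remainder(weights, G)

    # minority-only neighbors used for interpolation
    k_min = min(k, i_in - 1)
    nn_min = NearestNeighbors(n_neighbors=k_min + 1).fit(Z_min)
    nbr = nn_min.kneighbors(Z_min, return_distance=False)[:, 1:]

    synth = np.empty((G, X.shape[1]))
    pos = 0
    for i in range(i_in):
        g = int(alloc[i])
        if g == 0:
            continue
        z = nbr[i, rng.integers(0, k_min, size=g)]
        u = rng.random((g, 1))
        synth[pos : pos + g] = X_min[i] + u * (X_min[z] - X_min[i])
        pos += g

    Xb = np.vstack([X, synth])
    yb = np.concatenate([y, np.full(G, minority, dtype=np.int64)])
    return BalancedTrainingSet(Xb, yb, X.shape[0], G, minority)
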