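"""The twelve per-subband segment features.

For one bandpassed segment ``x = (x_1, ..., x_L)`` the feature vector is, in
fixed column order::

    [CV, FI, Var, RMS, DASD, MAV, MMAV, MMAV2, LD, PE, ShE, RE]

Nine amplitude statistics and three entropies:

* **CV** — coefficient of variation sigma/mu, with the *population* standard
  deviation (divisor L).  Defined as 0 (with a warning) when the mean is 0.
* **FI** — fluctuation index, mean absolute first difference (divisor L-1).
* **Var** — *sample* variance (divisor L-1).  The divisor differs from CV's
  sigma deliberately; both follow their printed definitions.
* **RMS** — root mean square.
* **DASD** — difference absolute standard deviation,
  sqrt(sum (x_{i+1}-x_i)^2 / (L-1)).
* **MAV** — mean absolute value.
* **MMAV** — MAV with window weight 1 on the middle half of the segment
  (0.25 L <= i <= 0.75 L, 1-based, real-valued thresholds) and 0.5 elsewhere.
* **MMAV2** — MAV with weight 1 on the middle half, ``4 i / L`` below it and
  ``4 (i - L) / L`` above it.  The upper ramp is kept as printed even though it
  is non-positive; set ``mmav2_abs_weights`` for the conventional
  ``4 (L - i) / L``.
* **LD** — log detector, exp(mean log |x_i|) with a floor epsilon inside the
  log because bandpassed iEEG always contains non-positive samples.
* **PE** — permutation entropy of the ordinal patterns of lagged embedding
  vectors (m = 3, tau = 1 by default), in bits.  Ties are broken by temporal
  order (stable sort), so a constant signal has a single pattern and PE = 0.
* **ShE / RE** — Shannon and order-gamma Rényi entropy (gamma = 2) of the
  normalized one-sided power spectrum (unwindowed DFT, DC bin included),
  in nats.  Zero total power maps both to 0 with a warning.

Scalar functions operate on one vector and are the reference implementation;
:func:`feature_matrix` computes all twelve features for a batch of segments
through a fused numba kernel and matches the scalar path to ~1e-9 relative.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import numba

from .errors import ConfigurationError

__all__ = [
    "FEATURE_NAMES",
    "PEConfig",
    "SpectralConfig",
    "FeatureConfig",
    "cv",
    "fi",
    "var",
    "rms",
    "dasd",
    "mav",
    "mmav",
    "mmav2",
    "ld",
    "permutation_entropy",
    "spectral_entropies",
    "feature_vector",
    "feature_matrix",
]

#: public column order of the feature vector; stable output contract
FEATURE_NAMES = ("CV", "FI", "Var", "RMS", "DASD", "MAV", "MMAV", "MMAV2", "LD", "PE", "ShE", "RE")


@dataclass(frozen=True)
class PEConfig:
    """Permutation-entropy embedding: dimension ``m`` and time lag ``tau``."""

    m: int = 3
    tau: int = 1

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ConfigurationError(f"embedding dimension m must be >= 2, got {self.m}")
        if self.tau < 1:
            raise ConfigurationError(f"time lag tau must be >= 1, got {self.tau}")


@dataclass(frozen=True)
class SpectralConfig:
    """Spectral-entropy options: Rényi order ``gamma`` and DC-bin inclusion."""

    gamma: float = 2.0
    dc_included: bool = True

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.gamma == 1.0:
            raise ConfigurationError(f"Rényi order must be positive and != 1, got {self.gamma}")


@dataclass(frozen=True)
class FeatureConfig:
    """All feature parameters in one place."""

    pe: PEConfig = field(default_factory=PEConfig)
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    ld_epsilon: float = 1e-12
    mmav2_abs_weights: bool = False


def _vec(x) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("expected a non-empty 1-D vector")
    return x


def cv(x) -> float:
    """Coefficient of variation sigma/mu with population sigma (divisor L)."""
    x = _vec(x)
    mu = x.mean()
    if mu == 0.0:
        warnings.warn("CV undefined for zero-mean signal; returning 0", stacklevel=2)
        return 0.0
    sigma = math.sqrt(np.square(x - mu).mean())
    return sigma / mu


def fi(x) -> float:
    """Fluctuation index: mean absolute first difference (divisor L-1)."""
    x = _vec(x)
    if x.size < 2:
        raise ValueError("FI needs at least 2 samples")
    return float(np.abs(np.diff(x)).sum() / (x.size - 1))


def var(x) -> float:
    """Sample variance (divisor L-1)."""
    x = _vec(x)
    if x.size < 2:
        raise ValueError("Var needs at least 2 samples")
    return float(np.square(x - x.mean()).sum() / (x.size - 1))


def rms(x) -> float:
    """Root mean square."""
    x = _vec(x)
    return math.sqrt(np.square(x).mean())


def dasd(x) -> float:
    """Difference absolute standard deviation: sqrt(mean squared first

    difference, divisor L-1)."""
    x = _vec(x)
    if x.size < 2:
        raise ValueError("DASD needs at least 2 samples")
    return math.sqrt(np.square(np.diff(x)).sum() / (x.size - 1))


def mav(x) -> float:
    """Mean absolute value."""
    x = _vec(x)
    return float(np.abs(x).mean())


def _mmav_weights(L: int) -> np.ndarray:
    i = np.arange(1, L + 1, dtype=np.float64)
    return np.where((i >= 0.25 * L) & (i <= 0.75 * L), 1.0, 0.5)


def _mmav2_weights(L: int, abs_weights: bool) -> np.ndarray:
    i = np.arange(1, L + 1, dtype=np.float64)
    mid = (i >= 0.25 * L) & (i <= 0.75 * L)
    low = i < 0.25 * L
    upper = (L - i) if abs_weights else (i - L)
    return np.where(mid, 1.0, np.where(low, 4.0 * i / L, 4.0 * upper / L))


def mmav(x) -> float:
    """Modified MAV: weight 1 on the middle half (1-based 0.25L..0.75L), 0.5

    elsewhere."""
    x = _vec(x)
    return float((_mmav_weights(x.size) * np.abs(x)).mean())


def mmav2(x, abs_weights: bool = False) -> float:
    """Modified MAV 2: ramped window weights (kept as printed; see module

    docstring for the ``abs_weights`` variant)."""
    x = _vec(x)
    return float((_mmav2_weights(x.size, abs_weights) * np.abs(x)).mean())


def ld(x, epsilon: float = 1e-12) -> float:
    """Log detector: exp(mean log(|x_i| + epsilon)), the geometric mean of

    magnitudes with a floor for zeros."""
    x = _vec(x)
    return math.exp(np.log(np.abs(x) + epsilon).mean())


def permutation_entropy(x, cfg: PEConfig | None = None) -> float:
    """Permutation entropy in bits over the m! ordinal patterns of lagged

    embedding vectors; ties broken by temporal order."""
    cfg = cfg or PEConfig()
    x = _vec(x)
    n_vec = x.size - (cfg.m - 1) * cfg.tau
    if n_vec < 2:
        raise ValueError(
            f"PE needs at least (m-1)*tau + 2 = {(cfg.m - 1) * cfg.tau + 2} samples, got {x.size}"
        )
    idx = np.arange(n_vec)[:, None] + np.arange(cfg.m)[None, :] * cfg.tau
    emb = x[idx]
    # stable argsort == sort by (value, temporal position)
    perm = np.argsort(emb, axis=1, kind="stable")
    codes = perm @ (cfg.m ** np.arange(cfg.m))
    counts = np.unique(codes, return_counts=True)[1]
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def power_spectrum(x, dc_included: bool = True) -> np.ndarray:
    """One-sided magnitude-squared DFT of the unwindowed segment."""
    x = _vec(x)
    P = np.abs(np.fft.rfft(x)) ** 2
    return P if dc_included else P[1:]


def spectral_entropies(x, cfg: SpectralConfig | None = None) -> tuple[float, float]:
    """Shannon and order-gamma Rényi entropy (nats) of the normalized

    one-sided power spectrum.  Returns (ShE, RE)."""
    cfg = cfg or SpectralConfig()
    P = power_spectrum(x, cfg.dc_included)
    total = P.sum()
    if total == 0.0:
        warnings.warn("zero total power; spectral entropies set to 0", stacklevel=2)
        return 0.0, 0.0
    p = P / total
    nz = p[p > 0]
    she = float(-(nz * np.log(nz)).sum())
    re = float(np.log((nz**cfg.gamma).sum()) / (1.0 - cfg.gamma))
    return she, re


def feature_vector(x, cfg: FeatureConfig | None = None) -> np.ndarray:
    """All twelve features of one subband segment, in ``FEATURE_NAMES`` order."""
    cfg = cfg or FeatureConfig()
    she, re = spectral_entropies(x, cfg.spectral)
    return np.array(
        [
            cv(x),
            fi(x),
            var(x),
            rms(x),
            dasd(x),
            mav(x),
            mmav(x),
            mmav2(x, cfg.mmav2_abs_weights),
            ld(x, cfg.ld_epsilon),
            permutation_entropy(x, cfg.pe),
            she,
            re,
        ]
    )


# --------------------------------------------------------------------------
# Vectorized batch path (used by the pipeline on (n_segments, L) blocks)
# --------------------------------------------------------------------------

_LOG2 = math.log(2.0)


@numba.njit(cache=True)
def _time_domain_kernel(Y, eps, mmav2_abs):  # pragma: no cover - exercised via feature_matrix
    """Single pass over each row: CV, FI, Var, RMS, DASD, MAV, MMAV, MMAV2,

    LD and the m=3, tau=1 permutation-entropy pattern census."""
    n_seg, L = Y.shape
    out = np.zeros((n_seg, 10))
    lo = 0.25 * L
    hi = 0.75 * L
    for s in range(n_seg):
        ssum = 0.0
        for i in range(L):
            ssum += Y[s, i]
        mu = ssum / L
        sdev = 0.0
        ssq = 0.0
        sabs = 0.0
        sad = 0.0
        sdsq = 0.0
        smm = 0.0
        smm2 = 0.0
        slog = 0.0
        c = np.zeros(8, dtype=np.int64)
        for i in range(L):
            x = Y[s, i]
            d0 = x - mu
            sdev += d0 * d0
            ssq += x * x
            ax = abs(x)
            sabs += ax
            ii = i + 1.0
            if lo <= ii <= hi:
                w1 = 1.0
                w2 = 1.0
            elif ii < lo:
                w1 = 0.5
                w2 = 4.0 * ii / L
            else:
                w1 = 0.5
                w2 = 4.0 * (L - ii) / L if mmav2_abs else 4.0 * (ii - L) / L
            smm += w1 * ax
            smm2 += w2 * ax
            slog += math.log(ax + eps)
            if i + 1 < L:
                d = Y[s, i + 1] - x
                sad += abs(d)
                sdsq += d * d
            if i + 2 < L:
                a = x
                b = Y[s, i + 1]
                cc = Y[s, i + 2]
                code = 0
                if b < a:
                    code += 4
                if cc < b:
                    code += 2
                if cc < a:
                    code += 1
                c[code] += 1
        sig = math.sqrt(sdev / L)
        out[s, 0] = sig / mu if mu != 0.0 else 0.0
        out[s, 1] = sad / (L - 1)
        out[s, 2] = sdev / (L - 1)
        out[s, 3] = math.sqrt(ssq / L)
        out[s, 4] = math.sqrt(sdsq / (L - 1))
        out[s, 5] = sabs / L
        out[s, 6] = smm / L
        out[s, 7] = smm2 / L
        out[s, 8] = math.exp(slog / L)
        tot = 0.0
        for j in range(8):
            tot += c[j]
        pe = 0.0
        for j in range(8):
            if c[j] > 0:
                p = c[j] / tot
                pe -= p * math.log(p) / _LOG2
        out[s, 9] = pe
    return out


@numba.njit(cache=True)
def _spectral_kernel(P, gamma):  # pragma: no cover - exercised via feature_matrix
    """Shannon and Rényi entropy per row of a power-spectrum matrix."""
    n_seg, n_bin = P.shape
    out = np.zeros((n_seg, 2))
    for s in range(n_seg):
        tot = 0.0
        for k in range(n_bin):
            tot += P[s, k]
        if tot == 0.0:
            continue
        she = 0.0
        sg = 0.0
        for k in range(n_bin):
            p = P[s, k] / tot
            if p > 0.0:
                she -= p * math.log(p)
                sg += p**gamma
        out[s, 0] = she
        out[s, 1] = math.log(sg) / (1.0 - gamma)
    return out


def feature_matrix(Y: np.ndarray, cfg: FeatureConfig | None = None) -> np.ndarray:
    """Compute the 12 features for every row of ``Y`` (n_segments, L).

    Equivalent to stacking :func:`feature_vector` over rows, but in a fused
    kernel; the pipeline calls this once per (channel, subband) block.
    """
    cfg = cfg or FeatureConfig()
    Y = np.ascontiguousarray(Y, dtype=np.float64)
    if Y.ndim != 2 or Y.shape[1] < (cfg.pe.m - 1) * cfg.pe.tau + 2:
        raise ValueError("Y must be (n_segments, L) with L >= (m-1)*tau + 2")
    td = _time_domain_kernel(Y, cfg.ld_epsilon, cfg.mmav2_abs_weights)
    if not (cfg.pe.m == 3 and cfg.pe.tau == 1):
        # generic (slower) permutation-entropy path
        pe_cfg = cfg.pe
        td[:, 9] = [permutation_entropy(row, pe_cfg) for row in Y]
    F = np.fft.rfft(Y, axis=1)
    P = F.real**2 + F.imag**2
    if not cfg.spectral.dc_included:
        P = P[:, 1:]
    zero_rows = P.sum(axis=1) == 0.0
    if zero_rows.any():
        warnings.warn(
            f"{int(zero_rows.sum())} segments with zero total power; spectral entropies set to 0",
            stacklevel=2,
        )
    spec = _spectral_kernel(P, cfg.spectral.gamma)
    return np.concatenate([td, spec], axis=1)
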