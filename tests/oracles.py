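"""Independent, literal loop-based reference implementations used as oracles.

Everything here is written as plainly as possible (explicit Python loops,
explicit DFT sums) and deliberately shares no code with the package.
"""

from __future__ import annotations

import cmath
import math


def oracle_cv(x):
    L = len(x)
    mu = sum(x) / L
    sigma = math.sqrt(sum((xi - mu) ** 2 for xi in x) / L)
    return 0.0 if mu == 0 else sigma / mu


def oracle_fi(x):
    L = len(x)
    return sum(abs(x[i + 1] - x[i]) for i in range(L - 1)) / (L - 1)


def oracle_var(x):
    L = len(x)
    mu = sum(x) / L
    return sum((xi - mu) ** 2 for xi in x) / (L - 1)


def oracle_rms(x):
    L = len(x)
    return math.sqrt(sum(xi**2 for xi in x) / L)


def oracle_dasd(x):
    L = len(x)
    return math.sqrt(sum((x[i + 1] - x[i]) ** 2 for i in range(L - 1)) / (L - 1))


def oracle_mav(x):
    return sum(abs(xi) for xi in x) / len(x)


def oracle_mmav(x):
    L = len(x)
    total = 0.0
    for i in range(1, L + 1):
        w = 1.0 if 0.25 * L <= i <= 0.75 * L else 0.5
        total += w * abs(x[i - 1])
    return total / L


def oracle_mmav2(x, abs_weights=False):
    L = len(x)
    total = 0.0
    for i in range(1, L + 1):
        if 0.25 * L <= i <= 0.75 * L:
            w = 1.0
        elif i < 0.25 * L:
            w = 4.0 * i / L
        else:
            w = 4.0 * (L - i) / L if abs_weights else 4.0 * (i - L) / L
        total += w * abs(x[i - 1])
    return total / L


def oracle_ld(x, eps=1e-12):
    L = len(x)
    return math.exp(sum(math.log(abs(xi) + eps) for xi in x) / L)


def oracle_pe(x, m=3, tau=1):
    """Pattern census with ties broken by temporal order."""
    counts: dict = {}
    n_vec = len(x) - (m - 1) * tau
    for i in range(n_vec):
        vec = [x[i + k * tau] for k in range(m)]
        pattern = tuple(sorted(range(m), key=lambda k: (vec[k], k)))
        counts[pattern] = counts.get(pattern, 0) + 1
    total = sum(counts.values())
    return -sum((c / total) * math.log2(c / total) for c in counts.values())


def oracle_spectral(x, gamma=2.0):
    """Explicit one-sided DFT power spectrum -> (Shannon, Rényi) in nats."""
    L = len(x)
    n_bins = L // 2 + 1
    P = []
    for k in range(n_bins):
        X = sum(x[i] * cmath.exp(-2j * math.pi * k * i / L) for i in range(L))
        P.append(abs(X) ** 2)
    total = sum(P)
    if total == 0:
        return 0.0, 0.0
    p = [v / total for v in P]
    she = -sum(v * math.log(v) for v in p if v > 0)
    re = math.log(sum(v**gamma for v in p if v > 0)) / (1.0 - gamma)
    return she, re


def oracle_mannwhitney_auc(pos_scores, neg_scores):
    """Pair-counting AUC: P(pos > neg) + 0.5 P(pos == neg)."""
    wins = 0.0
    for p in pos_scores:
        for n in neg_scores:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos_scores) * len(neg_scores))
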