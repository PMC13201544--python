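"""Independent oracles and small utilities shared by the test suite."""

from __future__ import annotations

import math

import numpy as np


def naive_global_moran(L, R, W):
    """Double-loop bivariate global Moran R (reference implementation)."""
    L = np.asarray(L, float)
    R = np.asarray(R, float)
    a, b = L - L.mean(), R - R.mean()
    M = len(L)
    num = 0.0
    for k in range(M):
        for s in range(M):
            num += W[k, s] * a[k] * b[s]
    return num / math.sqrt((a**2).sum() * (b**2).sum())


def naive_local_moran(L, R, W):
    """Double-loop sender/receiver decomposition (population sigma)."""
    L = np.asarray(L, float)
    R = np.asarray(R, float)
    M = len(L)
    a, b = L - L.mean(), R - R.mean()
    sig = math.sqrt((a**2).mean()) * math.sqrt((b**2).mean())
    sender = np.zeros(M)
    receiver = np.zeros(M)
    for k in range(M):
        sender[k] = a[k] / sig * sum(W[k, s] * b[s] for s in range(M))
        receiver[k] = b[k] / sig * sum(W[k, s] * a[s] for s in range(M))
    return sender, receiver


def hypergeom_upper_tail(a, N, K, n):
    """Exact upper-tail hypergeometric probability via binomial coefficients."""
    denom = math.comb(N, n)
    total = 0
    for j in range(a, min(K, n) + 1):
        if n - j <= N - K:
            total += math.comb(K, j) * math.comb(N - K, n - j)
    return total / denom


def top1_retrieval_rate(model, feats, Y, spot_idx, l):
    """Fraction of held-out spots whose image projection ranks its own
    expression projection first among the candidate panel."""
    from spotfuse.model import _tile_rows

    Hi = model.project(features=feats[_tile_rows(spot_idx, l)])
    He = model.project(Y=Y[spot_idx])
    S = Hi @ He.T
    return float((S.argmax(axis=1) == np.arange(len(spot_idx))).mean())


def binom_sf(k, n, p):
    """P[X > k] for X ~ Binomial(n, p) (one-sided, exact)."""
    from scipy import stats

    return float(stats.binom.sf(k, n, p))
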