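"""Bivariate Moran statistics for ligand-receptor spatial co-expression.

For each candidate pair the global statistic

.. math::

    R = \\frac{\\sum_k \\sum_s w_{ks} (L_k - \\bar L)(R_s - \\bar R)}
         {\\sqrt{\\sum_k (L_k-\\bar L)^2}\\,\\sqrt{\\sum_s (R_s-\\bar R)^2}}

measures whether high ligand values neighbor high receptor values. Its
one-sided significance uses analytic moments of the null in which both
fields are independently permuted across locations (a permutation fallback
is kept as an oracle). The local decomposition splits R into per-location
sender and receiver terms whose sum over locations equals ``2 M R`` under
the population standard-deviation convention. Pair selection applies
Benjamini-Hochberg FDR across all tested pairs plus a sparse-interaction
filter on the number of locally significant locations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class SpatialWeights:
    """Sparse non-negative neighborhood weights with zero diagonal."""

    W: sparse.csr_matrix
    lengthscale: float
    cutoff: int
    row_normalized: bool = False

    @property
    def M(self) -> int:
        return self.W.shape[0]


def build_weights(
    coords: np.ndarray,
    lengthscale: float | str = "auto",
    cutoff: int = 6,
    row_normalize: bool = False,
) -> SpatialWeights:
    """Gaussian-kernel weights truncated to each location's nearest neighbors.

    ``w_ks = exp(-d_ks^2 / (2 l^2))`` kept for the ``cutoff`` nearest
    neighbors of each location, symmetrized by the elementwise maximum, with
    zero diagonal. ``lengthscale='auto'`` uses 1.2x the median
    nearest-neighbor distance.
    """
    coords = np.asarray(coords, dtype=float)
    M = coords.shape[0]
    if M < 2:
        raise ValueError("need at least 2 locations")
    k = min(cutoff + 1, M)
    nn = NearestNeighbors(n_neighbors=k).fit(coords)
    dist, idx = nn.kneighbors(coords)
    # discard self matches (first column; duplicates handled by distance 0)
    dist, idx = dist[:, 1:], idx[:, 1:]
    if lengthscale == "auto":
        med = float(np.median(dist[:, 0]))
        if med <= 0:
            raise ValueError(
                "all-identical coordinates: cannot infer a lengthscale"
            )
        lengthscale = 1.2 * med
    lengthscale = float(lengthscale)
    w = np.exp(-(dist**2) / (2.0 * lengthscale**2))
    rows = np.repeat(np.arange(M), dist.shape[1])
    W = sparse.csr_matrix((w.ravel(), (rows, idx.ravel())), shape=(M, M))
    W = W.maximum(W.T)  # symmetrize
    W.setdiag(0.0)
    W.eliminate_zeros()
    return SpatialWeights(
        W=W.tocsr(), lengthscale=lengthscale, cutoff=cutoff,
        row_normalized=row_normalize,
    ) if not row_normalize else _row_normalized(W, lengthscale, cutoff)


def _row_normalized(W, lengthscale, cutoff) -> SpatialWeights:
    rs = np.asarray(W.sum(axis=1)).ravel()
    rs[rs == 0] = 1.0
    D = sparse.diags(1.0 / rs)
    return SpatialWeights(
        W=(D @ W).tocsr(), lengthscale=lengthscale, cutoff=cutoff,
        row_normalized=True,
    )


def pair_expression(
    expr: np.ndarray, gene_names: list[str], lr_db
) -> tuple[list[int], np.ndarray, np.ndarray]:
    """Ligand/receptor vectors per database pair on the expression panel.

    Multi-subunit complexes are averaged arithmetically over their subunit
    columns; pairs with any subunit missing from the panel are dropped with
    a log entry. Returns ``(pair_indices, L [M x P], R [M x P])``.
    """
    expr = np.asarray(expr, dtype=float)
    col = {g: i for i, g in enumerate(gene_names)}
    kept, Ls, Rs = [], [], []
    for pi, (lig, rec, _) in enumerate(lr_db.pairs):
        if all(g in col for g in lig) and all(g in col for g in rec):
            Ls.append(expr[:, [col[g] for g in lig]].mean(axis=1))
            Rs.append(expr[:, [col[g] for g in rec]].mean(axis=1))
            kept.append(pi)
        else:
            logger.info(
                "pair %s dropped: subunit missing from panel",
                lr_db.pair_names()[pi],
            )
    if not kept:
        raise ValueError("no LR pair has all subunits on the expression panel")
    return kept, np.stack(Ls, axis=1), np.stack(Rs, axis=1)


def _null_moments(weights: SpatialWeights):
    """Second moments of the double-permutation null (global and local)."""
    W = weights.W
    M = W.shape[0]
    r = np.asarray(W.sum(axis=1)).ravel()
    c = np.asarray(W.sum(axis=0)).ravel()
    S0 = r.sum()
    T1 = float((W.data**2).sum())
    T1k = np.asarray(W.multiply(W).sum(axis=1)).ravel()
    u = 1.0 / M
    v = -1.0 / (M * (M - 1.0))
    var_global = (
        u * u * T1
        + u * v * ((r**2).sum() - T1)
        + v * u * ((c**2).sum() - T1)
        + v * v * (S0**2 - (r**2).sum() - (c**2).sum() + T1)
    )
    var_sender = T1k - (r**2 - T1k) / (M - 1.0)
    cov_sr = r**2 / (M - 1.0) ** 2
    var_local = 2.0 * var_sender + 2.0 * cov_sr
    return var_global, np.maximum(var_local, 0.0)


def global_moran_r(
    L: np.ndarray, R: np.ndarray, weights: SpatialWeights
) -> tuple[float, float, float]:
    """Global bivariate Moran R with analytic one-sided z-score p-value."""
    L = np.asarray(L, dtype=float)
    R = np.asarray(R, dtype=float)
    a, b = L - L.mean(), R - R.mean()
    A2, B2 = float(a @ a), float(b @ b)
    if A2 == 0 or B2 == 0:
        raise ValueError("zero-variance field")
    num = float(a @ (weights.W @ b))
    r_global = num / np.sqrt(A2 * B2)
    var_g, _ = _null_moments(weights)
    z = r_global / np.sqrt(var_g)
    p = float(stats.norm.sf(z))
    return r_global, float(z), p


def local_moran_r(L: np.ndarray, R: np.ndarray, weights: SpatialWeights):
    """Per-location sender/receiver decomposition with one-sided p-values.

    Uses population (divide-by-M) standard deviations, which makes
    ``sum_k R_local_k == 2 M R_global`` exact for symmetric weights.
    """
    L = np.asarray(L, dtype=float)
    R = np.asarray(R, dtype=float)
    M = L.shape[0]
    a, b = L - L.mean(), R - R.mean()
    sig_l = np.sqrt((a @ a) / M)
    sig_r = np.sqrt((b @ b) / M)
    if sig_l == 0 or sig_r == 0:
        raise ValueError("zero-variance field")
    denom = sig_l * sig_r
    sender = a * (weights.W @ b) / denom
    receiver = b * (weights.W @ a) / denom
    local = sender + receiver
    _, var_local = _null_moments(weights)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var_local > 0, local / np.sqrt(var_local), 0.0)
    p = stats.norm.sf(z)
    return sender, receiver, local, p


def permutation_global_p(
    L: np.ndarray, R: np.ndarray, weights: SpatialWeights,
    n_perm: int = 1000, seed: int = 0,
) -> float:
    """Permutation oracle for the global statistic (upper tail)."""
    rng = np.random.default_rng(seed)
    obs, _, _ = global_moran_r(L, R, weights)
    L = np.asarray(L, float)
    R = np.asarray(R, float)
    count = 0
    for _ in range(n_perm):
        rp, _, _ = global_moran_r(
            rng.permutation(L), rng.permutation(R), weights
        )
        count += rp >= obs
    return (count + 1.0) / (n_perm + 1.0)


@dataclass
class MoranResult:
    """Per-pair global statistics and per-location local statistics."""

    pairs: pd.DataFrame  # ligand, receptor, pathway, R_global, z, p, q,
    #                      selected, n_interacting, eligible
    local_r: np.ndarray  # [M, P] R_local
    local_sender: np.ndarray
    local_receiver: np.ndarray
    local_p: np.ndarray  # [M, P]
    x_bin: np.ndarray  # [M, P] in {0, 1}
    x_con: np.ndarray  # [M, P] == 1 - local_p
    coords: np.ndarray | None = None


def score_pairs(
    expr: np.ndarray,
    gene_names: list[str],
    lr_db,
    weights: SpatialWeights,
) -> MoranResult:
    """Global and local Moran statistics for every usable database pair.

    Pairs whose ligand or receptor field has zero variance are reported with
    ``p = 1`` and excluded from local analysis (logged).
    """
    kept, Lmat, Rmat = pair_expression(expr, gene_names, lr_db)
    M = Lmat.shape[0]
    P = len(kept)
    rows = []
    local_r = np.zeros((M, P))
    local_s = np.zeros((M, P))
    local_rec = np.zeros((M, P))
    local_p = np.ones((M, P))
    for j, pi in enumerate(kept):
        lig, rec, pathway = lr_db.pairs[pi]
        L, R = Lmat[:, j], Rmat[:, j]
        if np.ptp(L) == 0 or np.ptp(R) == 0:
            logger.info("pair %d skipped: zero variance", pi)
            rows.append(
                dict(ligand="_".join(lig), receptor="_".join(rec),
                     pathway=pathway, R_global=0.0, z=0.0, p=1.0)
            )
            continue
        rg, z, p = global_moran_r(L, R, weights)
        s, r_, loc, pl = local_moran_r(L, R, weights)
        local_s[:, j], local_rec[:, j], local_r[:, j], local_p[:, j] = s, r_, loc, pl
        rows.append(
            dict(ligand="_".join(lig), receptor="_".join(rec),
                 pathway=pathway, R_global=rg, z=z, p=p)
        )
    pairs = pd.DataFrame(rows)
    return MoranResult(
        pairs=pairs,
        local_r=local_r,
        local_sender=local_s,
        local_receiver=local_rec,
        local_p=local_p,
        x_bin=np.zeros((M, P), dtype=int),
        x_con=1.0 - local_p,
    )


def select_pairs(
    result: MoranResult,
    fdr: float = 0.05,
    min_interacting: int = 3,
    local_p: float = 0.05,
) -> MoranResult:
    """BH selection of significant pairs plus the sparse-interaction filter.

    ``selected = (q < fdr)`` after Benjamini-Hochberg step-up across all
    tested pairs; a location interacts when its local p-value is below
    ``local_p``; pairs interacting in fewer than ``min_interacting``
    locations are flagged ineligible for pattern analysis (not deleted).
    """
    p = result.pairs["p"].to_numpy()
    _, q, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
    result.pairs["q"] = q
    result.pairs["selected"] = q < fdr
    result.x_bin = (result.local_p < local_p).astype(int)
    n_int = result.x_bin.sum(axis=0)
    result.pairs["n_interacting"] = n_int
    result.pairs["eligible"] = result.pairs["selected"] & (
        n_int >= min_interacting
    )
    return result
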