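"""Evaluation protocol: per-gene Pearson correlation and SSIM at spot scale.

Fine-resolution predictions (tiles or nuclei) are summed back into their
parent spots, then each gene is compared between truth and prediction as a
vector over locations (PCC) and as a rasterized 2-D image (SSIM with
``data_range=1`` after min-max scaling, uniform window). Genes with zero
variance in either field are reported as missing (NaN), never as zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity

logger = logging.getLogger(__name__)


def aggregate_to_spots(
    fine: np.ndarray, parent_index: np.ndarray, n_spots: int | None = None
) -> np.ndarray:
    """Sum fine-resolution rows into their parent spots.

    Orphan rows (parent -1, i.e. between-spot tiles) are excluded with a
    logged count.
    """
    fine = np.asarray(fine, dtype=float)
    parent = np.asarray(parent_index, dtype=int)
    orphans = parent < 0
    if orphans.any():
        logger.info("%d orphan tiles excluded from aggregation", orphans.sum())
    keep = ~orphans
    n = n_spots if n_spots is not None else int(parent[keep].max()) + 1
    out = np.zeros((n, fine.shape[1]))
    np.add.at(out, parent[keep], fine[keep])
    return out


def pcc_per_gene(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlation of each gene column; zero-variance -> NaN."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError("shape mismatch")
    if A.shape[0] < 2:
        raise ValueError("need at least 2 locations")
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    na = np.sqrt((Ac**2).sum(axis=0))
    nb = np.sqrt((Bc**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Ac * Bc).sum(axis=0) / (na * nb)
    r[(na == 0) | (nb == 0)] = np.nan
    return r


def rasterize(
    values: np.ndarray, coords: np.ndarray, pitch: tuple[float, float] | None = None
) -> np.ndarray:
    """Snap a location-indexed vector onto a regular 2-D grid.

    Grid pitch is inferred from the median positive coordinate gap unless
    given; locations mapping to the same cell are averaged; empty cells are
    filled with the field mean (so SSIM windows are defined everywhere).
    """
    coords = np.asarray(coords, dtype=float)
    v = np.asarray(values, dtype=float)
    if pitch is None:
        pitch = tuple(
            float(np.median(d[d > 0])) if (d := np.diff(np.unique(c))).size else 1.0
            for c in (coords[:, 0], coords[:, 1])
        )
    ix = np.round((coords[:, 0] - coords[:, 0].min()) / pitch[0]).astype(int)
    iy = np.round((coords[:, 1] - coords[:, 1].min()) / pitch[1]).astype(int)
    grid = np.zeros((iy.max() + 1, ix.max() + 1))
    count = np.zeros_like(grid)
    np.add.at(grid, (iy, ix), v)
    np.add.at(count, (iy, ix), 1.0)
    filled = count > 0
    grid[filled] /= count[filled]
    grid[~filled] = v.mean()
    return grid


def ssim_per_gene(
    A: np.ndarray,
    B: np.ndarray,
    coords: np.ndarray,
    pitch: tuple[float, float] | None = None,
) -> np.ndarray:
    """Structural similarity per gene on min-max-scaled rasterized fields.

    Each gene's two images are independently scaled to [0, 1] and compared
    with ``data_range=1`` and a uniform window (7x7, shrunk to the largest
    odd size that fits small images). Constant images give NaN.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError("shape mismatch")
    out = np.full(A.shape[1], np.nan)
    for g in range(A.shape[1]):
        ia = rasterize(A[:, g], coords, pitch)
        ib = rasterize(B[:, g], coords, pitch)
        ra, rb = np.ptp(ia), np.ptp(ib)
        if ra == 0 or rb == 0:
            continue
        ia = (ia - ia.min()) / ra
        ib = (ib - ib.min()) / rb
        win = min(7, ia.shape[0], ia.shape[1])
        if win % 2 == 0:
            win -= 1
        if win < 3:
            continue
        out[g] = structural_similarity(ia, ib, data_range=1.0, win_size=win)
    return out


@dataclass
class EvalReport:
    """Per-gene agreement between a truth field and a prediction."""

    genes: list[str]
    pcc: np.ndarray
    ssim: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.genes, "pcc": self.pcc, "ssim": self.ssim})


def evaluate(
    truth: np.ndarray,
    pred: np.ndarray,
    coords: np.ndarray,
    genes: list[str] | None = None,
) -> EvalReport:
    """PCC and SSIM per gene between matched location-by-gene matrices."""
    genes = genes or [f"g{i}" for i in range(np.asarray(truth).shape[1])]
    return EvalReport(
        genes=genes,
        pcc=pcc_per_gene(truth, pred),
        ssim=ssim_per_gene(truth, pred, coords),
    )
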