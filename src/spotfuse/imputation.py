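"""Blend image-based tile predictions with inverse-distance spot smoothing.

The final super-resolved expression of a tile is a convex combination::

    out = alpha * model_prediction + (1 - alpha) * IDW(kappa nearest spots)

where the smoothing arm averages the measured expression of the tile's
``kappa`` nearest probed spots with inverse-distance weights. Both arms must
be on the same scale (raw counts by default); distances are full-resolution
pixels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree


@dataclass
class ImputationConfig:
    """``kappa``: neighbor count (6 Visium / 4 VisiumHD); ``alpha``: blend
    weight in (0, 1), default 0.5 (alpha in {0, 1} allowed for testing the
    pure-arm limits)."""

    kappa: int = 6
    alpha: float = 0.5

    def __post_init__(self) -> None:
        if self.kappa < 1:
            raise ValueError("kappa must be >= 1")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must be in [0, 1]")


def default_kappa(platform_tag: str) -> int:
    return 4 if platform_tag == "visiumhd" else 6


def knn_spots(
    tile_centers: np.ndarray, spot_coords: np.ndarray, kappa: int
) -> tuple[np.ndarray, np.ndarray]:
    """Indices and distances of each tile's kappa nearest measured spots.

    Ties at the kappa-th distance are broken toward the lower spot index.
    If fewer than kappa spots exist, kappa is clipped with a warning.
    """
    tiles = np.atleast_2d(np.asarray(tile_centers, dtype=float))
    spots = np.asarray(spot_coords, dtype=float)
    n = spots.shape[0]
    if kappa > n:
        warnings.warn(f"kappa={kappa} clipped to {n} available spots")
        kappa = n
    tree = cKDTree(spots)
    k_query = min(n, kappa + 8)  # headroom to resolve distance ties by index
    dist, idx = tree.query(tiles, k=k_query)
    dist, idx = np.atleast_2d(dist), np.atleast_2d(idx)
    # stable tie-break: sort by (rounded distance, spot index)
    key_d = np.round(dist, 9)
    order = np.lexsort((idx, key_d), axis=1)
    rows = np.arange(tiles.shape[0])[:, None]
    dist, idx = dist[rows, order], idx[rows, order]
    return idx[:, :kappa], dist[:, :kappa]


def idw_weights(distances: np.ndarray) -> np.ndarray:
    """Inverse-distance weights, normalized to sum 1 per row.

    ``w_s = d_s^-1 / sum(d^-1)``; an exactly-zero distance takes all the
    weight (first such neighbor if several).
    """
    d = np.atleast_2d(np.asarray(distances, dtype=float))
    if d.size == 0:
        raise ValueError("empty distance list")
    w = np.zeros_like(d)
    zero_rows = (d == 0).any(axis=1)
    if zero_rows.any():
        first_zero = np.argmax(d[zero_rows] == 0, axis=1)
        w[np.flatnonzero(zero_rows), first_zero] = 1.0
    pos = ~zero_rows
    if pos.any():
        inv = 1.0 / d[pos]
        w[pos] = inv / inv.sum(axis=1, keepdims=True)
    return w if np.asarray(distances).ndim > 1 else w[0]


def smoothing_matrix(
    tile_centers: np.ndarray, spot_coords: np.ndarray, kappa: int
) -> sparse.csr_matrix:
    """Sparse ``[n_tiles, n_spots]`` IDW operator for neighborhood smoothing."""
    idx, dist = knn_spots(tile_centers, spot_coords, kappa)
    w = np.atleast_2d(idw_weights(dist))
    T, k = idx.shape
    rows = np.repeat(np.arange(T), k)
    return sparse.csr_matrix(
        (w.ravel(), (rows, idx.ravel())), shape=(T, np.asarray(spot_coords).shape[0])
    )


def impute_tiles(
    predictions: np.ndarray,
    tile_centers: np.ndarray,
    spot_coords: np.ndarray,
    measured: np.ndarray,
    config: ImputationConfig | None = None,
) -> np.ndarray:
    """Final super-resolved expression per tile.

    ``predictions`` are the model's tile-level inferences; ``measured`` the
    spot-level expression on the same gene panel and scale. Applies
    identically to within-spot, between-spot and nucleus tiles.
    """
    config = config or ImputationConfig()
    pred = np.asarray(predictions, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if pred.shape[1] != measured.shape[1]:
        raise ValueError(
            f"gene panel mismatch: predictions have {pred.shape[1]} genes, "
            f"measured spots {measured.shape[1]}"
        )
    if pred.shape[0] != np.asarray(tile_centers).shape[0]:
        raise ValueError("predictions not aligned with tile centers")
    S = smoothing_matrix(tile_centers, spot_coords, config.kappa)
    smoothed = S @ measured
    return config.alpha * pred + (1.0 - config.alpha) * smoothed
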