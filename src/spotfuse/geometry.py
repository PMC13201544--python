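"""Pixel bookkeeping: spot patches, tile grids, between-spot centers, nuclei tiles.

Conventions: 0-based pixel indices, half-open windows, coordinates are
(x=column, y=row). A probed spot at (x, y) owns the patch
``[y-P/2, y+P/2) x [x-P/2, x+P/2)`` of the slide for even patch size ``P``;
the patch is split into a ``g x g`` grid of square tiles in row-major order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

GEOMETRIC = "geometric"
NUCLEUS = "nucleus"


@dataclass
class TileSet:
    """Square tiles with parent-spot bookkeeping.

    ``parent_index`` is the probed-spot index a tile belongs to, or -1 for
    tiles of between-spot (gap) centers. For geometric tile sets the counts
    follow ``M = m * l`` with ``n`` probed spots, ``l`` tiles per spot and
    ``m`` total (within + between) spot centers.
    """

    tile_origin_px: np.ndarray  # int [T, 2] (row0, col0)
    tile_size_px: int
    parent_index: np.ndarray  # int [T], -1 for between-spot parents
    tile_kind: str  # "geometric" | "nucleus"
    tile_center_xy: np.ndarray  # float [T, 2] (x, y)
    n: int = 0  # probed spots
    l: int = 0  # tiles per spot (geometric)
    m: int = 0  # all spot centers incl. between
    parent_center_xy: np.ndarray | None = None  # [m, 2] for geometric sets

    def __post_init__(self) -> None:
        self.tile_origin_px = np.asarray(self.tile_origin_px, dtype=int)
        self.parent_index = np.asarray(self.parent_index, dtype=int)
        self.tile_center_xy = np.asarray(self.tile_center_xy, dtype=float)
        if self.tile_size_px <= 0:
            raise ValueError("tile_size_px must be positive")
        if self.tile_kind == GEOMETRIC and self.m and self.l:
            if len(self) != self.m * self.l:
                raise ValueError("geometric tile set must satisfy M == m*l")

    def __len__(self) -> int:
        return self.tile_origin_px.shape[0]

    @property
    def M(self) -> int:
        return len(self)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tile_id": np.arange(len(self)),
                "kind": self.tile_kind,
                "parent": self.parent_index,
                "row0": self.tile_origin_px[:, 0],
                "col0": self.tile_origin_px[:, 1],
                "size": self.tile_size_px,
                "center_x": self.tile_center_xy[:, 0],
                "center_y": self.tile_center_xy[:, 1],
            }
        )

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def extract_patches(
    bundle, patch_px: int = 112
) -> tuple[np.ndarray, np.ndarray]:
    """Patch windows centered on each spot.

    Returns ``(windows, kept)`` where ``windows`` is ``[n_kept, 2]`` of
    (row0, col0) origins for the half-open ``patch_px``-square windows and
    ``kept`` the indices of spots far enough from the border. Spots whose
    window would leave the image are excluded with a warning.
    """
    if patch_px % 2:
        raise ValueError("patch_px must be even")
    h, w = bundle.image.shape[:2]
    half = patch_px // 2
    cx = np.round(bundle.spot_coords[:, 0]).astype(int)
    cy = np.round(bundle.spot_coords[:, 1]).astype(int)
    row0, col0 = cy - half, cx - half
    ok = (row0 >= 0) & (col0 >= 0) & (row0 + patch_px <= h) & (col0 + patch_px <= w)
    if not ok.any():
        raise ValueError("all spots are too close to the image border")
    if (~ok).any():
        warnings.warn(
            f"{int((~ok).sum())} spots within {half}px of the border excluded"
        )
    windows = np.stack([row0[ok], col0[ok]], axis=1)
    return windows, np.flatnonzero(ok)


def tile_patch(window: np.ndarray, patch_px: int = 112, grid: int = 8) -> np.ndarray:
    """Row-major origins of the ``grid x grid`` tiles of one patch window.

    Tile (i, j) (1-based) occupies rows ``[(i-1)t, it)`` and columns
    ``[(j-1)t, jt)`` inside the patch, with ``t = patch_px / grid``.
    """
    if patch_px % grid:
        raise ValueError(f"patch_px={patch_px} not divisible by grid={grid}")
    t = patch_px // grid
    r0, c0 = int(window[0]), int(window[1])
    ii, jj = np.meshgrid(np.arange(grid), np.arange(grid), indexing="ij")
    return np.stack([r0 + ii.ravel() * t, c0 + jj.ravel() * t], axis=1)


def _lattice_pitch(coords: np.ndarray) -> float:
    d, _ = cKDTree(coords).query(coords, k=2)
    pitch = float(np.median(d[:, 1]))
    if pitch <= 0:
        raise ValueError("degenerate layout: duplicate spot coordinates")
    return pitch


def generate_between_spots(bundle) -> np.ndarray:
    """Augment probed spot centers with between-spot (gap) centers.

    For a hexagonal (Visium) lattice the gap centers are the midpoints of
    edges to each spot's nearest lattice neighbors; for square lattices
    (VisiumHD / generic) they are the 4-neighbor edge midpoints plus cell
    corners. Candidates are deduplicated on a snap grid of half the
    nearest-neighbor pitch and restricted to the convex hull of probed
    spots, yielding m/n in [3.5, 4.5] for large interior regions.

    Returns the augmented ``[m, 2]`` center array; the first ``n`` rows are
    the probed spots in their original order.
    """
    coords = np.asarray(bundle.spot_coords, dtype=float)
    n = coords.shape[0]
    if n == 1:
        return coords.copy()
    if n < 2:
        raise ValueError("need at least one spot")
    # degenerate (collinear) layouts cannot define a 2-D gap geometry
    if n >= 3:
        centered = coords - coords.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
            raise ValueError("degenerate layout: all spots collinear")
    pitch = _lattice_pitch(coords)
    hexa = bundle.platform_tag == "visium"
    tree = cKDTree(coords)

    k_neigh = 7 if hexa else 5
    dist, idx = tree.query(coords, k=min(k_neigh, n))
    cands = []
    for i in range(n):
        for j_pos in range(1, dist.shape[1]):
            d = dist[i, j_pos]
            if d <= 1.5 * pitch:
                cands.append((coords[i] + coords[idx[i, j_pos]]) / 2.0)
    if not hexa:
        # cell corners: average of the spot and its diagonal neighbors
        diag = np.sqrt(2.0) * pitch
        ddist, didx = tree.query(coords, k=min(9, n))
        for i in range(n):
            for j_pos in range(1, ddist.shape[1]):
                d = ddist[i, j_pos]
                if abs(d - diag) <= 0.25 * pitch:
                    cands.append((coords[i] + coords[didx[i, j_pos]]) / 2.0)
    if not cands:
        return coords.copy()
    cands = np.asarray(cands)

    # dedup on a snap grid of half the pitch
    snap = pitch / 2.0
    keys = np.floor(cands / snap + 0.5).astype(np.int64)  # half-up rounding
    _, first = np.unique(keys, axis=0, return_index=True)
    cands = cands[np.sort(first)]

    # drop candidates coinciding with probed spots
    d_spot, _ = tree.query(cands, k=1)
    cands = cands[d_spot > 0.25 * pitch]

    # keep candidates inside the convex hull of probed spots
    if len(cands):
        from scipy.spatial import Delaunay

        hull = Delaunay(coords)
        cands = cands[hull.find_simplex(cands) >= 0]

    out = np.vstack([coords, cands]) if len(cands) else coords.copy()
    logger.info("between-spot augmentation: n=%d -> m=%d", n, out.shape[0])
    return out


def build_geometric_tiles(
    bundle,
    patch_px: int = 112,
    grid: int = 8,
    include_between: bool = True,
) -> TileSet:
    """Full geometric tile set over within- and (optionally) between-spots."""
    centers = (
        generate_between_spots(bundle) if include_between else np.asarray(
            bundle.spot_coords, dtype=float
        )
    )
    n = bundle.n_spots
    h, w = bundle.image.shape[:2]
    half = patch_px // 2
    cx = np.round(centers[:, 0]).astype(int)
    cy = np.round(centers[:, 1]).astype(int)
    row0, col0 = cy - half, cx - half
    ok = (row0 >= 0) & (col0 >= 0) & (row0 + patch_px <= h) & (col0 + patch_px <= w)
    if not ok[:n].all():
        warnings.warn(
            f"{int((~ok[:n]).sum())} probed spots near the border excluded"
        )
    keep = np.flatnonzero(ok)
    l = grid * grid
    t = patch_px // grid
    origins = np.empty((len(keep) * l, 2), dtype=int)
    parents = np.empty(len(keep) * l, dtype=int)
    for pos, ci in enumerate(keep):
        origins[pos * l : (pos + 1) * l] = tile_patch(
            (row0[ci], col0[ci]), patch_px, grid
        )
        parents[pos * l : (pos + 1) * l] = ci if ci < n else -1
    centers_xy = np.stack(
        [origins[:, 1] + t / 2.0, origins[:, 0] + t / 2.0], axis=1
    )
    return TileSet(
        tile_origin_px=origins,
        tile_size_px=t,
        parent_index=parents,
        tile_kind=GEOMETRIC,
        tile_center_xy=centers_xy,
        n=int(ok[:n].sum()),
        l=l,
        m=len(keep),
        parent_center_xy=centers[keep],
    )


def nuclei_tiles(
    bundle, nuclei_centers: np.ndarray, tile_px: int = 14
) -> TileSet:
    """One tile per nucleus center, centered like spot patches.

    Centers within ``tile_px/2`` of the image border are excluded with a
    warning. Each retained nucleus is assigned to its nearest probed spot
    (ties to the lowest spot index) for per-spot bookkeeping.
    """
    centers = np.asarray(nuclei_centers, dtype=float)
    if centers.size == 0:
        raise ValueError("empty nuclei center list")
    h, w = bundle.image.shape[:2]
    half = tile_px // 2
    cx = np.round(centers[:, 0]).astype(int)
    cy = np.round(centers[:, 1]).astype(int)
    row0, col0 = cy - half, cx - half
    ok = (row0 >= 0) & (col0 >= 0) & (row0 + tile_px <= h) & (col0 + tile_px <= w)
    if (~ok).any():
        warnings.warn(f"{int((~ok).sum())} nuclei near the border excluded")
    keep = np.flatnonzero(ok)
    if keep.size == 0:
        raise ValueError("all nuclei centers are too close to the border")
    # nearest probed spot, ties broken toward the lowest index
    spots = np.asarray(bundle.spot_coords, dtype=float)
    diff = centers[keep, None, :] - spots[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    parent = np.argmin(d2, axis=1)  # argmin returns the first (lowest) index
    return TileSet(
        tile_origin_px=np.stack([row0[keep], col0[keep]], axis=1),
        tile_size_px=tile_px,
        parent_index=parent,
        tile_kind=NUCLEUS,
        tile_center_xy=centers[keep],
        n=bundle.n_spots,
        l=0,
        m=bundle.n_spots,
    )


def nuclei_counts_per_spot(tiles: TileSet, n_spots: int | None = None) -> np.ndarray:
    """Number of nucleus tiles assigned to each spot (sums to the tile count)."""
    if tiles.tile_kind != NUCLEUS:
        raise ValueError("expected a nucleus tile set")
    n = n_spots or tiles.n
    return np.bincount(tiles.parent_index, minlength=n)


def slice_tiles(image: np.ndarray, tiles: TileSet) -> np.ndarray:
    """Stack tile pixel windows into ``[T, t, t, 3]`` (uint8)."""
    t = tiles.tile_size_px
    out = np.empty((len(tiles), t, t, image.shape[2]), dtype=image.dtype)
    for i, (r0, c0) in enumerate(tiles.tile_origin_px):
        out[i] = image[r0 : r0 + t, c0 : c0 + t]
    return out
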