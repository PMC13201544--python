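"""Seeded synthetic slides with known sub-spot truth and planted signals.

The generator emulates a Visium-style experiment end to end: a spot lattice
(square or hexagonal), cells placed over the tissue with spatially clustered
types, per-cell expression rates (type markers, flat housekeeping genes, and
a ligand-receptor panel in which a subset of pairs carries a planted
co-expression hotspot), an RGB rendering in which each cell is a Gaussian
blob with a type-specific hue (so image features carry type signal), and
Poisson-sampled spot counts. Spot rates are the exact sums of member-cell
rates, so the true sub-spot expression of a spot's tiles sums to its
pre-noise value — the conservation law the evaluation protocol relies on.

Everything is a deterministic function of ``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import LRDatabase, SlideBundle


@dataclass
class SlideConfig:
    """Study conditions for a synthetic slide.

    Defaults give a 20x20-spot slide (~1,600 cells, 60 genes, 15 LR pairs
    of which 5 planted) that runs the full pipeline in well under two
    minutes. One pixel represents 0.5 synthetic micron, so a 14-px tile is
    about one cell.
    """

    n_rows: int = 20
    n_cols: int = 20
    pitch_px: float = 112.0
    patch_px: int = 112
    platform_tag: str = "visiumhd"  # square lattice; "visium" -> hex
    n_types: int = 3
    n_housekeeping: int = 10
    n_markers: int = 18
    n_lr_pairs: int = 15
    n_planted: int = 5
    multi_subunit_pairs: int = 2  # receptors with two subunits (non-planted)
    cells_per_spot: float = 6.0
    base_rate_median: float = 2.0  # per-cell per-gene rate scale
    base_rate_sigma: float = 0.4
    marker_boost: float = 3.0
    planted_boost: float = 4.0
    hotspot_radius_pitches: float = 2.5
    blob_sigma_px: float = 4.0
    render_image: bool = True
    shuffle_types: bool = False  # True destroys spatial type structure

    def __post_init__(self) -> None:
        if self.n_rows < 4 or self.n_cols < 4:
            raise ValueError("need at least a 4x4 spot lattice")
        if self.n_types < 1 or self.n_lr_pairs < 1:
            raise ValueError("need >= 1 type and >= 1 LR pair")
        if self.n_planted > self.n_lr_pairs:
            raise ValueError("cannot plant more pairs than exist")
        n_genes = (
            2 * self.n_lr_pairs + self.multi_subunit_pairs
            + self.n_markers + self.n_housekeeping
        )
        if n_genes < 10:
            raise ValueError("config yields fewer than 10 genes")

    @property
    def n_spots(self) -> int:
        return self.n_rows * self.n_cols


@dataclass
class SyntheticTruth:
    """Ground truth behind a synthetic slide."""

    cells_xy: np.ndarray  # [n_cells, 2]
    cell_types: np.ndarray  # [n_cells]
    cell_rates: np.ndarray  # [n_cells, n_genes] pre-noise expression rates
    spot_rates: np.ndarray  # [n_spots, n_genes] sums of member-cell rates
    cell_spot: np.ndarray  # [n_cells] owning spot index or -1
    planted: pd.DataFrame  # pair, ligand, receptor, cx, cy, radius, boost
    config: SlideConfig
    seed: int

    def tile_expression(self, tiles) -> np.ndarray:
        """True expression per tile: sum of rates of cells in each window."""
        t = tiles.tile_size_px
        out = np.zeros((len(tiles), self.cell_rates.shape[1]))
        px = np.floor(self.cells_xy[:, 0]).astype(int)
        py = np.floor(self.cells_xy[:, 1]).astype(int)
        for i, (r0, c0) in enumerate(tiles.tile_origin_px):
            inside = (py >= r0) & (py < r0 + t) & (px >= c0) & (px < c0 + t)
            if inside.any():
                out[i] = self.cell_rates[inside].sum(axis=0)
        return out


@dataclass
class SyntheticSlide:
    bundle: SlideBundle
    truth: SyntheticTruth
    nuclei_centers: np.ndarray
    lr_db: LRDatabase
    rtf_table: pd.DataFrame
    tftg_table: pd.DataFrame


def _spot_lattice(config: SlideConfig, margin: float) -> np.ndarray:
    p = config.pitch_px
    jj, ii = np.meshgrid(np.arange(config.n_cols), np.arange(config.n_rows))
    if config.platform_tag == "visium":
        x = (jj + 0.5 * (ii % 2)) * p + margin
        y = ii * (p * np.sqrt(3) / 2.0) + margin
    else:
        x = jj * p + margin
        y = ii * p + margin
    return np.stack([x.ravel(), y.ravel()], axis=1).astype(float)


def _gene_panel(config: SlideConfig):
    """Gene names, LR database, and planted/marker bookkeeping."""
    genes: list[str] = []
    pairs = []
    pathways = ["WNT", "BMP", "MHC-I", "CXCL"]
    lig_cols, rec_cols = [], []
    multi_left = config.multi_subunit_pairs
    for i in range(config.n_lr_pairs):
        lig = [f"LG{i}"]
        # planted pairs stay single-subunit; complexes exercise averaging
        if i >= config.n_planted and multi_left > 0:
            rec = [f"RC{i}A", f"RC{i}B"]
            multi_left -= 1
        else:
            rec = [f"RC{i}"]
        pairs.append((lig, rec, pathways[i % len(pathways)]))
        lig_cols.append([len(genes)])
        genes.extend(lig)
        rec_cols.append(list(range(len(genes), len(genes) + len(rec))))
        genes.extend(rec)
    marker_cols = list(range(len(genes), len(genes) + config.n_markers))
    genes.extend(f"MRK{i}" for i in range(config.n_markers))
    genes.extend(f"HK{i}" for i in range(config.n_housekeeping))
    return genes, LRDatabase(pairs), lig_cols, rec_cols, marker_cols


_TYPE_COLORS = np.array(
    [
        [188, 92, 138],  # epithelial-like, pink
        [86, 96, 186],  # lymphoid-like, blue
        [104, 168, 96],  # stromal-like, green
        [196, 160, 80],
        [120, 120, 200],
        [200, 120, 90],
    ],
    dtype=float,
)


def make_slide(config: SlideConfig | None = None, seed: int = 0) -> SyntheticSlide:
    """Generate a complete synthetic slide with planted LR co-expression."""
    config = config or SlideConfig()
    rng = np.random.default_rng(seed)
    margin = float(config.patch_px)
    spots = _spot_lattice(config, margin)
    n = spots.shape[0]
    width = int(np.ceil(spots[:, 0].max() + margin))
    height = int(np.ceil(spots[:, 1].max() + margin))

    # --- cells -----------------------------------------------------------
    n_cells = int(round(config.cells_per_spot * n))
    lo = spots.min(axis=0) - config.pitch_px / 2.0
    hi = spots.max(axis=0) + config.pitch_px / 2.0
    cells = rng.uniform(lo, hi, size=(n_cells, 2))

    # spatially clustered types from smooth random bump fields
    if config.n_types == 1:
        ctype = np.zeros(n_cells, dtype=int)
    else:
        fields = np.zeros((n_cells, config.n_types))
        for t in range(config.n_types):
            for _ in range(3):
                center = rng.uniform(lo, hi)
                widthb = rng.uniform(2.0, 4.0) * config.pitch_px
                amp = rng.uniform(1.5, 3.0)
                d2 = ((cells - center) ** 2).sum(axis=1)
                fields[:, t] += amp * np.exp(-d2 / (2 * widthb**2))
        gumbel = rng.gumbel(size=fields.shape)
        ctype = np.argmax(fields + gumbel, axis=1)
        if config.shuffle_types:
            ctype = rng.permutation(ctype)

    # --- expression rates -------------------------------------------------
    genes, lr_db, lig_cols, rec_cols, marker_cols = _gene_panel(config)
    G = len(genes)
    base = config.base_rate_median * np.exp(
        rng.normal(0.0, config.base_rate_sigma, size=G)
    )
    rates = np.tile(base, (n_cells, 1))
    for j, col in enumerate(marker_cols):
        t = j % config.n_types
        rates[ctype == t, col] *= config.marker_boost

    planted_rows = []
    radius = config.hotspot_radius_pitches * config.pitch_px
    interior_lo = lo + radius / 2.0
    interior_hi = hi - radius / 2.0
    for j in range(config.n_planted):
        center = rng.uniform(interior_lo, interior_hi)
        inside = ((cells - center) ** 2).sum(axis=1) < radius**2
        cols = lig_cols[j] + rec_cols[j]
        rates[np.ix_(inside, cols)] *= config.planted_boost
        lig, rec, _ = lr_db.pairs[j]
        planted_rows.append(
            dict(
                pair=j, ligand="_".join(lig), receptor="_".join(rec),
                cx=center[0], cy=center[1], radius=radius,
                boost=config.planted_boost,
            )
        )
    planted = pd.DataFrame(
        planted_rows,
        columns=["pair", "ligand", "receptor", "cx", "cy", "radius", "boost"],
    )

    # --- spot membership and counts --------------------------------------
    half = config.patch_px // 2
    from scipy.spatial import cKDTree

    _, nearest = cKDTree(spots).query(cells, k=1)
    r0 = np.round(spots[nearest, 1]).astype(int) - half
    c0 = np.round(spots[nearest, 0]).astype(int) - half
    px = np.floor(cells[:, 0]).astype(int)
    py = np.floor(cells[:, 1]).astype(int)
    in_window = (
        (py >= r0) & (py < r0 + config.patch_px)
        & (px >= c0) & (px < c0 + config.patch_px)
    )
    cell_spot = np.where(in_window, nearest, -1)
    spot_rates = np.zeros((n, G))
    owned = cell_spot >= 0
    np.add.at(spot_rates, cell_spot[owned], rates[owned])
    counts = rng.poisson(spot_rates)

    # --- image ------------------------------------------------------------
    background = np.array([234.0, 228.0, 238.0])
    image = np.tile(background, (height, width, 1))
    if config.render_image:
        s = config.blob_sigma_px
        rad = int(np.ceil(3 * s))
        ax = np.arange(-rad, rad + 1)
        kern = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2 * s**2))
        for (x, y), t in zip(cells, ctype):
            cxi, cyi = int(round(x)), int(round(y))
            r_lo, r_hi = max(0, cyi - rad), min(height, cyi + rad + 1)
            c_lo, c_hi = max(0, cxi - rad), min(width, cxi + rad + 1)
            kr = kern[
                r_lo - (cyi - rad) : kern.shape[0] - ((cyi + rad + 1) - r_hi),
                c_lo - (cxi - rad) : kern.shape[1] - ((cxi + rad + 1) - c_hi),
            ]
            color = _TYPE_COLORS[t % len(_TYPE_COLORS)]
            patch = image[r_lo:r_hi, c_lo:c_hi]
            patch += kr[:, :, None] * (color - background)[None, None, :]
        image += rng.normal(0.0, 2.0, size=image.shape)
    image = np.clip(image, 0, 255).astype(np.uint8)

    bundle = SlideBundle(
        image=image,
        spot_coords=spots,
        counts=counts,
        gene_names=genes,
        spot_ids=[f"spot{i}" for i in range(n)],
        spot_diameter_px=float(config.patch_px),
        platform_tag=config.platform_tag,
        lr_db=lr_db,
    )
    truth = SyntheticTruth(
        cells_xy=cells,
        cell_types=ctype,
        cell_rates=rates,
        spot_rates=spot_rates,
        cell_spot=cell_spot,
        planted=planted,
        config=config,
        seed=seed,
    )

    # --- downstream edge tables ------------------------------------------
    receptors = sorted({"_".join(r) for _, r, _ in lr_db.pairs})
    rtf_rows, tftg_rows = [], []
    for rec in receptors:
        for a in ("A", "B"):
            tf = f"TF_{rec}{a}"
            rtf_rows.append(
                dict(receptor=rec, tf=tf, score=float(rng.uniform(0.5, 1.0)))
            )
            for ti in range(2):
                tftg_rows.append(dict(tf=tf, target=f"TG_{rec}{a}{ti}"))
    return SyntheticSlide(
        bundle=bundle,
        truth=truth,
        nuclei_centers=cells.copy(),
        lr_db=lr_db,
        rtf_table=pd.DataFrame(rtf_rows),
        tftg_table=pd.DataFrame(tftg_rows),
    )


def make_null_slide(
    config: SlideConfig | None = None, seed: int = 0
) -> SyntheticSlide:
    """Slide with no planted hotspots and spatially shuffled cell types.

    Used for calibration: every LR pair is a true null for spatial
    co-expression.
    """
    config = config or SlideConfig()
    config = replace(config, n_planted=0, shuffle_types=True)
    return make_slide(config, seed)


def calibration_config(n_pairs: int = 500) -> SlideConfig:
    """Small-image null-slide conditions: 200 spots, ``n_pairs`` LR pairs."""
    return SlideConfig(
        n_rows=10,
        n_cols=20,
        pitch_px=28.0,
        patch_px=28,
        n_lr_pairs=n_pairs,
        n_planted=0,
        multi_subunit_pairs=0,
        n_markers=0,
        n_housekeeping=0,
        n_types=1,
        render_image=False,
    )
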