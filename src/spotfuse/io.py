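"""Reading, writing and preprocessing of slide-level inputs.

A :class:`SlideBundle` ties together the four inputs every downstream stage
consumes: the RGB histology image, per-spot pixel coordinates, the UMI count
matrix on a gene panel, and a ligand-receptor interaction database.  The
preprocessing here mirrors standard spot-level practice: restrict to the
ligand/receptor gene panel (plus any user genes), drop genes detected in too
few spots, and optionally total-count normalize to 10,000 followed by a
natural-log transform with pseudo-count 1.
"""

from __future__ import annotations

import logging
import os
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

logger = logging.getLogger(__name__)

PLATFORMS = ("visium", "visiumhd", "generic")


class ConsistencyError(ValueError):
    """Inputs disagree with each other (e.g. spot ids mismatch)."""


@dataclass
class LRDatabase:
    """Curated ligand-receptor pair list.

    Each pair is ``(ligand_subunits, receptor_subunits, pathway)``; multi-
    subunit complexes are lists of gene symbols (serialized joined by "_").
    """

    pairs: list[tuple[list[str], list[str], str]]

    def __post_init__(self) -> None:
        for lig, rec, _ in self.pairs:
            if not lig or not rec:
                raise ValueError("LR pair with empty subunit list")

    @property
    def lr_gene_set(self) -> set[str]:
        genes: set[str] = set()
        for lig, rec, _ in self.pairs:
            genes.update(lig)
            genes.update(rec)
        return genes

    def pair_names(self) -> list[str]:
        return [
            "_".join(lig) + " -> " + "_".join(rec) for lig, rec, _ in self.pairs
        ]

    @classmethod
    def from_csv(cls, path: str) -> "LRDatabase":
        df = pd.read_csv(path)
        required = {"ligand", "receptor", "pathway"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"LR database missing columns: {sorted(missing)}")
        pairs = [
            (str(r.ligand).split("_"), str(r.receptor).split("_"), str(r.pathway))
            for r in df.itertuples()
        ]
        return cls(pairs)

    def to_csv(self, path: str) -> None:
        pd.DataFrame(
            {
                "ligand": ["_".join(l) for l, _, _ in self.pairs],
                "receptor": ["_".join(r) for _, r, _ in self.pairs],
                "pathway": [p for _, _, p in self.pairs],
            }
        ).to_csv(path, index=False)


@dataclass
class SlideBundle:
    """One slide: image, spot coordinates, counts, gene panel, LR database.

    Coordinates are full-resolution pixels in (x=column, y=row) order.
    """

    image: np.ndarray  # uint8 [H, W, 3]
    spot_coords: np.ndarray  # float [n_spots, 2] (x, y)
    counts: np.ndarray  # float/int [n_spots, n_genes], non-negative
    gene_names: list[str]
    spot_ids: list[str]
    spot_diameter_px: float
    platform_tag: str = "visium"
    lr_db: LRDatabase | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        img = np.asarray(self.image)
        if img.ndim != 3 or img.shape[2] != 3:
            raise ValueError("image must be [H, W, 3]")
        coords = np.asarray(self.spot_coords, dtype=float)
        counts = np.asarray(self.counts)
        if coords.shape[0] != counts.shape[0]:
            raise ConsistencyError(
                f"{coords.shape[0]} coordinates but {counts.shape[0]} count rows"
            )
        if counts.shape[1] != len(self.gene_names):
            raise ConsistencyError("gene_names length != counts columns")
        if len(self.spot_ids) != coords.shape[0]:
            raise ConsistencyError("spot_ids length != number of spots")
        if np.min(counts) < 0:
            raise ValueError("counts must be non-negative")
        if not self.spot_diameter_px > 0:
            raise ValueError("spot_diameter_px must be positive")
        if self.platform_tag not in PLATFORMS:
            raise ValueError(f"platform_tag must be one of {PLATFORMS}")
        h, w = img.shape[:2]
        x, y = coords[:, 0], coords[:, 1]
        if coords.size and (
            x.min() < 0 or y.min() < 0 or x.max() >= w or y.max() >= h
        ):
            raise ConsistencyError("spot coordinates fall outside image bounds")
        self.image = img
        self.spot_coords = coords
        self.counts = counts

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]


def _read_image(path: str) -> np.ndarray:
    if not os.path.exists(path):
        raise FileNotFoundError(f"image file not found: {path}")
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile

        img = tifffile.imread(path)
    else:
        from PIL import Image

        img = np.asarray(Image.open(path).convert("RGB"))
    img = np.asarray(img)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.shape[2] > 3:
        img = img[:, :, :3]
    return img.astype(np.uint8)


def _read_counts(path: str) -> pd.DataFrame:
    """Counts as spots x genes with spot ids as index.

    Supported: dense TSV (rows=spots, first column spot id), Matrix Market
    ``.mtx`` with ``<stem>_genes.tsv`` / ``<stem>_spots.tsv`` sidecars, and
    AnnData ``.h5ad`` (thin adapter).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"counts file not found: {path}")
    if path.endswith(".h5ad"):
        import anndata as ad

        adata = ad.read_h5ad(path)
        X = adata.X
        X = X.toarray() if sparse.issparse(X) else np.asarray(X)
        return pd.DataFrame(X, index=adata.obs_names, columns=adata.var_names)
    if path.endswith(".mtx"):
        stem = path[: -len(".mtx")]
        genes = pd.read_csv(stem + "_genes.tsv", sep="\t", header=None)[0].tolist()
        spots = pd.read_csv(stem + "_spots.tsv", sep="\t", header=None)[0].tolist()
        mat = spio.mmread(path).toarray()
        return pd.DataFrame(mat, index=spots, columns=genes)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def load_slide(
    counts_path: str,
    coords_path: str,
    image_path: str,
    lr_db_path: str | None = None,
    platform_tag: str = "visium",
    spot_diameter_px: float | None = None,
) -> SlideBundle:
    """Assemble and validate a :class:`SlideBundle` from files on disk.

    Spot order follows the coordinate file; duplicated gene columns keep the
    first occurrence (with a warning). Spot-id mismatches between counts and
    coordinates raise a :class:`ConsistencyError` naming the offenders.
    """
    counts = _read_counts(counts_path)
    if not os.path.exists(coords_path):
        raise FileNotFoundError(f"coords file not found: {coords_path}")
    coords = pd.read_csv(coords_path, sep=None, engine="python")
    if not {"spot_id", "x", "y"} <= set(coords.columns):
        raise ValueError("coords file must have columns spot_id, x, y")
    coords["spot_id"] = coords["spot_id"].astype(str)

    missing = [s for s in coords["spot_id"] if s not in counts.index]
    extra = [s for s in counts.index if s not in set(coords["spot_id"])]
    if missing or extra:
        raise ConsistencyError(
            f"spot ids mismatch; in coords but not counts: {missing[:10]}; "
            f"in counts but not coords: {extra[:10]}"
        )

    if counts.columns.duplicated().any():
        dupes = counts.columns[counts.columns.duplicated()].unique().tolist()
        warnings.warn(f"duplicate gene names, keeping first occurrence: {dupes}")
        logger.warning("duplicate gene names dropped: %s", dupes)
        counts = counts.loc[:, ~counts.columns.duplicated()]

    counts = counts.loc[coords["spot_id"]]
    image = _read_image(image_path)
    lr_db = LRDatabase.from_csv(lr_db_path) if lr_db_path else None
    if spot_diameter_px is None:
        # fall back to nearest-neighbour pitch as a conservative diameter
        xy = coords[["x", "y"]].to_numpy(float)
        if len(xy) > 1:
            from scipy.spatial import cKDTree

            d, _ = cKDTree(xy).query(xy, k=2)
            spot_diameter_px = float(np.median(d[:, 1]))
        else:
            spot_diameter_px = 1.0
    return SlideBundle(
        image=image,
        spot_coords=coords[["x", "y"]].to_numpy(float),
        counts=counts.to_numpy(),
        gene_names=[str(g) for g in counts.columns],
        spot_ids=coords["spot_id"].tolist(),
        spot_diameter_px=spot_diameter_px,
        platform_tag=platform_tag,
        lr_db=lr_db,
    )


def save_bundle(bundle: SlideBundle, out_dir: str) -> None:
    """Write a bundle snapshot (counts, coords, genes, image, LR db)."""
    os.makedirs(out_dir, exist_ok=True)
    df = pd.DataFrame(bundle.counts, index=bundle.spot_ids, columns=bundle.gene_names)
    df.to_csv(os.path.join(out_dir, "counts.tsv"), sep="\t")
    pd.DataFrame(
        {
            "spot_id": bundle.spot_ids,
            "x": bundle.spot_coords[:, 0],
            "y": bundle.spot_coords[:, 1],
        }
    ).to_csv(os.path.join(out_dir, "coords.tsv"), sep="\t", index=False)
    from PIL import Image

    Image.fromarray(bundle.image).save(os.path.join(out_dir, "image.png"))
    if bundle.lr_db is not None:
        bundle.lr_db.to_csv(os.path.join(out_dir, "lr_db.csv"))
    with open(os.path.join(out_dir, "meta.txt"), "w") as fh:
        fh.write(f"platform_tag\t{bundle.platform_tag}\n")
        fh.write(f"spot_diameter_px\t{bundle.spot_diameter_px}\n")


def load_bundle(out_dir: str, platform_tag: str | None = None) -> SlideBundle:
    """Read back a snapshot written by :func:`save_bundle`."""
    meta = {}
    meta_path = os.path.join(out_dir, "meta.txt")
    if os.path.exists(meta_path):
        with open(meta_path) as fh:
            for line in fh:
                k, v = line.rstrip("\n").split("\t")
                meta[k] = v
    lr_path = os.path.join(out_dir, "lr_db.csv")
    return load_slide(
        counts_path=os.path.join(out_dir, "counts.tsv"),
        coords_path=os.path.join(out_dir, "coords.tsv"),
        image_path=os.path.join(out_dir, "image.png"),
        lr_db_path=lr_path if os.path.exists(lr_path) else None,
        platform_tag=platform_tag or meta.get("platform_tag", "visium"),
        spot_diameter_px=float(meta.get("spot_diameter_px", 0)) or None,
    )


def select_genes(
    bundle: SlideBundle,
    lr_db: LRDatabase | None = None,
    extra_genes: set[str] | None = None,
    min_spots: int = 10,
) -> SlideBundle:
    """Restrict the panel to LR genes (plus extras) detected in enough spots.

    A gene is retained when it belongs to the LR gene set (union of all
    subunits) or ``extra_genes``, and has nonzero counts in at least
    ``min_spots`` spots. Original gene order is preserved.
    """
    if min_spots < 1:
        raise ValueError("min_spots must be >= 1")
    lr_db = lr_db or bundle.lr_db
    wanted = set(extra_genes or set())
    if lr_db is not None:
        wanted |= lr_db.lr_gene_set
    if not wanted:
        raise ValueError("no LR database and no extra_genes supplied")
    nonzero_spots = (np.asarray(bundle.counts) > 0).sum(axis=0)
    keep = [
        i
        for i, g in enumerate(bundle.gene_names)
        if g in wanted and nonzero_spots[i] >= min_spots
    ]
    if not keep:
        raise ValueError(
            "no genes retained; relax min_spots or extend the gene list"
        )
    return replace(
        bundle,
        counts=np.asarray(bundle.counts)[:, keep],
        gene_names=[bundle.gene_names[i] for i in keep],
    )


def preprocess_counts(bundle: SlideBundle, normalize: bool = False) -> SlideBundle:
    """Total-count normalize to 10,000 and log1p, or pass counts through.

    With ``normalize=True`` each spot row is scaled so its pre-log sum is
    10,000 and then ``ln(value + 1)`` is applied; all-zero rows are kept
    all-zero with a warning. With ``normalize=False`` (the default model
    input) counts are returned unchanged.
    """
    if not normalize:
        return bundle
    counts = np.asarray(bundle.counts, dtype=float)
    row_sums = counts.sum(axis=1)
    zero_rows = row_sums == 0
    if zero_rows.any():
        warnings.warn(f"{int(zero_rows.sum())} all-zero spot rows left unchanged")
    scale = np.where(zero_rows, 1.0, 10_000.0 / np.where(zero_rows, 1.0, row_sums))
    out = np.log1p(counts * scale[:, None])
    return replace(bundle, counts=out)


def points_in_polygon(points: np.ndarray, polygon: np.ndarray) -> np.ndarray:
    """Even-odd-rule membership test; points on an edge count as inside."""
    pts = np.asarray(points, dtype=float)
    poly = np.asarray(polygon, dtype=float)
    if poly.shape[0] < 3:
        raise ValueError("polygon needs at least 3 vertices")
    x, y = pts[:, 0], pts[:, 1]
    inside = np.zeros(len(pts), dtype=bool)
    on_edge = np.zeros(len(pts), dtype=bool)
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        # boundary check: point on segment within tolerance
        dx, dy = x2 - x1, y2 - y1
        seg2 = dx * dx + dy * dy
        if seg2 == 0:
            on_edge |= (np.abs(x - x1) < 1e-9) & (np.abs(y - y1) < 1e-9)
            continue
        t = np.clip(((x - x1) * dx + (y - y1) * dy) / seg2, 0.0, 1.0)
        dist2 = (x - (x1 + t * dx)) ** 2 + (y - (y1 + t * dy)) ** 2
        on_edge |= dist2 < 1e-18
        # even-odd crossing count (half-open edge convention)
        cond = (y1 <= y) != (y2 <= y)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x1 + (y - y1) * dx / np.where(dy == 0, np.inf, dy)
        inside ^= cond & (x < xint)
    return inside | on_edge


def crop_roi(bundle: SlideBundle, polygon: np.ndarray) -> SlideBundle:
    """Restrict a bundle to spots inside a region-of-interest polygon.

    Membership uses the even-odd rule with the boundary counting as inside;
    the image is cropped to the polygon's bounding box and coordinates are
    re-offset accordingly.
    """
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[0] < 3 or poly.shape[1] != 2:
        raise ValueError("polygon must be [>=3, 2] vertices")
    keep = points_in_polygon(bundle.spot_coords, poly)
    if not keep.any():
        raise ValueError(
            f"no spots inside polygon with bounds x:[{poly[:,0].min()},"
            f"{poly[:,0].max()}] y:[{poly[:,1].min()},{poly[:,1].max()}]"
        )
    h, w = bundle.image.shape[:2]
    x0 = int(max(0, np.floor(poly[:, 0].min())))
    y0 = int(max(0, np.floor(poly[:, 1].min())))
    x1 = int(min(w, np.ceil(poly[:, 0].max()) + 1))
    y1 = int(min(h, np.ceil(poly[:, 1].max()) + 1))
    image = bundle.image[y0:y1, x0:x1]
    coords = bundle.spot_coords[keep] - np.array([x0, y0], dtype=float)
    return replace(
        bundle,
        image=image,
        spot_coords=coords,
        counts=np.asarray(bundle.counts)[keep],
        spot_ids=[s for s, k in zip(bundle.spot_ids, keep) if k],
    )
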