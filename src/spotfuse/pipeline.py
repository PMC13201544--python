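"""Stage orchestration shared by the CLI and scripted runs.

Thin glue over the library modules: assemble within-spot training inputs,
run training / imputation / discovery on a bundle, and keep per-stage seeds
derived from one top-level seed by fixed offsets.
"""

from __future__ import annotations

import numpy as np

from . import (
    ContrastiveImputation,
    ImputationConfig,
    build_geometric_tiles,
    build_weights,
    extract_features,
    get_extractor,
    impute_tiles,
    score_pairs,
    select_pairs,
)

SEED_OFFSETS = {"simulate": 0, "features": 1, "train": 2, "impute": 3, "discover": 4}


def stage_seed(seed: int, stage: str) -> int:
    return (int(seed) * 1000 + SEED_OFFSETS[stage]) % (2**31 - 1)


def within_spot_training_inputs(
    bundle, patch_px: int = 112, grid: int = 8, extractor=None, seed: int = 0
):
    """Tile features for probed spots plus aligned spot expression.

    Returns ``(features [n*l, C], Y [n, p], tiles, kept_spots)`` where rows
    of ``features`` group each kept spot's ``l`` tiles consecutively.
    """
    tiles = build_geometric_tiles(
        bundle, patch_px=patch_px, grid=grid, include_between=False
    )
    extractor = extractor or get_extractor(
        "stub", tile_px=patch_px // grid, seed=stage_seed(seed, "features")
    )
    feats = extract_features(tiles, bundle.image, extractor)
    kept = np.unique(tiles.parent_index)
    kept = kept[kept >= 0]
    Y = np.asarray(bundle.counts, dtype=float)[kept]
    return feats.values, Y, tiles, kept


def run_impute(
    bundle,
    model: ContrastiveImputation,
    patch_px: int = 112,
    grid: int = 8,
    extractor=None,
    config: ImputationConfig | None = None,
    include_between: bool = True,
    seed: int = 0,
):
    """Predict and blend expression for all geometric tiles of a slide."""
    tiles = build_geometric_tiles(
        bundle, patch_px=patch_px, grid=grid, include_between=include_between
    )
    extractor = extractor or get_extractor(
        "stub", tile_px=patch_px // grid, seed=stage_seed(seed, "features")
    )
    feats = extract_features(tiles, bundle.image, extractor)
    pred = model.predict(feats.values)
    out = impute_tiles(
        pred,
        tiles.tile_center_xy,
        bundle.spot_coords,
        np.asarray(bundle.counts, dtype=float),
        config or ImputationConfig(),
    )
    return out, tiles


def run_discover(
    expr: np.ndarray,
    coords: np.ndarray,
    gene_names: list[str],
    lr_db,
    fdr: float = 0.05,
    min_interacting: int = 3,
    cutoff: int = 6,
    lengthscale="auto",
):
    """Moran scoring plus BH selection for all usable LR pairs."""
    weights = build_weights(coords, lengthscale=lengthscale, cutoff=cutoff)
    result = score_pairs(expr, gene_names, lr_db, weights)
    result.coords = np.asarray(coords, dtype=float)
    return select_pairs(result, fdr=fdr, min_interacting=min_interacting)
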