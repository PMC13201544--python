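"""Tile-level image feature extraction behind a pluggable extractor interface.

Foundation-model extractors (Virchow2, ViT256-16) are optional plugins whose
embedding contracts (dimension, expected tile size) are declared in a profile
registry so downstream shape bookkeeping works without their weights. The
built-in :class:`StubExtractor` is a deterministic, Lipschitz featurizer
(channel statistics, low-order spatial moments, seeded random projection)
that carries enough texture/color signal for the contrastive model to learn
on synthetic slides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ExtractorProfile:
    name: str
    embed_dim: int
    tile_px: int


#: Declared contracts of the supported extractor profiles. The foundation
#: models are not bundled; their profiles exist so pipelines can be laid out
#: (and caches keyed) without loading weights.
EXTRACTOR_PROFILES = {
    "virchow2": ExtractorProfile("virchow2", 1280, 14),
    "vit256-16": ExtractorProfile("vit256-16", 384, 16),
}


class FeatureExtractor:
    """Interface: callable mapping ``[T, t, t, 3]`` tiles to ``[T, C]``."""

    embed_dim: int
    tile_px: int

    def __call__(self, tiles: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class StubExtractor(FeatureExtractor):
    """Deterministic tile featurizer used in place of a pre-trained ViT.

    The feature row concatenates per-channel means and variances (6), gray
    centroid and second spatial moments (6), and a fixed seeded random
    projection of the flattened, mean-centered tile filling the remaining
    ``C - 12`` dimensions. Identical pixels give identical rows; the map is
    Lipschitz in pixel values.
    """

    MOMENT_DIMS = 12

    def __init__(self, embed_dim: int = 48, tile_px: int = 14, seed: int = 0):
        if embed_dim < 8:
            raise ValueError("embed_dim must be >= 8")
        self.embed_dim = int(embed_dim)
        self.tile_px = int(tile_px)
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        n_in = tile_px * tile_px * 3
        n_proj = max(self.embed_dim - self.MOMENT_DIMS, 0)
        self._proj = rng.standard_normal((n_in, n_proj)) / np.sqrt(n_in)

    def __call__(self, tiles: np.ndarray) -> np.ndarray:
        tiles = np.asarray(tiles, dtype=float) / 255.0
        if tiles.ndim == 3:
            tiles = tiles[None]
        T, t = tiles.shape[0], tiles.shape[1]
        if t != self.tile_px or tiles.shape[2] != self.tile_px:
            raise ValueError(
                f"tile size {tiles.shape[1:3]} does not match extractor "
                f"contract {self.tile_px}"
            )
        ch_mean = tiles.mean(axis=(1, 2))  # [T, 3]
        ch_var = tiles.var(axis=(1, 2))  # [T, 3]
        gray = tiles.mean(axis=3)  # [T, t, t]
        # moments of the mean-centered gray image: brightness-shift invariant
        gray_c = gray - gray.mean(axis=(1, 2), keepdims=True)
        coords = (np.arange(t) - (t - 1) / 2.0) / t
        area = float(t * t)
        cr = (gray_c * coords[None, :, None]).sum(axis=(1, 2)) / area
        cc = (gray_c * coords[None, None, :]).sum(axis=(1, 2)) / area
        mrr = (gray_c * (coords**2)[None, :, None]).sum(axis=(1, 2)) / area
        mcc = (gray_c * (coords**2)[None, None, :]).sum(axis=(1, 2)) / area
        mrc = (
            gray_c * coords[None, :, None] * coords[None, None, :]
        ).sum(axis=(1, 2)) / area
        gvar = gray.var(axis=(1, 2))
        moments = np.stack([cr, cc, mrr, mcc, mrc, gvar], axis=1)
        flat = tiles.reshape(T, -1)
        centered = flat - flat.mean(axis=1, keepdims=True)
        proj = centered @ self._proj
        out = np.concatenate([ch_mean, ch_var, moments, proj], axis=1)
        return out[:, : self.embed_dim]


def get_extractor(
    profile: str = "stub",
    embed_dim: int = 48,
    tile_px: int = 14,
    seed: int = 0,
) -> FeatureExtractor:
    """Instantiate an extractor by profile name.

    The ``stub`` profile is always available; foundation-model profiles
    require their optional plugin packages and raise ImportError otherwise.
    """
    if profile == "stub":
        return StubExtractor(embed_dim=embed_dim, tile_px=tile_px, seed=seed)
    if profile in EXTRACTOR_PROFILES:
        prof = EXTRACTOR_PROFILES[profile]
        raise ImportError(
            f"extractor profile '{profile}' (C={prof.embed_dim}, "
            f"tile={prof.tile_px}px) requires its optional model plugin, "
            "which is not installed; use profile='stub'"
        )
    raise ValueError(f"unknown extractor profile '{profile}'")


@dataclass
class ImageFeatureMatrix:
    """Per-tile embeddings plus a back-reference into the tile set."""

    values: np.ndarray  # [n_tiles, C]
    tile_index: np.ndarray  # [n_tiles] indices into the TileSet

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.tile_index = np.asarray(self.tile_index, dtype=int)
        if self.values.shape[0] != self.tile_index.shape[0]:
            raise ValueError("row count must equal tile count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature values")

    @property
    def C(self) -> int:
        return self.values.shape[1]


def extract_features(
    tiles, image: np.ndarray, extractor: FeatureExtractor
) -> ImageFeatureMatrix:
    """Embed every tile of a tile set; one row per tile, in tile order."""
    from .geometry import slice_tiles

    if tiles.tile_size_px != extractor.tile_px:
        raise ValueError(
            f"tile size {tiles.tile_size_px}px does not match extractor "
            f"contract {extractor.tile_px}px"
        )
    pixels = slice_tiles(image, tiles)
    values = extractor(pixels)
    return ImageFeatureMatrix(values=values, tile_index=np.arange(len(tiles)))


def save_features(path: str, feats: ImageFeatureMatrix) -> None:
    np.savez(path, values=feats.values, tile_index=feats.tile_index)


def load_features(path: str) -> ImageFeatureMatrix:
    data = np.load(path)
    return ImageFeatureMatrix(values=data["values"], tile_index=data["tile_index"])
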