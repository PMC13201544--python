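import numpy as np
import pytest

import spotfuse
from spotfuse.pipeline import within_spot_training_inputs


@pytest.fixture(scope="session")
def slide12():
    """12x12-spot synthetic slide used across model/imputation tests."""
    return spotfuse.make_slide(spotfuse.SlideConfig(n_rows=12, n_cols=12), seed=7)


@pytest.fixture(scope="session")
def training_inputs(slide12):
    feats, Y, tiles, kept = within_spot_training_inputs(slide12.bundle, seed=7)
    return feats, Y, tiles, kept


@pytest.fixture(scope="session")
def trained_model(training_inputs):
    feats, Y, _, _ = training_inputs
    est = spotfuse.ContrastiveImputation(hidden_dim=32, K=64, epochs=60, seed=1)
    return est.fit(feats, Y)


@pytest.fixture()
def toy_bundle():
    """Tiny hand-made bundle: 4 spots on a square, 3 genes."""
    rng = np.random.default_rng(0)
    image = rng.integers(0, 255, size=(200, 200, 3), dtype=np.uint8)
    coords = np.array([[60.0, 60.0], [140.0, 60.0], [60.0, 140.0], [140.0, 140.0]])
    counts = np.array([[5, 0, 2], [1, 3, 0], [0, 0, 4], [2, 2, 2]])
    return spotfuse.SlideBundle(
        image=image,
        spot_coords=coords,
        counts=counts,
        gene_names=["GA", "GB", "GC"],
        spot_ids=[f"s{i}" for i in range(4)],
        spot_diameter_px=80.0,
        platform_tag="generic",
    )
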