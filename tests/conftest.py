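import numpy as np
import pytest

from patchscreen import (
    EncoderState,
    LocalityConfig,
    PatchSpec,
    ReferenceDB,
    SSLConfig,
    fit_covariance,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_random_db(
    rng: np.random.Generator,
    grid_dim: int = 4,
    n_images: int = 3,
    dim: int = 4,
    size: int = 8,
) -> ReferenceDB:
    """A small reference DB with random features, one record per cell/image."""
    db = ReferenceDB()
    for img in range(n_images):
        gx, gy = np.meshgrid(np.arange(grid_dim), np.arange(grid_dim))
        gx, gy = gx.ravel(), gy.ravel()
        H = rng.normal(size=(grid_dim ** 2, dim))
        db.add_records(size, gx, gy, [f"img{img}"] * len(gx), H)
    db.covariance[size] = fit_covariance(db.features(size), shrinkage=0.1)
    db.provenance["image_side"] = size * grid_dim
    return db


@pytest.fixture
def small_db(rng):
    return make_random_db(rng)


@pytest.fixture
def tiny_ssl_config():
    """A contrastive config small enough for sub-second training in tests."""
    return SSLConfig(
        epochs=2,
        batch_pairs=8,
        patches_per_epoch=16,
        feature_dim=8,
        projection_dim=4,
        hidden_dim=16,
        pool_side=8,
        input_scale=1.0,
        seed=7,
    )
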