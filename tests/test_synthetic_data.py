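import numpy as np
import pandas as pd
import pytest

from patchscreen import AnomalySpec, PhantomConfig, generate_normal, inject_anomaly
from patchscreen.exceptions import InvalidInputError
from patchscreen.patch_grid import load_image
from patchscreen.synthetic_data import (
    WHITE_LEVEL,
    _ellipse_mask,
    load_manifest,
    load_split,
    make_dataset,
)


class TestGenerateNormal:
    def test_same_seed_is_bit_identical(self):
        cfg = PhantomConfig()
        a = generate_normal(cfg, np.random.default_rng(9))
        b = generate_normal(cfg, np.random.default_rng(9))
        assert np.array_equal(a, b)

    def test_noiseless_zero_jitter_phantoms_identical(self):
        cfg = PhantomConfig(noise_sigma=0.0, jitter=0.0)
        a = generate_normal(cfg, np.random.default_rng(1))
        b = generate_normal(cfg, np.random.default_rng(2))
        # only the rib phase differs between draws; remove ribs too
        cfg0 = PhantomConfig(noise_sigma=0.0, jitter=0.0, rib_amplitude=0.0)
        a0 = generate_normal(cfg0, np.random.default_rng(1))
        b0 = generate_normal(cfg0, np.random.default_rng(2))
        assert np.array_equal(a0, b0)
        assert a.shape == b.shape == (cfg.side, cfg.side)

    def test_lung_fields_darker_than_surrounding_body(self):
        cfg = PhantomConfig(noise_sigma=0.0, jitter=0.0)
        img = generate_normal(cfg, np.random.default_rng(0))
        side = cfg.side
        bcx, bcy = cfg.body_center
        lungs = _ellipse_mask(side, bcx - cfg.lung_offset_x, cfg.lung_center_y, *cfg.lung_axes)
        lungs |= _ellipse_mask(side, bcx + cfg.lung_offset_x, cfg.lung_center_y, *cfg.lung_axes)
        body = _ellipse_mask(side, bcx, bcy, *cfg.body_axes)
        assert img[lungs].mean() < img[body & ~lungs].mean()

    def test_intensities_in_unit_interval(self):
        img = generate_normal(PhantomConfig(), np.random.default_rng(5))
        assert img.min() >= 0.0 and img.max() <= 1.0

    def test_invalid_geometry_rejected(self):
        bad = PhantomConfig(lung_offset_x=0.45, jitter=0.0)  # lungs poke outside body
        with pytest.raises(InvalidInputError):
            generate_normal(bad, np.random.default_rng(0))


class TestInjectAnomaly:
    @pytest.mark.parametrize("kind", ["bright-blob", "dark-blob", "shape-deformation"])
    def test_deterministic_and_mask_nonempty(self, kind):
        img = generate_normal(PhantomConfig(), np.random.default_rng(3))
        spec = AnomalySpec(kind=kind, diameter_range=(10.0, 20.0))
        a1, m1, p1 = inject_anomaly(img, spec, np.random.default_rng(4))
        a2, m2, p2 = inject_anomaly(img, spec, np.random.default_rng(4))
        assert np.array_equal(a1, a2) and np.array_equal(m1, m2) and p1 == p2
        assert m1.sum() > 0

    def test_mask_area_tracks_nominal_disc(self):
        img = generate_normal(PhantomConfig(), np.random.default_rng(3))
        spec = AnomalySpec(diameter_range=(16.0, 16.0), contrast_range=(0.3, 0.3))
        _, mask, params = inject_anomaly(img, spec, np.random.default_rng(7))
        nominal = np.pi * (params[0]["diameter"] / 2) ** 2
        assert 0.5 * nominal <= mask.sum() <= 1.5 * nominal

    def test_minimal_diameter_produces_mask(self):
        img = generate_normal(PhantomConfig(), np.random.default_rng(3))
        spec = AnomalySpec(diameter_range=(2.0, 2.0))
        _, mask, _ = inject_anomaly(img, spec, np.random.default_rng(0))
        assert mask.sum() >= 1

    def test_changed_pixels_confined_near_mask(self):
        img = generate_normal(PhantomConfig(noise_sigma=0.0), np.random.default_rng(3))
        spec = AnomalySpec(diameter_range=(12.0, 12.0), contrast_range=(0.4, 0.4))
        out, mask, params = inject_anomaly(img, spec, np.random.default_rng(5))
        diff = np.abs(out - img) > 1e-9
        # the smooth profile is truncated at twice the nominal radius
        cy, cx = params[0]["cy"], params[0]["cx"]
        yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
        r = np.hypot(xx - cx, yy - cy)
        assert not np.any(diff & (r > params[0]["diameter"] + 1))
        assert np.all(diff[r <= params[0]["diameter"] / 4])  # core definitely altered

    def test_zero_contrast_excluded_by_construction(self):
        with pytest.raises(InvalidInputError):
            AnomalySpec(contrast_range=(0.0, 0.2))

    def test_oversized_anomaly_rejected(self):
        img = generate_normal(PhantomConfig(side=32), np.random.default_rng(3))
        spec = AnomalySpec(diameter_range=(64.0, 64.0))
        with pytest.raises(InvalidInputError):
            inject_anomaly(img, spec, np.random.default_rng(0))


@pytest.fixture(scope="module")
def dataset(tmp_path_factory):
    root = tmp_path_factory.mktemp("ds")
    phantom = PhantomConfig(side=32)
    spec = AnomalySpec(diameter_range=(6.0, 16.0))
    manifest = make_dataset(root, 4, 2, 2, phantom, spec, seed=5)
    return root, manifest


class TestMakeDataset:
    def test_counts_and_balance(self, dataset):
        root, manifest = dataset
        assert len(manifest) == 4 + 2 * 2 + 2 * 2
        by = manifest.groupby(["split", "label"]).size()
        assert by[("train", 0)] == 4
        assert by[("val", 0)] == by[("val", 1)] == 2
        assert by[("test", 0)] == by[("test", 1)] == 2
        for fn in manifest["filename"]:
            assert (root / fn).exists()

    def test_seed_partition_disjoint(self, dataset):
        _, manifest = dataset
        assert manifest["image_seed"].is_unique

    def test_regeneration_is_bit_identical(self, dataset, tmp_path):
        root, manifest = dataset
        phantom = PhantomConfig(side=32)
        spec = AnomalySpec(diameter_range=(6.0, 16.0))
        m2 = make_dataset(tmp_path, 4, 2, 2, phantom, spec, seed=5)
        pd.testing.assert_frame_equal(manifest, m2)
        for fn in manifest["filename"]:
            assert np.array_equal(load_image(root / fn), load_image(tmp_path / fn))

    def test_anomaly_sizes_span_multiple_patch_scales(self, dataset):
        _, manifest = dataset
        d = manifest.loc[manifest["label"] == 1, "diameter"]
        # diameters straddle the 8-px patch scale of a 32-px image
        assert d.min() < 8.0 < d.max()

    def test_load_split_roundtrip(self, dataset):
        root, _ = dataset
        triples = load_split(root, "val", label=1)
        assert len(triples) == 2
        ids, imgs, labels = zip(*triples)
        assert all(l == 1 for l in labels)
        assert all(img.max() <= WHITE_LEVEL for img in imgs)

    def test_invalid_counts_rejected(self, tmp_path):
        with pytest.raises(InvalidInputError):
            make_dataset(tmp_path, 0, 1, 1)
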