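import numpy as np
import pytest

from patchscreen import SSLConfig, augment_pair, embed, nt_xent_loss, train_encoder
from patchscreen.exceptions import (
    ConfigurationError,
    InvalidInputError,
    UndefinedSimilarityError,
)
from patchscreen.ssl_encoder import (
    MLPNet,
    embed_batch,
    load_encoder,
    nt_xent_loss_and_grad,
    save_encoder,
)


def brute_force_nt_xent(Z, pairing, tau):
    """Independent term-by-term evaluation of the contrastive loss."""
    Z = np.asarray(Z, dtype=float)
    m = len(Z)
    U = Z / np.linalg.norm(Z, axis=1, keepdims=True)
    total = 0.0
    for i in range(m):
        j = pairing[i]
        num = np.exp(U[i] @ U[j] / tau)
        den = sum(np.exp(U[i] @ U[k] / tau) for k in range(m) if k != i)
        total += -np.log(num / den)
    return total / m


def simclr_pairing(n_pairs):
    return np.concatenate([np.arange(n_pairs, 2 * n_pairs), np.arange(n_pairs)])


class TestNTXent:
    def test_single_pair_has_zero_loss(self, rng):
        for tau in (0.1, 0.5, 2.0):
            Z = rng.normal(size=(2, 5))
            assert nt_xent_loss(Z, [1, 0], tau) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("n_pairs", [2, 4, 8])
    def test_matches_brute_force_oracle(self, n_pairs, rng):
        pairing = simclr_pairing(n_pairs)
        for _ in range(10):
            Z = rng.normal(size=(2 * n_pairs, 3))
            tau = float(rng.uniform(0.1, 2.0))
            assert nt_xent_loss(Z, pairing, tau) == pytest.approx(
                brute_force_nt_xent(Z, pairing, tau), abs=1e-6
            )

    def test_frozen_hand_batch(self):
        # 2N=4 batch of fixed 3-d vectors; expected value frozen from the
        # brute-force oracle above
        Z = np.array(
            [[1.0, 0.0, 0.0], [0.9, 0.1, 0.0], [0.0, 1.0, 0.0], [-0.1, 0.9, 0.2]]
        )
        pairing = [1, 0, 3, 2]
        expected = brute_force_nt_xent(Z, pairing, 0.5)
        assert nt_xent_loss(Z, pairing, 0.5) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.2499032, abs=1e-6)

    def test_high_temperature_limit_is_log_2n_minus_1(self, rng):
        for n_pairs in (2, 4, 8):
            Z = rng.normal(size=(2 * n_pairs, 6))
            loss = nt_xent_loss(Z, simclr_pairing(n_pairs), 1e6)
            assert loss == pytest.approx(np.log(2 * n_pairs - 1), abs=1e-3)

    def test_invariant_to_common_rescaling(self, rng):
        Z = rng.normal(size=(8, 4))
        pairing = simclr_pairing(4)
        base = nt_xent_loss(Z, pairing, 0.5)
        for c in (1e-3, 7.0, 1e4):
            assert nt_xent_loss(c * Z, pairing, 0.5) == pytest.approx(base, rel=1e-12)

    def test_loss_decreases_as_positive_alignment_improves(self):
        # rotate one positive toward its partner, negatives fixed
        neg = np.array([[0.0, 0.0, 1.0], [0.0, 1.0, 1.0]])
        pairing = [1, 0, 3, 2]
        losses = []
        for angle in (np.pi / 2, np.pi / 4, np.pi / 16):
            zi = np.array([1.0, 0.0, 0.0])
            zj = np.array([np.cos(angle), np.sin(angle), 0.0])
            losses.append(nt_xent_loss(np.vstack([zi, zj, neg]), pairing, 0.5))
        assert losses[0] > losses[1] > losses[2]

    def test_zero_norm_projection_rejected(self):
        Z = np.array([[0.0, 0.0], [1.0, 0.0]])
        with pytest.raises(UndefinedSimilarityError):
            nt_xent_loss(Z, [1, 0], 0.5)

    def test_nonpositive_temperature_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            nt_xent_loss(rng.normal(size=(4, 3)), [1, 0, 3, 2], 0.0)

    def test_invalid_pairing_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            nt_xent_loss(rng.normal(size=(4, 3)), [0, 1, 2, 3], 0.5)

    def test_analytic_gradient_matches_finite_differences(self, rng):
        Z = rng.normal(size=(6, 4))
        pairing = simclr_pairing(3)
        _, grad = nt_xent_loss_and_grad(Z, pairing, 0.7)
        eps = 1e-6
        for i, j in [(0, 0), (2, 3), (5, 1)]:
            zp, zm = Z.copy(), Z.copy()
            zp[i, j] += eps
            zm[i, j] -= eps
            num = (
                brute_force_nt_xent(zp, pairing, 0.7)
                - brute_force_nt_xent(zm, pairing, 0.7)
            ) / (2 * eps)
            assert grad[i, j] == pytest.approx(num, abs=1e-7)


class TestAugmentations:
    def test_identity_augmentation(self, rng):
        cfg = SSLConfig(crop_fraction=1.0, rotation_deg=0.0)
        patch = rng.uniform(size=(16, 16))
        a, b = augment_pair(patch, cfg, rng)
        assert np.array_equal(a, patch) and np.array_equal(b, patch)

    def test_views_keep_patch_size_and_are_reproducible(self):
        cfg = SSLConfig(crop_fraction=0.5, rotation_deg=5.0)
        patch = np.random.default_rng(3).uniform(size=(32, 32))
        a1, b1 = augment_pair(patch, cfg, np.random.default_rng(11))
        a2, b2 = augment_pair(patch, cfg, np.random.default_rng(11))
        assert a1.shape == b1.shape == (32, 32)
        assert np.array_equal(a1, a2) and np.array_equal(b1, b2)
        assert not np.array_equal(a1, b1)  # two independent draws

    def test_degenerate_single_pixel_patch(self, rng):
        a, b = augment_pair(np.array([[0.5]]), SSLConfig(), rng)
        assert a.shape == b.shape == (1, 1)


class TestTraining:
    def test_loss_curve_recorded_and_decreases(self, tiny_ssl_config, rng):
        # structured patches (two clusters) so there is signal to learn
        patches = [
            rng.normal(loc=(i % 2) * 0.8, scale=0.05, size=(8, 8)) for i in range(32)
        ]
        from dataclasses import replace

        cfg = replace(tiny_ssl_config, epochs=5)
        state = train_encoder(patches, cfg)
        assert len(state.loss_curve) == 5
        assert state.loss_curve[-1] <= state.loss_curve[0]

    def test_training_is_deterministic(self, tiny_ssl_config, rng):
        patches = [rng.uniform(size=(8, 8)) for _ in range(16)]
        s1 = train_encoder(patches, tiny_ssl_config)
        s2 = train_encoder(patches, tiny_ssl_config)
        assert np.array_equal(s1.loss_curve, s2.loss_curve)
        for k in s1.params:
            assert np.array_equal(s1.params[k], s2.params[k])

    def test_single_pair_batches_train_at_zero_loss(self, rng):
        cfg = SSLConfig(
            batch_pairs=1, epochs=2, patches_per_epoch=2, feature_dim=4,
            projection_dim=4, hidden_dim=8, pool_side=4, input_scale=1.0, seed=0,
        )
        state = train_encoder([rng.uniform(size=(4, 4)) for _ in range(2)], cfg)
        assert np.allclose(state.loss_curve, 0.0, atol=1e-12)

    def test_empty_input_rejected(self, tiny_ssl_config):
        with pytest.raises(InvalidInputError):
            train_encoder([], tiny_ssl_config)

    def test_mixed_sizes_rejected(self, tiny_ssl_config, rng):
        with pytest.raises(InvalidInputError):
            train_encoder([rng.uniform(size=(8, 8)), rng.uniform(size=(4, 4))], tiny_ssl_config)


class TestEmbedding:
    def test_embed_is_deterministic_with_declared_dim(self, tiny_ssl_config, rng):
        patches = [rng.uniform(size=(8, 8)) for _ in range(8)]
        state = train_encoder(patches, tiny_ssl_config)
        h1 = embed(patches[0], state)
        h2 = embed(patches[0], state)
        assert np.array_equal(h1, h2)
        assert h1.shape == (tiny_ssl_config.feature_dim,)

    def test_embed_batch_matches_single(self, tiny_ssl_config, rng):
        patches = [rng.uniform(size=(8, 8)) for _ in range(4)]
        state = train_encoder(patches, tiny_ssl_config)
        H = embed_batch(patches, state)
        for i, p in enumerate(patches):
            assert np.allclose(H[i], embed(p, state))

    def test_size_mismatch_rejected(self, tiny_ssl_config, rng):
        state = train_encoder([rng.uniform(size=(8, 8))], tiny_ssl_config)
        with pytest.raises(InvalidInputError):
            embed(rng.uniform(size=(16, 16)), state)

    def test_checkpoint_roundtrip(self, tiny_ssl_config, rng, tmp_path):
        patches = [rng.uniform(size=(8, 8)) for _ in range(8)]
        state = train_encoder(patches, tiny_ssl_config)
        save_encoder(state, tmp_path / "enc.npz")
        back = load_encoder(tmp_path / "enc.npz")
        assert back.config == state.config
        assert back.checksum() == state.checksum()
        assert np.array_equal(embed(patches[0], back), embed(patches[0], state))


def test_invalid_config_rejected():
    with pytest.raises(ConfigurationError):
        SSLConfig(temperature=-1.0)
    with pytest.raises(ConfigurationError):
        SSLConfig(crop_fraction=0.0)
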