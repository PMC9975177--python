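"""Self-supervised contrastive patch encoders (one per patch resolution).

Each patch resolution gets its own feature extractor trained with the
SimCLR recipe on normal patches only: two stochastic views of every patch
(random crop retaining a fixed fraction of the area, then a small random
rotation) are pushed through an encoder ``f`` and a projection head ``g``,
and the NT-Xent loss pulls the two views of the same patch together while
pushing apart views of other patches in the mini-batch.  After training the
projection head is discarded and ``h = f(x)`` is the feature stored in the
reference database.

The backbone here is a deliberately small, CPU-friendly network written in
NumPy with explicit backpropagation: patches are average-pooled to a fixed
``pool_side`` x ``pool_side`` raster, flattened, and passed through a
two-layer MLP to the feature vector ``h``, with a further two-layer MLP as
the projection head producing ``z``.  The training loop is backbone-agnostic
(any object implementing :class:`ContrastiveNet`'s interface can be
substituted), so a larger encoder can stand in without touching the rest of
the pipeline.  A "paper profile" for the full-scale setting (ResNet-50
backbone, ``h`` of 2048, ``z`` of 128, LARS at lr 4.8, batch 256, 100
epochs) is recorded in :data:`PAPER_PROFILE` for reference; it is not
runnable on a single CPU and is not the default.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import rotate as _nd_rotate
from skimage.transform import resize as _sk_resize

from .exceptions import (
    ConfigurationError,
    InvalidInputError,
    UndefinedSimilarityError,
)
from .patch_grid import Patch

__all__ = [
    "SSLConfig",
    "EncoderState",
    "PAPER_PROFILE",
    "augment_pair",
    "nt_xent_loss",
    "nt_xent_loss_and_grad",
    "train_encoder",
    "embed",
    "embed_batch",
    "save_encoder",
    "load_encoder",
]

_CHECKPOINT_VERSION = "patchscreen-encoder-1"


@dataclass(frozen=True)
class SSLConfig:
    """Hyper-parameters for contrastive training of one patch encoder.

    Defaults are the desk-scale profile: small enough that four encoders
    train in minutes on one CPU while still producing discriminative
    features on phantom data.

    Parameters
    ----------
    temperature : float
        NT-Xent temperature tau (> 0).
    batch_pairs : int
        Number of patches N per mini-batch; each contributes two views,
        so the contrastive batch holds 2N projections.
    epochs : int
        Passes over the (sub-sampled) patch collection.
    crop_fraction : float
        Fraction of patch *area* retained by the random crop; the crop is
        resized back to the patch size. 1.0 disables cropping.
    rotation_deg : float
        Views are rotated by an angle drawn uniformly in +-rotation_deg.
    feature_dim : int
        Dimension of the encoder output ``h`` kept after training.
    projection_dim : int
        Dimension of the projection ``z`` used only inside the loss.
    hidden_dim : int
        Width of the hidden layers in backbone and head.
    pool_side : int
        Patches are average-pooled/resized to this raster before the MLP.
    input_scale : float
        Pixel intensities are divided by this constant inside the network
        (16-bit white level by default); image files themselves are never
        rescaled.
    learning_rate : float
        Adam learning rate, decayed with a cosine schedule to 0.
    patches_per_epoch : int | None
        If set, at most this many patches are sampled (without replacement)
        per epoch; None uses every patch each epoch.
    seed : int
        Seed for augmentation sampling, batching and weight init.
    """

    temperature: float = 0.5
    batch_pairs: int = 64
    epochs: int = 6
    crop_fraction: float = 0.5
    rotation_deg: float = 5.0
    feature_dim: int = 64
    projection_dim: int = 32
    hidden_dim: int = 128
    pool_side: int = 16
    input_scale: float = 65535.0
    learning_rate: float = 1e-3
    patches_per_epoch: int | None = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ConfigurationError("temperature must be > 0")
        if self.batch_pairs < 1:
            raise ConfigurationError("batch_pairs must be >= 1")
        if not (0 < self.crop_fraction <= 1):
            raise ConfigurationError("crop_fraction must be in (0, 1]")
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")


#: Full-scale configuration mirroring the published training setup; kept for
#: provenance/fidelity, not runnable at desk scale.
PAPER_PROFILE = {
    "backbone": "resnet50",
    "feature_dim": 2048,
    "projection_dim": 128,
    "optimizer": "LARS",
    "learning_rate": 4.8,
    "weight_decay": 1e-6,
    "batch_pairs": 256,
    "epochs": 100,
    "crop_fraction": 0.5,
    "rotation_deg": 5.0,
    "image_side": 1024,
    "patch_sizes": (128, 256, 512, 1024),
}


# ---------------------------------------------------------------------------
# Augmentations
# ---------------------------------------------------------------------------

def _random_view(pixels: np.ndarray, config: SSLConfig, rng: np.random.Generator) -> np.ndarray:
    s = pixels.shape[0]
    crop_side = max(1, int(round(s * np.sqrt(config.crop_fraction))))
    crop_side = min(crop_side, s)
    r0 = int(rng.integers(0, s - crop_side + 1))
    c0 = int(rng.integers(0, s - crop_side + 1))
    angle = float(rng.uniform(-config.rotation_deg, config.rotation_deg))
    view = pixels[r0:r0 + crop_side, c0:c0 + crop_side]
    if crop_side != s:
        view = _sk_resize(
            view, (s, s), order=1, mode="edge",
            anti_aliasing=False, preserve_range=True,
        )
    else:
        view = view.astype(np.float64, copy=True)
    if angle != 0.0 and s > 1:
        view = _nd_rotate(view, angle, reshape=False, order=1, mode="nearest")
    return np.asarray(view, dtype=np.float64)


def augment_pair(
    patch: Patch | np.ndarray,
    config: SSLConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw two independent stochastic views of one patch.

    With ``crop_fraction=1`` and ``rotation_deg=0`` both views equal the
    input exactly; a degenerate 1x1 patch yields two copies.
    """
    pixels = patch.pixels if isinstance(patch, Patch) else np.asarray(patch)
    if pixels.size == 0:
        raise InvalidInputError("empty patch")
    return _random_view(pixels, config, rng), _random_view(pixels, config, rng)


# ---------------------------------------------------------------------------
# NT-Xent loss
# ---------------------------------------------------------------------------

def _validate_pairing(pairing: np.ndarray, m: int) -> np.ndarray:
    pairing = np.asarray(pairing, dtype=int)
    if pairing.shape != (m,):
        raise InvalidInputError(f"pairing must have length {m}")
    if np.any(pairing == np.arange(m)) or np.any(pairing[pairing] != np.arange(m)):
        raise InvalidInputError("pairing must be a perfect matching without fixed points")
    return pairing


def nt_xent_loss_and_grad(
    projections: np.ndarray,
    positive_pairing: Sequence[int],
    temperature: float,
) -> tuple[float, np.ndarray]:
    """NT-Xent loss and its gradient with respect to the raw projections.

    For each of the 2N ordered positives (i, j) the per-term loss is

        l_ij = -log( exp(cos(z_i, z_j)/tau) / sum_{k != i} exp(cos(z_i, z_k)/tau) )

    and the batch loss is the mean of all 2N terms. The gradient is taken
    through the cosine normalization, so callers can feed unnormalized
    projection-head outputs directly.
    """
    Z = np.asarray(projections, dtype=np.float64)
    if Z.ndim != 2 or Z.shape[0] < 2 or Z.shape[0] % 2 != 0:
        raise InvalidInputError("projections must be a (2N, D) array with N >= 1")
    if temperature <= 0:
        raise InvalidInputError("temperature must be > 0")
    m = Z.shape[0]
    pairing = _validate_pairing(np.asarray(positive_pairing), m)

    norms = np.linalg.norm(Z, axis=1)
    if np.any(norms == 0) or not np.all(np.isfinite(Z)):
        raise UndefinedSimilarityError("zero-norm or non-finite projection vector")
    U = Z / norms[:, None]
    sims = U @ U.T
    logits = sims / temperature
    np.fill_diagonal(logits, -np.inf)

    row_max = logits.max(axis=1)
    exp_shift = np.exp(logits - row_max[:, None])
    denom = exp_shift.sum(axis=1)
    log_probs = logits - (row_max + np.log(denom))[:, None]
    loss = float(-log_probs[np.arange(m), pairing].mean())

    # softmax over k != i, minus the one-hot positive, averaged over 2N rows
    P = exp_shift / denom[:, None]
    G = P.copy()
    G[np.arange(m), pairing] -= 1.0
    G /= m * temperature
    dU = (G + G.T) @ U
    dZ = (dU - (np.sum(dU * U, axis=1))[:, None] * U) / norms[:, None]
    return loss, dZ


def nt_xent_loss(
    projections: np.ndarray,
    positive_pairing: Sequence[int],
    temperature: float,
) -> float:
    """Batch-mean normalized temperature-scaled cross-entropy loss."""
    loss, _ = nt_xent_loss_and_grad(projections, positive_pairing, temperature)
    return loss


# ---------------------------------------------------------------------------
# Backbone: pooled-pixel MLP with explicit backprop
# ---------------------------------------------------------------------------

class ContrastiveNet:
    """Minimal trainable encoder+head interface.

    Alternative backbones implement ``init_params``, ``features``,
    ``forward`` and ``backward`` with the same signatures; ``params`` is a
    flat name->array dict so checkpointing and Adam stay generic.
    """

    @staticmethod
    def init_params(config: SSLConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
        raise NotImplementedError

    @staticmethod
    def features(params: dict[str, np.ndarray], X: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class MLPNet(ContrastiveNet):
    """Two-layer MLP backbone + two-layer projection head on pooled pixels."""

    @staticmethod
    def init_params(config: SSLConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
        d_in = config.pool_side ** 2
        h, f, p = config.hidden_dim, config.feature_dim, config.projection_dim

        def he(n_in, n_out):
            return rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))

        return {
            "W1": he(d_in, h), "b1": np.zeros(h),
            "W2": he(h, f), "b2": np.zeros(f),
            "P1": he(f, h), "pb1": np.zeros(h),
            "P2": he(h, p), "pb2": np.zeros(p),
        }

    @staticmethod
    def features(params: dict[str, np.ndarray], X: np.ndarray) -> np.ndarray:
        A1 = np.maximum(X @ params["W1"] + params["b1"], 0.0)
        return A1 @ params["W2"] + params["b2"]

    @staticmethod
    def forward(params: dict[str, np.ndarray], X: np.ndarray):
        A1 = np.maximum(X @ params["W1"] + params["b1"], 0.0)
        H = A1 @ params["W2"] + params["b2"]
        B1 = np.maximum(H @ params["P1"] + params["pb1"], 0.0)
        Z = B1 @ params["P2"] + params["pb2"]
        return Z, (X, A1, H, B1)

    @staticmethod
    def backward(params, cache, dZ) -> dict[str, np.ndarray]:
        X, A1, H, B1 = cache
        grads: dict[str, np.ndarray] = {}
        grads["P2"] = B1.T @ dZ
        grads["pb2"] = dZ.sum(axis=0)
        dB1 = (dZ @ params["P2"].T) * (B1 > 0)
        grads["P1"] = H.T @ dB1
        grads["pb1"] = dB1.sum(axis=0)
        dH = dB1 @ params["P1"].T
        grads["W2"] = A1.T @ dH
        grads["b2"] = dH.sum(axis=0)
        dA1 = (dH @ params["W2"].T) * (A1 > 0)
        grads["W1"] = X.T @ dA1
        grads["b1"] = dA1.sum(axis=0)
        return grads


def _pool_patch(pixels: np.ndarray, pool_side: int) -> np.ndarray:
    """Reduce a square patch to a fixed pool_side raster (block mean when
    the sizes are commensurate, bilinear resize otherwise)."""
    s = pixels.shape[0]
    if s == pool_side:
        return np.asarray(pixels, dtype=np.float64)
    if s % pool_side == 0:
        k = s // pool_side
        return (
            pixels.reshape(pool_side, k, pool_side, k)
            .mean(axis=(1, 3))
            .astype(np.float64)
        )
    return _sk_resize(
        np.asarray(pixels, dtype=np.float64), (pool_side, pool_side),
        order=1, mode="edge", anti_aliasing=False, preserve_range=True,
    )


def _views_to_input(views: list[np.ndarray], config: SSLConfig) -> np.ndarray:
    X = np.stack([_pool_patch(v, config.pool_side).ravel() for v in views])
    return X / config.input_scale


# ---------------------------------------------------------------------------
# Encoder state and training
# ---------------------------------------------------------------------------

@dataclass
class EncoderState:
    """A trained (or freshly initialized) per-resolution encoder.

    Only the backbone ``f`` is used for embedding; the projection-head
    parameters are retained in ``params`` purely as training metadata.
    """

    patch_size: int
    config: SSLConfig
    params: dict[str, np.ndarray]
    loss_curve: np.ndarray = field(default_factory=lambda: np.empty(0))
    version: str = _CHECKPOINT_VERSION

    def checksum(self) -> str:
        import hashlib

        digest = hashlib.sha256()
        digest.update(json.dumps(asdict(self.config), sort_keys=True).encode())
        digest.update(str(self.patch_size).encode())
        for name in sorted(self.params):
            digest.update(name.encode())
            digest.update(np.ascontiguousarray(self.params[name]).tobytes())
        return digest.hexdigest()


def train_encoder(
    patches: Sequence[Patch | np.ndarray],
    config: SSLConfig,
    net: type[MLPNet] = MLPNet,
) -> EncoderState:
    """Train one contrastive encoder on a collection of same-size patches.

    Fully deterministic under ``config.seed``: the recorded per-epoch mean
    loss curve is bit-identical across runs on the same machine.
    """
    if len(patches) == 0:
        raise InvalidInputError("no patches to train on")
    pixel_blocks = [
        p.pixels if isinstance(p, Patch) else np.asarray(p, dtype=np.float64)
        for p in patches
    ]
    sizes = {b.shape[0] for b in pixel_blocks}
    if len(sizes) != 1 or any(b.ndim != 2 or b.shape[0] != b.shape[1] for b in pixel_blocks):
        raise InvalidInputError("all patches must be square and share one size")
    patch_size = sizes.pop()

    rng = np.random.default_rng(config.seed)
    params = net.init_params(config, rng)
    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(v_) for k, v_ in params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    n = len(pixel_blocks)
    per_epoch = n if config.patches_per_epoch is None else min(n, config.patches_per_epoch)
    n_batches = max(1, int(np.ceil(per_epoch / config.batch_pairs)))
    total_steps = config.epochs * n_batches
    step = 0
    curve = np.empty(config.epochs)

    for epoch in range(config.epochs):
        order = rng.permutation(n)[:per_epoch]
        epoch_losses = []
        for start in range(0, per_epoch, config.batch_pairs):
            idx = order[start:start + config.batch_pairs]
            views_a, views_b = [], []
            for i in idx:
                a, b = augment_pair(pixel_blocks[i], config, rng)
                views_a.append(a)
                views_b.append(b)
            X = _views_to_input(views_a + views_b, config)
            k = len(idx)
            pairing = np.concatenate([np.arange(k, 2 * k), np.arange(0, k)])

            Z, cache = net.forward(params, X)
            loss, dZ = nt_xent_loss_and_grad(Z, pairing, config.temperature)
            grads = net.backward(params, cache, dZ)

            # Adam with cosine-decayed learning rate
            lr = config.learning_rate * 0.5 * (1.0 + np.cos(np.pi * step / max(1, total_steps)))
            step += 1
            for name in params:
                g = grads[name]
                m[name] = beta1 * m[name] + (1 - beta1) * g
                v[name] = beta2 * v[name] + (1 - beta2) * g * g
                mhat = m[name] / (1 - beta1 ** step)
                vhat = v[name] / (1 - beta2 ** step)
                params[name] -= lr * mhat / (np.sqrt(vhat) + eps)
            epoch_losses.append(loss)
        curve[epoch] = float(np.mean(epoch_losses))

    return EncoderState(
        patch_size=patch_size,
        config=config,
        params=params,
        loss_curve=curve,
    )


def embed(patch: Patch | np.ndarray, state: EncoderState) -> np.ndarray:
    """Embed one patch with the trained backbone ``f`` (head discarded)."""
    pixels = patch.pixels if isinstance(patch, Patch) else np.asarray(patch)
    if pixels.shape != (state.patch_size, state.patch_size):
        raise InvalidInputError(
            f"patch shape {pixels.shape} does not match encoder size "
            f"{state.patch_size}"
        )
    X = _views_to_input([pixels], state.config)
    return MLPNet.features(state.params, X)[0]


def embed_batch(patches: Sequence[Patch | np.ndarray], state: EncoderState) -> np.ndarray:
    """Embed many same-size patches in one forward pass; rows follow input order."""
    blocks = [p.pixels if isinstance(p, Patch) else np.asarray(p) for p in patches]
    for b in blocks:
        if b.shape != (state.patch_size, state.patch_size):
            raise InvalidInputError("patch size mismatch in embed_batch")
    X = _views_to_input(blocks, state.config)
    return MLPNet.features(state.params, X)


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_encoder(state: EncoderState, path: str | Path) -> None:
    """Serialize a checkpoint (versioned ``.npz`` with embedded config)."""
    payload = {f"param_{k}": v for k, v in state.params.items()}
    payload["loss_curve"] = state.loss_curve
    meta = {
        "version": state.version,
        "patch_size": state.patch_size,
        "config": asdict(state.config),
    }
    payload["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(Path(path), **payload)


def load_encoder(path: str | Path) -> EncoderState:
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["meta_json"]).decode())
        if meta["version"] != _CHECKPOINT_VERSION:
            raise ConfigurationError(
                f"unsupported checkpoint version {meta['version']!r}"
            )
        params = {
            k[len("param_"):]: data[k] for k in data.files if k.startswith("param_")
        }
        return EncoderState(
            patch_size=int(meta["patch_size"]),
            config=SSLConfig(**meta["config"]),
            params=params,
            loss_curve=data["loss_curve"].copy(),
        )


def export_loss_curve(state: EncoderState, path: str | Path) -> None:
    """Write the training curve as CSV (epoch, mean_loss)."""
    import pandas as pd

    pd.DataFrame(
        {"epoch": np.arange(1, len(state.loss_curve) + 1), "mean_loss": state.loss_curve}
    ).to_csv(Path(path), index=False)
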