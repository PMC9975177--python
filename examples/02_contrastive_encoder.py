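"""Train one contrastive patch encoder and inspect the NT-Xent loss.

Tiles phantom images into 32-px patches, trains the SimCLR-style encoder
for that resolution, and embeds two patches. The loss curve should
decrease; embeddings are deterministic, and the projection head plays no
role after training.
"""

import numpy as np

from patchscreen import (
    PatchSpec,
    PhantomConfig,
    SSLConfig,
    embed,
    generate_normal,
    nt_xent_loss,
    tile_image,
    train_encoder,
)

rng = np.random.default_rng(0)
phantom = PhantomConfig()
patches = []
for _ in range(10):
    img = generate_normal(phantom, rng) * 65535.0  # 16-bit scale, as stored on disk
    patches.extend(tile_image(img, PatchSpec(size_px=32, image_side_px=128)))

config = SSLConfig(epochs=4, batch_pairs=32, patches_per_epoch=128, seed=0)
state = train_encoder(patches, config)

print(f"trained on            : {len(patches)} patches of 32 px")
print("loss curve            :", np.array2string(state.loss_curve, precision=3))
h = embed(patches[0], state)
print(f"feature vector h      : dim {h.shape[0]}, first entries {np.round(h[:4], 3)}")
print(f"re-embedding identical: {np.array_equal(h, embed(patches[0], state))}")

# NT-Xent behaviour on hand-made projections: a single pair has no
# negatives (loss 0); at huge temperature the loss approaches log(2N-1).
z = rng.normal(size=(8, 16))
pairing = np.r_[np.arange(4, 8), np.arange(0, 4)]
print(f"single-pair loss      : {nt_xent_loss(z[:2], [1, 0], 0.5):.4f}")
print(f"tau->inf loss         : {nt_xent_loss(z, pairing, 1e6):.4f} "
      f"(log(2N-1) = {np.log(7):.4f})")
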