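"""Build a reference database and score query patches with locality search.

Trains encoders at two resolutions on normal phantoms, stores every
normal patch embedding as (size, gx, gy, image id, h), and scores a
normal and an anomalous query image patch-by-patch. The anomalous patch
should be far from every reference in its Chebyshev neighborhood.
"""

import numpy as np

from patchscreen import (
    AnomalySpec,
    LocalityConfig,
    PatchSpec,
    PhantomConfig,
    SSLConfig,
    build_reference,
    generate_normal,
    inject_anomaly,
    neighborhood,
    patch_anomaly_score,
    tile_image,
    train_encoder,
)
from patchscreen.ssl_encoder import embed_batch

rng = np.random.default_rng(0)
phantom = PhantomConfig()
images = [(f"normal{i}", generate_normal(phantom, rng) * 65535.0) for i in range(12)]

specs = [PatchSpec(16, 128), PatchSpec(32, 128)]
ssl = SSLConfig(epochs=3, batch_pairs=32, patches_per_epoch=128)
encoders = {}
for spec in specs:
    patches = [p for _, img in images for p in tile_image(img, spec)]
    encoders[spec.size_px] = train_encoder(patches, ssl)

db = build_reference(images, encoders, specs)
print(f"records: {db.n_records(16)} at 16 px + {db.n_records(32)} at 32 px "
      f"= {db.n_records()} (12 images x (64 + 16) cells)")

locality = LocalityConfig(d_per_size={16: 2, 32: 1})
print(f"neighborhood sizes at 16 px, d=2: interior "
      f"{len(neighborhood(db, 16, 4, 4, 2))} records, corner "
      f"{len(neighborhood(db, 16, 0, 0, 2))} records (border clipped)")

query_normal = generate_normal(phantom, rng) * 65535.0
query_abnormal, mask, params = inject_anomaly(
    query_normal / 65535.0, AnomalySpec(diameter_range=(24.0, 24.0)), rng
)
query_abnormal *= 65535.0

# score the 16-px patch at the anomaly centre for both images
gx, gy = params[0]["cx"] // 16, params[0]["cy"] // 16
for name, img in [("normal", query_normal), ("abnormal", query_abnormal)]:
    patches = tile_image(img, specs[0])
    H = embed_batch(patches, encoders[16])
    idx = gy * 8 + gx
    s = patch_anomaly_score(H[idx], 16, gx, gy, db, "mahalanobis", locality)
    print(f"{name:9s} patch ({gx},{gy}): score {s.score:8.3f}  "
          f"best match {s.best_ref_image_id}")
# The anomalous patch scores far above its normal counterpart.
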