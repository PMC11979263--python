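"""Train a small dense autoencoder on vessel ROIs and score reconstructions.

The full-size models (AE64/AE128/AE256) compress a 35,014-value ROI through a
width-halving encoder to a 64/128/256-value latent code; here a scaled-down
configuration (4387 -> 256 -> 128 -> 64) is trained for a few epochs on a tiny
cohort, then reconstruction quality is scored with SSIM on held-out images.
"""

import numpy as np

from stenograde import CohortSpec, TrainConfig, count_params, generate_cohort
from stenograde.autoencoder import AEConfig, DenseAutoencoder, ssim
from stenograde.pipeline import roi_matrix
from stenograde.roi import extract_cohort_rois

for name in ("AE64", "AE128", "AE256"):
    print(f"{name}: {count_params(name, scope='encoder'):,} encoder parameters")

spec = CohortSpec(n_patients=6, image_rows=120, seed=5)
images, _ = generate_cohort(spec)
rois = extract_cohort_rois(images, target_rows=107)
x, index = roi_matrix(rois)

config = AEConfig(input_dim=x.shape[1], encoder_widths=(256, 128), latent_dim=64)
model = DenseAutoencoder(config, seed=0)
model.fit(x[:100], TrainConfig(max_epochs=20, batch_size=16, seed=0))
print(f"\ntrain loss {model.history['train_loss'][0]:.4f} -> "
      f"{model.history['train_loss'][-1]:.4f} over 20 epochs")

held_out = x[100:120]
xhat = model.reconstruct(held_out)
scores = [
    ssim(a.reshape(107, 41), b.reshape(107, 41)) for a, b in zip(held_out, xhat)
]
print(f"held-out SSIM: mean {np.mean(scores):.3f} "
      f"(1 = identical structure; the latent code is {x.shape[1] // 64}x smaller)")
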