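"""The training objective and the counting metrics.

The objective is L = LE + alpha * LSSIM (alpha = 0.001): a pixelwise
Euclidean term plus a structural-similarity term that pays attention to
the local arrangement of density mass, not just its pointwise values.
"""

import numpy as np

from frycount import (
    LossConfig,
    PointSet,
    combined_loss,
    euclidean_loss,
    gaussian_density,
    mae,
    rmse,
    ssim_index,
    ssim_loss,
)

rng = np.random.default_rng(0)
pts = np.column_stack([rng.uniform(5, 59, 30), rng.uniform(5, 59, 30)])
gt = gaussian_density(PointSet(pts, 64, 64)).grid
noisy = np.clip(gt + rng.normal(0, 0.002, gt.shape), 0, None)

print(f"SSIM(gt, gt)      = {ssim_index(gt, gt).item():.6f}")
print(f"SSIM(gt, noisy)   = {ssim_index(gt, noisy).item():.6f}")
print(f"LE(gt, noisy)     = {euclidean_loss(gt, noisy).item():.6f}")
print(f"LSSIM(gt, noisy)  = {ssim_loss(gt, noisy).item():.6f}")
total = combined_loss(gt, noisy, LossConfig(alpha=0.001))
print(f"L = LE + 0.001*LSSIM = {total.item():.6f}")

# counting metrics over (true, predicted) pairs; RMSE >= MAE always
pairs = [(30, 28), (120, 131), (44, 44), (250, 239)]
print(f"MAE  = {mae(pairs):.3f}")
print(f"RMSE = {rmse(pairs):.3f}")
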