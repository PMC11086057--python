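"""Training objective and counting metrics.

The objective is a pixelwise Euclidean loss plus an alpha-weighted
structural-similarity (SSIM) term, L = LE + alpha * LSSIM with
alpha = 0.001; evaluation uses MAE and RMSE over per-image counts.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field

import numpy as np

from .nn import Tensor, conv2d

__all__ = [
    "LossConfig",
    "euclidean_loss",
    "ssim_index",
    "ssim_loss",
    "combined_loss",
    "mae",
    "rmse",
    "EvalReport",
]


@dataclass
class LossConfig:
    """Hyperparameters of the combined objective.

    ``alpha`` balances the orders of magnitude of the two terms.  The SSIM
    stabilizers default to the standard (0.01*L)^2 and (0.03*L)^2 with a
    dynamic range L of 1, applied to density maps as-is.
    ``euclidean_reduction`` chooses between the sum-over-pixels,
    half-batch-mean convention ("sum_half_batch", the one a 1e-7 learning
    rate is calibrated against) and a plain per-pixel mean ("mean").
    ``ssim_windowed=False`` switches to a single global-statistics SSIM.
    """

    alpha: float = 0.001
    ssim_window: int = 11
    ssim_window_sigma: float = 1.5
    c1: float = 1e-4
    c2: float = 9e-4
    euclidean_reduction: str = "sum_half_batch"
    ssim_windowed: bool = True

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("c1 and c2 must be positive")
        if self.ssim_window < 3 or self.ssim_window % 2 == 0:
            raise ValueError("ssim_window must be odd and >= 3")
        if self.euclidean_reduction not in ("sum_half_batch", "mean"):
            raise ValueError("euclidean_reduction must be 'sum_half_batch' or 'mean'")


def _as_batch(x) -> Tensor:
    """Coerce ndarray/Tensor of shape (H,W), (B,H,W) or (B,1,H,W) to (B,1,H,W)."""
    t = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))
    if t.ndim == 2:
        t = t.reshape(1, 1, *t.shape)
    elif t.ndim == 3:
        t = t.reshape(t.shape[0], 1, t.shape[1], t.shape[2])
    elif t.ndim != 4:
        raise ValueError(f"expected a 2-D/3-D/4-D density array, got shape {t.shape}")
    return t


def euclidean_loss(pred, gt, cfg: LossConfig | None = None) -> Tensor:
    """Pixelwise squared-error loss.

    Default convention: (1 / 2B) * sum over the batch of the summed squared
    per-pixel differences.
    """
    cfg = cfg or LossConfig()
    p, g = _as_batch(pred), _as_batch(gt)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs gt {g.shape}")
    sq = (p - g) ** 2.0
    if cfg.euclidean_reduction == "mean":
        return sq.mean()
    return sq.sum() * (0.5 / p.shape[0])


def _gaussian_window_1d(size: int, sigma: float, dtype) -> np.ndarray:
    r = size // 2
    g = np.exp(-0.5 * ((np.arange(size) - r) / sigma) ** 2)
    g /= g.sum()
    return g.astype(dtype)


def _window_filter(t: Tensor, size: int, sigma: float) -> Tensor:
    """Valid-region Gaussian-window local mean, applied separably."""
    g = _gaussian_window_1d(size, sigma, t.data.dtype)
    t = conv2d(t, Tensor(g.reshape(1, 1, size, 1)))
    return conv2d(t, Tensor(g.reshape(1, 1, 1, size)))


def ssim_index(pred, gt, cfg: LossConfig | None = None) -> Tensor:
    """Mean structural similarity between two (batches of) density maps.

    Local means, variances and covariance are taken under a Gaussian window
    (valid region only, so border pixels never mix with out-of-image zeros);
    the per-pixel index

        SSIM = (2 mu_p mu_g + c1)(2 cov_pg + c2)
               / ((mu_p^2 + mu_g^2 + c1)(var_p + var_g + c2))

    is averaged over pixels and batch.  With ``ssim_windowed=False`` the
    statistics are global (one SSIM value per image).
    """
    cfg = cfg or LossConfig()
    p, g = _as_batch(pred), _as_batch(gt)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs gt {g.shape}")
    c1, c2 = cfg.c1, cfg.c2
    if cfg.ssim_windowed:
        if cfg.ssim_window > min(p.shape[2], p.shape[3]):
            raise ValueError(
                f"SSIM window {cfg.ssim_window} exceeds image size {p.shape[2]}x{p.shape[3]}"
            )
        k, s = cfg.ssim_window, cfg.ssim_window_sigma
        mu_p = _window_filter(p, k, s)
        mu_g = _window_filter(g, k, s)
        e_pp = _window_filter(p * p, k, s)
        e_gg = _window_filter(g * g, k, s)
        e_pg = _window_filter(p * g, k, s)
    else:
        mu_p = p.mean(axis=(2, 3), keepdims=True)
        mu_g = g.mean(axis=(2, 3), keepdims=True)
        e_pp = (p * p).mean(axis=(2, 3), keepdims=True)
        e_gg = (g * g).mean(axis=(2, 3), keepdims=True)
        e_pg = (p * g).mean(axis=(2, 3), keepdims=True)
    var_p = e_pp - mu_p * mu_p
    var_g = e_gg - mu_g * mu_g
    cov = e_pg - mu_p * mu_g
    num = (2.0 * mu_p * mu_g + c1) * (2.0 * cov + c2)
    den = (mu_p * mu_p + mu_g * mu_g + c1) * (var_p + var_g + c2)
    return (num / den).mean()


def ssim_loss(pred, gt, cfg: LossConfig | None = None) -> Tensor:
    """LSSIM = 1 - mean SSIM; 0 for identical maps, at most 2."""
    return 1.0 - ssim_index(pred, gt, cfg)


def combined_loss(pred, gt, cfg: LossConfig | None = None) -> Tensor:
    """L = LE + alpha * LSSIM."""
    cfg = cfg or LossConfig()
    total = euclidean_loss(pred, gt, cfg)
    if cfg.alpha > 0:
        total = total + cfg.alpha * ssim_loss(pred, gt, cfg)
    return total


# -- counting metrics ------------------------------------------------------


def _errors(pairs) -> np.ndarray:
    arr = np.asarray(list(pairs), dtype=float)
    if arr.size == 0:
        raise ValueError("metrics need at least one (true, predicted) pair")
    return arr[:, 0] - arr[:, 1]


def mae(pairs) -> float:
    """Mean absolute error of predicted counts: (1/N) sum |y_i - yhat_i|."""
    return float(np.abs(_errors(pairs)).mean())


def rmse(pairs) -> float:
    """Root-mean-square error: sqrt((1/N) sum (y_i - yhat_i)^2)."""
    return float(math.sqrt((_errors(pairs) ** 2).mean()))


@dataclass
class EvalReport:
    """Per-image counting results plus aggregate MAE/RMSE."""

    per_image: list[tuple[float, float, float]] = field(default_factory=list)
    mae: float = 0.0
    rmse: float = 0.0
    n_images: int = 0
    per_level: dict[str, dict[str, float]] | None = None

    @classmethod
    def from_pairs(cls, pairs, per_level: dict | None = None) -> "EvalReport":
        pairs = [(float(y), float(yh)) for y, yh in pairs]
        per_image = [(y, yh, abs(y - yh)) for y, yh in pairs]
        return cls(
            per_image=per_image,
            mae=mae(pairs),
            rmse=rmse(pairs),
            n_images=len(pairs),
            per_level=per_level,
        )

    def to_csv(self, path: str) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["true_count", "predicted_count", "absolute_error"])
            for y, yh, err in self.per_image:
                writer.writerow([f"{y:.6f}", f"{yh:.6f}", f"{err:.6f}"])

    def to_json(self, path: str | None = None) -> str:
        payload = {
            "mae": round(self.mae, 3),
            "rmse": round(self.rmse, 3),
            "n_images": self.n_images,
        }
        if self.per_level is not None:
            payload["per_level"] = self.per_level
        text = json.dumps(payload, indent=2)
        if path:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def summary(self) -> str:
        return f"MAE {self.mae:.3f}  RMSE {self.rmse:.3f}  (n={self.n_images})"
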