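"""Training and evaluation procedure.

Center-crop to the working resolution, 50%-probability mirror / 180-degree
rotation augmentation, SGD (momentum 0.95, weight decay 5e-4, learning rate
1e-7) minimizing the combined Euclidean+SSIM objective, per-epoch validation
MAE/RMSE from integrated counts, best-validation checkpointing, and
per-density-level evaluation reports.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import numpy as np

from .density import DensityMap, gaussian_density, integrate
from .losses import EvalReport, LossConfig, combined_loss
from .model import FryCountNet, model_forward
from .nn import SGD, Tensor
from .nn.layers import DTYPE
from .points import PointSet
from .synthetic import LEVELS

__all__ = [
    "TrainConfig",
    "History",
    "Sample",
    "DensityLevel",
    "center_crop",
    "augment",
    "fit",
    "predict_count",
    "evaluate",
    "assign_density_level",
    "make_samples",
]

log = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Optimizer recipe and data handling knobs.

    Defaults follow the reference training protocol: 300 epochs, batch 10,
    SGD with learning rate 1e-7, momentum 0.95, weight decay 5e-4,
    768 x 576 center crops, and independent 50% mirror / 180-degree
    rotation augmentation.
    """

    epochs: int = 300
    batch_size: int = 10
    learning_rate: float = 1e-7
    momentum: float = 0.95
    weight_decay: float = 5e-4
    optimizer: str = "sgd"
    flip_prob: float = 0.5
    rotate180_prob: float = 0.5
    crop_width: int = 768
    crop_height: int = 576
    seed: int = 42
    loss: LossConfig = field(default_factory=LossConfig)

    def __post_init__(self) -> None:
        for p in (self.flip_prob, self.rotate180_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("augmentation probabilities must be in [0, 1]")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0 and batch_size >= 1")
        if self.optimizer != "sgd":
            raise ValueError("only the 'sgd' optimizer is supported")
        if self.crop_width % 8 or self.crop_height % 8:
            raise ValueError("crop dimensions must be divisible by 8")


@dataclass
class History:
    """Per-epoch loss/metric trace; ``best_epoch`` minimizes validation MAE."""

    per_epoch: list[tuple[int, float, float, float]] = field(default_factory=list)
    best_epoch: int = -1

    def to_csv(self, path: str) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["epoch", "train_loss", "val_mae", "val_rmse"])
            for row in self.per_epoch:
                writer.writerow([row[0], f"{row[1]:.6g}", f"{row[2]:.6f}", f"{row[3]:.6f}"])


@dataclass
class Sample:
    """One annotated training/evaluation image."""

    image: np.ndarray  # H x W x 3 in [0, 1]
    density: np.ndarray  # H x W ground-truth density
    count: float  # true count (annotation count)
    points: PointSet | None = None


@dataclass
class DensityLevel:
    label: str
    range: tuple[int, int]


def assign_density_level(count: float) -> DensityLevel:
    """Bin a per-image count into Low/Medium/High/Higher.

    Counts above the top of the Higher range still map to Higher.
    """
    if count < 0:
        raise ValueError(f"count must be >= 0, got {count}")
    for label, (lo, hi) in LEVELS.items():
        if lo <= count <= hi:
            return DensityLevel(label, (lo, hi))
    return DensityLevel("Higher", LEVELS["Higher"])


def make_samples(dataset, sigma: float = 3.0) -> list[Sample]:
    """Build Samples from (image, PointSet) pairs by generating density maps."""
    out = []
    for img, ps in dataset:
        dm = gaussian_density(ps, sigma=sigma)
        out.append(Sample(image=img, density=dm.grid, count=float(ps.count()), points=ps))
    return out


def center_crop(
    image: np.ndarray, ps: PointSet | None = None, width: int = 768, height: int = 576
):
    """Crop the centered width x height window; shift/drop points with it.

    Odd remainders are split with floor offsets.  Points falling outside the
    window are dropped; survivors are shifted into crop coordinates.
    """
    h, w = image.shape[:2]
    if h < height or w < width:
        raise ValueError(f"image {w}x{h} is smaller than the {width}x{height} crop")
    ox = (w - width) // 2
    oy = (h - height) // 2
    cropped = image[oy : oy + height, ox : ox + width].copy()
    if ps is None:
        return cropped, None
    pts = ps.points
    keep = (
        (pts[:, 0] >= ox)
        & (pts[:, 0] < ox + width)
        & (pts[:, 1] >= oy)
        & (pts[:, 1] < oy + height)
    )
    new_ps = PointSet(pts[keep] - np.array([ox, oy]), width, height)
    return cropped, new_ps


def augment(
    image: np.ndarray,
    dm: DensityMap | np.ndarray,
    ps: PointSet | None,
    cfg: TrainConfig,
    rng: np.random.Generator,
):
    """Random mirror and 180-degree rotation, applied consistently.

    Each transform fires independently with its configured probability;
    image, density map and points receive the identical permutation of
    cells, so the annotated count is exactly invariant.
    """
    grid = dm.grid if isinstance(dm, DensityMap) else np.asarray(dm)
    h, w = grid.shape
    pts = None if ps is None else ps.points.copy()
    if rng.random() < cfg.flip_prob:
        image = image[:, ::-1].copy()
        grid = grid[:, ::-1].copy()
        if pts is not None and len(pts):
            pts[:, 0] = (w - 1) - pts[:, 0]
    if rng.random() < cfg.rotate180_prob:
        image = image[::-1, ::-1].copy()
        grid = grid[::-1, ::-1].copy()
        if pts is not None and len(pts):
            pts[:, 0] = (w - 1) - pts[:, 0]
            pts[:, 1] = (h - 1) - pts[:, 1]
    out_dm = DensityMap(grid, sigma=dm.sigma) if isinstance(dm, DensityMap) else grid
    out_ps = None if ps is None else PointSet(np.clip(pts, 0, None), w, h)
    return image, out_dm, out_ps


def _validate(model: FryCountNet, val_set: list[Sample]) -> tuple[float, float]:
    errs = []
    for s in val_set:
        count, _ = predict_count(model, s.image)
        errs.append(s.count - count)
    errs = np.asarray(errs)
    return float(np.abs(errs).mean()), float(np.sqrt((errs**2).mean()))


def fit(
    model: FryCountNet,
    train_set: list[Sample],
    val_set: list[Sample],
    cfg: TrainConfig,
    progress: bool = False,
) -> tuple[FryCountNet, History]:
    """Train ``model`` in place; return it with its best-validation weights.

    Every epoch shuffles the training set, applies augmentation per sample,
    and steps SGD on the combined loss per mini-batch; validation MAE/RMSE
    are computed from integrated counts.  Fully determined by cfg.seed.
    """
    if cfg.epochs > 0 and not train_set:
        raise ValueError("empty training set")
    if cfg.epochs > 0 and cfg.batch_size > len(train_set):
        raise ValueError(
            f"batch_size {cfg.batch_size} exceeds the {len(train_set)}-image training set"
        )
    history = History()
    if cfg.epochs == 0:
        return model, history

    rng = np.random.default_rng(cfg.seed)
    opt = SGD(
        model.parameters(),
        lr=cfg.learning_rate,
        momentum=cfg.momentum,
        weight_decay=cfg.weight_decay,
    )
    best_mae = np.inf
    best_state = model.state_dict()
    n = len(train_set)
    iterator = range(cfg.epochs)
    if progress:
        from tqdm import tqdm

        iterator = tqdm(iterator, desc="epochs")
    for epoch in iterator:
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n - cfg.batch_size + 1, cfg.batch_size):
            batch = [train_set[i] for i in order[start : start + cfg.batch_size]]
            imgs, gts = [], []
            for s in batch:
                img, dmg, _ = augment(s.image, s.density, None, cfg, rng)
                imgs.append(img)
                gts.append(dmg)
            x = np.stack(imgs).astype(DTYPE)
            gt = Tensor(np.stack(gts)[:, None].astype(DTYPE))
            opt.zero_grad()
            pred = model.forward(x)
            loss = combined_loss(pred, gt, cfg.loss)
            loss.backward()
            opt.step()
            epoch_loss += loss.item()
            n_batches += 1
        train_loss = epoch_loss / max(n_batches, 1)
        if val_set:
            val_mae, val_rmse = _validate(model, val_set)
        else:
            val_mae = val_rmse = float("nan")
        history.per_epoch.append((epoch, train_loss, val_mae, val_rmse))
        log.info(
            "epoch %d  loss %.6g  val MAE %.3f  val RMSE %.3f", epoch, train_loss, val_mae, val_rmse
        )
        if val_set and val_mae < best_mae:
            best_mae = val_mae
            best_state = model.state_dict()
            history.best_epoch = epoch
    if val_set:
        model.load_state_dict(best_state)
    elif history.per_epoch:
        history.best_epoch = history.per_epoch[-1][0]
    return model, history


def predict_count(model: FryCountNet, image: np.ndarray) -> tuple[float, DensityMap]:
    """Predicted count = integral of the predicted full-resolution map.

    Images whose sides are not divisible by 8 are reflect-padded up to the
    next multiple and the output map is cropped back.
    """
    h, w = image.shape[:2]
    ph = (-h) % 8
    pw = (-w) % 8
    if ph or pw:
        image = np.pad(image, ((0, ph), (0, pw), (0, 0)), mode="reflect")
    dm = model_forward(model, image)
    if ph or pw:
        dm = DensityMap(dm.grid[:h, :w], sigma=dm.sigma)
    return integrate(dm), dm


def evaluate(model: FryCountNet, dataset: list[Sample], by_level: bool = True) -> EvalReport:
    """Counting MAE/RMSE over a dataset, optionally per density level."""
    if not dataset:
        raise ValueError("cannot evaluate on an empty dataset")
    pairs = []
    for s in dataset:
        pred, _ = predict_count(model, s.image)
        pairs.append((s.count, pred))
    per_level = None
    if by_level:
        per_level = {}
        for label in LEVELS:
            lv = [p for p in pairs if assign_density_level(p[0]).label == label]
            if lv:
                from .losses import mae as _mae, rmse as _rmse

                per_level[label] = {"mae": _mae(lv), "rmse": _rmse(lv), "n_images": len(lv)}
    return EvalReport.from_pairs(pairs, per_level=per_level)
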