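"""Seeded synthetic shrimp-tank scenes with exact point annotations.

Emulates top-down photographs of a shallow, LED-lit rearing tank: a light,
gently vignetted background over which 0-1000 small elongated dark larvae
are composited.  Each larva is a quadratic Bezier stroke with a Gaussian
cross-profile (slightly curved, 8-22 px long), annotated at its ink
centroid, so the rendered count always equals the annotation count exactly.
Every scene is a pure function of its spec (including the seed).
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .points import PointSet, write_points

__all__ = [
    "SceneSpec",
    "DatasetSpec",
    "LEVELS",
    "render_scene",
    "make_dataset",
    "easy_benchmark",
]

MAX_FRY = 1000

# density levels: label -> inclusive count range
LEVELS: dict[str, tuple[int, int]] = {
    "Low": (0, 249),
    "Medium": (250, 499),
    "High": (500, 749),
    "Higher": (750, 1000),
}

# images per (split, level); the study design this generator emulates
DEFAULT_SPLIT_SIZES: dict[str, dict[str, int]] = {
    "train": {"Low": 121, "Medium": 139, "High": 105, "Higher": 25},
    "val": {"Low": 21, "Medium": 15, "High": 14, "Higher": 13},
    "test": {"Low": 55, "Medium": 11, "High": 19, "Higher": 18},
}


@dataclass
class SceneSpec:
    """Parameters of one synthetic tank scene."""

    width: int = 768
    height: int = 576
    n_fry: int = 100
    fry_length: tuple[float, float] = (8.0, 22.0)
    fry_width: tuple[float, float] = (1.5, 3.5)
    curvature: tuple[float, float] = (-0.6, 0.6)
    fry_intensity: tuple[float, float] = (0.05, 0.35)
    background_level: float = 0.75
    vignette_strength: float = 0.15
    noise_std: float = 0.02
    allow_overlap: bool = True
    min_distance: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.n_fry <= MAX_FRY):
            raise ValueError(f"n_fry must be in [0, {MAX_FRY}], got {self.n_fry}")
        if self.fry_length[0] <= 0 or self.fry_width[0] <= 0:
            raise ValueError("fry geometry ranges must be positive")
        for lo, hi in (self.fry_intensity, (self.background_level, self.background_level)):
            if not (0 <= lo <= 1 and 0 <= hi <= 1):
                raise ValueError("intensities must lie in [0, 1]")


@dataclass
class DatasetSpec:
    """Split/level layout of a full synthetic dataset."""

    split_sizes: dict[str, dict[str, int]] = field(
        default_factory=lambda: {s: dict(d) for s, d in DEFAULT_SPLIT_SIZES.items()}
    )
    scene: SceneSpec = field(default_factory=lambda: SceneSpec(n_fry=0))
    seed: int = 0

    def __post_init__(self) -> None:
        for split, levels in self.split_sizes.items():
            for level, n in levels.items():
                if level not in LEVELS:
                    raise ValueError(f"unknown density level {level!r} in split {split!r}")
                if n < 0:
                    raise ValueError("per-level image counts must be >= 0")


def _bezier(p0, p1, p2, ts):
    """Quadratic Bezier curve sampled at parameters ts."""
    ts = ts[:, None]
    return (1 - ts) ** 2 * p0 + 2 * (1 - ts) * ts * p1 + ts**2 * p2


def _render_fry(rng: np.random.Generator, spec: SceneSpec, center: np.ndarray):
    """Rasterize one larva; returns (patch alpha, patch origin, centroid, albedo)."""
    length = rng.uniform(*spec.fry_length)
    width = rng.uniform(*spec.fry_width)
    curv = rng.uniform(*spec.curvature)
    theta = rng.uniform(0.0, 2.0 * np.pi)
    albedo = rng.uniform(*spec.fry_intensity)

    d = np.array([np.cos(theta), np.sin(theta)])
    n = np.array([-d[1], d[0]])
    p0 = center - 0.5 * length * d
    p2 = center + 0.5 * length * d
    p1 = center + curv * 0.25 * length * n

    n_samples = max(8, int(2 * length))
    pts = _bezier(p0, p1, p2, np.linspace(0.0, 1.0, n_samples))

    sigma = width / 2.0
    pad = 3.0 * sigma + 1.0
    x0 = int(np.floor(pts[:, 0].min() - pad))
    x1 = int(np.ceil(pts[:, 0].max() + pad))
    y0 = int(np.floor(pts[:, 1].min() - pad))
    y1 = int(np.ceil(pts[:, 1].max() + pad))
    xs = np.arange(x0, x1 + 1)
    ys = np.arange(y0, y1 + 1)
    gx, gy = np.meshgrid(xs, ys)
    # distance from each patch pixel to the sampled stroke polyline
    dx = gx[..., None] - pts[:, 0]
    dy = gy[..., None] - pts[:, 1]
    dist2 = (dx * dx + dy * dy).min(axis=-1)
    alpha = np.exp(-dist2 / (2.0 * sigma * sigma))
    alpha[alpha < 1e-3] = 0.0

    mass = alpha.sum()
    cx = float((alpha * gx).sum() / mass)
    cy = float((alpha * gy).sum() / mass)
    return alpha, (y0, x0), (cx, cy), albedo


def render_scene(spec: SceneSpec) -> tuple[np.ndarray, PointSet]:
    """Render one scene; returns (H x W x 3 float image in [0,1], PointSet).

    Exactly ``spec.n_fry`` larvae are drawn; the annotation of each is its
    ink centroid.  With ``allow_overlap=False`` body centers are rejection-
    sampled to keep pairwise distances >= ``spec.min_distance``.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width

    # vignetted light background with a faint tank tint
    yy, xx = np.mgrid[0:h, 0:w]
    r2 = ((yy - (h - 1) / 2) / (h / 2)) ** 2 + ((xx - (w - 1) / 2) / (w / 2)) ** 2
    base = spec.background_level * (1.0 - spec.vignette_strength * r2 / 2.0)
    tint = np.array([0.97, 1.0, 0.99])
    img = base[..., None] * tint

    margin = spec.fry_length[1] / 2.0 + 4.0
    margin_x = min(margin, w / 2.0 - 1.0)
    margin_y = min(margin, h / 2.0 - 1.0)

    centers: list[np.ndarray] = []
    max_tries = 200
    for _ in range(spec.n_fry):
        for _try in range(max_tries):
            c = np.array(
                [
                    rng.uniform(margin_x, w - 1 - margin_x),
                    rng.uniform(margin_y, h - 1 - margin_y),
                ]
            )
            if spec.allow_overlap or all(
                np.hypot(*(c - o)) >= spec.min_distance for o in centers
            ):
                break
        else:
            raise RuntimeError(
                f"could not place {spec.n_fry} non-overlapping bodies "
                f"(min_distance={spec.min_distance}) in a {w}x{h} scene"
            )
        centers.append(c)

    points = []
    for c in centers:
        alpha, (y0, x0), (cx, cy), albedo = _render_fry(rng, spec, c)
        ph, pw = alpha.shape
        ys = slice(max(0, y0), min(h, y0 + ph))
        xs = slice(max(0, x0), min(w, x0 + pw))
        ays = slice(ys.start - y0, ys.stop - y0)
        axs = slice(xs.start - x0, xs.stop - x0)
        a = alpha[ays, axs][..., None]
        img[ys, xs] = img[ys, xs] * (1.0 - a) + albedo * a
        eps = 1e-6
        points.append([min(max(cx, 0.0), w - 1 - eps), min(max(cy, 0.0), h - 1 - eps)])

    if spec.noise_std > 0:
        img = img + rng.normal(0.0, spec.noise_std, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    pts = np.array(points, dtype=float).reshape(-1, 2)
    return img, PointSet(pts, w, h)


def make_dataset(ds: DatasetSpec, out_dir: str) -> list[dict]:
    """Render a full dataset to ``out_dir`` and return its manifest.

    Layout: ``images/`` (PNG), ``points/`` (matching .npy stems),
    ``manifest.csv`` (filename, split, count, level) and ``params.json``
    recording the generator parameters.  Per image, the body count is drawn
    uniformly within its level's range.
    """
    import imageio.v3 as iio

    rng = np.random.default_rng(ds.seed)
    manifest: list[dict] = []
    total = sum(n for levels in ds.split_sizes.values() for n in levels.values())
    if total > 0:
        os.makedirs(os.path.join(out_dir, "images"), exist_ok=True)
        os.makedirs(os.path.join(out_dir, "points"), exist_ok=True)
    idx = 0
    for split, levels in ds.split_sizes.items():
        for level, n_images in levels.items():
            lo, hi = LEVELS[level]
            for _ in range(n_images):
                n_fry = int(rng.integers(lo, hi + 1))
                scene = SceneSpec(
                    **{
                        **asdict(ds.scene),
                        "n_fry": n_fry,
                        "seed": int(rng.integers(0, 2**31 - 1)),
                    }
                )
                img, ps = render_scene(scene)
                stem = f"{split}_{idx:05d}"
                iio.imwrite(
                    os.path.join(out_dir, "images", f"{stem}.png"),
                    (img * 255).round().astype(np.uint8),
                )
                write_points(ps, os.path.join(out_dir, "points", f"{stem}.npy"))
                manifest.append(
                    {"filename": f"{stem}.png", "split": split, "count": n_fry, "level": level}
                )
                idx += 1
    if total > 0:
        with open(os.path.join(out_dir, "manifest.csv"), "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["filename", "split", "count", "level"])
            writer.writeheader()
            writer.writerows(manifest)
        params = asdict(ds)
        with open(os.path.join(out_dir, "params.json"), "w") as fh:
            json.dump(params, fh, indent=2)
    return manifest


def easy_benchmark(
    n_images: int,
    counts: tuple[int, int] = (5, 40),
    seed: int = 42,
    width: int = 192,
    height: int = 144,
) -> list[tuple[np.ndarray, PointSet]]:
    """Small, high-contrast, widely spaced scenes for CPU-scale training.

    Returns an in-memory list of (image, PointSet).  Counts are drawn
    uniformly in ``counts`` (inclusive), capped at 60.
    """
    lo, hi = counts
    if not (0 <= lo <= hi <= 60):
        raise ValueError("easy_benchmark counts must lie within [0, 60]")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_images):
        spec = SceneSpec(
            width=width,
            height=height,
            n_fry=int(rng.integers(lo, hi + 1)),
            fry_length=(10.0, 16.0),
            fry_width=(2.0, 3.2),
            fry_intensity=(0.05, 0.15),
            noise_std=0.01,
            vignette_strength=0.05,
            allow_overlap=False,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        out.append(render_scene(spec))
    return out
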