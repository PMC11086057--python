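"""Dataset directory layout: images/, points/, optional densities/, manifest.csv."""

from __future__ import annotations

import csv
import os

import numpy as np

from .density import gaussian_density, load_density, save_density
from .pipeline import Sample
from .points import PointSet, read_points, write_points

__all__ = ["read_manifest", "load_pairs", "load_samples", "write_pairs", "load_image"]


def load_image(path: str) -> np.ndarray:
    """Read an image file as H x W x 3 floats in [0, 1]."""
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    return np.clip(arr.astype(float), 0.0, 1.0)


def read_manifest(data_dir: str) -> list[dict]:
    path = os.path.join(data_dir, "manifest.csv")
    if not os.path.exists(path):
        raise FileNotFoundError(f"no manifest.csv in {data_dir}")
    with open(path, newline="") as fh:
        return [dict(r) for r in csv.DictReader(fh)]


def load_pairs(data_dir: str, split: str | None = None) -> list[tuple[np.ndarray, PointSet]]:
    """Load (image, PointSet) pairs for one split (or all)."""
    rows = read_manifest(data_dir)
    if split is not None:
        rows = [r for r in rows if r["split"] == split]
    out = []
    for r in rows:
        stem = os.path.splitext(r["filename"])[0]
        img = load_image(os.path.join(data_dir, "images", r["filename"]))
        ps = read_points(
            os.path.join(data_dir, "points", f"{stem}.npy"),
            width=img.shape[1],
            height=img.shape[0],
        )
        out.append((img, ps))
    return out


def load_samples(data_dir: str, split: str | None = None, sigma: float = 3.0) -> list[Sample]:
    """Load Samples for one split, using cached densities/ when present."""
    rows = read_manifest(data_dir)
    if split is not None:
        rows = [r for r in rows if r["split"] == split]
    out = []
    for r in rows:
        stem = os.path.splitext(r["filename"])[0]
        img = load_image(os.path.join(data_dir, "images", r["filename"]))
        ps = read_points(
            os.path.join(data_dir, "points", f"{stem}.npy"),
            width=img.shape[1],
            height=img.shape[0],
        )
        dpath = os.path.join(data_dir, "densities", f"{stem}.npz")
        if os.path.exists(dpath):
            dm = load_density(dpath)
        else:
            dm = gaussian_density(ps, sigma=sigma)
        out.append(Sample(image=img, density=dm.grid, count=float(ps.count()), points=ps))
    return out


def densify_dataset(data_dir: str, sigma: float = 3.0) -> int:
    """Generate and cache ground-truth density archives for a dataset."""
    rows = read_manifest(data_dir)
    os.makedirs(os.path.join(data_dir, "densities"), exist_ok=True)
    for r in rows:
        stem = os.path.splitext(r["filename"])[0]
        img_path = os.path.join(data_dir, "images", r["filename"])
        img = load_image(img_path)
        ps = read_points(
            os.path.join(data_dir, "points", f"{stem}.npy"),
            width=img.shape[1],
            height=img.shape[0],
        )
        dm = gaussian_density(ps, sigma=sigma)
        save_density(dm, os.path.join(data_dir, "densities", f"{stem}.npz"), source=r["filename"])
    return len(rows)


def write_pairs(
    pairs: list[tuple[np.ndarray, PointSet]], out_dir: str, split: str = "train"
) -> list[dict]:
    """Write in-memory (image, PointSet) pairs using the standard layout."""
    import imageio.v3 as iio

    os.makedirs(os.path.join(out_dir, "images"), exist_ok=True)
    os.makedirs(os.path.join(out_dir, "points"), exist_ok=True)
    manifest = []
    for i, (img, ps) in enumerate(pairs):
        stem = f"{split}_{i:05d}"
        iio.imwrite(
            os.path.join(out_dir, "images", f"{stem}.png"),
            (img * 255).round().astype(np.uint8),
        )
        write_points(ps, os.path.join(out_dir, "points", f"{stem}.npy"))
        manifest.append(
            {"filename": f"{stem}.png", "split": split, "count": ps.count(), "level": "Low"}
        )
    path = os.path.join(out_dir, "manifest.csv")
    exists = os.path.exists(path)
    rows = []
    if exists:
        with open(path, newline="") as fh:
            rows = [dict(r) for r in csv.DictReader(fh)]
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["filename", "split", "count", "level"])
        writer.writeheader()
        writer.writerows(rows + manifest)
    return manifest
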