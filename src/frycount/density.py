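"""Ground-truth density maps from point annotations.

Each annotated animal is replaced by a unit impulse that is blurred with an
isotropic Gaussian kernel; the resulting per-pixel field integrates to the
object count, which is what makes count-by-integration work.  The kernel
scale defaults to sigma = 3 px.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .points import PointSet

__all__ = [
    "DensityMap",
    "impulse_matrix",
    "gaussian_density",
    "integrate",
    "save_density",
    "load_density",
    "density_to_image",
]


@dataclass
class DensityMap:
    """A non-negative per-pixel density grid (animals per pixel).

    ``grid.sum()`` is the (fractional) object count.  ``sigma`` records the
    Gaussian scale used to generate the map.
    """

    grid: np.ndarray
    sigma: float = 3.0

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        if g.ndim != 2:
            raise ValueError(f"density grid must be 2-D, got shape {g.shape}")
        if (g < 0).any():
            raise ValueError("density grid has negative cells")
        self.grid = g

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape  # type: ignore[return-value]

    def integral(self) -> float:
        return float(self.grid.sum())


def impulse_matrix(ps: PointSet) -> np.ndarray:
    """Integer grid of unit spikes: each point adds 1 at its nearest pixel.

    Rounding is to the nearest integer with ties toward +inf; coordinates
    that round to the grid edge are kept on the grid.  Coincident points
    accumulate.
    """
    grid = np.zeros((ps.height, ps.width), dtype=np.int64)
    if ps.count() == 0:
        return grid
    cols = np.floor(ps.points[:, 0] + 0.5).astype(int)
    rows = np.floor(ps.points[:, 1] + 0.5).astype(int)
    cols = np.clip(cols, 0, ps.width - 1)
    rows = np.clip(rows, 0, ps.height - 1)
    np.add.at(grid, (rows, cols), 1)
    return grid


def gaussian_density(
    ps: PointSet,
    sigma: float = 3.0,
    truncate: float | None = 4.0,
    renormalize: bool = True,
) -> DensityMap:
    """Blur each annotation into an isotropic Gaussian of scale ``sigma``.

    The Gaussian is centered at the continuous (x, y) coordinate and
    evaluated at pixel centers (pixel (r, c) sits at coordinate (c, r)).
    ``truncate`` limits each point's footprint to a window of half-width
    ``truncate * sigma`` pixels per axis (pass ``None`` to evaluate every
    kernel on the full grid, the strict un-truncated form).  With
    ``renormalize`` each point's on-grid mass is rescaled to exactly 1, so
    the map integrates to ``ps.count()`` even for border-adjacent points.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    if truncate is not None and truncate <= 0:
        raise ValueError(f"truncate must be positive or None, got {truncate}")

    h, w = ps.height, ps.width
    grid = np.zeros((h, w), dtype=float)
    if ps.count() == 0:
        return DensityMap(grid, sigma=sigma)

    norm = 1.0 / (2.0 * math.pi * sigma * sigma)
    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    if truncate is None:
        radius = max(h, w)  # window spans the whole grid
    else:
        radius = int(math.ceil(truncate * sigma))

    for x0, y0 in ps.points:
        c0 = int(math.floor(x0))
        r0 = int(math.floor(y0))
        cl, cr = max(0, c0 - radius), min(w - 1, c0 + radius + 1)
        rl, rr = max(0, r0 - radius), min(h - 1, r0 + radius + 1)
        cs = np.arange(cl, cr + 1)
        rs = np.arange(rl, rr + 1)
        gx = np.exp(-((cs - x0) ** 2) * inv2s2)
        gy = np.exp(-((rs - y0) ** 2) * inv2s2)
        patch = norm * np.outer(gy, gx)
        if renormalize:
            mass = patch.sum()
            if mass > 0:
                patch = patch / mass
        grid[rl : rr + 1, cl : cr + 1] += patch
    return DensityMap(grid, sigma=sigma)


def integrate(dm: DensityMap | np.ndarray) -> float:
    """Total count carried by a density map: the sum of all cells."""
    grid = dm.grid if isinstance(dm, DensityMap) else np.asarray(dm)
    return float(grid.sum())


def save_density(dm: DensityMap, path: str, source: str = "") -> None:
    """Store grid + sigma (+ source image name) in a compressed archive."""
    np.savez_compressed(path, grid=dm.grid, sigma=np.float64(dm.sigma), source=np.str_(source))


def load_density(path: str) -> DensityMap:
    with np.load(path, allow_pickle=False) as npz:
        return DensityMap(npz["grid"], sigma=float(npz["sigma"]))


def density_to_image(dm: DensityMap | np.ndarray, cmap: str = "jet") -> np.ndarray:
    """8-bit color-mapped rendering of a density map, for display only.

    Normalized per map (max -> 1), so absolute scale is not preserved.
    """
    import matplotlib

    grid = dm.grid if isinstance(dm, DensityMap) else np.asarray(dm, dtype=float)
    peak = grid.max()
    norm = grid / peak if peak > 0 else grid
    rgba = matplotlib.colormaps[cmap](norm)
    return (rgba[..., :3] * 255).astype(np.uint8)
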