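"""Point annotations: one sub-pixel (x, y) click per animal.

Coordinates are 0-based with ``x`` the column and ``y`` the row, matching the
convention of point-annotation tools.  Duplicate points are allowed: two
animals may legitimately be annotated at the same pixel.
"""

from __future__ import annotations

import csv
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np

__all__ = ["PointSet", "read_points", "write_points"]

log = logging.getLogger(__name__)


@dataclass
class PointSet:
    """An image's point annotations plus the image dimensions.

    Parameters
    ----------
    points
        Array of shape (N, 2) holding (x, y) = (column, row) coordinates.
        Sub-pixel positions are allowed.
    width, height
        Image dimensions in pixels; every point must satisfy
        ``0 <= x < width`` and ``0 <= y < height``.
    """

    points: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    width: int = 0
    height: int = 0

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.size == 0:
            pts = pts.reshape(0, 2)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError(f"points must have shape (N, 2), got {pts.shape}")
        self.points = pts
        self.width = int(self.width)
        self.height = int(self.height)
        self.validate()

    def validate(self) -> None:
        if self.width < 0 or self.height < 0:
            raise ValueError("width and height must be non-negative")
        if len(self.points) == 0:
            return
        x, y = self.points[:, 0], self.points[:, 1]
        if (x < 0).any() or (x >= self.width).any() or (y < 0).any() or (y >= self.height).any():
            bad = self.points[(x < 0) | (x >= self.width) | (y < 0) | (y >= self.height)]
            raise ValueError(
                f"{len(bad)} point(s) outside the {self.width}x{self.height} "
                f"image, first offender {tuple(bad[0])}"
            )

    def count(self) -> int:
        return len(self.points)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.points)

    def clamped(self) -> "PointSet":
        """Return a copy with every point clamped into the valid range."""
        eps = 1e-9
        pts = self.points.copy()
        pts[:, 0] = np.clip(pts[:, 0], 0.0, max(self.width - eps, 0.0))
        pts[:, 1] = np.clip(pts[:, 1], 0.0, max(self.height - eps, 0.0))
        return PointSet(pts, self.width, self.height)

    def shifted(self, dx: float, dy: float) -> "PointSet":
        pts = self.points + np.array([dx, dy])
        return PointSet(pts, self.width, self.height)


_EXT_FORMAT = {".npy": "npy", ".csv": "csv", ".json": "json"}


def _infer_format(path: str, fmt: str) -> str:
    if fmt != "auto":
        return fmt
    ext = os.path.splitext(path)[1].lower()
    if ext not in _EXT_FORMAT:
        raise ValueError(f"cannot infer annotation format from extension {ext!r}")
    return _EXT_FORMAT[ext]


def read_points(
    path: str,
    fmt: str = "auto",
    *,
    width: int | None = None,
    height: int | None = None,
    clamp: bool = False,
) -> PointSet:
    """Load point annotations from ``path``.

    Formats: ``npy`` (binary array, shape N x 2), ``csv`` (header ``x,y``),
    ``json`` (either a bare list of [x, y] pairs or an object with keys
    ``points``, ``width``, ``height``).  ``width``/``height`` must be given
    unless the file itself carries them (JSON object form).  Out-of-bounds
    points raise unless ``clamp`` is set, in which case they are clamped to
    the valid range with a logged warning.
    """
    fmt = _infer_format(path, fmt)
    file_w = file_h = None
    if fmt == "npy":
        pts = np.load(path, allow_pickle=False)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError(f"annotation array must have shape (N, 2), got {pts.shape}")
    elif fmt == "csv":
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
        pts = np.array([[float(r["x"]), float(r["y"])] for r in rows]).reshape(-1, 2)
    elif fmt == "json":
        with open(path) as fh:
            payload = json.load(fh)
        if isinstance(payload, dict):
            pts = np.asarray(payload["points"], dtype=float).reshape(-1, 2)
            file_w = payload.get("width")
            file_h = payload.get("height")
        else:
            pts = np.asarray(payload, dtype=float).reshape(-1, 2)
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")

    w = width if width is not None else file_w
    h = height if height is not None else file_h
    if w is None or h is None:
        raise ValueError(
            f"{path}: image dimensions are not stored in this format; "
            "pass width= and height= explicitly"
        )
    pts = np.asarray(pts, dtype=float)
    if clamp:
        eps = 1e-9
        out = (pts[:, 0] < 0) | (pts[:, 0] >= w) | (pts[:, 1] < 0) | (pts[:, 1] >= h)
        if out.any():
            log.warning("%s: clamped %d out-of-bounds point(s)", path, int(out.sum()))
            pts = pts.copy()
            pts[:, 0] = np.clip(pts[:, 0], 0.0, w - eps)
            pts[:, 1] = np.clip(pts[:, 1], 0.0, h - eps)
    return PointSet(pts, int(w), int(h))


def write_points(ps: PointSet, path: str, fmt: str = "auto") -> None:
    """Write ``ps`` so that :func:`read_points` can recover it.

    JSON keeps width/height alongside the coordinates; npy and csv store the
    bare coordinate table.
    """
    fmt = _infer_format(path, fmt)
    if fmt == "npy":
        np.save(path, np.asarray(ps.points, dtype=float).reshape(-1, 2))
    elif fmt == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["x", "y"])
            for x, y in ps.points:
                writer.writerow([repr(float(x)), repr(float(y))])
    elif fmt == "json":
        with open(path, "w") as fh:
            json.dump(
                {
                    "points": [[float(x), float(y)] for x, y in ps.points],
                    "width": ps.width,
                    "height": ps.height,
                },
                fh,
            )
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")
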