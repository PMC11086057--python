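"""Gaussian density-map generation: conservation, oracle equivalence,
equivariance and superposition."""

import numpy as np
import pytest

from frycount import (
    DensityMap,
    PointSet,
    gaussian_density,
    impulse_matrix,
    integrate,
)
from frycount.density import load_density, save_density


def brute_force_density(ps: PointSet, sigma: float = 3.0) -> np.ndarray:
    """Independent oracle: per-point, per-pixel evaluation of the 2-D
    Gaussian over the whole grid, each point renormalized to unit mass."""
    grid = np.zeros((ps.height, ps.width))
    ys, xs = np.mgrid[0 : ps.height, 0 : ps.width]
    for x0, y0 in ps.points:
        g = np.exp(-((xs - x0) ** 2 + (ys - y0) ** 2) / (2 * sigma**2))
        g /= 2 * np.pi * sigma**2
        grid += g / g.sum()
    return grid


def test_impulse_matrix_superposition_and_sum(rng):
    ps = PointSet(np.array([[5.2, 5.2], [5.2, 5.2]]), 16, 16)
    grid = impulse_matrix(ps)
    assert grid[5, 5] == 2 and grid.sum() == 2

    pts = np.column_stack([rng.uniform(0, 64, 500), rng.uniform(0, 64, 500)])
    assert impulse_matrix(PointSet(pts, 64, 64)).sum() == 500


def test_impulse_matrix_rounds_ties_up():
    ps = PointSet(np.array([[2.5, 3.5]]), 8, 8)
    assert impulse_matrix(ps)[4, 3] == 1


def test_empty_inputs():
    ps = PointSet(np.empty((0, 2)), 32, 32)
    assert impulse_matrix(ps).sum() == 0
    dm = gaussian_density(ps)
    assert dm.integral() == 0.0
    assert integrate(dm) == 0.0


def test_default_sigma_is_three():
    dm = gaussian_density(PointSet(np.array([[16.0, 16.0]]), 32, 32))
    assert dm.sigma == 3.0


def test_sigma_must_be_positive():
    ps = PointSet(np.array([[4.0, 4.0]]), 8, 8)
    with pytest.raises(ValueError, match="sigma"):
        gaussian_density(ps, sigma=0.0)


def test_single_center_point_matches_brute_force():
    ps = PointSet(np.array([[32.0, 32.0]]), 64, 64)
    dm = gaussian_density(ps, truncate=None)
    assert abs(dm.integral() - 1.0) <= 1e-9
    np.testing.assert_allclose(dm.grid, brute_force_density(ps), atol=1e-9)


def test_oracle_equivalence_random_points(rng):
    for _ in range(5):
        n = int(rng.integers(1, 50))
        pts = np.column_stack([rng.uniform(0, 96, n), rng.uniform(0, 64, n)])
        ps = PointSet(pts, 96, 64)
        dm = gaussian_density(ps, truncate=None)
        np.testing.assert_allclose(dm.grid, brute_force_density(ps), atol=1e-9)


def test_conservation_with_border_points(rng):
    for _ in range(20):
        n = int(rng.integers(0, 400))
        pts = np.column_stack([rng.uniform(0, 128, n), rng.uniform(0, 128, n)])
        if n >= 3:
            pts[:3] = [[0.05, 0.05], [127.9, 0.3], [64.0, 127.95]]
        dm = gaussian_density(PointSet(pts, 128, 128))
        assert abs(dm.integral() - n) <= 1e-6


def test_translation_equivariance_interior(rng):
    # coordinates on a 1/64 grid so the integer shift is exact in floating point
    pts = np.round(
        np.column_stack([rng.uniform(25, 45, 12), rng.uniform(25, 45, 12)]) * 64
    ) / 64
    a = gaussian_density(PointSet(pts, 96, 96)).grid
    b = gaussian_density(PointSet(pts + [7, 4], 96, 96)).grid
    np.testing.assert_array_equal(a[20:60, 20:60], b[24:64, 27:67])


def test_superposition(rng):
    pa = np.column_stack([rng.uniform(0, 64, 10), rng.uniform(0, 64, 10)])
    pb = np.column_stack([rng.uniform(0, 64, 15), rng.uniform(0, 64, 15)])
    da = gaussian_density(PointSet(pa, 64, 64)).grid
    db = gaussian_density(PointSet(pb, 64, 64)).grid
    dab = gaussian_density(PointSet(np.vstack([pa, pb]), 64, 64)).grid
    np.testing.assert_allclose(dab, da + db, atol=1e-9)


def test_integrate_linearity(rng):
    pts = np.column_stack([rng.uniform(10, 50, 250), rng.uniform(10, 50, 250)])
    dm = gaussian_density(PointSet(pts, 64, 64))
    assert abs(integrate(dm) - 250.0) <= 1e-6
    assert abs(integrate(DensityMap(2 * dm.grid, dm.sigma)) - 2 * integrate(dm)) <= 1e-9


def test_negative_grid_rejected():
    with pytest.raises(ValueError, match="negative"):
        DensityMap(np.array([[-1.0, 0.0]]))


def test_density_archive_round_trip(tmp_path, rng):
    pts = np.column_stack([rng.uniform(0, 32, 9), rng.uniform(0, 32, 9)])
    dm = gaussian_density(PointSet(pts, 32, 32))
    path = str(tmp_path / "d.npz")
    save_density(dm, path, source="img.png")
    back = load_density(path)
    np.testing.assert_array_equal(back.grid, dm.grid)
    assert back.sigma == dm.sigma
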