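"""Euclidean loss, SSIM loss, combined objective, MAE/RMSE."""

import math

import numpy as np
import pytest

from frycount import (
    LossConfig,
    combined_loss,
    euclidean_loss,
    mae,
    rmse,
    ssim_index,
    ssim_loss,
)
from frycount.nn import Tensor


def test_euclidean_zero_on_identical(rng):
    x = rng.random((2, 16, 16))
    assert euclidean_loss(x, x).item() == 0.0


def test_euclidean_constant_offset_closed_form():
    p = np.full((1, 12, 9), 0.7)
    g = np.full((1, 12, 9), 0.2)
    # batch 1, P pixels, difference c everywhere -> 0.5 * P * c^2
    assert math.isclose(euclidean_loss(p, g).item(), 0.5 * 12 * 9 * 0.25, rel_tol=1e-12)


def test_euclidean_matches_brute_force_loop(rng):
    p = rng.random((3, 16, 16))
    g = rng.random((3, 16, 16))
    acc = 0.0
    for b in range(3):
        for i in range(16):
            for j in range(16):
                acc += (p[b, i, j] - g[b, i, j]) ** 2
    assert abs(euclidean_loss(p, g).item() - acc / (2 * 3)) < 1e-9


def test_euclidean_mean_reduction(rng):
    p, g = rng.random((2, 8, 8)), rng.random((2, 8, 8))
    cfg = LossConfig(euclidean_reduction="mean")
    assert abs(euclidean_loss(p, g, cfg).item() - ((p - g) ** 2).mean()) < 1e-12


def test_euclidean_shape_mismatch(rng):
    with pytest.raises(ValueError, match="mismatch"):
        euclidean_loss(rng.random((4, 4)), rng.random((4, 5)))


def test_ssim_identity_and_symmetry(rng):
    x = rng.random((24, 24))
    y = rng.random((24, 24))
    assert ssim_index(x, x).item() == pytest.approx(1.0, abs=1e-12)
    assert abs(ssim_index(x, y).item() - ssim_index(y, x).item()) <= 1e-12


def test_ssim_against_reference_implementation(rng):
    from skimage.metrics import structural_similarity

    for _ in range(20):
        a, b = rng.random((32, 40)), rng.random((32, 40))
        ref = structural_similarity(
            a,
            b,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            data_range=1.0,
            K1=0.01,
            K2=0.03,
        )
        assert abs(ssim_index(a, b).item() - ref) < 1e-6


def test_ssim_window_larger_than_image(rng):
    with pytest.raises(ValueError, match="window"):
        ssim_index(rng.random((8, 8)), rng.random((8, 8)))


def test_global_ssim_flag(rng):
    a, b = rng.random((16, 16)), rng.random((16, 16))
    cfg = LossConfig(ssim_windowed=False)
    mu_a, mu_b = a.mean(), b.mean()
    va, vb = a.var(), b.var()
    cov = ((a - mu_a) * (b - mu_b)).mean()
    ref = ((2 * mu_a * mu_b + 1e-4) * (2 * cov + 9e-4)) / (
        (mu_a**2 + mu_b**2 + 1e-4) * (va + vb + 9e-4)
    )
    assert abs(ssim_index(a, b, cfg).item() - ref) < 1e-12


def test_ssim_loss_bounds_and_batch_mean(rng):
    x = rng.random((2, 24, 24))
    assert ssim_loss(x, x).item() == pytest.approx(0.0, abs=1e-12)
    a, b = rng.random((2, 24, 24)), rng.random((2, 24, 24))
    loss = ssim_loss(a, b).item()
    assert 0.0 <= loss <= 2.0
    per_image = np.mean([ssim_loss(a[i], b[i]).item() for i in range(2)])
    assert abs(loss - per_image) <= 1e-12


def test_combined_loss_default_alpha_and_composition(rng):
    assert LossConfig().alpha == 0.001
    a, b = rng.random((2, 24, 24)), rng.random((2, 24, 24))
    total = combined_loss(a, b).item()
    parts = euclidean_loss(a, b).item() + 0.001 * ssim_loss(a, b).item()
    assert abs(total - parts) <= 1e-12
    assert combined_loss(a, a).item() == pytest.approx(0.0, abs=1e-12)


def test_combined_loss_gradient_is_finite(rng):
    p = Tensor(rng.random((1, 1, 24, 24)), requires_grad=True)
    g = Tensor(rng.random((1, 1, 24, 24)))
    combined_loss(p, g).backward()
    assert np.isfinite(p.grad).all()
    assert np.abs(p.grad).max() > 0


def test_mae_rmse_hand_computed():
    pairs = [(5, 4), (10, 12), (0, 3)]  # errors 1, 2, 3
    assert mae(pairs) == pytest.approx(2.0)
    assert rmse(pairs) == pytest.approx(math.sqrt(14 / 3))


def test_perfect_predictions():
    pairs = [(3, 3), (7, 7)]
    assert mae(pairs) == 0.0 and rmse(pairs) == 0.0


def test_rmse_dominates_mae(rng):
    for _ in range(100):
        n = int(rng.integers(1, 30))
        y = rng.uniform(0, 100, n)
        yh = y + rng.normal(0, 5, n)
        pairs = list(zip(y, yh))
        assert rmse(pairs) >= mae(pairs) - 1e-12


def test_metrics_order_invariant(rng):
    y = rng.uniform(0, 50, 11)
    yh = y + rng.normal(0, 2, 11)
    pairs = list(zip(y, yh))
    perm = [pairs[i] for i in rng.permutation(11)]
    assert mae(pairs) == pytest.approx(mae(perm))
    assert rmse(pairs) == pytest.approx(rmse(perm))


def test_empty_pairs_error():
    with pytest.raises(ValueError):
        mae([])


def test_eval_report_round_trip(tmp_path, rng):
    from frycount import EvalReport

    pairs = [(10.0, 11.5), (250.0, 240.0)]
    report = EvalReport.from_pairs(pairs)
    assert report.n_images == 2
    assert report.rmse >= report.mae
    report.to_csv(str(tmp_path / "r.csv"))
    assert len(open(tmp_path / "r.csv").read().strip().splitlines()) == 3
    text = report.to_json()
    assert '"mae"' in text
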