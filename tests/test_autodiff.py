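"""Backward passes of every tensor operator against finite differences."""

import numpy as np
import pytest

from frycount.nn import Tensor, bilinear_resize, concat, conv2d, maxpool2x2, no_grad

from conftest import finite_difference_grads


def assert_grads_match(fn, tensors, tol=5e-7):
    out = fn(*tensors)
    out.backward()
    numeric = finite_difference_grads(fn, tensors)
    for t, num in zip(tensors, numeric):
        np.testing.assert_allclose(t.grad, num, atol=tol)


def test_arithmetic_chain_gradients(rng):
    x = Tensor(rng.normal(size=(3, 4)), requires_grad=True)
    y = Tensor(rng.normal(size=(1, 4)), requires_grad=True)

    def fn(x, y):
        return ((x * y - 2.0 * x + 1.0) / (y.sigmoid() + 1.5)).mean() + (
            0.3 / (x.exp() + 1.0)
        ).sum()

    assert_grads_match(fn, [x, y])


def test_reductions_and_broadcast_gradients(rng):
    x = Tensor(rng.normal(size=(2, 3, 4)), requires_grad=True)

    def fn(x):
        return (x.max(axis=2) * x.mean(axis=(1, 2), keepdims=True).reshape(2, 1)).sum() + (
            x.sum(axis=0) ** 2.0
        ).mean()

    assert_grads_match(fn, [x])


def test_conv2d_gradients_with_padding_and_dilation(rng):
    x = Tensor(rng.normal(size=(2, 3, 6, 8)), requires_grad=True)
    w = Tensor(rng.normal(size=(4, 3, 3, 3)) * 0.5, requires_grad=True)
    b = Tensor(rng.normal(size=4), requires_grad=True)
    assert_grads_match(
        lambda x, w, b: (conv2d(x, w, b, padding=2, dilation=2) ** 2.0).sum(), [x, w, b]
    )


def test_conv2d_matches_scipy_correlation(rng):
    from scipy.signal import correlate2d

    x = rng.normal(size=(1, 2, 9, 11))
    w = rng.normal(size=(3, 2, 3, 3))
    out = conv2d(Tensor(x), Tensor(w), padding=1).data
    for o in range(3):
        ref = sum(
            correlate2d(x[0, c], w[o, c], mode="same", boundary="fill") for c in range(2)
        )
        np.testing.assert_allclose(out[0, o], ref, atol=1e-12)


def test_maxpool_gradients_and_tie_sharing(rng):
    x = Tensor(rng.normal(size=(1, 2, 4, 6)), requires_grad=True)
    assert_grads_match(lambda x: (maxpool2x2(x) ** 2.0).sum(), [x])

    t = Tensor(np.ones((1, 1, 2, 2)), requires_grad=True)
    maxpool2x2(t).sum().backward()
    np.testing.assert_allclose(t.grad, 0.25 * np.ones((1, 1, 2, 2)))


def test_maxpool_rejects_odd_dims():
    with pytest.raises(ValueError, match="even"):
        maxpool2x2(Tensor(np.zeros((1, 1, 3, 4))))


@pytest.mark.parametrize("out_hw", [(9, 13), (3, 4), (12, 16)])
def test_bilinear_resize_gradients(rng, out_hw):
    weight = Tensor(rng.normal(size=(1, 2, *out_hw)))
    x = Tensor(rng.normal(size=(1, 2, 6, 8)), requires_grad=True)
    assert_grads_match(lambda x: (bilinear_resize(x, *out_hw) * weight).sum(), [x])


def test_bilinear_resize_matches_scipy_zoom_interior(rng):
    # half-pixel-center bilinear agrees with scipy.ndimage.zoom(order=1,
    # grid_mode=True, mode='nearest') which uses the same convention
    from scipy.ndimage import zoom

    x = rng.normal(size=(5, 7))
    ours = bilinear_resize(Tensor(x[None, None]), 10, 14).data[0, 0]
    ref = zoom(x, 2, order=1, grid_mode=True, mode="nearest")
    np.testing.assert_allclose(ours, ref, atol=1e-12)


def test_concat_and_matmul_gradients(rng):
    a = Tensor(rng.normal(size=(2, 3, 4, 4)), requires_grad=True)
    b = Tensor(rng.normal(size=(2, 1, 4, 4)), requires_grad=True)
    m = Tensor(rng.normal(size=(3, 5)), requires_grad=True)
    assert_grads_match(
        lambda a, b: (concat([a, b + a.mean(axis=1, keepdims=True)], axis=1) ** 2.0).mean(),
        [a, b],
    )
    x = Tensor(rng.normal(size=(4, 3)), requires_grad=True)
    assert_grads_match(lambda x, m: ((x @ m).sigmoid()).sum(), [x, m])


def test_scalar_ops_preserve_float32(rng):
    t = Tensor(rng.normal(size=(2, 3)).astype(np.float32), requires_grad=True)
    y = 1.0 - (t.mean(axis=1) * 0.3 + 2.0 / (t.max(axis=1) + 5.0))
    assert y.data.dtype == np.float32
    y.sum().backward()
    assert t.grad.dtype == np.float32


def test_no_grad_suppresses_graph(rng):
    t = Tensor(rng.normal(size=(2, 2)), requires_grad=True)
    with no_grad():
        y = (t * 2.0).sum()
    assert not y.requires_grad and y._backward is None


def test_backward_accumulates_over_reuse(rng):
    t = Tensor(np.array([2.0]), requires_grad=True)
    y = t * t + t  # dy/dt = 2t + 1 = 5
    y.sum().backward()
    np.testing.assert_allclose(t.grad, [5.0])
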