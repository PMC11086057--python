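"""Architecture contracts: frontend taps, fusion, attention, decoder,
full-resolution output, initialization and checkpointing."""

import numpy as np
import pytest

import frycount as fc
from frycount.model import _VGG13_PLAN
from frycount.nn import Tensor


TINY = dict(width_multiplier=1 / 16, seed=7)


def test_frontend_has_13_conv_layers(tiny_model):
    assert len(tiny_model.frontend_convs) == 13
    assert sum(1 for it in _VGG13_PLAN if it == "M") == 3  # 1/8 resolution


def test_width_multiplier_shrinks_parameter_count():
    full = fc.build_model(fc.ModelConfig(seed=0))
    eighth = fc.build_model(fc.ModelConfig(width_multiplier=1 / 8, seed=0))
    assert eighth.num_parameters() < 0.02 * full.num_parameters()


def test_seeded_builds_are_identical():
    a = fc.build_model(fc.ModelConfig(**TINY))
    b = fc.build_model(fc.ModelConfig(**TINY))
    for (na, pa), (nb, pb) in zip(a.named_parameters(), b.named_parameters()):
        assert na == nb
        np.testing.assert_array_equal(pa.data, pb.data)


def test_decoder_channel_list_must_have_five_entries():
    with pytest.raises(ValueError, match="five"):
        fc.ModelConfig(decoder_channels=(512, 512, 512, 256, 128, 64))


def test_frontend_tap_shapes(tiny_model, rng):
    img = rng.random((64, 64, 3))
    f1, f2 = fc.frontend_forward(tiny_model, img)
    assert f1.scale == 4 and f2.scale == 8
    assert f1.tensor.shape[2:] == (16, 16)
    assert f2.tensor.shape[2:] == (8, 8)
    assert f2.tensor.shape[1] == tiny_model.cfg.channels(512)


def test_frontend_768x576_gives_96x72(rng):
    model = fc.build_model(fc.ModelConfig(width_multiplier=1 / 32, seed=0))
    img = rng.random((576, 768, 3)).astype(np.float32)
    _, f2 = fc.frontend_forward(model, img)
    assert f2.tensor.shape[2:] == (72, 96)


def test_non_divisible_input_names_constraint(tiny_model):
    with pytest.raises(ValueError, match="divisible-by-8"):
        fc.frontend_forward(tiny_model, np.zeros((60, 64, 3)))


def test_zero_input_is_finite(tiny_model):
    out = fc.model_forward(tiny_model, np.zeros((64, 64, 3)))
    assert np.isfinite(out.grid).all()


def test_fusion_output_shape_and_sensitivity(tiny_model, rng):
    img = rng.random((64, 96, 3))
    f1, f2 = fc.frontend_forward(tiny_model, img)
    fused = fc.multiscale_fuse(tiny_model, f1, f2)
    assert fused.tensor.shape == f2.tensor.shape
    # fusion consumes F1: perturbing it changes the output with F2 fixed
    f1b = fc.FeatureMap(Tensor(f1.tensor.data + 0.5), scale=4)
    fused_b = fc.multiscale_fuse(tiny_model, f1b, f2)
    assert not np.allclose(fused.tensor.data, fused_b.tensor.data)


def test_fusion_bypass():
    model = fc.build_model(fc.ModelConfig(fusion_enabled=False, **TINY))
    img = np.random.default_rng(0).random((64, 64, 3))
    f1, f2 = fc.frontend_forward(model, img)
    fused = fc.multiscale_fuse(model, f1, f2)
    assert fused is f2


def test_cbam_preserves_shape_and_bypass(tiny_model, rng):
    img = rng.random((64, 64, 3))
    f1, f2 = fc.frontend_forward(tiny_model, img)
    fused = fc.multiscale_fuse(tiny_model, f1, f2)
    att = fc.cbam_forward(tiny_model, fused)
    assert att.tensor.shape == fused.tensor.shape

    plain = fc.build_model(fc.ModelConfig(cbam_enabled=False, **TINY))
    f = fc.FeatureMap(Tensor(rng.random((1, 32, 8, 8))), scale=8)
    assert fc.cbam_forward(plain, f) is f


def test_cbam_spatially_constant_input(tiny_model, rng):
    c = tiny_model.cfg.channels(512)
    base = rng.random((1, c, 1, 1))
    f = fc.FeatureMap(Tensor(np.broadcast_to(base, (1, c, 12, 12)).copy()), scale=8)
    out = fc.cbam_forward(tiny_model, f).tensor.data
    # constant input -> pooled mean/max maps constant -> attention constant
    # away from the zero-padded border of the 7x7 spatial convolution
    k = tiny_model.cfg.cbam_spatial_kernel // 2
    interior = out[:, :, k:-k, k:-k]
    assert np.abs(interior - interior[:, :, :1, :1]).max() < 1e-6


def test_cbam_rejects_too_few_channels():
    with pytest.raises(ValueError, match="reduction"):
        fc.build_model(fc.ModelConfig(width_multiplier=1 / 64, seed=0))


def test_decoder_shape_and_nonnegativity(tiny_model, rng):
    c = tiny_model.cfg.channels(512)
    f = fc.FeatureMap(Tensor(rng.random((1, c, 12, 9)).astype(np.float32)), scale=8)
    out = fc.decoder_forward(tiny_model, f)
    assert out.shape == (1, 1, 12, 9)
    assert out.data.min() >= 0  # relu output activation


def test_decoder_receptive_field():
    # five 3x3 dilation-2 layers: radius 5 * 2 = 10 px at scale 8
    model = fc.build_model(fc.ModelConfig(cbam_enabled=False, fusion_enabled=False, **TINY))
    c = model.cfg.channels(512)
    rng = np.random.default_rng(3)
    base = rng.random((1, c, 32, 32)).astype(np.float32)
    pert = base.copy()
    pert[0, :, 16, 16] += 1.0
    a = fc.decoder_forward(model, fc.FeatureMap(Tensor(base), 8)).data[0, 0]
    b = fc.decoder_forward(model, fc.FeatureMap(Tensor(pert), 8)).data[0, 0]
    diff = np.abs(a - b)
    changed = np.argwhere(diff > 1e-12)
    radius = np.abs(changed - 16).max() if len(changed) else 0
    assert radius <= 10


@pytest.mark.parametrize(
    "hw", [(64, 64), (64, 144), (128, 64), (128, 144), (192, 96)]
)
def test_model_forward_shape_contract(tiny_model, rng, hw):
    img = rng.random((*hw, 3)).astype(np.float32)
    dm = fc.model_forward(tiny_model, img)
    assert dm.grid.shape == hw
    count = fc.integrate(dm)
    assert np.isfinite(count) and count >= 0


def test_model_forward_deterministic(tiny_model, rng):
    img = rng.random((64, 64, 3)).astype(np.float32)
    a = fc.model_forward(tiny_model, img).grid
    b = fc.model_forward(tiny_model, img).grid
    np.testing.assert_array_equal(a, b)


@pytest.mark.parametrize(
    "fusion,cbam", [(False, False), (True, False), (False, True), (True, True)]
)
def test_ablation_lattice_builds_runs_and_differentiates(rng, fusion, cbam):
    model = fc.build_model(
        fc.ModelConfig(fusion_enabled=fusion, cbam_enabled=cbam, **TINY)
    )
    img = rng.random((2, 64, 64, 3)).astype(np.float32)
    gt = Tensor(rng.random((2, 1, 64, 64)).astype(np.float32) * 0.01)
    pred = model.forward(img)
    assert pred.shape == (2, 1, 64, 64)
    loss = fc.combined_loss(pred, gt)
    loss.backward()
    for name, p in model.named_parameters():
        assert p.grad is not None, name
        assert np.isfinite(p.grad).all(), name


def test_init_weights_gaussian_recipe():
    model = fc.build_model(fc.ModelConfig(width_multiplier=1 / 8, seed=0))
    fc.init_weights(model, backend_std=0.01)
    w = model.decoder_convs[0].weight.data  # 64x64x3x3 = 36864 weights
    assert w.size >= 10_000
    assert abs(w.std() - 0.01) < 0.001
    for conv in model.decoder_convs:
        assert np.all(conv.bias.data == 0.0)


def test_pretrained_frontend_unavailable_raises():
    with pytest.raises(RuntimeError, match="use_pretrained_frontend=False"):
        fc.build_model(fc.ModelConfig(use_pretrained_frontend=True, seed=0))


def test_checkpoint_round_trip_bit_exact(tmp_path, tiny_model):
    path = str(tmp_path / "ckpt.npz")
    fc.save_checkpoint(tiny_model, path, epoch=17)
    model, epoch = fc.load_checkpoint(path)
    assert epoch == 17
    assert model.cfg == tiny_model.cfg
    for (na, pa), (_, pb) in zip(model.named_parameters(), tiny_model.named_parameters()):
        np.testing.assert_array_equal(pa.data, pb.data)
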