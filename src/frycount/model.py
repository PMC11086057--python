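"""The multi-scale attention density-regression network.

A truncated VGG-16 frontend (13 convolution layers, only the first three
2x max-poolings retained) extracts features at 1/8 of the input resolution.
The backend fuses three scales (1/4, 1/8, 1/16) by channel concatenation,
refines the fused map with a channel+spatial attention block, decodes it
through five dilated (rate 2) 3x3 convolutions, and bilinearly up-samples
the single-channel output back to the input resolution — so the predicted
density map has the same size as the image and its sum is the predicted
count.

All channel counts scale with ``width_multiplier`` so a CPU-trainable
miniature of the same architecture can be built for experiments.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .density import DensityMap
from .nn import Conv2d, Linear, Module, SGD, Tensor, bilinear_resize, concat, maxpool2x2, no_grad
from .nn.layers import DTYPE

__all__ = [
    "ModelConfig",
    "FeatureMap",
    "FryCountNet",
    "build_model",
    "frontend_forward",
    "multiscale_fuse",
    "cbam_forward",
    "decoder_forward",
    "model_forward",
    "init_weights",
    "save_checkpoint",
    "load_checkpoint",
]

# first 13 convolution layers of VGG-16; 'M' marks the retained poolings
_VGG13_PLAN = [64, 64, "M", 128, 128, "M", 256, 256, 256, "M", 512, 512, 512, 512, 512, 512]

# channel statistics used to standardize [0,1] RGB inputs (ImageNet convention)
_IMG_MEAN = np.array([0.485, 0.456, 0.406])
_IMG_STD = np.array([0.229, 0.224, 0.225])

# decoder convolutions start at 0.7x the He scale: five stacked ReLU layers
# then shrink the pre-head activation RMS enough to keep momentum SGD stable
# at the reference recipe's step sizes without freezing learning
_DECODER_INIT_GAIN = 0.7


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``fusion_enabled`` / ``cbam_enabled`` realize the four ablation
    configurations (neither / multi-scale / attention / both).
    ``init`` selects the scratch initialization: "he" (default, suited to
    training without pretrained weights) or "gaussian" (N(0, 0.01), the
    scheme intended for a pretrained frontend).
    """

    width_multiplier: float = 1.0
    use_pretrained_frontend: bool = False
    pretrained_weights_path: str | None = None
    frontend_conv_layers: int = 13
    fusion_enabled: bool = True
    cbam_enabled: bool = True
    cbam_reduction: int = 16
    cbam_spatial_kernel: int = 7
    decoder_channels: tuple[int, ...] = (512, 512, 512, 256, 128)
    decoder_dilation: int = 2
    output_activation: str = "relu"
    init: str = "he"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.width_multiplier <= 1):
            raise ValueError("width_multiplier must be in (0, 1]")
        if self.frontend_conv_layers != 13:
            raise ValueError("the frontend is the fixed 13-convolution VGG-16 prefix")
        self.decoder_channels = tuple(int(c) for c in self.decoder_channels)
        if len(self.decoder_channels) != 5:
            raise ValueError(
                "decoder_channels must list exactly the five dilated-layer widths "
                f"(got {len(self.decoder_channels)})"
            )
        if self.cbam_spatial_kernel % 2 != 1 or self.cbam_spatial_kernel < 3:
            raise ValueError("cbam_spatial_kernel must be an odd integer >= 3")
        if self.output_activation not in ("relu", "none"):
            raise ValueError("output_activation must be 'relu' or 'none'")
        if self.init not in ("he", "gaussian"):
            raise ValueError("init must be 'he' or 'gaussian'")
        for c in self.decoder_channels:
            if self.channels(c) < 1:
                raise ValueError("width_multiplier collapses a layer below 1 channel")

    def channels(self, c: int) -> int:
        return max(1, int(round(c * self.width_multiplier)))


@dataclass
class FeatureMap:
    """A feature tensor plus its scale denominator relative to the input."""

    tensor: Tensor
    scale: int = 8


class _CBAM(Module):
    """Channel attention (pooled-vector shared MLP) then spatial attention
    (7x7 convolution over stacked channelwise mean/max maps)."""

    def __init__(self, channels: int, reduction: int, spatial_kernel: int, rng):
        if channels < reduction:
            raise ValueError(
                f"attention input has {channels} channels, fewer than the "
                f"reduction ratio {reduction}"
            )
        hidden = max(1, channels // reduction)
        self.fc1 = Linear(channels, hidden, rng=rng)
        self.fc2 = Linear(hidden, channels, rng=rng)
        self.spatial = Conv2d(2, 1, spatial_kernel, padding=spatial_kernel // 2, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        b, c = x.shape[0], x.shape[1]
        avg = x.mean(axis=(2, 3))
        mx = x.max(axis=(2, 3))
        att = (self.fc2(self.fc1(avg).relu()) + self.fc2(self.fc1(mx).relu())).sigmoid()
        x = x * att.reshape(b, c, 1, 1)
        sp = concat([x.mean(axis=1, keepdims=True), x.max(axis=1, keepdims=True)], axis=1)
        return x * self.spatial(sp).sigmoid()


class FryCountNet(Module):
    """Density-regression counting network (see module docstring)."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        ch = cfg.channels

        # frontend: 13 VGG-16 convolutions, poolings after blocks 1-3 only
        self.frontend_convs: list[Conv2d] = []
        self._plan: list[int | str] = list(_VGG13_PLAN)
        in_c = 3
        for item in self._plan:
            if item == "M":
                continue
            self.frontend_convs.append(
                Conv2d(in_c, ch(item), 3, padding=1, rng=rng, init=cfg.init)
            )
            in_c = ch(item)
        # index of the conv after which the scale-4 tap (F1) is taken
        self._f1_after = 3  # fourth conv ends block 2; its pooling yields scale 4

        trunk_c = ch(512)
        self.f1_channels = ch(128)
        if cfg.fusion_enabled:
            self.f3_conv = Conv2d(trunk_c, trunk_c, 3, padding=1, rng=rng, init=cfg.init)
            self.fuse_proj = Conv2d(
                self.f1_channels + 2 * trunk_c, trunk_c, 1, rng=rng, init=cfg.init
            )
        if cfg.cbam_enabled:
            self.cbam = _CBAM(trunk_c, cfg.cbam_reduction, cfg.cbam_spatial_kernel, rng)

        self.decoder_convs: list[Conv2d] = []
        in_c = trunk_c
        for c in cfg.decoder_channels:
            self.decoder_convs.append(
                Conv2d(
                    in_c,
                    ch(c),
                    3,
                    padding=cfg.decoder_dilation,
                    dilation=cfg.decoder_dilation,
                    rng=rng,
                    init=cfg.init,
                    init_gain=_DECODER_INIT_GAIN,
                )
            )
            in_c = ch(c)
        # small-scale head keeps the initial prediction near zero without
        # saturating the output nonlinearity (densities are ~1e-2 per pixel)
        self.out_proj = Conv2d(in_c, 1, 1, rng=rng, init="gaussian", init_std=0.01)

        if cfg.use_pretrained_frontend:
            self._load_pretrained_frontend()

    # -- stages ------------------------------------------------------------

    def _prepare(self, image: np.ndarray | Tensor) -> Tensor:
        """Accept HxWx3 or BxHxWx3 arrays in [0,1]; standardize to NCHW."""
        if isinstance(image, Tensor):
            return image
        arr = np.asarray(image, dtype=DTYPE)
        if arr.ndim == 3:
            arr = arr[None]
        if arr.ndim != 4 or arr.shape[-1] != 3:
            raise ValueError(f"expected HxWx3 or BxHxWx3 image array, got {arr.shape}")
        arr = (arr - _IMG_MEAN.astype(DTYPE)) / _IMG_STD.astype(DTYPE)
        return Tensor(arr.transpose(0, 3, 1, 2))

    @staticmethod
    def _check_divisible(h: int, w: int) -> None:
        if h % 8 or w % 8:
            raise ValueError(
                f"input spatial size {h}x{w} violates the divisible-by-8 "
                "constraint imposed by the three 2x poolings"
            )

    def frontend(self, x: np.ndarray | Tensor) -> tuple[FeatureMap, FeatureMap]:
        """Run the 13-convolution frontend; return taps at scales 4 and 8."""
        t = self._prepare(x)
        self._check_divisible(t.shape[2], t.shape[3])
        f1 = None
        conv_i = 0
        for item in self._plan:
            if item == "M":
                t = maxpool2x2(t)
            else:
                t = self.frontend_convs[conv_i](t).relu()
                conv_i += 1
            if conv_i == self._f1_after + 1 and item == "M":
                f1 = t
        # F1 is the activation right after the second pooling (scale 4)
        if f1 is None:  # pragma: no cover - plan always contains the tap
            raise RuntimeError("frontend tap not reached")
        return FeatureMap(f1, scale=4), FeatureMap(t, scale=8)

    @staticmethod
    def _halve(t: Tensor) -> Tensor:
        h, w = t.shape[2], t.shape[3]
        if h % 2 == 0 and w % 2 == 0:
            return maxpool2x2(t)
        return bilinear_resize(t, (h + 1) // 2, (w + 1) // 2)

    def fuse(self, f1: FeatureMap, f2: FeatureMap) -> FeatureMap:
        """Three-scale fusion at F2's resolution (identity when disabled)."""
        if not self.cfg.fusion_enabled:
            return f2
        h, w = f2.tensor.shape[2], f2.tensor.shape[3]
        f3 = self._halve(self.f3_conv(f2.tensor).relu())  # scale 16
        f1_down = bilinear_resize(f1.tensor, h, w)
        f3_up = bilinear_resize(f3, h, w)
        fused = concat([f1_down, f2.tensor, f3_up], axis=1)
        return FeatureMap(self.fuse_proj(fused).relu(), scale=8)

    def attend(self, f: FeatureMap) -> FeatureMap:
        if not self.cfg.cbam_enabled:
            return f
        return FeatureMap(self.cbam(f.tensor), scale=f.scale)

    def decode(self, f: FeatureMap) -> Tensor:
        t = f.tensor
        for conv in self.decoder_convs:
            t = conv(t).relu()
        t = self.out_proj(t)
        if self.cfg.output_activation == "relu":
            t = t.relu()
        return t

    def forward(self, image: np.ndarray | Tensor) -> Tensor:
        """Full pass: (B,)HxWx3 image -> (B, 1, H, W) density tensor."""
        f1, f2 = self.frontend(image)
        h, w = f2.tensor.shape[2] * 8, f2.tensor.shape[3] * 8
        fused = self.attend(self.fuse(f1, f2))
        raw = self.decode(fused)
        return bilinear_resize(raw, h, w)

    # -- pretrained weights -------------------------------------------------

    def _load_pretrained_frontend(self) -> None:
        path = self.cfg.pretrained_weights_path
        if not path:
            raise RuntimeError(
                "pretrained frontend weights are not bundled and cannot be "
                "downloaded here; either pass pretrained_weights_path pointing "
                "at a local VGG-16 weight archive, or set "
                "use_pretrained_frontend=False to train from scratch"
            )
        with np.load(path, allow_pickle=False) as npz:
            for i, conv in enumerate(self.frontend_convs):
                w, b = npz[f"conv{i}.weight"], npz[f"conv{i}.bias"]
                if w.shape != conv.weight.data.shape:
                    raise ValueError(
                        f"pretrained conv{i} shape {w.shape} != {conv.weight.data.shape} "
                        "(width_multiplier must be 1 for pretrained weights)"
                    )
                conv.weight.data = w.astype(DTYPE)
                conv.bias.data = b.astype(DTYPE)


def build_model(cfg: ModelConfig | None = None) -> FryCountNet:
    """Construct the network; same config + seed gives identical weights."""
    return FryCountNet(cfg or ModelConfig())


# -- functional wrappers (stage-level API) ---------------------------------


def frontend_forward(model: FryCountNet, image) -> tuple[FeatureMap, FeatureMap]:
    return model.frontend(image)


def multiscale_fuse(model: FryCountNet, f1: FeatureMap, f2: FeatureMap) -> FeatureMap:
    return model.fuse(f1, f2)


def cbam_forward(model: FryCountNet, f: FeatureMap) -> FeatureMap:
    return model.attend(f)


def decoder_forward(model: FryCountNet, f: FeatureMap) -> Tensor:
    return model.decode(f)


def model_forward(model: FryCountNet, image: np.ndarray) -> DensityMap:
    """Inference: HxWx3 image in [0,1] -> full-resolution DensityMap."""
    with no_grad():
        out = model.forward(image)
    grid = out.data[0, 0].astype(float)
    if model.cfg.output_activation == "none":
        grid = np.maximum(grid, 0.0)
    return DensityMap(grid, sigma=float("nan"))


def init_weights(model: FryCountNet, backend_std: float = 0.01) -> None:
    """Classical initialization recipe: backend convolutions N(0, backend_std),
    biases 0; frontend from pretrained weights when configured, otherwise the
    same Gaussian scheme."""
    rng = np.random.default_rng(model.cfg.seed)
    if model.cfg.use_pretrained_frontend:
        model._load_pretrained_frontend()
    else:
        for conv in model.frontend_convs:
            conv.reinit(rng, backend_std)
    backend: list[Module] = []
    if model.cfg.fusion_enabled:
        backend += [model.f3_conv, model.fuse_proj]
    if model.cfg.cbam_enabled:
        backend.append(model.cbam)
    backend += list(model.decoder_convs) + [model.out_proj]
    for mod in backend:
        for _, p in mod.named_parameters():
            if p.data.ndim > 1:
                p.data = rng.normal(0.0, backend_std, size=p.data.shape).astype(DTYPE)
            else:
                p.data = np.zeros_like(p.data)


# -- checkpoints ------------------------------------------------------------


def save_checkpoint(model: FryCountNet, path: str, epoch: int = 0) -> None:
    """Single-file archive: weights + config + epoch; loads bit-exactly."""
    state = {f"param:{k}": v for k, v in model.state_dict().items()}
    cfg = asdict(model.cfg)
    cfg["decoder_channels"] = list(cfg["decoder_channels"])
    np.savez_compressed(path, __config__=np.str_(json.dumps(cfg)), __epoch__=np.int64(epoch), **state)


def load_checkpoint(path: str) -> tuple[FryCountNet, int]:
    with np.load(path, allow_pickle=False) as npz:
        cfg_d = json.loads(str(npz["__config__"]))
        cfg_d["decoder_channels"] = tuple(cfg_d["decoder_channels"])
        pretrained = cfg_d.pop("use_pretrained_frontend", False)
        cfg = ModelConfig(use_pretrained_frontend=False, **cfg_d)
        epoch = int(npz["__epoch__"])
        model = FryCountNet(cfg)
        model.cfg.use_pretrained_frontend = bool(pretrained)
        state = {k[len("param:"):]: npz[k] for k in npz.files if k.startswith("param:")}
    model.load_state_dict(state)
    return model, epoch
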