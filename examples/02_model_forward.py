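"""Build the counting network and push an image through it.

Uses a 1/8-width miniature (the full-width model has ~20M parameters and
is meant for GPU-scale training).  The output density map has the same
size as the input image; its sum is the predicted count.
"""

from frycount import ModelConfig, SceneSpec, build_model, model_forward, integrate, render_scene

image, points = render_scene(SceneSpec(width=192, height=144, n_fry=30, seed=3))

cfg = ModelConfig(width_multiplier=1 / 8, seed=0)
model = build_model(cfg)
print(f"parameters: {model.num_parameters():,} (width multiplier {cfg.width_multiplier})")

dm = model_forward(model, image)
print(f"input {image.shape[:2]} -> density map {dm.grid.shape}")
print(f"untrained predicted count: {integrate(dm):.2f} (true {points.count()})")
# An untrained network predicts a meaningless count; see
# 04_train_tiny.py for the full train-then-count workflow.

# the four ablation variants all build from the same config surface
for fusion, cbam in [(False, False), (True, False), (False, True), (True, True)]:
    m = build_model(
        ModelConfig(width_multiplier=1 / 8, fusion_enabled=fusion, cbam_enabled=cbam, seed=0)
    )
    label = ("multi-scale " if fusion else "") + ("attention" if cbam else "") or "plain trunk"
    print(f"  {label:<24} {m.num_parameters():>10,} params")
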