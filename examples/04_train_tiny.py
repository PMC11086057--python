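"""Train a CPU-scale miniature end to end and count held-out scenes.

Generates 80 easy benchmark scenes (192x144 px, 5-40 well-separated fry),
trains a 1/8-width network for a few epochs with the reference recipe
(SGD, momentum 0.95, weight decay 5e-4) at a learning rate scaled up to
1e-6 for the miniature, then evaluates counting error on the 20 held-out
scenes.  Takes a few minutes on one CPU; increase epochs for better
accuracy.
"""

import numpy as np

from frycount import (
    ModelConfig,
    TrainConfig,
    build_model,
    easy_benchmark,
    evaluate,
    fit,
    make_samples,
)

scenes = easy_benchmark(80, counts=(5, 40), seed=42)
samples = make_samples(scenes)
train_set, val_set, held_out = samples[:48], samples[48:60], samples[60:]
print(f"{len(train_set)} train / {len(val_set)} val / {len(held_out)} held-out scenes")

model = build_model(ModelConfig(width_multiplier=1 / 8, seed=42, output_activation="none"))
cfg = TrainConfig(epochs=10, batch_size=6, learning_rate=1e-6, seed=42)
model, history = fit(model, train_set, val_set, cfg, progress=True)
print(f"best validation MAE {min(r[2] for r in history.per_epoch):.3f} "
      f"at epoch {history.best_epoch}")

report = evaluate(model, held_out, by_level=False)
print(f"held-out: {report.summary()}")
rel = np.mean([err / max(y, 1) for y, _, err in report.per_image])
print(f"mean relative count error: {100 * rel:.1f}%")
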