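"""Generate a full synthetic dataset with the study's split design.

The default DatasetSpec mirrors the four density levels
(Low [0,249], Medium [250,499], High [500,749], Higher [750,1000]) and
split sizes (390 train / 63 validation / 103 test).  Here the per-level
counts are scaled down 20x and the scenes shrunk so the example runs in
seconds; drop the overrides for the full-size dataset.
"""

import collections
import tempfile

from frycount import DatasetSpec, SceneSpec, make_dataset

ds = DatasetSpec(
    split_sizes={
        "train": {"Low": 6, "Medium": 7, "High": 5, "Higher": 1},
        "val": {"Low": 1, "Medium": 1, "High": 1, "Higher": 1},
        "test": {"Low": 3, "Medium": 1, "High": 1, "Higher": 1},
    },
    scene=SceneSpec(width=256, height=192, n_fry=0),
    seed=0,
)
with tempfile.TemporaryDirectory() as out:
    manifest = make_dataset(ds, out)
    per_split = collections.Counter(r["split"] for r in manifest)
    print(f"wrote {len(manifest)} scenes: {dict(per_split)}")
    for row in manifest[:5]:
        print(f"  {row['filename']}  {row['level']:<7} count={row['count']}")

full = DatasetSpec()  # the full-size defaults
totals = {s: sum(d.values()) for s, d in full.split_sizes.items()}
print(f"full-size split design: {totals}")
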