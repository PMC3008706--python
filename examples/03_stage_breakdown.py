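"""Per-stage error accounting on a crowded scene.

The pipeline has three assembly stages: greedy claiming from filter maxima,
recovery of overlooked (masked) nuclei from unclaimed slices, and conflict
resolution of overlapping claims. On a crowded scene with dim neighbors and
oversized double-lobed nuclei, recovery cuts the false-negative rate and
conflict resolution cuts the false-positive rate.
"""

from blobslice import detect, match_detections
from blobslice.synthetic_data import (
    crowded_spec,
    default_config,
    generate_scene,
    train_default_model,
)

model = train_default_model()
scene = generate_scene(crowded_spec(seed=42))
config = default_config(scene.spec).with_spacing(scene.spacing)

stages = {}
record = detect(scene.volume, model, config, stage_records=stages)

tol = config.nuclear_diameter / 2 * config.xy_spacing
print("stage                 FN%    FP%")
for name, rec in [
    ("initial maxima", stages["seeded"]),
    ("after recovery", stages["recovered"]),
    ("after resolution", record),
]:
    rep = match_detections(scene.truth, rec, scene.spacing, tol)
    print(f"{name:20s} {rep.fn_rate:5.1f}  {rep.fp_rate:5.1f}")
# The characteristic pattern: recovery halves the misses (dim nuclei masked
# by bright neighbors become seeds), at the cost of a few extra redundant
# detections, which conflict resolution then merges away.
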