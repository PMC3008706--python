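"""Retrain the 7-D Gaussian slice-membership model from labeled candidates.

The model decides whether a candidate slice on a nearby plane belongs to a
nucleus (member) or to a neighbor (distractor). Training data is a worksheet
of candidate slices around each seed; here the synthetic ground truth plays
the role of the human curator who deletes non-members.
"""

from blobslice import classify, train_model
from blobslice.synthetic_data import (
    generate_scene,
    scene_training_labels,
    training_spec,
)
from dataclasses import replace

train_scene = generate_scene(training_spec())
examples = scene_training_labels(train_scene)
n_member = sum(1 for _, label in examples if label == "member")
print(f"training examples: {n_member} members, {len(examples) - n_member} distractors")

model = train_model(examples)
print(f"member mean feature vector:     {model.member_mean.round(2)}")
print(f"distractor mean feature vector: {model.distractor_mean.round(2)}")

held_out = generate_scene(replace(training_spec(), seed=91))
test_examples = scene_training_labels(held_out)
correct = sum(1 for f, label in test_examples if classify(f, model)[0] == label)
print(f"held-out accuracy: {100 * correct / len(test_examples):.1f} %")
# Feature order: z-offset; offset/radius/intensity relative to the center
# slice; offset/radius/intensity relative to the closest intervening slice.
# Members sit near zero offsets and mild log-ratios; distractors are offset
# and dissimilar.
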