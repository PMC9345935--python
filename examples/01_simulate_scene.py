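"""Generate a synthetic wetland-like scene and inspect its composition.

Builds the default five-class recipe (four vegetation classes plus "other
types"), renders it, and prints per-class pixel fractions — the fragmented,
irregular patch geometry stands in for a UAV orthomosaic of a karst wetland.
"""

import numpy as np

from karstseg import default_recipe, generate_scene

recipe = default_recipe(size=(512, 512), seed=0)
scene, labels = generate_scene(recipe)

print(f"scene: {scene.shape[0]} x {scene.shape[1]} pixels, "
      f"{scene.num_channels} channels")
print("class coverage (fraction of pixels):")
for entry in labels.legend.entries:
    frac = float((labels.labels == entry.class_id).mean())
    print(f"  {entry.name:<24} {frac:.3f}")

# Each fraction is the share of the scene occupied by that vegetation type;
# the 'other_types' share is pinned at the recipe's other_fraction target.
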