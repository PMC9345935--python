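import numpy as np
import pytest

from karstseg import (
    ClassSpec,
    Legend,
    LegendEntry,
    LabelRaster,
    Scene,
    SceneRecipe,
)


@pytest.fixture
def legend5():
    """Five-class wetland legend (4 vegetation classes + other types)."""
    return Legend(
        (
            LegendEntry(0, "karst_water", (52, 84, 120)),
            LegendEntry(1, "karst_grass", (110, 160, 70)),
            LegendEntry(2, "karst_broadleaf_forest", (40, 95, 45)),
            LegendEntry(3, "karst_aquatic_flora", (95, 150, 110)),
            LegendEntry(4, "other_types", (150, 135, 110)),
        )
    )


@pytest.fixture
def legend2():
    return Legend(
        (
            LegendEntry(0, "background", (0, 0, 0)),
            LegendEntry(1, "foreground", (255, 255, 255)),
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_scene(rng):
    """64x64 random-but-valid RGB scene."""
    pixels = rng.integers(0, 256, size=(64, 64, 3)).astype(np.float32)
    return Scene(pixels)


@pytest.fixture
def small_labels(small_scene, legend5, rng):
    labels = rng.integers(0, 5, size=small_scene.shape).astype(np.int64)
    return LabelRaster(labels, legend5)


@pytest.fixture
def noisefree_recipe(legend5):
    """Recipe rendering exactly the legend colors (color_sd 0, no texture),
    so a nearest-color rule recovers the labels exactly."""
    classes = tuple(
        ClassSpec(e.class_id, e.name, tuple(float(v) for v in e.color), 0.0, None)
        for e in legend5.entries
    )
    return SceneRecipe(
        size=(128, 128), classes=classes, patch_scale=16.0,
        other_fraction=0.1, other_class_id=4, seed=7,
    )
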