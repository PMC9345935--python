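"""Synthetic wetland-like scenes and mock classifiers.

The real study imagery (UAV orthomosaics of a karst wetland) is not publicly
deposited, so this module generates labeled stand-in scenes with the
properties that matter to the pipeline: fragmented, intersecting, irregular
vegetation patches; per-class color statistics; and per-class texture so that
windowed texture channels carry discriminative signal that single-pixel color
does not.

Label geometry: one smoothed Gaussian noise field per class, per-pixel argmax.
The smoothing length (``patch_scale``) is the single knob controlling patch
size and fragmentation. An optional "other types" class is carved out at an
exact target fraction by thresholding its field at the matching quantile.

Rendering: class mean color + white Gaussian noise + an optional texture
pattern (oriented sinusoidal stripes, or smoothed-noise speckle), clipped to
[0, 255].

Mock classifiers (nearest mean color, optionally on an r x r window mean)
satisfy the pixel-classifier contract with an exactly known receptive field;
they are the oracles for the seamless-stitching guarantees.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter, uniform_filter

from .errors import ConfigError, UsageError
from .network import PixelClassifier, binary_legend
from .raster import LabelRaster, Legend, LegendEntry, Scene

__all__ = [
    "Stripes",
    "Speckle",
    "ClassSpec",
    "SceneRecipe",
    "default_recipe",
    "texture_pair_recipe",
    "generate_scene",
    "generate_texture_pair",
    "MockClassifier",
    "make_mock_classifier",
    "make_single_class_mock",
]


# ---------------------------------------------------------------------------
# Recipes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Stripes:
    """Oriented sinusoidal stripe pattern (period px, amplitude DN, angle deg)."""

    period: float
    amplitude: float
    angle: float = 0.0


@dataclass(frozen=True)
class Speckle:
    """Smoothed-noise speckle (grain = smoothing sigma px, amplitude DN)."""

    grain: float
    amplitude: float


@dataclass(frozen=True)
class ClassSpec:
    class_id: int
    name: str
    color_mean: tuple[float, float, float]
    color_sd: float
    texture: Stripes | Speckle | None = None
    #: legend palette color; defaults to the rounded color mean. Needed when
    #: two classes share a rendering color (texture pairs) since legend
    #: palette colors must be unique.
    display_color: tuple[int, int, int] | None = None

    @property
    def palette_color(self) -> tuple[int, int, int]:
        if self.display_color is not None:
            return tuple(int(v) for v in self.display_color)
        return tuple(int(round(v)) for v in self.color_mean)


@dataclass(frozen=True)
class SceneRecipe:
    """Everything needed to render one labeled scene deterministically."""

    size: tuple[int, int] = (512, 512)
    classes: tuple[ClassSpec, ...] = ()
    patch_scale: float = 40.0
    other_fraction: float = 0.0
    other_class_id: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.patch_scale < 1:
            raise ConfigError("patch_scale must be >= 1")
        if not 0 <= self.other_fraction < 1:
            raise ConfigError("other_fraction must be in [0, 1)")
        if self.other_fraction > 0 and self.other_class_id is None:
            raise ConfigError("other_fraction > 0 needs other_class_id")
        ids = [c.class_id for c in self.classes]
        if self.other_class_id is not None and self.other_class_id not in ids:
            raise ConfigError("other_class_id must be one of the recipe classes")
        for c in self.classes:
            if min(c.color_mean) < 0 or max(c.color_mean) > 255:
                raise ConfigError("class colors must lie within [0, 255]")

    def legend(self) -> Legend:
        entries = tuple(
            LegendEntry(c.class_id, c.name, c.palette_color)
            for c in sorted(self.classes, key=lambda c: c.class_id)
        )
        return Legend(entries)

    # -- YAML ---------------------------------------------------------------

    def to_yaml(self, path) -> None:
        d = {
            "size": list(self.size),
            "patch_scale": self.patch_scale,
            "other_fraction": self.other_fraction,
            "other_class_id": self.other_class_id,
            "seed": self.seed,
            "classes": [
                {
                    "id": c.class_id,
                    "name": c.name,
                    "color_mean": list(c.color_mean),
                    "color_sd": c.color_sd,
                    "texture": _texture_to_dict(c.texture),
                    "display_color": None
                    if c.display_color is None
                    else list(c.display_color),
                }
                for c in self.classes
            ],
        }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SceneRecipe":
        d = yaml.safe_load(Path(path).read_text())
        classes = tuple(
            ClassSpec(
                int(c["id"]),
                str(c["name"]),
                tuple(float(v) for v in c["color_mean"]),
                float(c["color_sd"]),
                _texture_from_dict(c.get("texture")),
                None
                if c.get("display_color") is None
                else tuple(int(v) for v in c["display_color"]),
            )
            for c in d["classes"]
        )
        return cls(
            size=tuple(d.get("size", (512, 512))),
            classes=classes,
            patch_scale=float(d.get("patch_scale", 40.0)),
            other_fraction=float(d.get("other_fraction", 0.0)),
            other_class_id=d.get("other_class_id"),
            seed=int(d.get("seed", 0)),
        )


def _texture_to_dict(t):
    if t is None:
        return None
    if isinstance(t, Stripes):
        return {"kind": "stripes", "period": t.period, "amplitude": t.amplitude,
                "angle": t.angle}
    return {"kind": "speckle", "grain": t.grain, "amplitude": t.amplitude}


def _texture_from_dict(d):
    if d is None:
        return None
    if d["kind"] == "stripes":
        return Stripes(float(d["period"]), float(d["amplitude"]), float(d.get("angle", 0.0)))
    if d["kind"] == "speckle":
        return Speckle(float(d["grain"]), float(d["amplitude"]))
    raise ConfigError(f"unknown texture kind {d['kind']!r}")


def default_recipe(size: tuple[int, int] = (512, 512), seed: int = 0) -> SceneRecipe:
    """Four vegetation classes plus an 'other types' class.

    Colors and textures loosely emulate the mapped categories: dark smooth
    open water, striped grassland, coarsely speckled broad-leaved canopy,
    finer-textured floating aquatic flora, and a brownish other/agriculture
    class. Textures differ across classes so texture channels are informative.
    """
    classes = (
        ClassSpec(0, "karst_water", (52.0, 84.0, 120.0), 10.0, None),
        ClassSpec(1, "karst_grass", (110.0, 160.0, 70.0), 16.0,
                  Stripes(period=9.0, amplitude=14.0, angle=30.0)),
        ClassSpec(2, "karst_broadleaf_forest", (40.0, 95.0, 45.0), 18.0,
                  Speckle(grain=2.5, amplitude=26.0)),
        ClassSpec(3, "karst_aquatic_flora", (95.0, 150.0, 110.0), 14.0,
                  Stripes(period=14.0, amplitude=12.0, angle=100.0)),
        ClassSpec(4, "other_types", (150.0, 135.0, 110.0), 14.0, None),
    )
    return SceneRecipe(
        size=size,
        classes=classes,
        patch_scale=40.0,
        other_fraction=0.12,
        other_class_id=4,
        seed=seed,
    )


def two_class_recipe(size: tuple[int, int] = (512, 512), seed: int = 0) -> SceneRecipe:
    """Water-vs-grass scene for single-model training checks."""
    classes = (
        ClassSpec(0, "karst_water", (52.0, 84.0, 120.0), 10.0, None),
        ClassSpec(1, "karst_grass", (110.0, 160.0, 70.0), 16.0,
                  Stripes(period=9.0, amplitude=14.0, angle=30.0)),
    )
    return SceneRecipe(size=size, classes=classes, patch_scale=40.0, seed=seed)


def texture_pair_recipe(size: tuple[int, int] = (256, 256), seed: int = 0) -> SceneRecipe:
    """Two classes identical in color statistics, separable only by texture.

    Both classes carry speckle of matched variance but different grain — one
    nearly white, one smooth — so the single-pixel intensity histograms
    overlap while windowed co-occurrence statistics (contrast, and friends)
    differ strongly.
    """
    classes = (
        ClassSpec(0, "fine_speckle", (120.0, 120.0, 120.0), 8.0,
                  Speckle(grain=0.7, amplitude=9.5),
                  display_color=(220, 220, 80)),
        ClassSpec(1, "coarse_speckle", (120.0, 120.0, 120.0), 8.0,
                  Speckle(grain=3.0, amplitude=11.0),
                  display_color=(80, 80, 220)),
    )
    return SceneRecipe(size=size, classes=classes, patch_scale=48.0, seed=seed)


# ---------------------------------------------------------------------------
# Scene generation
# ---------------------------------------------------------------------------

def generate_scene(recipe: SceneRecipe) -> tuple[Scene, LabelRaster]:
    """Render a labeled scene; deterministic under the recipe seed."""
    if not recipe.classes:
        raise ConfigError("recipe has no classes")
    h, w = recipe.size
    rng = np.random.default_rng(recipe.seed)
    legend = recipe.legend() if len(recipe.classes) >= 2 else None
    ordered = sorted(recipe.classes, key=lambda c: c.class_id)

    if len(ordered) == 1:
        labels = np.full((h, w), ordered[0].class_id, dtype=np.int64)
    else:
        main = [c for c in ordered if c.class_id != recipe.other_class_id]
        fields = {}
        for c in ordered:  # draw in class order for determinism
            fields[c.class_id] = gaussian_filter(
                rng.standard_normal((h, w)), sigma=recipe.patch_scale, mode="reflect"
            )
        main_stack = np.stack([fields[c.class_id] for c in main], axis=2)
        win = np.argmax(main_stack, axis=2)
        labels = np.array([c.class_id for c in main], dtype=np.int64)[win]
        if recipe.other_fraction > 0:
            other = fields[recipe.other_class_id]
            gap = np.max(main_stack, axis=2) - other
            thr = np.quantile(gap, recipe.other_fraction)
            labels[gap < thr] = recipe.other_class_id

    pixels = np.zeros((h, w, 3), dtype=np.float64)
    for c in ordered:
        sel = labels == c.class_id
        noise = rng.normal(0.0, c.color_sd, size=(h, w, 3))
        layer = np.asarray(c.color_mean, dtype=np.float64) + noise
        pattern = _texture_pattern(c.texture, (h, w), rng)
        if pattern is not None:
            layer += pattern[:, :, None]
        pixels[sel] = layer[sel]
    pixels = np.clip(pixels, 0.0, 255.0).astype(np.float32)
    if legend is None:
        # single-class recipes still need a valid 2-class legend
        c = ordered[0]
        legend = Legend(
            (
                LegendEntry(0, c.name, tuple(int(round(v)) for v in c.color_mean)),
                LegendEntry(1, "unused", (255, 255, 255)),
            )
        ) if c.class_id == 0 else None
        if legend is None:
            raise ConfigError("single-class recipes must use class_id 0")
    scene = Scene(pixels)
    return scene, LabelRaster(labels, legend)


def _texture_pattern(texture, shape, rng: np.random.Generator):
    """Additive texture field; always consumes the same rng draws per kind so
    label determinism is preserved across texture edits."""
    if texture is None:
        return None
    h, w = shape
    if isinstance(texture, Stripes):
        yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
        theta = np.deg2rad(texture.angle)
        phase = rng.uniform(0, 2 * np.pi)
        t = (xx * np.cos(theta) + yy * np.sin(theta)) / texture.period
        return texture.amplitude * np.sin(2 * np.pi * t + phase)
    if isinstance(texture, Speckle):
        g = gaussian_filter(rng.standard_normal((h, w)), sigma=texture.grain)
        sd = g.std()
        if sd > 0:
            g = g / sd
        return texture.amplitude * g
    raise ConfigError(f"unknown texture {texture!r}")


def generate_texture_pair(recipe: SceneRecipe) -> tuple[Scene, LabelRaster]:
    """Generate a scene whose classes share color statistics but differ in
    texture; refuses recipes where color means or sds differ."""
    if len(recipe.classes) < 2:
        raise ConfigError("texture pair needs >= 2 classes")
    ref = recipe.classes[0]
    for c in recipe.classes[1:]:
        if c.color_mean != ref.color_mean or c.color_sd != ref.color_sd:
            raise ConfigError(
                "texture-pair classes must share color_mean and color_sd"
            )
    texs = [c.texture for c in recipe.classes]
    if len(set(texs)) < len(texs):
        raise ConfigError("texture-pair classes must have distinct textures")
    return generate_scene(recipe)


# ---------------------------------------------------------------------------
# Mock classifiers
# ---------------------------------------------------------------------------

class MockClassifier(PixelClassifier):
    """Nearest-mean-color decision rule with an exactly known receptive field.

    ``nearest_color`` (r = 1) classifies each pixel by the legend class whose
    palette color is closest in RGB; ``window_mean_color`` applies the same
    rule to the r x r local mean, so its output at a pixel depends on inputs
    within the r-window only. Probabilities are one-hot with a small label
    smoothing epsilon so they are valid softmax-like outputs.
    """

    def __init__(self, legend: Legend, mode: str, r: int = 1, smoothing: float = 1e-3):
        if mode not in ("nearest_color", "window_mean_color"):
            raise UsageError(f"unknown mock mode {mode!r}")
        if mode == "nearest_color":
            r = 1
        else:
            if r <= 1 or r % 2 == 0:
                raise UsageError("window_mean_color needs odd r > 1")
        self.mode = mode
        self.legend = legend
        self.classes = legend.class_ids
        self.receptive_field = r
        self.smoothing = smoothing
        self.metadata = {"mock": mode, "r": r}
        self._colors = np.array(
            [legend.color_of(c) for c in legend.class_ids], dtype=np.float64
        )

    def predict_tile(self, tile: np.ndarray) -> np.ndarray:
        rgb = np.asarray(tile, dtype=np.float64)[:, :, :3]
        if self.mode == "window_mean_color":
            rgb = uniform_filter(
                rgb, size=(self.receptive_field, self.receptive_field, 1),
                mode="reflect",
            )
        d2 = ((rgb[:, :, None, :] - self._colors[None, None, :, :]) ** 2).sum(axis=3)
        nearest = np.argmin(d2, axis=2)
        k = len(self.classes)
        probs = np.full(nearest.shape + (k,), self.smoothing / k)
        np.put_along_axis(probs, nearest[..., None], 1.0 - self.smoothing * (k - 1) / k, axis=-1)
        return probs


class _SingleClassMock(PixelClassifier):
    """2-way wrapper: foreground where the nearest legend color is the target."""

    def __init__(self, inner: MockClassifier, target_class: int):
        self.inner = inner
        self.target_class = target_class
        self.classes = (0, 1)
        self.receptive_field = inner.receptive_field
        self.legend = binary_legend(inner.legend, target_class)
        self.metadata = {"mock": inner.mode, "target_class": target_class}

    def predict_tile(self, tile: np.ndarray) -> np.ndarray:
        full = self.inner.predict_tile(tile)
        ch = list(self.inner.classes).index(self.target_class)
        nearest_is_target = full.argmax(axis=2) == ch
        eps = self.inner.smoothing
        fg = np.where(nearest_is_target, 1.0 - eps / 2, eps / 2)
        return np.stack([1.0 - fg, fg], axis=2)


def make_mock_classifier(
    legend: Legend, mode: str = "nearest_color", r: int = 1, smoothing: float = 1e-3
) -> MockClassifier:
    return MockClassifier(legend, mode, r=r, smoothing=smoothing)


def make_single_class_mock(
    legend: Legend,
    target_class: int,
    mode: str = "nearest_color",
    r: int = 1,
    smoothing: float = 1e-3,
) -> PixelClassifier:
    """One-vs-rest mock expert for one legend class (for fusion tests)."""
    return _SingleClassMock(MockClassifier(legend, mode, r=r, smoothing=smoothing), target_class)
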