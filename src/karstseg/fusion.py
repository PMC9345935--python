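"""Maximum-probability fusion of single-class classifiers.

Each one-vs-rest model j reports, per pixel, the softmax probability that its
own target class is present. Fusion stacks these foreground maps and assigns
every pixel the class whose dedicated model is most confident:

    P(X_i) = foreground probability of class i's model
    label  = argmax_i P(X_i)      (ties -> lowest class id)

Pixels where no model reaches the confidence threshold tau fall back to the
designated "other types" class. Background probabilities (1 - foreground) are
not redistributed across classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DataError, UsageError
from .inference import ProbabilityMap, TileScheme, predict_seamless
from .raster import LabelRaster, Legend, Scene

logger = logging.getLogger(__name__)

__all__ = ["SingleClassMap", "FusionPolicy", "fuse_max_probability", "fuse_pipeline"]


@dataclass
class SingleClassMap:
    """Foreground-probability grid of one one-vs-rest model."""

    class_id: int
    foreground: np.ndarray  # H x W in [0, 1]
    source: dict | None = None

    def __post_init__(self):
        self.foreground = np.asarray(self.foreground, dtype=np.float64)
        if self.foreground.ndim != 2:
            raise UsageError("foreground must be a 2-D grid")
        if self.foreground.min() < -1e-9 or self.foreground.max() > 1 + 1e-9:
            raise DataError("foreground probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class FusionPolicy:
    """Where unconfident pixels go and at what threshold."""

    other_class_id: int
    confidence_threshold: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.confidence_threshold <= 1.0:
            raise UsageError("confidence_threshold must be in [0, 1]")


def fuse_max_probability(
    maps: list[SingleClassMap],
    policy: FusionPolicy,
    legend: Legend,
    mask: np.ndarray = None,
) -> tuple[LabelRaster, ProbabilityMap]:
    """Per-pixel maximum-probability fusion of >= 2 single-class maps.

    Returns the fused label raster and the stacked, per-pixel renormalized
    probability map (channels in ascending class-id order) for inspection.
    Pixels whose maximal foreground probability falls below the threshold are
    assigned ``policy.other_class_id``.
    """
    if len(maps) < 2:
        raise UsageError("fusion needs at least 2 single-class maps")
    ids = [m.class_id for m in maps]
    if len(set(ids)) != len(ids):
        raise UsageError(f"duplicate class ids in fusion: {ids}")
    if policy.other_class_id not in legend.class_ids:
        raise UsageError("other_class_id not in legend")
    shape = maps[0].foreground.shape
    for m in maps:
        if m.foreground.shape != shape:
            raise DataError("all foreground maps must share the same grid")
    order = np.argsort(ids)
    sorted_ids = np.asarray(ids, dtype=np.int64)[order]
    stack = np.stack([maps[i].foreground for i in order], axis=2)
    winner = np.argmax(stack, axis=2)  # first max -> lowest class id
    maxp = np.take_along_axis(stack, winner[..., None], axis=2)[..., 0]
    labels = sorted_ids[winner]
    labels[maxp < policy.confidence_threshold] = policy.other_class_id
    if mask is not None:
        labels[~np.asarray(mask, dtype=bool)] = legend.nodata_id
    total = stack.sum(axis=2, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        renorm = np.where(total > 0, stack / total, 1.0 / stack.shape[2])
    prob_map = ProbabilityMap(
        renorm, legend, mask=mask, class_ids=tuple(int(i) for i in sorted_ids)
    )
    return LabelRaster(labels, legend), prob_map


def fuse_pipeline(
    scene: Scene,
    single_class_models: list,
    scheme: TileScheme = TileScheme(),
    policy: FusionPolicy = None,
    legend: Legend = None,
) -> LabelRaster:
    """Seamless per-model inference followed by maximum-probability fusion.

    Each model must be a 2-class classifier tagged with its target class
    (``model.target_class`` or ``metadata["target_class"]``). Per-class
    coverage fractions of the fused map are logged.
    """
    if policy is None or legend is None:
        raise UsageError("fuse_pipeline requires a policy and a legend")
    maps = []
    for model in single_class_models:
        target = getattr(model, "target_class", None)
        if target is None:
            target = (model.metadata or {}).get("target_class")
        if target is None:
            raise ConfigError("single-class model lacks a target-class tag")
        pm = predict_seamless(scene, model, scheme)
        fg_channel = list(model.classes).index(1)
        maps.append(
            SingleClassMap(
                int(target),
                pm.probs[:, :, fg_channel],
                source=dict(model.metadata or {}),
            )
        )
    fused, _ = fuse_max_probability(maps, policy, legend, mask=scene.mask)
    valid = fused.valid
    nvalid = max(int(valid.sum()), 1)
    for cid in legend.class_ids:
        frac = float((fused.labels[valid] == cid).sum()) / nvalid
        logger.info("fused coverage: %s = %.3f", legend.name_of(cid), frac)
    return fused
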