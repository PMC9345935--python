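"""Scene-level convenience pipeline: patches -> model -> map -> metrics.

The desk-scale training protocol used throughout: small patches cut densely
from the scene so that, at the fixed optimizer settings, stochastic gradient
descent gets enough minibatch iterations to converge on a single CPU. Patch
area is traded for iteration count at constant pixel throughput — with the
learning rate pinned at 0.001 the iteration count, not the patch size, is
what drives convergence at this scale.
"""

from __future__ import annotations

import numpy as np

from .errors import UsageError
from .evaluation import compute_metrics, confusion_from_rasters
from .inference import TileScheme, argmax_labels, predict_seamless
from .network import (
    ArchitectureConfig,
    SegNetClassifier,
    TrainConfig,
    binarize_labels,
    build_model,
    train,
)
from .raster import LabelRaster, PatchSet, Scene, make_patchset

__all__ = ["train_scene_model", "heldout_accuracy", "scene_overall_accuracy"]

#: Desk-scale defaults: 16 px patches, dense sampling.
DESK_PATCH_SIZE = 16
DESK_N_PATCHES_BINARY = 1700
DESK_N_PATCHES_MULTI = 3400


def train_scene_model(
    scene: Scene,
    labels: LabelRaster,
    seed: int,
    target_class: int | None = None,
    patch_size: int = DESK_PATCH_SIZE,
    n_patches: int | None = None,
    epochs: int = 5,
    arch: ArchitectureConfig | None = None,
) -> tuple[SegNetClassifier, PatchSet, list[float]]:
    """Train one desk-scale model on a labeled scene.

    ``target_class=None`` trains the multi-class variant over the full legend;
    otherwise a one-vs-rest model for that class (tagged with it). Returns the
    model, the patchset used (75/25 split) and the loss history.
    """
    if target_class is not None:
        labels = binarize_labels(labels, target_class)
        num_classes = 2
    else:
        num_classes = labels.legend.num_classes
    if n_patches is None:
        n_patches = DESK_N_PATCHES_BINARY if target_class is not None else DESK_N_PATCHES_MULTI
    patchset = make_patchset(
        scene, labels, patch_size=patch_size, n_patches=n_patches,
        train_fraction=0.75, seed=seed,
    )
    if arch is None:
        arch = ArchitectureConfig(
            input_channels=scene.num_channels, num_classes=num_classes
        )
    model = build_model(arch, seed=seed)
    model, history = train(model, patchset, TrainConfig(epochs=epochs, seed=seed))
    if target_class is not None:
        model.target_class = int(target_class)
        model.metadata["target_class"] = int(target_class)
    model.legend = labels.legend
    return model, patchset, history


def heldout_accuracy(model: SegNetClassifier, patchset: PatchSet) -> float:
    """Mean per-pixel accuracy on the patchset's test split."""
    xs, ys = patchset.subset("test")
    if not xs:
        raise UsageError("patchset has no test split")
    return float(
        np.mean(
            [(model.predict_tile(x).argmax(-1) == y).mean() for x, y in zip(xs, ys)]
        )
    )


def scene_overall_accuracy(
    pred: LabelRaster, reference: LabelRaster
) -> float:
    return compute_metrics(confusion_from_rasters(pred, reference)).overall_accuracy
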