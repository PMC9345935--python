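"""Encoder-decoder pixel classifier (SegNet-style) and its training loop.

The network is a symmetric encoder-decoder: every encoder stage is a block of
3x3 conv + batch norm + ReLU layers ending in 2x2 max pooling that records its
argmax indices; every decoder stage upsamples by placing values back at the
recorded indices, followed by a mirrored conv block. A final convolution
produces per-pixel class scores turned into probabilities by softmax.

Two variants are used throughout:

* single-class (one-vs-rest): a 2-way softmax over {background, foreground}
  for one target vegetation class, trained on binarized labels;
* multi-class: one softmax over all legend classes.

Training uses stochastic gradient descent with momentum, L2 weight decay,
categorical cross-entropy loss and a stepped learning-rate schedule (the rate
is multiplied by ``gamma`` every ``step_size`` iterations). All randomness
(weight init, minibatch shuffling) derives from explicit seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import _layers as L
from .errors import ConfigError, UsageError
from .raster import LabelRaster, Legend, LegendEntry, PatchSet

__all__ = [
    "ArchitectureConfig",
    "TrainConfig",
    "PixelClassifier",
    "SegNetClassifier",
    "build_model",
    "binarize_labels",
    "binary_legend",
    "train",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ArchitectureConfig:
    """Shape of the encoder-decoder.

    The default "desk" variant (3 stages x 2 convs, base 16 channels) is small
    enough to train on a CPU in seconds-to-minutes; ``full()`` returns the
    canonical 13-convolution encoder mirrored in the decoder.
    """

    stages: int = 3
    convs_per_stage: tuple[int, ...] = (2, 2, 2)
    base_channels: int = 16
    input_channels: int = 3
    num_classes: int = 2
    max_channels: int = 512

    def __post_init__(self):
        if self.stages < 1:
            raise ConfigError("stages must be >= 1")
        if len(self.convs_per_stage) != self.stages:
            raise ConfigError("convs_per_stage length must equal stages")
        if self.num_classes < 2:
            raise ConfigError("num_classes must be >= 2")

    def stage_channels(self, s: int) -> int:
        return min(self.base_channels * 2**s, self.max_channels)

    @classmethod
    def full(cls, input_channels: int = 3, num_classes: int = 2) -> "ArchitectureConfig":
        return cls(
            stages=5,
            convs_per_stage=(2, 2, 3, 3, 3),
            base_channels=64,
            input_channels=input_channels,
            num_classes=num_classes,
        )


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer settings: SGD with momentum, stepped learning rate,
    categorical cross-entropy."""

    learning_rate: float = 0.001
    gamma: float = 0.1
    momentum: float = 0.8
    weight_decay: float = 0.0001
    step_size: int = 1000
    batch_size: int = 8
    epochs: int = 5
    seed: int = 0
    class_weights: tuple | None = None  # optional inverse-frequency weighting

    def __post_init__(self):
        if min(self.learning_rate, self.gamma, self.momentum + 1e-12) <= 0:
            raise ConfigError("rates must be positive")
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")


class PixelClassifier:
    """Contract for anything mapping a context tile to per-pixel probabilities.

    Implementations provide ``predict_tile`` (S x S x C -> S x S x K, rows
    summing to 1), ``classes`` (the class ids of the K output channels, in
    channel order), ``receptive_field`` (a truthful upper bound, in pixels, on
    how far an input pixel can influence an output pixel) and ``metadata``.
    """

    classes: tuple[int, ...] = ()
    receptive_field: int = 1
    metadata: dict = {}

    def predict_tile(self, tile: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class SegNetClassifier(PixelClassifier):
    """The trainable encoder-decoder classifier."""

    def __init__(self, arch: ArchitectureConfig, seed: int = 0):
        self.arch = arch
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.encoder = []  # list of stages; each stage is a list of layers
        self.decoder = []
        cin = arch.input_channels
        for s in range(arch.stages):
            cout = arch.stage_channels(s)
            block = []
            for _ in range(arch.convs_per_stage[s]):
                block += [L.Conv3x3(cin, cout, rng), L.BatchNorm(cout), L.ReLU()]
                cin = cout
            self.encoder.append(block)
        # decoder[k] mirrors encoder stage (stages-1-k) and ends at the
        # channel width of the stage below it
        for s in reversed(range(arch.stages)):
            cout = arch.stage_channels(max(s - 1, 0))
            block = []
            nconv = arch.convs_per_stage[s]
            for i in range(nconv):
                c_to = cout if i == nconv - 1 else cin
                block += [L.Conv3x3(cin, c_to, rng), L.BatchNorm(c_to), L.ReLU()]
                cin = c_to
            self.decoder.append(block)
        self.head = L.Conv3x3(cin, arch.num_classes, rng)
        self.classes = tuple(range(arch.num_classes))
        self.receptive_field = _receptive_field_bound(arch)
        self.metadata = {"arch": asdict(arch), "seed": seed}
        self._saved_idx = None
        self._probs = None

    # -- parameters ---------------------------------------------------------

    def parameters(self) -> list[dict]:
        out = []
        for layer in self._layers():
            out.extend(layer.params)
        return out

    def _layers(self):
        for block in self.encoder + self.decoder:
            yield from block
        yield self.head

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Batched forward pass: (N, S, S, C) in [0, 255] -> (N, S, S, K) probs."""
        n, h, w, c = x.shape
        div = 2**self.arch.stages
        if h % div or w % div:
            raise ConfigError(
                f"input size {h}x{w} must be divisible by 2^stages = {div}"
            )
        if c != self.arch.input_channels:
            raise ConfigError(f"expected {self.arch.input_channels} channels, got {c}")
        x = np.asarray(x, dtype=np.float32) / 255.0
        saved_idx = []
        for block in self.encoder:
            for layer in block:
                x = layer.forward(x, training)
            x, idx = L.max_pool_2x2(x)
            saved_idx.append(idx)
        for k, block in enumerate(self.decoder):
            x = L.max_unpool_2x2(x, saved_idx[self.arch.stages - 1 - k])
            for layer in block:
                x = layer.forward(x, training)
        logits = self.head.forward(x, training)
        probs = L.softmax(logits)
        if training:
            self._saved_idx = saved_idx
            self._probs = probs
        return probs

    def backward(self, labels: np.ndarray, weights=None) -> None:
        """Backprop of the mean cross-entropy; fills parameter gradients."""
        probs = self._probs
        onehot = np.zeros_like(probs)
        np.put_along_axis(onehot, labels[..., None].astype(np.int64), 1.0, axis=-1)
        if weights is None:
            dlogits = (probs - onehot) / labels.size
        else:
            wpix = np.asarray(weights, dtype=np.float32)[labels]
            dlogits = (probs - onehot) * (wpix / wpix.sum())[..., None]
        d = self.head.backward(dlogits.astype(np.float32))
        saved_idx = self._saved_idx
        for k in range(self.arch.stages - 1, -1, -1):
            for layer in reversed(self.decoder[k]):
                d = layer.backward(d)
            d = _unpool_backward(d, saved_idx[self.arch.stages - 1 - k])
        for s in range(self.arch.stages - 1, -1, -1):
            d = L.max_unpool_2x2(d, saved_idx[s])  # pool backward = scatter
            for layer in reversed(self.encoder[s]):
                d = layer.backward(d)
        self._saved_idx = None
        self._probs = None

    # -- inference ----------------------------------------------------------

    def predict_tile(self, tile: np.ndarray) -> np.ndarray:
        tile = np.asarray(tile)
        if tile.ndim != 3:
            raise UsageError("tile must be S x S x C")
        return self.forward(tile[None], training=False)[0]


def _unpool_backward(d: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Gradient of index unpooling: gather dout at the scattered positions."""
    n, h, w, c = d.shape
    win = (
        d.reshape(n, h // 2, 2, w // 2, 2, c)
        .transpose(0, 1, 3, 5, 2, 4)
        .reshape(n, h // 2, w // 2, c, 4)
    )
    return np.take_along_axis(win, idx[..., None].astype(np.int64), axis=-1)[..., 0]


def _receptive_field_bound(arch: ArchitectureConfig) -> int:
    """Half-width bound on the input neighborhood influencing one output pixel."""
    rf, jump = 1, 1
    for s in range(arch.stages):
        rf += 2 * jump * arch.convs_per_stage[s]
        rf += jump  # 2x2 pool
        jump *= 2
    for s in reversed(range(arch.stages)):
        jump //= 2
        rf += 2 * jump * arch.convs_per_stage[s]
    rf += 2  # head conv
    return (rf - 1) // 2 + 1


def build_model(arch: ArchitectureConfig, seed: int = 0) -> SegNetClassifier:
    """Fresh, seeded, untrained classifier."""
    return SegNetClassifier(arch, seed=seed)


# ---------------------------------------------------------------------------
# One-vs-rest label binarization
# ---------------------------------------------------------------------------

def binary_legend(legend: Legend, target_class: int) -> Legend:
    """2-class legend {0: background, 1: <target name>} for one-vs-rest work."""
    entry = legend.entry(target_class)
    color = entry.color if entry.color != (0, 0, 0) else (255, 255, 255)
    return Legend(
        (LegendEntry(0, "background", (0, 0, 0)), LegendEntry(1, entry.name, color)),
        nodata_id=legend.nodata_id,
    )


def binarize_labels(label_raster: LabelRaster, target_class: int) -> LabelRaster:
    """Foreground = target class, background = every other valid class;
    nodata preserved."""
    legend = label_raster.legend
    if target_class not in legend.class_ids:
        raise UsageError(f"target class {target_class} not in legend")
    labels = label_raster.labels
    out = np.where(labels == target_class, 1, 0).astype(np.int64)
    out[labels == legend.nodata_id] = legend.nodata_id
    return LabelRaster(out, binary_legend(legend, target_class))


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def train(
    model: SegNetClassifier,
    patchset: PatchSet,
    cfg: TrainConfig,
) -> tuple[SegNetClassifier, list[float]]:
    """SGD-with-momentum training on the patchset's train split.

    Iterates ``epochs x ceil(n_train / batch_size)`` minibatches, multiplying
    the learning rate by ``gamma`` every ``step_size`` iterations, and returns
    the model plus the per-epoch mean training loss.
    """
    images, labels = patchset.subset("train")
    if not images:
        raise ConfigError("patchset has no training patches")
    if images[0].shape[2] != model.arch.input_channels:
        raise ConfigError(
            f"patch channels {images[0].shape[2]} != model input "
            f"{model.arch.input_channels}"
        )
    lab_max = max(int(np.max(lab)) for lab in labels)
    if lab_max >= model.arch.num_classes:
        raise ConfigError(
            f"label {lab_max} outside model's {model.arch.num_classes} classes"
        )
    x_all = np.stack(images).astype(np.float32)
    y_all = np.stack(labels).astype(np.int64)
    rng = np.random.default_rng(cfg.seed)
    params = model.parameters()
    n = len(x_all)
    it = 0
    history: list[float] = []
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = x_all[idx], y_all[idx]
            probs = model.forward(xb, training=True)
            losses.append(L.cross_entropy(probs, yb, cfg.class_weights))
            model.backward(yb, cfg.class_weights)
            lr = cfg.learning_rate * cfg.gamma ** (it // cfg.step_size)
            for p in params:
                grad = p["dw"] + cfg.weight_decay * p["w"]
                p["v"][...] = cfg.momentum * p["v"] - lr * grad
                p["w"][...] += p["v"]
            it += 1
        history.append(float(np.mean(losses)))
    model.metadata["train"] = {
        "config": asdict(cfg),
        "iterations": it,
        "final_lr": cfg.learning_rate * cfg.gamma ** ((it - 1) // cfg.step_size),
        "loss_history": history,
    }
    return model, history


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_model(model: SegNetClassifier, path) -> None:
    """Write weights (.npz) plus JSON metadata next to it."""
    path = Path(path)
    arrays = {}
    for i, layer in enumerate(model._layers()):
        if isinstance(layer, L.Conv3x3):
            arrays[f"l{i}_w"] = layer.w
            arrays[f"l{i}_b"] = layer.b
        elif isinstance(layer, L.BatchNorm):
            arrays[f"l{i}_gamma"] = layer.gamma
            arrays[f"l{i}_beta"] = layer.beta
            arrays[f"l{i}_rmean"] = layer.running_mean
            arrays[f"l{i}_rvar"] = layer.running_var
    np.savez(path.with_suffix(".npz"), **arrays)
    meta = dict(model.metadata)
    meta["receptive_field"] = model.receptive_field
    meta["classes"] = list(model.classes)
    legend = getattr(model, "legend", None)
    if legend is not None:
        meta["legend"] = legend.to_dict()
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, default=str))


def load_model(path) -> SegNetClassifier:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    arch_d = dict(meta["arch"])
    arch_d["convs_per_stage"] = tuple(arch_d["convs_per_stage"])
    arch = ArchitectureConfig(**arch_d)
    model = SegNetClassifier(arch, seed=int(meta.get("seed", 0)))
    with np.load(path.with_suffix(".npz")) as data:
        for i, layer in enumerate(model._layers()):
            if isinstance(layer, L.Conv3x3):
                layer.w[...] = data[f"l{i}_w"]
                layer.b[...] = data[f"l{i}_b"]
            elif isinstance(layer, L.BatchNorm):
                layer.gamma[...] = data[f"l{i}_gamma"]
                layer.beta[...] = data[f"l{i}_beta"]
                layer.running_mean[...] = data[f"l{i}_rmean"]
                layer.running_var[...] = data[f"l{i}_rvar"]
    model.metadata = meta
    if "target_class" in meta:
        model.target_class = meta["target_class"]
    if "legend" in meta:
        model.legend = Legend.from_dict(meta["legend"])
    return model
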