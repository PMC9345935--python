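"""Core raster data model and I/O.

The unit of work is a :class:`Scene` — an RGB (optionally RGB + appended
feature channels) pixel grid with a validity mask and an opaque, carried-through
georeference — paired with a :class:`LabelRaster` sharing its grid. Scenes are
read from and written to GeoTIFF (via tifffile) or PNG (via Pillow); label
rasters are single-band integer images or paletted PNGs whose palette maps onto
the legend colors.

Coordinate convention: row-major, 0-based, pixel-center. Point samples are
``(x, y)`` = (column, row).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

import tifffile

from .errors import DataError, FormatError, LegendMismatchError, UsageError

logger = logging.getLogger(__name__)

# GeoTIFF tags carried through opaquely (pixel scale, tiepoints, transform,
# geo-key directory and parameters, GDAL metadata/nodata).
_GEO_TAGS = (33550, 33922, 34264, 34735, 34736, 34737, 42112, 42113)


# ---------------------------------------------------------------------------
# Legend
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LegendEntry:
    class_id: int
    name: str
    color: tuple[int, int, int]


@dataclass(frozen=True)
class Legend:
    """Ordered mapping class id <-> name <-> palette color.

    Class ids must be the contiguous range ``0..K-1``; ``nodata_id`` lies
    outside that range and marks unlabeled/invalid pixels.
    """

    entries: tuple[LegendEntry, ...]
    nodata_id: int = 255

    def __post_init__(self):
        ids = [e.class_id for e in self.entries]
        if len(ids) < 2:
            raise UsageError("legend needs at least 2 classes")
        if sorted(ids) != list(range(len(ids))):
            raise UsageError(f"class ids must be contiguous 0..K-1, got {ids}")
        colors = [tuple(e.color) for e in self.entries]
        if len(set(colors)) != len(colors):
            raise UsageError("legend colors must be unique")
        if 0 <= self.nodata_id < len(ids):
            raise UsageError("nodata_id must lie outside the class id range")

    @property
    def num_classes(self) -> int:
        return len(self.entries)

    @property
    def class_ids(self) -> tuple[int, ...]:
        return tuple(e.class_id for e in self.entries)

    def entry(self, class_id: int) -> LegendEntry:
        for e in self.entries:
            if e.class_id == class_id:
                return e
        raise UsageError(f"class id {class_id} not in legend")

    def name_of(self, class_id: int) -> str:
        return self.entry(class_id).name

    def color_of(self, class_id: int) -> tuple[int, int, int]:
        return self.entry(class_id).color

    def color_to_id(self) -> dict[tuple[int, int, int], int]:
        return {tuple(e.color): e.class_id for e in self.entries}

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "nodata_id": int(self.nodata_id),
            "classes": [
                {
                    "id": int(e.class_id),
                    "name": e.name,
                    "color": "#%02x%02x%02x" % tuple(e.color),
                }
                for e in self.entries
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Legend":
        entries = []
        for c in d["classes"]:
            col = c["color"]
            if isinstance(col, str):
                col = col.lstrip("#")
                color = tuple(int(col[i : i + 2], 16) for i in (0, 2, 4))
            else:
                color = tuple(int(v) for v in col)
            entries.append(LegendEntry(int(c["id"]), str(c["name"]), color))
        return cls(tuple(entries), nodata_id=int(d.get("nodata_id", 255)))

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "Legend":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Scene / LabelRaster / PointSamples
# ---------------------------------------------------------------------------

@dataclass
class Scene:
    """An H x W x C pixel grid; channels 0-2 are RGB in [0, 255], channels >= 3
    are appended feature channels. ``mask`` is True where pixels are valid."""

    pixels: np.ndarray
    mask: np.ndarray = None
    georef: dict | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] < 3:
            raise UsageError(
                f"scene pixels must be H x W x C with C >= 3, got {self.pixels.shape}"
            )
        if self.mask is None:
            self.mask = np.ones(self.pixels.shape[:2], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.pixels.shape[:2]:
            raise UsageError("mask shape must match pixel grid")
        rgb = np.asarray(self.pixels[:, :, :3], dtype=np.float64)
        if rgb[self.mask].size and (
            rgb[self.mask].min() < 0 or rgb[self.mask].max() > 255
        ):
            raise UsageError("RGB channels must lie within [0, 255]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def num_channels(self) -> int:
        return self.pixels.shape[2]

    def with_pixels(self, pixels: np.ndarray) -> "Scene":
        return Scene(pixels, mask=self.mask.copy(), georef=self.georef)


@dataclass
class LabelRaster:
    """Integer class map on a Scene's grid plus its legend."""

    labels: np.ndarray
    legend: Legend

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise UsageError("labels must be a 2-D grid")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise UsageError("labels must be integer-typed")
        allowed = set(self.legend.class_ids) | {self.legend.nodata_id}
        present = set(np.unique(self.labels).tolist())
        bad = sorted(present - allowed)
        if bad:
            raise LegendMismatchError(bad)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def valid(self) -> np.ndarray:
        return self.labels != self.legend.nodata_id


@dataclass
class PointSamples:
    """Ground-truth point records ``(x=column, y=row, class_id)``."""

    records: np.ndarray  # (n, 3) int array

    def __post_init__(self):
        self.records = np.asarray(self.records, dtype=np.int64)
        if self.records.ndim != 2 or self.records.shape[1] != 3:
            raise UsageError("records must be an (n, 3) array of (x, y, class_id)")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def x(self) -> np.ndarray:
        return self.records[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.records[:, 1]

    @property
    def class_id(self) -> np.ndarray:
        return self.records[:, 2]

    def validate(self, shape: tuple[int, int], legend: Legend) -> None:
        h, w = shape
        if len(self) == 0:
            raise DataError("empty point-sample set")
        if (self.x < 0).any() or (self.x >= w).any() or (self.y < 0).any() or (
            self.y >= h
        ).any():
            raise DataError("point samples fall outside the raster bounds")
        bad = sorted(set(self.class_id.tolist()) - set(legend.class_ids))
        if bad:
            raise LegendMismatchError(bad)

    def save(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["x", "y", "class_id"])
            w.writerows(self.records.tolist())

    @classmethod
    def load(cls, path) -> "PointSamples":
        with open(path, newline="") as fh:
            rows = list(csv.reader(fh))
        if not rows or [c.strip() for c in rows[0]] != ["x", "y", "class_id"]:
            raise FormatError(f"{path}: expected header 'x,y,class_id'")
        return cls(np.array([[int(v) for v in r] for r in rows[1:]], dtype=np.int64))


# ---------------------------------------------------------------------------
# Scene I/O
# ---------------------------------------------------------------------------

def _is_tiff(path: Path) -> bool:
    return path.suffix.lower() in (".tif", ".tiff")


def read_scene(path) -> Scene:
    """Read a GeoTIFF or PNG raster into a Scene.

    The first three bands become RGB; an alpha band of 0 or a GDAL nodata tag
    populates the mask (a pixel is invalid when *all* of its first three bands
    equal the nodata value). GeoTIFF georeference tags are carried through
    opaquely.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    georef = None
    nodata = None
    if _is_tiff(path):
        try:
            with tifffile.TiffFile(path) as tf:
                page = tf.pages[0]
                series = tf.series[0]
                arr = series.asarray()
                if arr.ndim == 3 and series.axes[0] in "SC":
                    # planar (C, H, W) layout -> interleaved
                    arr = np.moveaxis(arr, 0, -1)
                georef = {}
                for tag in _GEO_TAGS:
                    if tag in page.tags:
                        georef[tag] = page.tags[tag].value
                if not georef:
                    georef = None
                if 42113 in page.tags:  # GDAL_NODATA, ascii
                    try:
                        nodata = float(str(page.tags[42113].value).strip("\x00 "))
                    except ValueError:
                        nodata = None
        except (tifffile.TiffFileError, ValueError) as exc:
            raise FormatError(f"unreadable TIFF {path}: {exc}") from exc
    else:
        try:
            arr = np.asarray(Image.open(path))
        except (OSError, Image.UnidentifiedImageError) as exc:
            raise FormatError(f"unreadable image {path}: {exc}") from exc
    if arr.ndim == 2 or arr.shape[-1] < 3:
        nb = 1 if arr.ndim == 2 else arr.shape[-1]
        raise FormatError(f"{path}: scene needs >= 3 bands, found {nb}")
    mask = np.ones(arr.shape[:2], dtype=bool)
    pixels = arr
    if arr.shape[-1] == 4 and not _is_tiff(path):
        # PNG alpha channel: alpha == 0 marks nodata
        mask &= arr[:, :, 3] != 0
        pixels = arr[:, :, :3]
    if nodata is not None:
        mask &= ~np.all(pixels[:, :, :3] == nodata, axis=-1)
    return Scene(pixels, mask=mask, georef=georef)


def write_scene(path, scene: Scene, nodata: float | None = None) -> None:
    """Write a Scene to GeoTIFF or PNG (lossless for integer data).

    For GeoTIFF, carried georeference tags are re-emitted and an optional
    nodata value is stamped into invalid pixels and recorded as GDAL_NODATA.
    PNG output supports only 3-channel uint8 scenes (alpha added when the mask
    has invalid pixels).
    """
    path = Path(path)
    if _is_tiff(path):
        pixels = scene.pixels
        extratags = []
        if scene.georef:
            for tag, value in scene.georef.items():
                if tag == 42113:
                    continue  # rewritten below if nodata requested
                extratags.append(_geotag(tag, value))
        if nodata is not None:
            pixels = pixels.copy()
            pixels[~scene.mask] = nodata
            extratags.append((42113, "s", 0, str(nodata), True))
        if pixels.shape[2] in (3, 4):
            tifffile.imwrite(path, pixels, photometric="rgb", extratags=extratags)
        else:
            tifffile.imwrite(path, pixels, photometric="minisblack",
                             planarconfig="contig", extratags=extratags)
    elif path.suffix.lower() == ".png":
        if scene.num_channels != 3:
            raise UsageError("PNG scenes support exactly 3 channels")
        rgb = np.clip(np.round(scene.pixels), 0, 255).astype(np.uint8)
        if scene.mask.all():
            Image.fromarray(rgb, mode="RGB").save(path)
        else:
            alpha = np.where(scene.mask, 255, 0).astype(np.uint8)
            Image.fromarray(np.dstack([rgb, alpha]), mode="RGBA").save(path)
    else:
        raise UsageError(f"unsupported scene format: {path.suffix}")


def _geotag(code: int, value):
    """Rebuild a tifffile extratag tuple for a carried GeoTIFF tag."""
    if code in (33550, 33922, 34264, 34736):
        v = np.atleast_1d(np.asarray(value, dtype=np.float64))
        return (code, "d", len(v), tuple(v.tolist()), True)
    if code == 34735:
        v = np.atleast_1d(np.asarray(value, dtype=np.uint16)).ravel()
        return (code, "H", len(v), tuple(int(x) for x in v), True)
    # ascii tags (34737, 42112, 42113)
    s = value if isinstance(value, str) else str(value)
    return (code, "s", 0, s, True)


# ---------------------------------------------------------------------------
# Label I/O
# ---------------------------------------------------------------------------

def read_labels(path, legend: Legend) -> LabelRaster:
    """Read a label raster and map it onto legend class ids.

    Accepts a single-band integer raster (values must already be legend ids or
    the nodata id) or a paletted/RGB PNG whose colors all occur in the legend.
    Unknown colors or values raise :class:`LegendMismatchError` rather than
    being silently mapped to nodata.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if _is_tiff(path):
        arr = tifffile.imread(path)
        if arr.ndim == 3 and arr.shape[2] == 1:
            arr = arr[:, :, 0]
        if arr.ndim != 2:
            raise FormatError(f"{path}: label TIFF must be single-band")
        return LabelRaster(arr.astype(np.int64), legend)
    img = Image.open(path)
    if img.mode == "P":
        idx = np.asarray(img)
        pal = np.asarray(img.getpalette(), dtype=np.int64).reshape(-1, 3)
        color_map = legend.color_to_id()
        lut = np.full(256, -1, dtype=np.int64)
        offenders = []
        for i in np.unique(idx):
            color = tuple(int(v) for v in pal[i])
            if color in color_map:
                lut[i] = color_map[color]
            elif i == legend.nodata_id:
                lut[i] = legend.nodata_id
            else:
                offenders.append(color)
        if offenders:
            raise LegendMismatchError(offenders)
        return LabelRaster(lut[idx], legend)
    arr = np.asarray(img)
    if arr.ndim == 2:
        return LabelRaster(arr.astype(np.int64), legend)
    rgb = arr[:, :, :3]
    color_map = legend.color_to_id()
    flat = rgb.reshape(-1, 3).astype(np.int64)
    codes = flat[:, 0] * 65536 + flat[:, 1] * 256 + flat[:, 2]
    out = np.full(codes.shape, -1, dtype=np.int64)
    for color, cid in color_map.items():
        out[codes == color[0] * 65536 + color[1] * 256 + color[2]] = cid
    if (out < 0).any():
        bad_codes = np.unique(codes[out < 0])
        offenders = [(int(c // 65536), int(c // 256 % 256), int(c % 256)) for c in bad_codes]
        raise LegendMismatchError(offenders)
    return LabelRaster(out.reshape(rgb.shape[:2]), legend)


def write_labels(path, raster: LabelRaster, paletted: bool = False) -> None:
    """Write labels as a single-band raster, or a paletted PNG using the
    legend palette when ``paletted=True``."""
    path = Path(path)
    labels = raster.labels
    if _is_tiff(path):
        tifffile.imwrite(path, labels.astype(np.int32))
        return
    if path.suffix.lower() != ".png":
        raise UsageError(f"unsupported label format: {path.suffix}")
    if not paletted:
        if labels.min() < 0 or labels.max() > 255:
            raise UsageError("single-band PNG labels must fit in uint8")
        Image.fromarray(labels.astype(np.uint8), mode="L").save(path)
        return
    img = Image.fromarray(labels.astype(np.uint8), mode="P")
    palette = [0] * 768
    for e in raster.legend.entries:
        palette[3 * e.class_id : 3 * e.class_id + 3] = list(e.color)
    img.putpalette(palette)
    img.save(path)


# ---------------------------------------------------------------------------
# Patch datasets
# ---------------------------------------------------------------------------

@dataclass
class PatchSet:
    """Co-registered image/label training patches with a train/test split."""

    images: list  # list of S x S x C arrays
    labels: list  # list of S x S int arrays
    split: list  # 'train' / 'test' per patch
    patch_size: int
    seed: int
    legend: Legend = None

    def __len__(self) -> int:
        return len(self.images)

    def subset(self, which: str) -> tuple[list, list]:
        idx = [i for i, s in enumerate(self.split) if s == which]
        return [self.images[i] for i in idx], [self.labels[i] for i in idx]

    @property
    def n_train(self) -> int:
        return sum(1 for s in self.split if s == "train")

    @property
    def n_test(self) -> int:
        return len(self) - self.n_train

    @property
    def num_channels(self) -> int:
        return self.images[0].shape[2] if self.images else 0


def make_patchset(
    scene: Scene,
    labels: LabelRaster,
    patch_size: int = 256,
    n_patches: int = 100,
    train_fraction: float = 0.75,
    seed: int = 0,
    max_redraws: int = 1000,
) -> PatchSet:
    """Cut ``n_patches`` random co-registered image/label crops and split them.

    Windows are drawn independently and uniformly (overlap allowed); any window
    touching a nodata pixel — in the scene mask or the label raster — is
    rejected and redrawn, up to ``max_redraws`` consecutive rejections. The
    train/test split is assigned by a seeded shuffle, so the same seed yields a
    byte-identical PatchSet.
    """
    h, w = scene.shape
    if labels.shape != (h, w):
        raise DataError("labels not aligned to scene")
    if patch_size > min(h, w):
        raise UsageError(f"patch_size {patch_size} exceeds scene {h}x{w}")
    if not 0 <= train_fraction <= 1:
        raise UsageError("train_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    valid = scene.mask & labels.valid
    images, labs = [], []
    rejections = 0
    while len(images) < n_patches:
        r0 = int(rng.integers(0, h - patch_size + 1))
        c0 = int(rng.integers(0, w - patch_size + 1))
        win = valid[r0 : r0 + patch_size, c0 : c0 + patch_size]
        if not win.all():
            rejections += 1
            if rejections > max_redraws:
                raise DataError(
                    f"no nodata-free {patch_size}x{patch_size} window found after "
                    f"{max_redraws} redraws"
                )
            continue
        rejections = 0
        images.append(scene.pixels[r0 : r0 + patch_size, c0 : c0 + patch_size].copy())
        labs.append(labels.labels[r0 : r0 + patch_size, c0 : c0 + patch_size].copy())
    n_train = int(round(train_fraction * n_patches))
    order = rng.permutation(n_patches)
    split = ["test"] * n_patches
    for i in order[:n_train]:
        split[i] = "train"
    return PatchSet(images, labs, split, patch_size, seed, legend=labels.legend)


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

AUGMENT_OPS = (
    "flip_x",
    "flip_y",
    "rot90",
    "rot180",
    "rot270",
    "color_shift",
    "random_scale",
    "invert",
)

#: Per-channel additive color-shift range (uniform draw), in DN.
COLOR_SHIFT_RANGE = 25.0
#: Random-scale factor range (uniform draw).
SCALE_RANGE = (0.8, 1.25)


def augment_patch(
    image: np.ndarray,
    label: np.ndarray,
    op_code: str,
    seed: int = 0,
    color_shift_range: float = COLOR_SHIFT_RANGE,
    scale_range: tuple[float, float] = SCALE_RANGE,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one augmentation to a co-registered image/label patch.

    Geometric ops (flips, right-angle rotations, random scaling) transform
    image and label identically; radiometric ops (color shift, invert) alter
    the RGB channels only and leave the label untouched. Results are clipped
    to [0, 255] and returned at the original patch size.
    """
    if op_code not in AUGMENT_OPS:
        raise UsageError(f"unknown augmentation op {op_code!r}; valid: {AUGMENT_OPS}")
    image = np.asarray(image)
    label = np.asarray(label)
    if op_code == "flip_x":
        return image[:, ::-1].copy(), label[:, ::-1].copy()
    if op_code == "flip_y":
        return image[::-1].copy(), label[::-1].copy()
    if op_code in ("rot90", "rot180", "rot270"):
        k = {"rot90": 1, "rot180": 2, "rot270": 3}[op_code]
        return (
            np.rot90(image, k, axes=(0, 1)).copy(),
            np.rot90(label, k, axes=(0, 1)).copy(),
        )
    if op_code == "invert":
        out = np.array(image, dtype=np.float64, copy=True)
        out[:, :, :3] = 255.0 - out[:, :, :3]
        return out.astype(image.dtype, copy=False), label.copy()
    if op_code == "color_shift":
        rng = np.random.default_rng(seed)
        shift = rng.uniform(-color_shift_range, color_shift_range, size=3)
        out = np.array(image, dtype=np.float64, copy=True)
        out[:, :, :3] = np.clip(out[:, :, :3] + shift, 0, 255)
        return out.astype(image.dtype, copy=False), label.copy()
    # random_scale: rescale then center-crop / reflect-pad back to S x S;
    # nearest-neighbour resampling keeps label values in the legend.
    from skimage.transform import rescale

    rng = np.random.default_rng(seed)
    factor = float(rng.uniform(*scale_range))
    img = rescale(
        np.asarray(image, dtype=np.float64),
        factor,
        order=1,
        channel_axis=2,
        preserve_range=True,
        anti_aliasing=factor < 1,
    )
    lab = rescale(
        label.astype(np.float64),
        factor,
        order=0,
        preserve_range=True,
        anti_aliasing=False,
    ).astype(label.dtype)
    img = np.clip(img, 0, 255)
    s0, s1 = image.shape[0], image.shape[1]
    img = _fit_to(img, s0, s1)
    lab = _fit_to(lab, s0, s1)
    return img.astype(image.dtype, copy=False) if np.issubdtype(
        image.dtype, np.integer
    ) else img, lab


def _fit_to(arr: np.ndarray, s0: int, s1: int) -> np.ndarray:
    """Center-crop or reflect-pad the first two axes to (s0, s1)."""
    h, w = arr.shape[:2]
    if h > s0:
        off = (h - s0) // 2
        arr = arr[off : off + s0]
    if w > s1:
        off = (w - s1) // 2
        arr = arr[:, off : off + s1]
    h, w = arr.shape[:2]
    if h < s0 or w < s1:
        ph, pw = s0 - h, s1 - w
        pad = [(ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2)]
        pad += [(0, 0)] * (arr.ndim - 2)
        arr = np.pad(arr, pad, mode="reflect")
    return arr
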