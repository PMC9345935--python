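"""Per-pixel grey-level co-occurrence (Haralick) texture features.

For every pixel, a symmetric, normalized co-occurrence matrix is accumulated
over all pixel pairs inside the centered window that are related by each
displacement offset (pairs pooled over offsets), and the requested Haralick
statistics are evaluated from it. The band is min-max quantized to a fixed
number of grey levels first, and window borders are handled by reflecting the
band, so the output stays aligned to the input grid.

Feature definitions (p = normalized symmetric co-occurrence, i row / j column
level, p_x the marginal):

    mean            mu = sum_i i p_x(i)
    variance        sum_i (i - mu)^2 p_x(i)
    homogeneity     sum p / (1 + (i-j)^2)
    contrast        sum p (i-j)^2
    dissimilarity   sum p |i-j|
    entropy         -sum p ln p          (0 ln 0 := 0)
    second_moment   sum p^2
    correlation     (sum p i j - mu^2) / variance   (:= 0 when variance = 0)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .errors import DataError, UsageError
from .raster import Scene

FEATURE_NAMES = (
    "mean",
    "variance",
    "homogeneity",
    "contrast",
    "dissimilarity",
    "entropy",
    "second_moment",
    "correlation",
)

#: Distance-1 offsets at 0, 45, 90 and 135 degrees — the conventional setup.
DEFAULT_OFFSETS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))

#: Luminance weights used to derive the default texture source band from RGB.
_LUMA = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class GLCMSpec:
    """Window size (odd, pixels), grey-level count, displacement offsets and
    the Haralick features to evaluate."""

    window: int = 3
    levels: int = 64
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS
    features: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self):
        if self.window < 3 or self.window % 2 == 0:
            raise UsageError(f"window must be odd and >= 3, got {self.window}")
        if self.levels < 2:
            raise UsageError("levels must be >= 2")
        if not self.offsets or any(dy == 0 and dx == 0 for dy, dx in self.offsets):
            raise UsageError("offsets must be non-empty and non-zero")
        bad = [f for f in self.features if f not in FEATURE_NAMES]
        if bad:
            raise UsageError(f"unknown features {bad}; valid: {FEATURE_NAMES}")

    def to_dict(self) -> dict:
        return {
            "window": self.window,
            "levels": self.levels,
            "offsets": [list(o) for o in self.offsets],
            "features": list(self.features),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GLCMSpec":
        return cls(
            window=int(d.get("window", 3)),
            levels=int(d.get("levels", 64)),
            offsets=tuple(tuple(int(v) for v in o) for o in d.get("offsets", DEFAULT_OFFSETS)),
            features=tuple(d.get("features", FEATURE_NAMES)),
        )


def default_texture_specs(
    windows: tuple[int, ...] = (3, 5, 7),
    levels: int = 64,
    features: tuple[str, ...] = FEATURE_NAMES,
) -> list[GLCMSpec]:
    """One spec per window size, all eight features, 64 grey levels."""
    return [GLCMSpec(window=w, levels=levels, features=features) for w in windows]


def quantize(band: np.ndarray, levels: int, mask: np.ndarray = None) -> np.ndarray:
    """Min-max quantize a band onto integer levels ``0..levels-1``.

    The valid range (under the optional mask) is mapped linearly; a constant
    band maps to all-zero levels. Non-finite values under the mask are a data
    error.
    """
    band = np.asarray(band, dtype=np.float64)
    if band.ndim != 2:
        raise UsageError("band must be 2-D")
    valid = np.ones(band.shape, dtype=bool) if mask is None else np.asarray(mask, bool)
    if not np.isfinite(band[valid]).all():
        raise DataError("band contains non-finite values under the valid mask")
    if not valid.any():
        raise DataError("no valid pixels to quantize")
    mn = band[valid].min()
    mx = band[valid].max()
    if mx == mn:
        return np.zeros(band.shape, dtype=np.int32)
    q = np.floor((band - mn) / (mx - mn) * levels).astype(np.int32)
    return np.clip(q, 0, levels - 1)


@njit(cache=True)
def _glcm_kernel(padded, h, w, half, window, offsets, levels):  # pragma: no cover
    n_off = offsets.shape[0]
    # upper bound on symmetric pair entries per window
    max_pairs = 0
    for k in range(n_off):
        dy, dx = offsets[k, 0], offsets[k, 1]
        max_pairs += 2 * (window - abs(dy)) * (window - abs(dx))
    out = np.empty((h, w, 8), dtype=np.float64)
    buf = np.empty(max_pairs, dtype=np.int64)
    for r in range(h):
        for c in range(w):
            m = 0
            s_a = 0.0
            s_ab = 0.0
            s_d1 = 0.0
            s_d2 = 0.0
            s_hom = 0.0
            for k in range(n_off):
                dy = offsets[k, 0]
                dx = offsets[k, 1]
                y0 = 0 if dy >= 0 else -dy
                y1 = window - dy if dy >= 0 else window
                x0 = 0 if dx >= 0 else -dx
                x1 = window - dx if dx >= 0 else window
                for wy in range(y0, y1):
                    for wx in range(x0, x1):
                        a = padded[r + wy, c + wx]
                        b = padded[r + wy + dy, c + wx + dx]
                        buf[m] = a * levels + b
                        buf[m + 1] = b * levels + a
                        m += 2
                        d = a - b
                        if d < 0:
                            d = -d
                        s_a += a + b
                        s_ab += 2.0 * a * b
                        s_d1 += 2.0 * d
                        s_d2 += 2.0 * d * d
                        s_hom += 2.0 / (1.0 + d * d)
            fm = float(m)
            mu = s_a / fm
            # variance of the marginal = mean over pair endpoints of (v - mu)^2
            s_var = 0.0
            for t in range(m):
                a = buf[t] // levels
                s_var += (a - mu) * (a - mu)
            var = s_var / fm
            contrast = s_d2 / fm
            dissim = s_d1 / fm
            homog = s_hom / fm
            if var > 0.0:
                corr = (s_ab / fm - mu * mu) / var
            else:
                corr = 0.0
            # entropy and second moment need the distribution itself
            codes = np.sort(buf[:m])
            asm = 0.0
            ent = 0.0
            run = 1
            for t in range(1, m):
                if codes[t] == codes[t - 1]:
                    run += 1
                else:
                    p = run / fm
                    asm += p * p
                    ent -= p * np.log(p)
                    run = 1
            p = run / fm
            asm += p * p
            ent -= p * np.log(p)
            out[r, c, 0] = mu
            out[r, c, 1] = var
            out[r, c, 2] = homog
            out[r, c, 3] = contrast
            out[r, c, 4] = dissim
            out[r, c, 5] = ent
            out[r, c, 6] = asm
            out[r, c, 7] = corr
    return out


def glcm_features(
    band: np.ndarray, spec: GLCMSpec, quantized: bool = False
) -> np.ndarray:
    """Per-pixel Haralick feature stack (H x W x F) for one window size.

    ``band`` is quantized internally unless ``quantized=True`` (then it must
    already hold integer levels in ``0..levels-1``).
    """
    band = np.asarray(band)
    if band.ndim != 2:
        raise UsageError("band must be 2-D")
    h, w = band.shape
    if spec.window > min(h, w):
        raise UsageError(f"window {spec.window} larger than band {h}x{w}")
    if quantized:
        q = np.asarray(band, dtype=np.int32)
        if q.min() < 0 or q.max() >= spec.levels:
            raise UsageError("quantized band outside 0..levels-1")
    else:
        q = quantize(band, spec.levels)
    half = spec.window // 2
    padded = np.pad(q, half, mode="reflect")
    offsets = np.asarray(spec.offsets, dtype=np.int64)
    all_feats = _glcm_kernel(
        padded.astype(np.int64), h, w, half, spec.window, offsets, spec.levels
    )
    idx = [FEATURE_NAMES.index(f) for f in spec.features]
    return np.ascontiguousarray(all_feats[:, :, idx])


def luminance(scene_or_pixels) -> np.ndarray:
    """Luminance band 0.299 R + 0.587 G + 0.114 B."""
    px = scene_or_pixels.pixels if isinstance(scene_or_pixels, Scene) else scene_or_pixels
    px = np.asarray(px, dtype=np.float64)
    return _LUMA[0] * px[:, :, 0] + _LUMA[1] * px[:, :, 1] + _LUMA[2] * px[:, :, 2]


def append_texture_channels(
    scene: Scene,
    specs,
    source_channel: int | None = None,
) -> Scene:
    """Compute texture features and append them as scene channels.

    ``specs`` is one :class:`GLCMSpec` or a sequence (one per window size);
    each feature channel is rescaled to [0, 255] by its global min-max so that
    appended channels share the RGB value range. The source band defaults to
    the luminance of RGB.
    """
    if isinstance(specs, GLCMSpec):
        specs = [specs]
    if sum(len(s.features) for s in specs) == 0:
        return scene
    if source_channel is None:
        band = luminance(scene)
    else:
        if source_channel >= scene.num_channels:
            raise UsageError(f"source channel {source_channel} not in scene")
        band = np.asarray(scene.pixels[:, :, source_channel], dtype=np.float64)
    stacks = []
    for spec in specs:
        feats = glcm_features(band, spec)
        for k in range(feats.shape[2]):
            ch = feats[:, :, k]
            lo, hi = ch.min(), ch.max()
            if hi > lo:
                ch = (ch - lo) / (hi - lo) * 255.0
            else:
                ch = np.zeros_like(ch)
            stacks.append(ch)
    out = np.concatenate(
        [np.asarray(scene.pixels, dtype=np.float64)]
        + [s[:, :, None] for s in stacks],
        axis=2,
    )
    return Scene(out.astype(np.float32), mask=scene.mask.copy(), georef=scene.georef)
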