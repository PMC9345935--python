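"""Independent brute-force reference implementations used only by tests.

These deliberately share no code with the package: the GLCM oracle builds an
explicit co-occurrence distribution per pixel with a dictionary; the fusion
and argmax oracles are plain Python loops.
"""

from collections import Counter

import math

import numpy as np


def glcm_oracle(levels_grid, window, offsets, levels):
    """Per-pixel Haralick features by explicit pair enumeration.

    Returns an H x W x 8 array in the canonical feature order
    (mean, variance, homogeneity, contrast, dissimilarity, entropy,
    second_moment, correlation).
    """
    h, w = levels_grid.shape
    half = window // 2
    padded = np.pad(levels_grid, half, mode="reflect")
    out = np.zeros((h, w, 8))
    for r in range(h):
        for c in range(w):
            win = padded[r : r + window, c : c + window]
            entries = []
            for dy, dx in offsets:
                for wy in range(window):
                    for wx in range(window):
                        y2, x2 = wy + dy, wx + dx
                        if 0 <= y2 < window and 0 <= x2 < window:
                            a, b = int(win[wy, wx]), int(win[y2, x2])
                            entries.append((a, b))
                            entries.append((b, a))
            m = len(entries)
            dist = Counter(entries)
            mean = sum(n * i for (i, j), n in dist.items()) / m
            var = sum(n * (i - mean) ** 2 for (i, j), n in dist.items()) / m
            homog = sum(n / (1 + (i - j) ** 2) for (i, j), n in dist.items()) / m
            contrast = sum(n * (i - j) ** 2 for (i, j), n in dist.items()) / m
            dissim = sum(n * abs(i - j) for (i, j), n in dist.items()) / m
            entropy = -sum((n / m) * math.log(n / m) for n in dist.values())
            asm = sum((n / m) ** 2 for n in dist.values())
            if var > 0:
                corr = (sum(n * i * j for (i, j), n in dist.items()) / m - mean**2) / var
            else:
                corr = 0.0
            out[r, c] = (mean, var, homog, contrast, dissim, entropy, asm, corr)
    return out


def fuse_oracle(foregrounds, class_ids, tau, other_id):
    """Per-pixel linear scan over classes; ties -> lowest class id."""
    h, w = foregrounds[0].shape
    labels = np.empty((h, w), dtype=np.int64)
    pairs = sorted(zip(class_ids, foregrounds))
    for r in range(h):
        for c in range(w):
            best_id, best_p = None, -1.0
            for cid, fg in pairs:
                if fg[r, c] > best_p:
                    best_id, best_p = cid, fg[r, c]
            labels[r, c] = other_id if best_p < tau else best_id
    return labels


def argmax_oracle(probs, class_ids):
    """Per-pixel linear-scan maximum with lowest-class-id tie-break."""
    h, w, k = probs.shape
    pairs = sorted(zip(class_ids, range(k)))
    out = np.empty((h, w), dtype=np.int64)
    for r in range(h):
        for c in range(w):
            best_id, best_p = None, -np.inf
            for cid, ch in pairs:
                if probs[r, c, ch] > best_p:
                    best_id, best_p = cid, probs[r, c, ch]
            out[r, c] = best_id
    return out


def confusion_oracle(ref, pred, k, nodata):
    counts = np.zeros((k, k), dtype=np.int64)
    for r, p in zip(ref.ravel(), pred.ravel()):
        if r != nodata and p != nodata:
            counts[r, p] += 1
    return counts
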