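"""Independent brute-force oracles used across the test suite.

Everything here is written as plain loops and set arithmetic so it
shares no code path with the package implementation it checks.
"""

import numpy as np


def gray_weighted_sum(rgb, weights):
    h, w, _ = rgb.shape
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            out[i, j] = sum(rgb[i, j, c] * weights[c] for c in range(3))
    return out


def per_line_counts(mask, axis):
    """axis 0 -> per-column counts, axis 1 -> per-row counts."""
    h, w = mask.shape
    if axis == 0:
        return np.array([sum(1 for i in range(h) if mask[i, j]) for j in range(w)])
    return np.array([sum(1 for j in range(w) if mask[i, j]) for i in range(h)])


def dilate_set(mask, elem):
    """Dilation as a union of shifts; outside the raster is background."""
    h, w = mask.shape
    eh, ew = elem.shape
    cy, cx = eh // 2, ew // 2
    out = np.zeros_like(mask)
    for i in range(h):
        for j in range(w):
            if not mask[i, j]:
                continue
            for di in range(eh):
                for dj in range(ew):
                    if elem[di, dj]:
                        y, x = i + di - cy, j + dj - cx
                        if 0 <= y < h and 0 <= x < w:
                            out[y, x] = True
    return out


def erode_set(mask, elem):
    """Erosion as an intersection test; outside the raster is background."""
    h, w = mask.shape
    eh, ew = elem.shape
    cy, cx = eh // 2, ew // 2
    out = np.zeros_like(mask)
    for i in range(h):
        for j in range(w):
            ok = True
            for di in range(eh):
                for dj in range(ew):
                    if elem[di, dj]:
                        y, x = i + di - cy, j + dj - cx
                        if not (0 <= y < h and 0 <= x < w and mask[y, x]):
                            ok = False
                            break
                if not ok:
                    break
            out[i, j] = ok
    return out


def open_set(mask, elem):
    return dilate_set(erode_set(mask, elem), elem)


def close_set(mask, elem):
    return erode_set(dilate_set(mask, elem), elem)


def argmin_first(values):
    best, arg = None, None
    for i, v in enumerate(values):
        if best is None or v < best:
            best, arg = v, i
    return arg


def argmin_last(values):
    best, arg = None, None
    for i, v in enumerate(values):
        if best is None or v <= best:
            best, arg = v, i
    return arg


def convolve_replicate(img, kernel):
    """3x3 correlation-style convolution with edge replication, by loops."""
    h, w = img.shape
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            acc = 0.0
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    y = min(max(i + di, 0), h - 1)
                    x = min(max(j + dj, 0), w - 1)
                    acc += kernel[di + 1, dj + 1] * img[y, x]
            out[i, j] = acc
    return out


def metrics_by_hand(tp, fp, fn, tn):
    total = tp + fp + fn + tn
    acc = (tp + tn) / total if total else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return acc, prec, rec, f1
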