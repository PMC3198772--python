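"""Independent reference implementations used to check the morphology code.

These deliberately avoid scipy.ndimage: erosion/dilation are evaluated
directly from their definitions by stacking padded shifts (and, for tiny
fixtures, by literal nested loops), so agreement with the package is a
genuine two-route check.
"""

from __future__ import annotations

import numpy as np


def _offsets(footprint: np.ndarray) -> np.ndarray:
    c = footprint.shape[0] // 2
    ii, jj = np.nonzero(footprint)
    return np.stack([ii - c, jj - c], axis=1)


def _shift_stack(pixels: np.ndarray, footprint: np.ndarray, pad_value: float) -> np.ndarray:
    """stack[k] = image translated by the k-th footprint offset, padded."""
    offs = _offsets(footprint)
    r = int(np.abs(offs).max(initial=0))
    padded = np.pad(pixels, r, mode="constant", constant_values=pad_value)
    h, w = pixels.shape
    return np.stack(
        [padded[r + di : r + di + h, r + dj : r + dj + w] for di, dj in offs]
    )


def brute_erode(pixels: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """min over the footprint, out-of-image treated as +inf."""
    return _shift_stack(pixels, footprint, np.inf).min(axis=0)


def brute_dilate(pixels: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """max over the reflected footprint, out-of-image treated as -inf."""
    return _shift_stack(pixels, footprint[::-1, ::-1], -np.inf).max(axis=0)


def brute_open(pixels: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    return brute_dilate(brute_erode(pixels, footprint), footprint)


def loop_erode(pixels: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """Literal nested-loop erosion, for very small fixtures only."""
    h, w = pixels.shape
    out = np.empty_like(pixels, dtype=float)
    offs = _offsets(footprint)
    for i in range(h):
        for j in range(w):
            vals = [
                pixels[i + di, j + dj]
                for di, dj in offs
                if 0 <= i + di < h and 0 <= j + dj < w
            ]
            out[i, j] = min(vals)
    return out
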