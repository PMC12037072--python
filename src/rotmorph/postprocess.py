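"""Histogram modification and automatic thresholding.

``histogram_modification`` turns a signed operator output into a
contrast-enhanced grayscale image in three steps: shift the dynamic range so
the minimum is zero, apply classic CDF-based histogram equalization over the
full bit-depth bin range, then linearly stretch to span [0, 2^b − 1].

Two histogram thresholders are provided: Otsu's between-class-variance
maximizer and Tsai's moment-preserving method, which picks the threshold so
that a bilevel image preserves the first three gray-level moments of the
input.  Both operate on the histogram only, so they are invariant to any
permutation of pixel positions.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

__all__ = [
    "histogram_modification",
    "otsu_threshold",
    "tsai_threshold",
    "ThresholdResult",
]


class ThresholdResult(NamedTuple):
    threshold: int
    binary: np.ndarray  # uint8 of {0, 1}
    degenerate: bool


def histogram_modification(s: np.ndarray, bit_depth: int) -> np.ndarray:
    """Shift-to-zero, equalize, and stretch a (possibly signed) image.

    The input may have any real range: after the shift, values are scaled
    down (only if they exceed the bit-depth range) and rounded to integer
    levels before equalization.  A constant input maps to constant 0.
    """
    s = np.asarray(s, dtype=np.float64)
    if not np.all(np.isfinite(s)):
        raise ValueError("histogram modification requires finite input")
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    levels = 2**bit_depth
    out_dtype = np.uint8 if bit_depth == 8 else np.uint16

    shifted = s - s.min()
    top = shifted.max()
    if top == 0:
        return np.zeros(s.shape, dtype=out_dtype)
    if top > levels - 1:
        shifted = shifted * ((levels - 1) / top)
    q = np.round(shifted).astype(np.int64)

    hist = np.bincount(q.ravel(), minlength=levels)
    cdf = np.cumsum(hist)
    cdf_min = cdf[np.nonzero(hist)[0][0]]  # darkest occupied level maps to 0
    n = cdf[-1]
    if n == cdf_min:
        return np.zeros(s.shape, dtype=out_dtype)
    lut = np.round((cdf - cdf_min) / (n - cdf_min) * (levels - 1)).astype(np.int64)
    eq = lut[q]

    lo, hi = eq.min(), eq.max()
    if hi == lo:
        return np.zeros(s.shape, dtype=out_dtype)
    stretched = np.round((eq - lo) / (hi - lo) * (levels - 1))
    return stretched.astype(out_dtype)


def _histogram(f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if f.dtype == np.uint8:
        levels = 256
    elif f.dtype == np.uint16:
        levels = 65536
    else:
        raise TypeError("thresholding expects a uint8 or uint16 grayscale image")
    hist = np.bincount(f.ravel(), minlength=levels).astype(np.float64)
    return hist, np.arange(levels, dtype=np.float64)


def otsu_threshold(f: np.ndarray) -> ThresholdResult:
    """Exhaustive between-class-variance scan; smallest maximizer wins.

    Pixels strictly above the threshold are foreground.  A constant image is
    flagged degenerate and binarizes to all zeros.
    """
    hist, levels = _histogram(f)
    occupied = np.nonzero(hist)[0]
    if occupied.size < 2:
        return ThresholdResult(int(occupied[0]) if occupied.size else 0,
                               np.zeros(f.shape, dtype=np.uint8), True)

    n = hist.sum()
    w0 = np.cumsum(hist)  # pixels at level <= t
    sum0 = np.cumsum(hist * levels)
    mu_total = sum0[-1] / n
    w1 = n - w0
    valid = (w0 > 0) & (w1 > 0)
    mu0 = np.where(w0 > 0, sum0 / np.maximum(w0, 1), 0.0)
    mu1 = np.where(w1 > 0, (sum0[-1] - sum0) / np.maximum(w1, 1), 0.0)
    sigma_b = np.where(valid, w0 * w1 * (mu0 - mu1) ** 2, -np.inf)
    t = int(np.argmax(sigma_b))  # np.argmax returns the first (smallest) maximizer
    del mu_total
    return ThresholdResult(t, (f > t).astype(np.uint8), False)


def tsai_threshold(f: np.ndarray) -> ThresholdResult:
    """Moment-preserving bilevel threshold.

    Solves for the two representative levels z0 < z1 and the below-fraction
    p0 that preserve the first three gray-level moments, then thresholds at
    the smallest level whose cumulative frequency reaches p0.  Pixels above
    the threshold are foreground.
    """
    hist, levels = _histogram(f)
    occupied = np.nonzero(hist)[0]
    if occupied.size < 2:
        return ThresholdResult(int(occupied[0]) if occupied.size else 0,
                               np.zeros(f.shape, dtype=np.uint8), True)

    p = hist / hist.sum()
    m1 = float(np.sum(p * levels))
    m2 = float(np.sum(p * levels**2))
    m3 = float(np.sum(p * levels**3))

    cd = m2 - m1 * m1  # variance; > 0 for >= 2 occupied levels
    if cd <= 0:
        return ThresholdResult(int(occupied[0]), np.zeros(f.shape, dtype=np.uint8), True)
    c0 = (m1 * m3 - m2 * m2) / cd
    c1 = (m1 * m2 - m3) / cd
    disc = c1 * c1 - 4.0 * c0
    if disc < 0:
        return ThresholdResult(int(occupied[0]), np.zeros(f.shape, dtype=np.uint8), True)
    z0 = 0.5 * (-c1 - np.sqrt(disc))
    z1 = 0.5 * (-c1 + np.sqrt(disc))
    p0 = (z1 - m1) / (z1 - z0)

    cum = np.cumsum(p)
    # smallest level whose cumulative frequency reaches p0 (tiny epsilon
    # guards the exactly-bilevel case against float round-off)
    t = int(np.searchsorted(cum, p0 - 1e-12))
    return ThresholdResult(t, (f > t).astype(np.uint8), False)
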