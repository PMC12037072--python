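"""Classic flat grayscale morphology.

Erosion is a moving minimum over the structuring-element support, dilation a
moving maximum; opening, closing and the two top-hats are the usual
compositions.  These serve both as the N=1 reference operators and as the
per-rotation kernel of the rotational operators.

Images are 2D numpy arrays.  Integer arrays (uint8/uint16) are treated as
8-/16-bit grayscale; float arrays are accepted as well because the rotation
workspace holds bilinearly interpolated (real-valued) samples, on which the
min/max operators remain well defined.  Top-hats return signed float64
difference images.

The default border policy is edge replication, which prevents spurious
top-hat responses at the image frame; ``reflect`` and ``constant`` are also
available.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .se import StructuringElement

__all__ = [
    "erode",
    "dilate",
    "opening",
    "closing",
    "white_top_hat",
    "black_top_hat",
    "max_level",
    "BORDER_POLICIES",
]

# Maps the public border-policy names onto scipy.ndimage modes.
BORDER_POLICIES = {"edge": "nearest", "reflect": "mirror", "constant": "constant"}


def max_level(image: np.ndarray) -> int:
    """Complement level M = 2**bit_depth - 1 for an integer grayscale image."""
    if image.dtype == np.uint8:
        return 255
    if image.dtype == np.uint16:
        return 65535
    raise TypeError(f"bit depth undefined for dtype {image.dtype}; expected uint8/uint16")


def _check(f: np.ndarray, se: StructuringElement, border: str) -> str:
    if f.ndim != 2:
        raise ValueError("expected a 2D grayscale image")
    if se.mask.shape[0] > f.shape[0] or se.mask.shape[1] > f.shape[1]:
        raise ValueError(
            f"structuring element {se.mask.shape} larger than image {f.shape}"
        )
    try:
        return BORDER_POLICIES[border]
    except KeyError:
        raise ValueError(f"unknown border policy {border!r}") from None


def erode(
    f: np.ndarray, se: StructuringElement, border: str = "edge", cval: float = 0.0
) -> np.ndarray:
    """Flat erosion: out(p) = min over foreground offsets b of f(p + b)."""
    mode = _check(f, se, border)
    return ndimage.grey_erosion(f, footprint=se.mask, mode=mode, cval=cval)


def dilate(
    f: np.ndarray, se: StructuringElement, border: str = "edge", cval: float = 0.0
) -> np.ndarray:
    """Flat dilation: moving maximum over the (point-symmetric) support."""
    mode = _check(f, se, border)
    return ndimage.grey_dilation(f, footprint=se.mask, mode=mode, cval=cval)


def opening(
    f: np.ndarray, se: StructuringElement, border: str = "edge", cval: float = 0.0
) -> np.ndarray:
    """Erosion followed by dilation; removes bright structure smaller than the SE."""
    return dilate(erode(f, se, border, cval), se, border, cval)


def closing(
    f: np.ndarray, se: StructuringElement, border: str = "edge", cval: float = 0.0
) -> np.ndarray:
    """Dilation followed by erosion; fills dark structure smaller than the SE."""
    return erode(dilate(f, se, border, cval), se, border, cval)


def white_top_hat(
    f: np.ndarray, se: StructuringElement, border: str = "edge", cval: float = 0.0
) -> np.ndarray:
    """f - opening(f): extracts the bright structure the opening removed.

    Returns a signed float64 image (non-negative in the classic, unrotated
    case; shared code path with the rotational variant, which can produce
    small interpolation-induced negatives).
    """
    return np.asarray(f, dtype=np.float64) - opening(f, se, border, cval)


def black_top_hat(
    f: np.ndarray, se: StructuringElement, border: str = "edge", cval: float = 0.0
) -> np.ndarray:
    """closing(f) - f: extracts the dark structure the closing filled."""
    return closing(f, se, border, cval) - np.asarray(f, dtype=np.float64)
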