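"""TIFF I/O, stack handling and slice selection.

Grayscale 8-/16-bit TIFFs are supported, single-page or multi-page; pixel
values round-trip bit-exactly.  Stacks are processed slice by slice.  Slice
selections use ImageJ-style 1-based inclusive numbering: ``"all"``, a range
``"2-5"`` or an explicit list ``"1,3,7"``.

A plugin-style size policy caps input images at 2048 × 2048 pixels; the cap
is policy, not an algorithmic necessity, and can be lifted with
``no_limits=True`` (``--no-limits`` on the command line).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import tifffile

from .ops import RMPRequest, run_rmp

__all__ = [
    "MAX_IMAGE_SIZE",
    "ImageStack",
    "read_image",
    "write_image",
    "parse_selection",
    "process_stack",
]

MAX_IMAGE_SIZE = 2048


class UnsupportedFormatError(ValueError):
    pass


class ImageSizeError(ValueError):
    pass


@dataclass
class ImageStack:
    """An ordered stack of same-shape, same-depth grayscale slices."""

    data: np.ndarray  # (n_slices, H, W), uint8 or uint16

    def __post_init__(self) -> None:
        if self.data.ndim != 3 or self.data.shape[0] < 1:
            raise ValueError("stack must be a (n_slices, H, W) array with >= 1 slice")
        if self.data.dtype not in (np.dtype(np.uint8), np.dtype(np.uint16)):
            raise UnsupportedFormatError("stack must be uint8 or uint16 grayscale")

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def bit_depth(self) -> int:
        return 8 if self.data.dtype == np.uint8 else 16


def _validate_frame(arr: np.ndarray, no_limits: bool) -> None:
    if arr.dtype not in (np.dtype(np.uint8), np.dtype(np.uint16)):
        raise UnsupportedFormatError(
            f"unsupported pixel type {arr.dtype}: only 8-bit and 16-bit "
            "grayscale images are supported"
        )
    h, w = arr.shape[-2:]
    if not no_limits and (h > MAX_IMAGE_SIZE or w > MAX_IMAGE_SIZE):
        raise ImageSizeError(
            f"image is {h} x {w}: the maximum input size is "
            f"{MAX_IMAGE_SIZE} x {MAX_IMAGE_SIZE} pixels (use no_limits to override)"
        )


def read_image(path, no_limits: bool = False) -> np.ndarray | ImageStack:
    """Read a grayscale TIFF; multi-page files come back as an ImageStack."""
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        _validate_frame(arr, no_limits)
        return arr
    if arr.ndim == 3:
        # reject RGB pages: a trailing axis of 3/4 with 2D pages is color
        if arr.shape[-1] in (3, 4) and arr.shape[0] > 4:
            raise UnsupportedFormatError("color (RGB/RGBA) images are not supported")
        _validate_frame(arr, no_limits)
        return ImageStack(data=arr)
    raise UnsupportedFormatError(f"unsupported TIFF layout with shape {arr.shape}")


def write_image(path, image: np.ndarray | ImageStack) -> None:
    """Write a single image or a multi-page stack, preserving bit depth."""
    data = image.data if isinstance(image, ImageStack) else image
    tifffile.imwrite(path, data, photometric="minisblack")


def parse_selection(selection: str, n_slices: int) -> list[int]:
    """Turn ``"all"``, ``"2-5"`` or ``"1,3,7"`` into 0-based slice indices."""
    s = selection.strip().lower()
    if s == "all":
        return list(range(n_slices))
    if "-" in s and "," not in s:
        first_s, last_s = s.split("-", 1)
        first, last = int(first_s), int(last_s)
        if not (1 <= first <= last <= n_slices):
            raise ValueError(
                f"slice range {selection!r} out of bounds for {n_slices} slices "
                "(1-based inclusive)"
            )
        return list(range(first - 1, last))
    indices = sorted({int(tok) for tok in s.split(",") if tok.strip()})
    if not indices:
        raise ValueError("empty slice selection")
    if indices[0] < 1 or indices[-1] > n_slices:
        raise ValueError(
            f"slice list {selection!r} out of bounds for {n_slices} slices (1-based)"
        )
    return [i - 1 for i in indices]


def process_stack(
    stack: ImageStack,
    request: RMPRequest,
    selection: str = "all",
    histmod: bool = False,
) -> ImageStack:
    """Apply a rotational operator to the selected slices, one by one.

    Unselected slices pass through bit-identically; slice order is kept.
    """
    chosen = parse_selection(selection, len(stack))
    if not chosen:
        raise ValueError("empty slice selection")
    out = stack.data.copy()
    for i in chosen:
        out[i] = run_rmp(stack.data[i], request, histmod=histmod)
    return ImageStack(data=out)
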