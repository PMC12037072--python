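"""Flat (binary) structuring elements.

Three probe shapes are supported — ``disk``, ``line`` and ``square`` — each
defined by a single pixel size: the disk diameter, the line length, or the
square side.  All three masks are point-symmetric about their anchor, which
is what makes rotational processing well defined: probing at angle θ and at
θ + 180° is the same operation, so the angle set only needs to cover
[0°, 180°).

The line element is always built horizontal.  Orientation diversity comes
from rotating the *image*, never from resampling the element itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StructuringElement", "make_se", "MAX_SE_SIZE", "SE_SHAPES"]

#: Largest admitted element size, in pixels (plugin-style policy cap).
MAX_SE_SIZE = 99

SE_SHAPES = ("disk", "line", "square")


class SESizeError(ValueError):
    """Raised when an element size is outside the admitted [1, 99] range."""


@dataclass(frozen=True)
class StructuringElement:
    """A flat morphological probe.

    Parameters
    ----------
    mask
        Boolean 2D array with odd height and odd width; the anchor is the
        exact center cell and is always foreground.
    shape_tag
        One of ``disk``, ``line``, ``square``.
    size_px
        The size actually used to build the mask (odd).
    requested_size
        The size the caller asked for; differs from ``size_px`` only when an
        even size was promoted to the next odd integer.
    """

    mask: np.ndarray
    shape_tag: str
    size_px: int
    requested_size: int
    note: str = field(default="")

    @property
    def anchor(self) -> tuple[int, int]:
        return (self.mask.shape[0] // 2, self.mask.shape[1] // 2)

    @property
    def n_foreground(self) -> int:
        return int(self.mask.sum())

    def __post_init__(self) -> None:
        h, w = self.mask.shape
        if h % 2 == 0 or w % 2 == 0:
            raise ValueError("structuring element mask must have odd dimensions")
        if not self.mask[self.anchor]:
            raise ValueError("anchor cell must be foreground")

    def to_text(self) -> str:
        """Serialize as rows of 0/1 characters."""
        return "\n".join("".join("1" if v else "0" for v in row) for row in self.mask)

    @classmethod
    def from_text(cls, text: str, shape_tag: str = "custom") -> "StructuringElement":
        rows = [line.strip() for line in text.strip().splitlines() if line.strip()]
        mask = np.array([[c == "1" for c in row] for row in rows], dtype=bool)
        size = max(mask.shape)
        return cls(mask=mask, shape_tag=shape_tag, size_px=size, requested_size=size)


def _disk_mask(size: int) -> np.ndarray:
    # Cell (r, c) is foreground iff its center lies within diameter/2 of the
    # anchor center (inclusive boundary): the anchor row then holds exactly
    # `size` foreground cells, matching the "size = diameter" convention.
    r = size // 2
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    return dy * dy + dx * dx <= (size / 2.0) ** 2


def make_se(shape_tag: str, size_px: int) -> StructuringElement:
    """Build a flat structuring element of the given shape and pixel size.

    Even sizes are promoted to the next odd integer so that a center anchor
    exists; the promotion is recorded in the ``note`` field.

    Raises
    ------
    SESizeError
        If ``size_px`` is outside [1, 99].
    ValueError
        If ``shape_tag`` is not one of ``disk``, ``line``, ``square``.
    """
    if not isinstance(size_px, (int, np.integer)):
        raise TypeError("size_px must be an integer")
    if size_px < 1 or size_px > MAX_SE_SIZE:
        raise SESizeError(
            f"structuring element size {size_px} outside [1, {MAX_SE_SIZE}]: "
            f"the maximum SE size is {MAX_SE_SIZE} x {MAX_SE_SIZE} pixels"
        )
    if shape_tag not in SE_SHAPES:
        raise ValueError(f"unknown SE shape {shape_tag!r}; expected one of {SE_SHAPES}")

    size = int(size_px)
    note = ""
    if size % 2 == 0:
        size += 1
        note = f"even size {size_px} promoted to {size}"

    if shape_tag == "square":
        mask = np.ones((size, size), dtype=bool)
    elif shape_tag == "line":
        mask = np.ones((1, size), dtype=bool)
    else:
        mask = _disk_mask(size)

    return StructuringElement(
        mask=mask,
        shape_tag=shape_tag,
        size_px=size,
        requested_size=int(size_px),
        note=note,
    )
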