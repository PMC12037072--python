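"""Lossless rotate / rotate-back engine.

The rotational operators need every original pixel to survive an arbitrary
rotation and come back to its place.  To guarantee that, the image is first
edge-padded onto a square workspace whose side is at least the image
diagonal; rotation about the workspace center then keeps every original
pixel strictly inside the canvas for any angle (no-clip guarantee).

Interpolation is bilinear, all workspace arithmetic is float64, and angles
are counter-clockwise positive in array coordinates.  θ ≡ 0 (mod 360) is an
exact identity and exact multiples of 90° are lattice rotations performed
with ``np.rot90`` (bit-exact, no interpolation); both special cases match
the general bilinear path's geometry.

Because all three structuring-element shapes are point symmetric, probing at
θ and θ + 180° is identical, so a rotation plan with N angles spaces them
uniformly over [0°, 180°).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "RotationPlan",
    "plan_angles",
    "workspace_geometry",
    "rotate_workspace",
    "unrotate_workspace",
]


@dataclass(frozen=True)
class RotationPlan:
    """Rotation count N and the derived angle list θ_i = (180/N)·i."""

    n: int
    angles_deg: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("rotation count N must be >= 1")
        if len(self.angles_deg) != self.n:
            raise ValueError("angle list length must equal N")


def plan_angles(n: int) -> RotationPlan:
    """Uniform angles (180/N)·i for i = 0..N-1; N=1 gives the single angle 0°."""
    if not isinstance(n, (int, np.integer)) or n < 1:
        raise ValueError("rotation count N must be an integer >= 1")
    if n > 360:
        raise ValueError("rotation count N must be <= 360")
    step = 180.0 / n
    return RotationPlan(n=int(n), angles_deg=tuple(step * i for i in range(n)))


def workspace_geometry(shape: tuple[int, int]) -> tuple[int, int, int]:
    """Workspace side D and the (top, left) offset of the original window.

    D is the smallest integer at least the image diagonal (and at least each
    image side), so every original pixel stays inside under any rotation
    about the workspace center.
    """
    h, w = shape
    d = max(int(np.ceil(np.hypot(h, w))), h, w)
    while True:
        top, left = (d - h) // 2, (d - w) // 2
        cy = cx = (d - 1) / 2.0
        rmax = max(
            np.hypot(y - cy, x - cx)
            for y in (top, top + h - 1)
            for x in (left, left + w - 1)
        )
        if rmax <= (d - 1) / 2.0:
            return d, top, left
        d += 1


def _rotate_canvas(ws: np.ndarray, theta_deg: float) -> np.ndarray:
    k4 = theta_deg / 90.0
    if float(theta_deg) % 360.0 == 0.0:
        return ws.copy()
    if k4 == int(k4):
        return np.rot90(ws, int(k4) % 4).copy()
    return ndimage.rotate(ws, theta_deg, reshape=False, order=1, mode="nearest")


def rotate_workspace(f: np.ndarray, theta_deg: float) -> np.ndarray:
    """Pad ``f`` to the no-clip workspace and rotate it by θ (bilinear)."""
    if not np.isfinite(theta_deg):
        raise ValueError("rotation angle must be finite")
    h, w = f.shape
    d, top, left = workspace_geometry((h, w))
    ws = np.pad(
        np.asarray(f, dtype=np.float64),
        ((top, d - h - top), (left, d - w - left)),
        mode="edge",
    )
    return _rotate_canvas(ws, theta_deg)


def unrotate_workspace(
    ws: np.ndarray, theta_deg: float, original_shape: tuple[int, int]
) -> np.ndarray:
    """Apply −θ and crop back to the original height × width window."""
    h, w = original_shape
    d, top, left = workspace_geometry((h, w))
    if ws.shape != (d, d):
        raise ValueError(
            f"workspace shape {ws.shape} does not match geometry ({d}, {d}) "
            f"derived from original shape {original_shape}"
        )
    back = _rotate_canvas(ws, -theta_deg)
    return back[top : top + h, left : left + w]
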