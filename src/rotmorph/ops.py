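"""The seven rotational morphological operators.

Each operator follows the same scheme: rotate the image through the N plan
angles, apply a classic flat operation with the *same* structuring element
after each rotation, rotate back, and fuse the per-angle results pixelwise
in the original frame — max for the opening family (γR), min for the closing
family (ϕR).  Rotating the image rather than the element makes a discretized
probe behave almost isotropically and lets a line element sweep all
orientations.

The seven operators:

=============  ===============================================  ==========
name           definition (γR/ϕR kept in float)                 output
=============  ===============================================  ==========
opening        γR = max_i unrotate(open(rotate(f, θ_i)))        grayscale
closing        ϕR = min_i unrotate(close(rotate(f, θ_i)))       grayscale
white_top_hat  WTHR = f − γR(f)                                 signed
black_top_hat  BTHR = ϕR(f) − f                                 signed
smoothing      MSR  = ϕR(γR(f))  (open-then-close)              grayscale
enhance1       MCE1R = f − MSR(f)                               signed
enhance2       MCE2R = f + WTHR(f) − BTHR(f)                    signed
=============  ===============================================  ==========

With N = 1 every operator reduces bit-exactly to its classic composition.
All intermediate arithmetic is float64; quantization to the image bit depth
(round half away from zero, clip) happens exactly once, at output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import morphology
from .morphology import max_level
from .rotation import RotationPlan, plan_angles, rotate_workspace, unrotate_workspace
from .se import StructuringElement

__all__ = [
    "OPERATIONS",
    "SMOOTHING_OPERATIONS",
    "ENHANCEMENT_OPERATIONS",
    "RMPRequest",
    "rmp_primitive",
    "rmp_primitive_float",
    "rmp_derived",
    "run_rmp",
    "quantize",
    "default_rotations",
]

OPERATIONS = (
    "opening",
    "closing",
    "white_top_hat",
    "black_top_hat",
    "smoothing",
    "enhance1",
    "enhance2",
)

#: Smoothing-group operators (histogram modification not applicable).
SMOOTHING_OPERATIONS = ("opening", "closing", "smoothing")
#: Enhancement-group operators (signed output; histogram modification allowed).
ENHANCEMENT_OPERATIONS = ("white_top_hat", "black_top_hat", "enhance1", "enhance2")


def default_rotations(se_shape: str) -> int:
    """Recommended rotation count: 8 for disk/square probes, 36 for line."""
    return 36 if se_shape == "line" else 8


@dataclass(frozen=True)
class RMPRequest:
    """A fully specified rotational-processing job."""

    operation: str
    se: StructuringElement
    plan: RotationPlan
    smoothing_order: str = field(default="oc")

    def __post_init__(self) -> None:
        if self.operation not in OPERATIONS:
            raise ValueError(
                f"unknown operation {self.operation!r}; expected one of {OPERATIONS}"
            )
        if self.smoothing_order not in ("oc", "co", "average"):
            raise ValueError("smoothing_order must be 'oc', 'co' or 'average'")


def quantize(x: np.ndarray, bit_depth: int) -> np.ndarray:
    """Round half away from zero and clip to [0, 2**bit_depth − 1]."""
    m = 2**bit_depth - 1
    rounded = np.where(x >= 0, np.floor(x + 0.5), np.ceil(x - 0.5))
    out = np.clip(rounded, 0, m)
    return out.astype(np.uint8 if bit_depth == 8 else np.uint16)


def _bit_depth(f: np.ndarray) -> int:
    return 8 if max_level(f) == 255 else 16


def rmp_primitive_float(
    f: np.ndarray,
    kind: str,
    se: StructuringElement,
    plan: RotationPlan,
    border: str = "edge",
) -> np.ndarray:
    """Float-valued γR (kind='opening') or ϕR (kind='closing').

    For each plan angle the padded workspace is rotated, the classic flat
    operation applied, and the result rotated back and cropped; the N images
    are then fused pixelwise (max for opening, min for closing).
    """
    if kind not in ("opening", "closing"):
        raise ValueError("kind must be 'opening' or 'closing'")
    classic = morphology.opening if kind == "opening" else morphology.closing
    fuse = np.maximum if kind == "opening" else np.minimum
    shape = f.shape
    out: np.ndarray | None = None
    for theta in plan.angles_deg:
        k4 = theta / 90.0
        if k4 == int(k4) and (int(k4) % 2 == 0 or shape[0] == shape[1]):
            # Lattice rotation: operate in the original frame (bit-exact,
            # classic edge replication at the true image border).  Odd
            # multiples of 90 deg need a square image to keep the frame.
            k = int(k4) % 4
            g = np.rot90(classic(np.rot90(np.asarray(f, dtype=np.float64), k),
                                 se, border=border), -k)
            h = np.ascontiguousarray(g)
        else:
            ws = rotate_workspace(f, theta)
            g = classic(ws, se, border=border)
            h = unrotate_workspace(g, theta, shape)
        out = h if out is None else fuse(out, h)
    assert out is not None
    return out


def rmp_primitive(
    f: np.ndarray, kind: str, se: StructuringElement, plan: RotationPlan
) -> np.ndarray:
    """Quantized rotational opening/closing at the input bit depth."""
    return quantize(rmp_primitive_float(f, kind, se, plan), _bit_depth(f))


def _smoothed_float(
    f: np.ndarray, se: StructuringElement, plan: RotationPlan, order: str
) -> np.ndarray:
    def oc(x: np.ndarray) -> np.ndarray:
        return rmp_primitive_float(
            rmp_primitive_float(x, "opening", se, plan), "closing", se, plan
        )

    def co(x: np.ndarray) -> np.ndarray:
        return rmp_primitive_float(
            rmp_primitive_float(x, "closing", se, plan), "opening", se, plan
        )

    if order == "oc":
        return oc(f)
    if order == "co":
        return co(f)
    return 0.5 * (oc(f) + co(f))


def rmp_derived(
    f: np.ndarray,
    operation: str,
    se: StructuringElement,
    plan: RotationPlan,
    smoothing_order: str = "oc",
) -> np.ndarray:
    """The five derived operators, in float.

    ``smoothing`` returns a float grayscale image (still to be quantized);
    the other four return signed difference images.
    """
    ff = np.asarray(f, dtype=np.float64)
    if operation == "white_top_hat":
        return ff - rmp_primitive_float(f, "opening", se, plan)
    if operation == "black_top_hat":
        return rmp_primitive_float(f, "closing", se, plan) - ff
    if operation == "smoothing":
        return _smoothed_float(f, se, plan, smoothing_order)
    if operation == "enhance1":
        return ff - _smoothed_float(f, se, plan, smoothing_order)
    if operation == "enhance2":
        wth = ff - rmp_primitive_float(f, "opening", se, plan)
        bth = rmp_primitive_float(f, "closing", se, plan) - ff
        return ff + wth - bth
    raise ValueError(f"unknown derived operation {operation!r}")


def run_rmp(f: np.ndarray, request: RMPRequest, histmod: bool = False) -> np.ndarray:
    """Execute a rotational-processing job on one grayscale image.

    Histogram modification (shift → equalize → stretch) is only meaningful
    for the signed enhancement outputs; requesting it for the smoothing
    group is an error.
    """
    depth = _bit_depth(f)
    if histmod and request.operation in SMOOTHING_OPERATIONS:
        raise ValueError(
            "histogram modification applies only to top-hat/enhancement "
            f"operators, not {request.operation!r}"
        )
    if request.operation in ("opening", "closing"):
        out = rmp_primitive_float(f, request.operation, request.se, request.plan)
    else:
        out = rmp_derived(
            f, request.operation, request.se, request.plan, request.smoothing_order
        )
    if histmod:
        from .postprocess import histogram_modification

        return histogram_modification(out, depth)
    return quantize(out, depth)
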