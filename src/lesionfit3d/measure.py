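"""Scalar lesion measurements.

Two families of measurement are provided, mirroring how they are obtained in
the clinic:

* ``ellipsoid3d`` — derived from the best-fit ellipsoid: maximum diameter is
  twice the major semi-axis (which may point in any direction), volume is
  V = (4π/3)·a·b·c.
* ``manual2d`` — radiologist-style: maximum diameter is the in-plane Feret
  diameter on the axial slice with the largest ROI, volume is planimetric
  (per-slice area sum times the slice profile, i.e. thickness + gap).

Diameters are reported in cm and volumes in cc; all internal geometry stays
in mm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from .ellipsoid import Ellipsoid
from .errors import EmptyInputError, ValidationError
from .grid import LesionMask

__all__ = [
    "Measurement",
    "ellipsoid_volume",
    "ellipsoid_tmd",
    "planimetric_volume",
    "axial_max_diameter",
    "measure_mask",
]


@dataclass(frozen=True)
class Measurement:
    """A (TMD, TV) pair with the method that produced it."""

    method: str  # "ellipsoid3d" | "manual2d"
    tmd_cm: float
    tv_cc: float

    def __post_init__(self) -> None:
        if self.method not in ("ellipsoid3d", "manual2d"):
            raise ValidationError(f"unknown measurement method {self.method!r}")
        if not (self.tmd_cm >= 0 and self.tv_cc >= 0):
            raise ValidationError("measurements must be non-negative")


def ellipsoid_volume(e: Ellipsoid) -> float:
    """Tumour volume V = (4π/3)·a·b·c of the fitted ellipsoid, in cc."""
    a, b, c = e.semi_axes
    return 4.0 * np.pi / 3.0 * float(a * b * c) / 1000.0


def ellipsoid_tmd(e: Ellipsoid) -> float:
    """Tumour maximum diameter: twice the largest semi-axis, in cm."""
    return 2.0 * float(np.max(e.semi_axes)) / 10.0


def planimetric_volume(mask: LesionMask) -> float:
    """Planimetric volume: Σ per-slice area × slice profile, in cc.

    The slice profile is thickness + gap of the mask's own grid; intended for
    the original (non-interpolated) acquisition grid.
    """
    if mask.is_empty:
        raise EmptyInputError("cannot measure an empty mask")
    profile = mask.grid.slice_thickness + mask.grid.slice_gap
    return float(mask.slice_areas_mm2().sum() * profile) / 1000.0


def axial_max_diameter(mask: LesionMask) -> float:
    """Maximum in-plane Feret diameter on the largest-area axial slice, in cm.

    The slice with the largest ROI area is selected (ties: lower slice
    index); the diameter is the maximum pairwise distance between inside
    voxel centres, computed over the convex hull.  A single-voxel slice has
    no extent and returns 0 with a warning.
    """
    if mask.is_empty:
        raise EmptyInputError("cannot measure an empty mask")
    counts = mask.occupancy.sum(axis=(0, 1))
    k = int(np.argmax(counts))  # argmax takes the first (lowest) max index
    idx = np.argwhere(mask.occupancy[:, :, k]).astype(float)
    if idx.shape[0] == 1:
        warnings.warn(
            f"largest ROI slice (k={k}) contains a single voxel; diameter is "
            "degenerate and reported as 0",
            stacklevel=2,
        )
        return 0.0
    pts = idx * np.array([mask.grid.dx, mask.grid.dy])
    if pts.shape[0] > 4:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # collinear voxels: brute-force over all centres
    return float(pdist(pts).max()) / 10.0


def measure_mask(
    mask: LesionMask,
    mode: str = "both",
    k: float = 4.0,
    interp_spacing: float = 1.0,
    allow_single_slice: bool = False,
) -> dict[str, Measurement]:
    """Measure a mask with the manual-style and/or ellipsoid-fit method."""
    from .ellipsoid import fit_ellipsoid  # local import to avoid cycle at module load

    if mode not in ("manual2d", "ellipsoid3d", "both"):
        raise ValidationError(f"unknown measurement mode {mode!r}")
    out: dict[str, Measurement] = {}
    if mode in ("manual2d", "both"):
        out["manual2d"] = Measurement(
            method="manual2d",
            tmd_cm=axial_max_diameter(mask),
            tv_cc=planimetric_volume(mask),
        )
    if mode in ("ellipsoid3d", "both"):
        e = fit_ellipsoid(
            mask, k=k, target_spacing=interp_spacing,
            allow_single_slice=allow_single_slice,
        )
        out["ellipsoid3d"] = Measurement(
            method="ellipsoid3d", tmd_cm=ellipsoid_tmd(e), tv_cc=ellipsoid_volume(e)
        )
    return out
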