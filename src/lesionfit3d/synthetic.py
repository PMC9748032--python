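"""Phantoms and simulated cohorts with known ground truth.

No patient imaging ships with this package; every stage of the measurement
pipeline is exercised on synthetic lesions instead.  Phantoms are ellipsoids
(optionally with a smooth radial perturbation for irregular-lesion studies)
rasterized onto MRI-like voxel grids; cohorts draw per-score true volumes
from lognormal distributions moment-matched to the published per-score
mean ± SD of ellipsoid-measured tumour volume, then *measure* each phantom
with both the manual-style 2D operators and the 3D ellipsoid fit — so the
manual columns exhibit the axial-underestimation mechanism rather than an
assumed offset.

Default grid geometry emulates the DWI acquisition the lesions were contoured
on: 2.6 × 2.6 mm in-plane, 3 mm slice thickness, 3 mm gap (6 mm slice
centres).  Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .ellipsoid import LesionEllipsoidModel
from .errors import (
    EmptyPhantomError,
    InsufficientDataError,
    NotAnEllipsoidError,
    TruncationError,
    ValidationError,
)
from .grid import LesionMask, VoxelGrid
from .measure import axial_max_diameter, planimetric_volume

__all__ = [
    "PhantomSpec",
    "dwi_grid",
    "t2_grid",
    "voxelize_ellipsoid",
    "perturb_blob",
    "simulate_cohort",
    "DEFAULT_TV_PARAMS_CC",
]

# Per-score (mean, SD) of true tumour volume in cc; ellipsoid-method column
# of the published per-score summary table.
DEFAULT_TV_PARAMS_CC: dict[int, tuple[float, float]] = {
    3: (0.49, 0.31),
    4: (0.99, 0.58),
    5: (1.05, 0.78),
}


def dwi_grid(nx: int = 32, ny: int = 32, nz: int = 14) -> VoxelGrid:
    """DWI-like geometry: 2.6 mm in-plane, 3 mm thickness + 3 mm gap."""
    return VoxelGrid(nx=nx, ny=ny, nz=nz, dx=2.6, dy=2.6,
                     slice_thickness=3.0, slice_gap=3.0)


def t2_grid(nx: int = 128, ny: int = 128, nz: int = 14) -> VoxelGrid:
    """T2-like geometry: 0.49 mm in-plane, 3 mm thickness + 3 mm gap."""
    return VoxelGrid(nx=nx, ny=ny, nz=nz, dx=0.49, dy=0.49,
                     slice_thickness=3.0, slice_gap=3.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Ground-truth description of a synthetic lesion.

    ``euler_deg`` are intrinsic (azimuth-about-z, tilt-about-y, roll-about-z)
    angles in degrees; with zero roll the tilt is exactly the out-of-axial-
    plane angle of the major axis.  ``perturb_amplitude`` is the radial
    perturbation as a fraction of the local ellipsoid radius (0 = pure
    ellipsoid).
    """

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    grid: VoxelGrid
    euler_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    perturb_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        a, b, c = self.semi_axes
        if not (a >= b >= c > 0):
            raise ValidationError(f"semi_axes must satisfy a >= b >= c > 0, got {self.semi_axes}")
        if not (0.0 <= self.perturb_amplitude <= 0.5):
            raise ValidationError(
                f"perturb_amplitude must be in [0, 0.5], got {self.perturb_amplitude}"
            )

    @property
    def rotation(self) -> np.ndarray:
        return Rotation.from_euler("zyz", self.euler_deg, degrees=True).as_matrix()


def _voxel_centers(grid: VoxelGrid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x = grid.origin[0] + np.arange(grid.nx) * grid.dx
    y = grid.origin[1] + np.arange(grid.ny) * grid.dy
    z = grid.origin[2] + np.arange(grid.nz) * grid.dz
    return np.meshgrid(x, y, z, indexing="ij")


def _check_truncation(spec: PhantomSpec) -> None:
    g = spec.grid
    R = spec.rotation
    axes = np.asarray(spec.semi_axes)
    # bounding-box half extent of the (unperturbed) ellipsoid along world axes
    half = np.sqrt(((R * axes) ** 2).sum(axis=1)) * (1.0 + spec.perturb_amplitude)
    lo = np.asarray(g.origin) - 0.5 * np.asarray(g.spacing)
    hi = np.asarray(g.origin) + (np.asarray(g.shape) - 0.5) * np.asarray(g.spacing)
    c = np.asarray(spec.center)
    if np.any(c - half < lo) or np.any(c + half > hi):
        raise TruncationError(
            f"phantom (centre {tuple(c)}, extent ±{half.round(2)}) extends beyond "
            "the voxel grid"
        )


def _ellipsoid_radius(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Normalised ellipsoid radius of every voxel centre and unit directions.

    Radius <= 1 means inside the unperturbed ellipsoid.  Directions are in
    the ellipsoid's own frame (for evaluating angular perturbations).
    """
    X, Y, Z = _voxel_centers(spec.grid)
    pts = np.stack([X, Y, Z], axis=-1) - np.asarray(spec.center)
    local = pts @ spec.rotation  # R^T applied to each point
    u = local / np.asarray(spec.semi_axes)
    r = np.sqrt((u**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        dirs = np.where(r[..., None] > 0, u / np.maximum(r[..., None], 1e-300), 0.0)
    return r, dirs


def voxelize_ellipsoid(spec: PhantomSpec) -> tuple[LesionMask, dict]:
    """Rasterize an exact ellipsoid: voxel inside iff its centre is inside.

    Returns the mask and a truth record with the analytic volume
    (4π/3·a·b·c) and maximum diameter (2a).
    """
    _check_truncation(spec)
    r, _ = _ellipsoid_radius(spec)
    occ = r <= 1.0
    if not occ.any():
        raise EmptyPhantomError("ellipsoid is smaller than a single voxel on this grid")
    a, b, c = spec.semi_axes
    truth = {
        "tv_cc": 4.0 * np.pi / 3.0 * a * b * c / 1000.0,
        "tmd_cm": 2.0 * a / 10.0,
    }
    return LesionMask(spec.grid, occ), truth


# Real spherical-harmonic-style angular basis up to degree 2 (Cartesian form).
_ANGULAR_BASIS = (
    lambda u: u[..., 0],
    lambda u: u[..., 1],
    lambda u: u[..., 2],
    lambda u: u[..., 0] * u[..., 1],
    lambda u: u[..., 0] * u[..., 2],
    lambda u: u[..., 1] * u[..., 2],
    lambda u: u[..., 0] ** 2 - u[..., 1] ** 2,
    lambda u: 3 * u[..., 2] ** 2 - 1.0,
)


def _angular_field(coeffs: np.ndarray, dirs: np.ndarray) -> np.ndarray:
    return sum(c * f(dirs) for c, f in zip(coeffs, _ANGULAR_BASIS))


def _fibonacci_dirs(n: int = 512) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def perturb_blob(spec: PhantomSpec) -> tuple[LesionMask, dict]:
    """Rasterize an irregular lesion: ellipsoid with smooth radial perturbation.

    The boundary radius is scaled by ``1 + amplitude * f(direction)`` where f
    is a seeded low-order angular harmonic sum normalised to max |f| = 1.
    Amplitude 0 reduces exactly to :func:`voxelize_ellipsoid`.  The truth
    volume is the rasterized voxel count times voxel volume (the analytic
    ellipsoid volume no longer applies).
    """
    if spec.perturb_amplitude == 0.0:
        mask, truth = voxelize_ellipsoid(spec)
        truth = dict(truth)
        truth["tv_cc"] = mask.voxel_count * np.prod(spec.grid.spacing) / 1000.0
        return mask, truth
    _check_truncation(spec)
    rng = np.random.default_rng(spec.seed)
    coeffs = rng.normal(size=len(_ANGULAR_BASIS))
    norm = np.abs(_angular_field(coeffs, _fibonacci_dirs())).max()
    coeffs = coeffs / norm

    r, dirs = _ellipsoid_radius(spec)
    rho = 1.0 + spec.perturb_amplitude * _angular_field(coeffs, dirs)
    occ = r <= rho
    if not occ.any():
        raise EmptyPhantomError("perturbed blob is smaller than a single voxel")
    mask = LesionMask(spec.grid, occ)
    truth = {
        "tv_cc": mask.voxel_count * np.prod(spec.grid.spacing) / 1000.0,
        "tmd_cm": 2.0 * spec.semi_axes[0] / 10.0,  # nominal, pre-perturbation
    }
    return mask, truth


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-match a lognormal to a given mean and SD."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def simulate_cohort(
    n_per_score: dict[int, int],
    seed: int = 0,
    grid: VoxelGrid | None = None,
    tv_params_cc: dict[int, tuple[float, float]] | None = None,
    tilt_range_deg: tuple[float, float] = (0.0, 60.0),
    k: float = 4.0,
    interp_spacing: float = 1.0,
    keep_truth: bool = True,
    max_placement_tries: int = 50,
    masks_dir=None,
) -> pd.DataFrame:
    """Simulate a measured cohort with paired manual/automated columns.

    Per subject: draw true TV from the per-score lognormal, draw axis ratios
    (b/a ~ U(0.55, 0.9), c/a ~ U(0.35, b/a)) and a major-axis tilt uniform in
    ``tilt_range_deg``, rasterize on the (default DWI-like) grid with random
    sub-voxel placement, then record ``manual_*`` from planimetric volume and
    axial Feret diameter and ``auto_*`` from the constrained ellipsoid fit.

    Placement is conditioned on visibility: if a (small) lesion misses every
    slice centre, its through-plane position is redrawn — an invisible lesion
    cannot be part of a measured cohort.

    When ``masks_dir`` is given, each phantom mask is also written there as
    ``<subject_id>.nii.gz``.
    """
    for s, n in n_per_score.items():
        if s not in (3, 4, 5):
            raise ValidationError(f"scores must be in {{3,4,5}}, got {s}")
        if not (isinstance(n, (int, np.integer)) and n >= 1):
            raise ValidationError(f"n for score {s} must be >= 1, got {n}")
    grid = grid if grid is not None else dwi_grid()
    tv_params = tv_params_cc if tv_params_cc is not None else DEFAULT_TV_PARAMS_CC
    rng = np.random.default_rng(seed)
    center0 = (
        grid.origin[0] + (grid.nx - 1) / 2.0 * grid.dx,
        grid.origin[1] + (grid.ny - 1) / 2.0 * grid.dy,
        grid.origin[2] + (grid.nz - 1) / 2.0 * grid.dz,
    )

    rows = []
    for score in sorted(n_per_score):
        mu, sigma = _lognormal_params(*tv_params[score])
        for i in range(n_per_score[score]):
            tv_true = float(rng.lognormal(mu, sigma))
            abc = 3.0 * tv_true * 1000.0 / (4.0 * np.pi)  # product of semi-axes, mm^3
            r1 = rng.uniform(0.55, 0.9)
            r2 = rng.uniform(0.35, r1)
            a = (abc / (r1 * r2)) ** (1.0 / 3.0)
            axes = (a, r1 * a, r2 * a)
            tilt = rng.uniform(*tilt_range_deg)
            azim = rng.uniform(0.0, 360.0)

            mask = None
            for _ in range(max_placement_tries):
                jitter = (
                    rng.uniform(-grid.dx / 2, grid.dx / 2),
                    rng.uniform(-grid.dy / 2, grid.dy / 2),
                    rng.uniform(-grid.dz / 2, grid.dz / 2),
                )
                spec = PhantomSpec(
                    center=tuple(np.asarray(center0) + jitter),
                    semi_axes=axes,
                    grid=grid,
                    euler_deg=(azim, tilt, 0.0),
                )
                try:
                    candidate, _truth = voxelize_ellipsoid(spec)
                except EmptyPhantomError:
                    continue
                try:
                    fit = LesionEllipsoidModel(
                        candidate, k=k, interp_spacing=interp_spacing,
                        allow_single_slice=True,
                    ).fit()
                except (InsufficientDataError, NotAnEllipsoidError):
                    continue
                mask = candidate
                break
            if mask is None:
                raise EmptyPhantomError(
                    f"could not place a visible lesion of {tv_true:.3f} cc on the grid "
                    f"after {max_placement_tries} tries (score {score}, subject {i + 1})"
                )

            import warnings as _warnings

            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")  # single-voxel-slice diameters
                manual_tmd = axial_max_diameter(mask)
            row = {
                "subject_id": f"S{score}-{i + 1:03d}",
                "initial_score": score,
                "manual_tv_cc": planimetric_volume(mask),
                "manual_tmd_cm": manual_tmd,
                "auto_tv_cc": fit.tv_cc,
                "auto_tmd_cm": fit.tmd_cm,
            }
            if keep_truth:
                row.update(
                    true_tv_cc=tv_true,
                    true_tmd_cm=2.0 * a / 10.0,
                    tilt_deg=tilt,
                )
            if masks_dir is not None:
                import pathlib

                from .io import write_mask

                outdir = pathlib.Path(masks_dir)
                outdir.mkdir(parents=True, exist_ok=True)
                write_mask(mask, outdir / f"{row['subject_id']}.nii.gz")
            rows.append(row)
    return pd.DataFrame(rows)
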