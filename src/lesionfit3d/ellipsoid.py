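"""Ellipsoid-specific least-squares quadric fitting.

A general quadric surface

    a x^2 + b y^2 + c z^2 + 2f yz + 2g xz + 2h xy + 2p x + 2q y + 2r z + d = 0

is fitted to surface points by minimising the algebraic residual ||D u||^2
subject to the ellipsoid-specific normalisation

    k J - I^2 = 1,   I = a + b + c,   J = ab + bc + ac - f^2 - g^2 - h^2,

with k = 4 by default.  For k = 4 the constraint guarantees the minimiser is
an ellipsoid whenever the semi-axes are of comparable length (the constraint
quadratic form has exactly one positive eigen-direction, so the constrained
minimum is the generalized eigenvector of the reduced scatter matrix with
positive constraint value).  The solve is non-iterative: block elimination of
the linear coefficients followed by a 6x6 generalized eigenproblem.

The algebraic solution is converted to geometric parameters (centre, ordered
semi-axes, rotation) by translating to the quadric centre and
eigendecomposing the quadratic-form matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .errors import (
    DegenerateGeometryError,
    EmptyInputError,
    InsufficientDataError,
    NotAnEllipsoidError,
    ValidationError,
)
from .grid import LesionMask, PointCloud, interpolate_z, surface_points

__all__ = [
    "Quadric",
    "Ellipsoid",
    "fit_quadric",
    "quadric_to_ellipsoid",
    "fit_ellipsoid",
    "LesionEllipsoidModel",
    "EllipsoidFitResult",
]


@dataclass(frozen=True)
class Quadric:
    """Coefficients of a general second-degree surface.

    Stored in the convention
    ``a x² + b y² + c z² + 2f yz + 2g xz + 2h xy + 2p x + 2q y + 2r z + d = 0``.
    ``k`` records the constraint parameter the surface was fitted under.
    """

    a: float
    b: float
    c: float
    f: float
    g: float
    h: float
    p: float
    q: float
    r: float
    d: float
    k: float = 4.0

    def __post_init__(self) -> None:
        coeffs = self.coefficients
        if not np.all(np.isfinite(coeffs)):
            raise ValidationError("quadric coefficients must be finite")
        if np.all(coeffs == 0):
            raise ValidationError("quadric coefficient vector must be nonzero")

    @property
    def coefficients(self) -> np.ndarray:
        """The 10-vector (a, b, c, f, g, h, p, q, r, d)."""
        return np.array(
            [self.a, self.b, self.c, self.f, self.g, self.h,
             self.p, self.q, self.r, self.d]
        )

    @property
    def I(self) -> float:  # noqa: E743 - the field's standard symbol
        """Trace invariant a + b + c."""
        return self.a + self.b + self.c

    @property
    def J(self) -> float:
        """Second invariant ab + bc + ac − f² − g² − h²."""
        return (
            self.a * self.b + self.b * self.c + self.a * self.c
            - self.f**2 - self.g**2 - self.h**2
        )

    @property
    def form_matrix(self) -> np.ndarray:
        """Symmetric 3x3 quadratic-form matrix [[a,h,g],[h,b,f],[g,f,c]]."""
        return np.array(
            [[self.a, self.h, self.g],
             [self.h, self.b, self.f],
             [self.g, self.f, self.c]]
        )

    @property
    def linear(self) -> np.ndarray:
        """The linear coefficient vector (p, q, r)."""
        return np.array([self.p, self.q, self.r])

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        """Algebraic residual of the quadric at each point (zero on-surface)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        quad = np.einsum("ni,ij,nj->n", pts, self.form_matrix, pts)
        return quad + 2.0 * pts @ self.linear + self.d


@dataclass(frozen=True)
class Ellipsoid:
    """Geometric ellipsoid: centre (mm), ordered semi-axes (mm), rotation.

    ``semi_axes`` are sorted a >= b >= c > 0; the columns of ``rotation`` are
    the corresponding axis directions and form a right-handed orthonormal
    frame.
    """

    center: np.ndarray
    semi_axes: np.ndarray
    rotation: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        center = np.asarray(self.center, dtype=float).reshape(3)
        axes = np.asarray(self.semi_axes, dtype=float).reshape(3)
        rot = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        if not (np.all(np.isfinite(center)) and np.all(np.isfinite(axes))
                and np.all(np.isfinite(rot))):
            raise ValidationError("ellipsoid parameters must be finite")
        if not (axes[0] >= axes[1] >= axes[2] > 0):
            raise ValidationError(f"semi-axes must satisfy a >= b >= c > 0, got {axes}")
        if not np.allclose(rot.T @ rot, np.eye(3), atol=1e-9):
            raise ValidationError("rotation must be orthonormal to 1e-9")
        if not np.isclose(np.linalg.det(rot), 1.0, atol=1e-9):
            raise ValidationError("rotation must have determinant +1 to 1e-9")
        object.__setattr__(self, "center", center)
        object.__setattr__(self, "semi_axes", axes)
        object.__setattr__(self, "rotation", rot)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean array: point inside or on the surface."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        u = (pts - self.center) @ self.rotation / self.semi_axes
        return (u**2).sum(axis=1) <= 1.0

    def surface_points(self, n: int = 200) -> np.ndarray:
        """Deterministic quasi-uniform surface sample (Fibonacci sphere)."""
        i = np.arange(n) + 0.5
        phi = np.arccos(1 - 2 * i / n)
        theta = np.pi * (1 + 5**0.5) * i
        unit = np.column_stack(
            [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
        )
        return self.center + (unit * self.semi_axes) @ self.rotation.T


def _constraint_matrix(k: float) -> np.ndarray:
    """6x6 quadratic form C with u1' C u1 = kJ - I^2 for u1=(a,b,c,f,g,h)."""
    C = np.zeros((6, 6))
    C[:3, :3] = (k - 2.0) / 2.0
    np.fill_diagonal(C[:3, :3], -1.0)
    C[3:, 3:] = -k * np.eye(3)
    return C


def _design_matrix(pts: np.ndarray) -> np.ndarray:
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    return np.column_stack(
        [x * x, y * y, z * z, 2 * y * z, 2 * x * z, 2 * x * y,
         2 * x, 2 * y, 2 * z, np.ones_like(x)]
    )


def _denormalize(u1: np.ndarray, b_n: np.ndarray, d_n: float,
                 centroid: np.ndarray, scale: float, k: float) -> Quadric:
    """Map quadric coefficients fitted in centred/scaled coordinates back to
    physical mm and renormalise so |kJ - I^2| = 1."""
    A_n = np.array(
        [[u1[0], u1[5], u1[4]],
         [u1[5], u1[1], u1[3]],
         [u1[4], u1[3], u1[2]]]
    )
    s2 = scale * scale
    A_p = A_n / s2
    b_p = b_n / scale - A_n @ centroid / s2
    d_p = d_n + centroid @ A_n @ centroid / s2 - 2.0 * b_n @ centroid / scale

    coeffs = np.array(
        [A_p[0, 0], A_p[1, 1], A_p[2, 2], A_p[1, 2], A_p[0, 2], A_p[0, 1],
         b_p[0], b_p[1], b_p[2], d_p]
    )
    I = coeffs[0] + coeffs[1] + coeffs[2]
    J = (coeffs[0] * coeffs[1] + coeffs[1] * coeffs[2] + coeffs[0] * coeffs[2]
         - coeffs[3]**2 - coeffs[4]**2 - coeffs[5]**2)
    gval = k * J - I * I
    norm = np.sqrt(abs(gval)) if abs(gval) > 1e-30 else np.linalg.norm(coeffs)
    return Quadric(*(coeffs / norm), k=k)


def fit_quadric(points: PointCloud | np.ndarray, k: float = 4.0) -> Quadric:
    """Least-squares quadric fit under the constraint kJ − I² = 1.

    The point cloud is centred and scaled to unit RMS radius before the solve
    (raw mm² monomials are badly conditioned) and the recovered coefficients
    are mapped back to physical coordinates and renormalised so that
    kJ − I² = 1 holds in physical units.

    Raises
    ------
    InsufficientDataError
        Fewer than 10 points.
    DegenerateGeometryError
        Points do not determine a 3D quadric (e.g. coplanar).
    NotAnEllipsoidError
        No admissible eigen-solution with positive constraint value.
    """
    pts = points.points if isinstance(points, PointCloud) else np.asarray(points, float)
    pts = np.atleast_2d(pts)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValidationError(f"points must have shape (N, 3), got {pts.shape}")
    n = pts.shape[0]
    if n < 10:
        raise InsufficientDataError(f"need at least 10 points to fit a quadric, got {n}")
    if k < 4.0:
        raise ValidationError(
            f"k={k} rejected: for k < 4 the constraint no longer guarantees an "
            "ellipsoid solution (use k >= 4)"
        )

    centroid = pts.mean(axis=0)
    centered = pts - centroid
    scale = float(np.sqrt((centered**2).sum(axis=1).mean()))
    if scale <= 0:
        raise DegenerateGeometryError("all points coincide")
    P = centered / scale

    D = _design_matrix(P)
    _, sv, Vt = np.linalg.svd(D)
    # rank >= 9 required: exactly-on-quadric data has one near-zero singular
    # value; coplanar or conic-degenerate data loses more.
    if sv[8] <= 1e-9 * sv[0]:
        raise DegenerateGeometryError(
            "point configuration does not determine a 3D quadric "
            "(rank-deficient design system)"
        )

    if sv[9] <= 1e-10 * sv[0]:
        # The points lie exactly on a unique quadric (zero-residual null
        # vector).  That quadric is the least-squares solution outright; the
        # k-constraint's ellipsoid guarantee is replaced by direct validation.
        # This matters for elongated ellipsoids (axis ratio > ~2), whose true
        # coefficients have kJ - I^2 < 0 and are unreachable under the +1
        # normalisation ("k ~ 4" presumes comparable semi-axes).
        quadric = _denormalize(Vt[9, :6], Vt[9, 6:9], Vt[9, 9],
                               centroid, scale, k)
        try:
            quadric_to_ellipsoid(quadric)
        except NotAnEllipsoidError:
            pass  # exact quadric is not an ellipsoid; use the constrained fit
        else:
            return quadric

    S = D.T @ D
    S11, S12, S22 = S[:6, :6], S[:6, 6:], S[6:, 6:]
    try:
        elim = np.linalg.solve(S22, S12.T)  # S22^{-1} S21
    except np.linalg.LinAlgError as exc:  # pragma: no cover - caught by rank check
        raise DegenerateGeometryError("singular linear block in the design system") from exc
    M = S11 - S12 @ elim
    C = _constraint_matrix(k)

    eigvals, eigvecs = scipy.linalg.eig(M, C)
    # After scaling u = v/sqrt(v'Cv), the residual u'Mu equals the eigenvalue,
    # so among admissible eigenvectors (positive constraint value) the
    # constrained minimiser is the one with the smallest eigenvalue.
    best = None
    for i in range(6):
        lam = eigvals[i]
        if not np.isfinite(lam.real) or abs(lam.imag) > 1e-8 * (1 + abs(lam.real)):
            continue
        v = np.real(eigvecs[:, i])
        nv = np.linalg.norm(v)
        if nv == 0:
            continue
        v = v / nv
        qval = float(v @ C @ v)
        if qval > 1e-12 and lam.real > -1e-9:
            if best is None or lam.real < best[2]:
                best = (v, qval, lam.real)
    if best is None:
        raise NotAnEllipsoidError(
            "no admissible eigen-solution: the best-fit quadric under "
            f"k={k} is not an ellipsoid"
        )
    v, qval, _ = best
    u1 = v / np.sqrt(qval)
    u2 = -elim @ u1
    quadric = _denormalize(u1, u2[:3], u2[3], centroid, scale, k)
    # the constrained branch must land on the positive branch of kJ - I^2
    # (the normalisation is sign-preserving under the coordinate map)
    if quadric.k * quadric.J - quadric.I**2 <= 0:
        raise NotAnEllipsoidError(
            "fitted quadric violates the ellipsoid constraint sign (kJ - I^2 <= 0)"
        )
    return quadric


def quadric_to_ellipsoid(quadric: Quadric) -> Ellipsoid:
    """Convert algebraic quadric coefficients to geometric parameters.

    The centre solves ``A x0 = -b`` (zero of the gradient); in centre
    coordinates the surface is ``(x-x0)' A (x-x0) = -d_c`` with
    ``d_c = d + b·x0``, so the semi-axes are ``sqrt(-d_c / λ_i)`` for the
    eigenvalues of A.  Mixed eigenvalue signs or non-positive axis lengths
    mean a hyperboloid/paraboloid/imaginary surface.
    """
    A = quadric.form_matrix
    bvec = quadric.linear
    dval = quadric.d
    # Overall sign is arbitrary; normalise so the quadratic form has positive trace.
    if np.trace(A) < 0:
        A, bvec, dval = -A, -bvec, -dval

    det = np.linalg.det(A)
    if abs(det) < 1e-300 or not np.isfinite(det):
        raise NotAnEllipsoidError("quadratic-form matrix is singular (paraboloid)")
    try:
        center = np.linalg.solve(A, -bvec)
    except np.linalg.LinAlgError as exc:
        raise NotAnEllipsoidError("quadratic-form matrix is singular (paraboloid)") from exc
    d_c = dval + bvec @ center

    lam, vecs = np.linalg.eigh(A)
    radii_sq = np.where(lam != 0, -d_c / lam, -np.inf)
    if np.any(radii_sq <= 0) or not np.all(np.isfinite(radii_sq)):
        raise NotAnEllipsoidError(
            "quadric is not a real ellipsoid (mixed-sign eigenvalues or "
            "non-positive squared semi-axes)"
        )
    semi = np.sqrt(radii_sq)

    # Deterministic eigenvector signs: largest-magnitude component positive.
    for i in range(3):
        col = vecs[:, i]
        j = int(np.argmax(np.abs(col)))
        if col[j] < 0:
            vecs[:, i] = -col

    # Sort by descending axis length; ties by lexicographic axis direction.
    order = sorted(range(3), key=lambda i: (-semi[i], tuple(vecs[:, i])))
    semi = semi[order]
    vecs = vecs[:, order]
    if np.linalg.det(vecs) < 0:
        vecs[:, 2] = -vecs[:, 2]
    return Ellipsoid(center=center, semi_axes=semi, rotation=vecs)


def fit_ellipsoid(
    mask: LesionMask,
    k: float = 4.0,
    target_spacing: float = 1.0,
    allow_single_slice: bool = False,
) -> Ellipsoid:
    """Fit a best-fit ellipsoid to a lesion mask.

    Pipeline: shape-based interpolation to fine slices (default 1 mm) →
    sub-voxel surface sampling (marching cubes) → constrained quadric fit →
    geometric conversion.  Deterministic for fixed input.

    A mask occupying a single original slice carries almost no through-plane
    shape information and is refused unless ``allow_single_slice=True`` (its
    z-extent is then set by the end-extension rule alone).
    """
    if mask.is_empty:
        raise EmptyInputError("cannot fit an ellipsoid to an empty mask")
    n_orig = len(mask.occupied_slices())
    if n_orig < 2 and not allow_single_slice:
        raise InsufficientDataError(
            "lesion occupies a single slice: insufficient 3D extent for an "
            "ellipsoid fit (pass allow_single_slice=True to fit anyway, with "
            "through-plane extent set by the slice profile)"
        )
    interp = interpolate_z(mask, target_spacing)
    if len(interp.occupied_slices()) < 3:
        raise InsufficientDataError(
            "fewer than 3 occupied slices after interpolation: insufficient "
            "z-extent for an ellipsoid fit"
        )
    cloud = surface_points(interp)
    quadric = fit_quadric(cloud, k=k)
    return quadric_to_ellipsoid(quadric)


class LesionEllipsoidModel:
    """Constrained ellipsoid-fit model for a lesion mask or point cloud.

    Statsmodels-style usage::

        model = LesionEllipsoidModel(mask, k=4)
        result = model.fit()
        print(result.summary())

    Parameters
    ----------
    mask
        Binary lesion mask on a voxel grid.  Mutually exclusive with
        ``points``.
    points
        Surface points (mm) to fit directly, skipping interpolation and
        boundary extraction.
    k
        Ellipsoid-constraint parameter (>= 4).
    interp_spacing
        Target slice spacing (mm) for shape-based interpolation of masks.
    allow_single_slice
        Permit fitting masks that occupy a single original slice.
    """

    def __init__(
        self,
        mask: LesionMask | None = None,
        points: PointCloud | np.ndarray | None = None,
        k: float = 4.0,
        interp_spacing: float = 1.0,
        allow_single_slice: bool = False,
    ) -> None:
        if (mask is None) == (points is None):
            raise ValidationError("provide exactly one of mask or points")
        if k < 4.0:
            raise ValidationError(
                f"k={k} rejected: for k < 4 the ellipsoid guarantee weakens (use k >= 4)"
            )
        self.mask = mask
        self.points = None if points is None else (
            points if isinstance(points, PointCloud) else PointCloud(np.asarray(points))
        )
        self.k = float(k)
        self.interp_spacing = float(interp_spacing)
        self.allow_single_slice = bool(allow_single_slice)

    @classmethod
    def from_mask(cls, mask: LesionMask, **kwargs) -> "LesionEllipsoidModel":
        return cls(mask=mask, **kwargs)

    def fit(self) -> "EllipsoidFitResult":
        """Run the constrained fit and return a results object."""
        if self.mask is not None:
            if self.mask.is_empty:
                raise EmptyInputError("cannot fit an ellipsoid to an empty mask")
            n_orig = len(self.mask.occupied_slices())
            if n_orig < 2 and not self.allow_single_slice:
                raise InsufficientDataError(
                    "lesion occupies a single slice: insufficient 3D extent "
                    "(pass allow_single_slice=True to fit anyway)"
                )
            interp = interpolate_z(self.mask, self.interp_spacing)
            if len(interp.occupied_slices()) < 3:
                raise InsufficientDataError(
                    "fewer than 3 occupied slices after interpolation"
                )
            cloud = surface_points(interp)
        else:
            cloud = self.points
        quadric = fit_quadric(cloud, k=self.k)
        ellipsoid = quadric_to_ellipsoid(quadric)
        # dimensionless unit-form residual: ||u||^2 - 1 with u the point in
        # the ellipsoid frame scaled by the semi-axes (0 for on-surface)
        u = ((cloud.points - ellipsoid.center) @ ellipsoid.rotation
             / ellipsoid.semi_axes)
        resid = (u**2).sum(axis=1) - 1.0
        return EllipsoidFitResult(
            model=self,
            quadric=quadric,
            ellipsoid=ellipsoid,
            n_points=len(cloud),
            residual_rms=float(np.sqrt(np.mean(resid**2))),
        )


@dataclass(frozen=True)
class EllipsoidFitResult:
    """Result of :meth:`LesionEllipsoidModel.fit`.

    Carries the algebraic coefficients, the geometric ellipsoid, and the
    derived clinical measurements (maximum diameter and volume).
    """

    model: LesionEllipsoidModel
    quadric: Quadric
    ellipsoid: Ellipsoid
    n_points: int
    residual_rms: float

    @property
    def tmd_cm(self) -> float:
        """Tumour maximum diameter: major axis of the fit, in cm."""
        return 2.0 * float(self.ellipsoid.semi_axes[0]) / 10.0

    @property
    def tv_cc(self) -> float:
        """Tumour volume: (4π/3)·a·b·c, in cc."""
        a, b, c = self.ellipsoid.semi_axes
        return 4.0 * np.pi / 3.0 * float(a * b * c) / 1000.0

    def to_dict(self) -> dict:
        e = self.ellipsoid
        return {
            "quadric": {
                name: getattr(self.quadric, name)
                for name in ("a", "b", "c", "f", "g", "h", "p", "q", "r", "d")
            },
            "k": self.quadric.k,
            "center_mm": list(map(float, e.center)),
            "semi_axes_mm": list(map(float, e.semi_axes)),
            "rotation": e.rotation.tolist(),
            "tmd_cm": self.tmd_cm,
            "tv_cc": self.tv_cc,
            "n_points": self.n_points,
            "residual_rms": self.residual_rms,
        }

    def summary(self) -> str:
        e = self.ellipsoid
        lines = [
            "Constrained ellipsoid fit (kJ - I^2 = 1)",
            "=" * 44,
            f"constraint k           {self.quadric.k:>10.3g}",
            f"points fitted          {self.n_points:>10d}",
            f"residual RMS           {self.residual_rms:>10.3e}",
            f"centre (mm)            ({e.center[0]:.2f}, {e.center[1]:.2f}, {e.center[2]:.2f})",
            f"semi-axes a,b,c (mm)   ({e.semi_axes[0]:.2f}, {e.semi_axes[1]:.2f}, {e.semi_axes[2]:.2f})",
            f"max diameter TMD (cm)  {self.tmd_cm:>10.2f}",
            f"volume TV (cc)         {self.tv_cc:>10.2f}",
        ]
        return "\n".join(lines)
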