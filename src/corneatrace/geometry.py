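"""Conic (quadric-of-revolution) surface geometry.

The cornea is modelled in a 2D meridional plane: the optical axis is ``z``
(mm, positive into the eye), the radial coordinate is ``y`` (mm).  Each
refracting surface is a conic of revolution with apex on the axis,

    z - z0 = (r^2 / R) / (1 + sqrt(1 - (1 + Q) r^2 / R^2)),

where ``R`` is the central radius of curvature (``R > 0`` for a surface
convex toward ``-z``) and ``Q`` the asphericity (conic constant): ``Q = 0``
sphere, ``Q < 0`` prolate (the typical cornea), ``Q = -1`` paraboloid.
Eccentricity ``e`` exported by topographers maps to ``Q = -e^2``.

All functions broadcast over numpy arrays of radial heights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import RayMissError, SurfaceExtentError

__all__ = [
    "ConicSurface",
    "eccentricity_to_asphericity",
    "conic_sag",
    "surface_normal",
    "ray_surface_intersection",
]

_EPS = 1e-12


def eccentricity_to_asphericity(e):
    """Convert corneal eccentricity ``e`` to asphericity ``Q = -e**2``.

    Topographers commonly export the eccentricity of the best-fit conic
    meridian; the conic constant used in sag formulas is its negative
    square (e=0 sphere, e=1 parabola).

    Parameters
    ----------
    e : float or array_like
        Eccentricity, must be >= 0.
    """
    e = np.asarray(e, dtype=float)
    if np.any(e < 0):
        raise ValueError("eccentricity must be >= 0")
    q = -(e**2)
    return float(q) if q.ndim == 0 else q


@dataclass(frozen=True)
class ConicSurface:
    """One rotationally symmetric conic refracting surface.

    Parameters
    ----------
    z0 : float
        Axial position of the surface apex (mm).
    R : float
        Central radius of curvature (mm); positive for a surface convex
        toward ``-z`` (both corneal surfaces).
    Q : float
        Asphericity (conic constant).
    """

    z0: float
    R: float
    Q: float

    def __post_init__(self) -> None:
        if self.R == 0:
            raise ValueError("central radius R must be nonzero")

    @property
    def max_height(self) -> float:
        """Largest radial height on the surface (inf for Q <= -1)."""
        if self.Q > -1:
            return abs(self.R) / np.sqrt(1.0 + self.Q)
        return np.inf

    def sag(self, r):
        return conic_sag(self, r)

    def normal(self, r):
        return surface_normal(self, r)


def conic_sag(surface: ConicSurface, r):
    """Axial sag ``z - z0`` of the surface at radial height ``r`` (mm).

    Even in ``r``; the central curvature is ``1/R``.  Raises
    :class:`SurfaceExtentError` for heights beyond the geometric extent
    (where the square-root argument turns negative, Q > -1 only).
    """
    r = np.asarray(r, dtype=float)
    R, Q = surface.R, surface.Q
    u = (1.0 + Q) * r**2 / R**2
    arg = 1.0 - u
    if np.any(arg < -_EPS):
        raise SurfaceExtentError(
            f"height beyond surface extent (R={R}, Q={Q}, max r={surface.max_height:.4g} mm)"
        )
    arg = np.clip(arg, 0.0, None)
    s = (r**2 / R) / (1.0 + np.sqrt(arg))
    return float(s) if s.ndim == 0 else s


def surface_normal(surface: ConicSurface, r):
    """Unit surface normal at height ``r``, pointing toward the incident side.

    Returns the (radial, axial) components; at the apex this is (0, -1).
    For a sphere (Q=0) the normal line passes through the centre of
    curvature at ``z0 + R``.
    """
    r = np.asarray(r, dtype=float)
    R, Q = surface.R, surface.Q
    disc = R**2 - (1.0 + Q) * r**2
    if np.any(disc <= 0):
        raise SurfaceExtentError("height beyond surface extent")
    # dz/dr of the sag; odd in r
    slope = r / np.sqrt(disc)
    norm = np.sqrt(slope**2 + 1.0)
    ny = slope / norm
    nz = -1.0 / norm
    if r.ndim == 0:
        return np.array([float(ny), float(nz)])
    return np.stack([ny, nz], axis=-1)


def _intersect_many(y0, z0, dy, dz, surface: ConicSurface):
    """Vectorised ray/conic intersection.

    Rays are ``(y0, z0) + t (dy, dz)`` with ``dz > 0``.  The conic apex
    branch satisfies ``y^2 = 2 R s - (1+Q) s^2`` with ``s = z - z0 >= 0``
    (and ``s <= R/(1+Q)`` for Q > -1).  Returns the travel parameter ``t``
    of the smallest positive root on that branch; NaN where the ray misses.

    The quadratic is solved with the numerically stable "q" formulation to
    avoid cancellation for paraxial rays.
    """
    R, Q = surface.R, surface.Q
    w = z0 - surface.z0
    p = 1.0 + Q
    A = dy**2 + p * dz**2
    B = 2.0 * (y0 * dy + p * w * dz - R * dz)
    C = y0**2 + p * w**2 - 2.0 * R * w

    t = np.full(np.broadcast(y0, dy).shape, np.nan)
    disc = B**2 - 4.0 * A * C
    ok = disc >= 0
    sq = np.sqrt(np.where(ok, disc, 0.0))
    # q-formulation: q = -(B + sign(B) sqrt(disc)) / 2 ; roots q/A and C/q
    sgn = np.where(B >= 0, 1.0, -1.0)
    q = -0.5 * (B + sgn * sq)

    with np.errstate(divide="ignore", invalid="ignore"):
        r1 = np.where(np.abs(A) > _EPS, q / A, np.where(np.abs(B) > _EPS, -C / B, np.nan))
        r2 = np.where(np.abs(q) > _EPS, C / q, r1)

    s_max = R / p if p > 0 else np.inf
    for root in (r1, r2):
        s = w + root * dz
        valid = (
            ok
            & np.isfinite(root)
            & (root > -1e-10)
            & (s > -1e-9)
            & (s < s_max + 1e-9)
        )
        t = np.where(valid & (~np.isfinite(t) | (root < t)), root, t)
    return t


def ray_surface_intersection(origin, direction, surface: ConicSurface):
    """Intersect a single ray with the surface's physical (apex) branch.

    Parameters
    ----------
    origin : (2,) array_like
        Ray start point (y, z) in mm.
    direction : (2,) array_like
        Unit direction; must propagate toward +z.
    surface : ConicSurface

    Returns
    -------
    (2,) ndarray
        Intersection point (y, z).  Among real roots the smallest positive
        travel on the apex-side branch is chosen.

    Raises
    ------
    RayMissError
        If no real intersection exists on the physical branch (the ray
        passes outside the surface extent).
    """
    origin = np.asarray(origin, dtype=float)
    direction = np.asarray(direction, dtype=float)
    t = _intersect_many(
        np.float64(origin[0]), np.float64(origin[1]),
        np.float64(direction[0]), np.float64(direction[1]), surface,
    )
    if not np.isfinite(t):
        raise RayMissError("ray does not intersect the surface's physical branch")
    return origin + float(t) * direction
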