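"""Collimated ray fans traced through the two-surface cornea.

A bundle of meridional rays starts on the plano reference plane ``z = 0``,
refracts at the corneal front surface (apex at the origin) and again at the
back surface (apex at ``z = CCT``), accumulating optical path length
``OPL = sum(n * geometric length)`` along the way.  The refractive indices
default to the Liou–Brennan schematic-eye values (cornea 1.376, aqueous
humour 1.336).

Because a meridional ray at radius ``r`` stands in for a whole annulus of
the pupil, rays carry area weights.  The default ``area_linear`` scheme
weights each ray by ``|r|`` (annulus area ~ r dr for equidistant radii);
``quadratic`` (``w ~ r^2``) is available as an alternative pupil
apodisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import RayMissError, TotalInternalReflectionError
from .geometry import ConicSurface, _intersect_many, surface_normal

__all__ = [
    "OpticalConstants",
    "CorneaModel",
    "RayFan",
    "TracedFan",
    "LIOU_BRENNAN",
    "refract_snell",
    "build_fan",
    "trace_eye",
]


@dataclass(frozen=True)
class OpticalConstants:
    """Refractive indices of the media surrounding the corneal stroma."""

    n_air: float = 1.0
    n_cornea: float = 1.376
    n_aqueous: float = 1.336

    def __post_init__(self) -> None:
        if not (self.n_cornea > self.n_aqueous > self.n_air > 0):
            raise ValueError("expected n_cornea > n_aqueous > n_air > 0")


#: Liou & Brennan schematic-eye indices (cornea / aqueous humour)
LIOU_BRENNAN = OpticalConstants()


@dataclass(frozen=True)
class CorneaModel:
    """Two conic surfaces plus central thickness and media indices.

    The front apex sits at the origin; the back apex at ``z = CCT`` (mm).
    """

    front: ConicSurface
    back: ConicSurface
    CCT: float
    constants: OpticalConstants = LIOU_BRENNAN

    def __post_init__(self) -> None:
        if self.CCT <= 0:
            raise ValueError("CCT must be positive (mm)")
        if self.front.z0 != 0.0:
            raise ValueError("front apex must be at the origin")

    @classmethod
    def from_biometry(
        cls,
        R_f: float,
        Q_f: float,
        R_b: float,
        Q_b: float,
        CCT: float,
        constants: OpticalConstants = LIOU_BRENNAN,
    ) -> "CorneaModel":
        """Build a cornea from the usual tomography export (CCT in mm)."""
        return cls(
            front=ConicSurface(z0=0.0, R=R_f, Q=Q_f),
            back=ConicSurface(z0=CCT, R=R_b, Q=Q_b),
            CCT=CCT,
            constants=constants,
        )


@dataclass(frozen=True)
class RayFan:
    """Collimated input fan: radial start heights and area weights."""

    heights: np.ndarray
    weights: np.ndarray
    weighting: str = "area_linear"

    @property
    def n_rays(self) -> int:
        return self.heights.size

    @property
    def aperture_diameter(self) -> float:
        return float(self.heights.max() - self.heights.min())


@dataclass(frozen=True)
class TracedFan:
    """Per-ray state after the corneal back surface.

    ``exit_points`` are the intersection points with the back surface,
    ``directions`` the unit ray directions in the aqueous, ``opl`` the
    cumulative optical path length (mm) from the ``z = 0`` plane.
    """

    heights: np.ndarray
    exit_points: np.ndarray  # (n, 2) -> (y, z)
    directions: np.ndarray  # (n, 2) unit vectors
    opl: np.ndarray  # (n,) mm
    weights: np.ndarray
    cornea: CorneaModel = field(repr=False)
    weighting: str = "area_linear"

    @property
    def n_rays(self) -> int:
        return self.heights.size


def refract_snell(direction, normal, n1: float, n2: float):
    """Refract unit direction(s) at an interface via vector Snell's law.

    ``normal`` must point against the incident ray (``d . n < 0``).  Both
    arguments broadcast as (..., 2) arrays.  Raises
    :class:`TotalInternalReflectionError` when no real transmitted ray
    exists.
    """
    d = np.asarray(direction, dtype=float)
    n = np.asarray(normal, dtype=float)
    if n1 <= 0 or n2 <= 0:
        raise ValueError("refractive indices must be positive")
    eta = n1 / n2
    cos_i = -np.sum(d * n, axis=-1)
    k = 1.0 - eta**2 * (1.0 - cos_i**2)
    if np.any(k < 0):
        raise TotalInternalReflectionError(
            f"total internal reflection (n1={n1}, n2={n2})"
        )
    t = eta * d + (eta * cos_i - np.sqrt(k))[..., None] * n
    t /= np.linalg.norm(t, axis=-1, keepdims=True)
    return t


def build_fan(
    aperture_diameter: float,
    n_rays: int = 1001,
    weighting: str = "area_linear",
) -> RayFan:
    """Build a collimated fan spanning the pupil projection.

    Heights are equally spaced on ``[-D/2, +D/2]`` (odd ``n_rays`` keeps the
    chief ray at 0).  ``weighting='area_linear'`` sets ``w ~ |r|`` (annulus
    area correction, default); ``'quadratic'`` sets ``w ~ r^2``.  Weights
    are normalised to sum 1; the chief ray carries zero weight in the
    statistics but is retained.
    """
    if aperture_diameter <= 0:
        raise ValueError("aperture diameter must be positive")
    if n_rays < 3:
        raise ValueError("need at least 3 rays")
    h = np.linspace(-aperture_diameter / 2.0, aperture_diameter / 2.0, n_rays)
    if weighting == "area_linear":
        w = np.abs(h)
    elif weighting == "quadratic":
        w = h**2
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    w = w / w.sum()
    return RayFan(heights=h, weights=w, weighting=weighting)


def trace_eye(cornea: CorneaModel, fan: RayFan) -> TracedFan:
    """Trace a collimated fan through both corneal surfaces.

    Each ray starts at ``(h, 0)`` travelling along +z, is refracted at the
    front and back surfaces and emerges into the aqueous.  The chief ray
    passes undeviated with ``OPL = n_cornea * CCT``.

    Raises
    ------
    RayMissError
        If any ray fails to intersect a surface (fan wider than the
        surface extent).
    TotalInternalReflectionError
        If Snell's law has no solution at either interface.
    """
    c = cornea.constants
    h = np.asarray(fan.heights, dtype=float)
    y = h.copy()
    z = np.zeros_like(h)
    d = np.zeros((h.size, 2))
    d[:, 1] = 1.0
    opl = np.zeros_like(h)

    for surface, n_in, n_out in (
        (cornea.front, c.n_air, c.n_cornea),
        (cornea.back, c.n_cornea, c.n_aqueous),
    ):
        t = _intersect_many(y, z, d[:, 0], d[:, 1], surface)
        if not np.all(np.isfinite(t)):
            n_bad = int(np.sum(~np.isfinite(t)))
            raise RayMissError(
                f"{n_bad}/{h.size} rays miss the surface at z0={surface.z0}"
            )
        y = y + t * d[:, 0]
        z = z + t * d[:, 1]
        opl = opl + n_in * t  # |d| == 1, so t is the geometric length
        normals = surface_normal(surface, y)
        d = refract_snell(d, normals, n_in, n_out)

    return TracedFan(
        heights=h,
        exit_points=np.stack([y, z], axis=-1),
        directions=d,
        opl=opl,
        weights=np.asarray(fan.weights, dtype=float),
        cornea=cornea,
        weighting=fan.weighting,
    )
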