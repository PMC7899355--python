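"""Wavefront maps over a fixed 6-mm zone and radial Zernike coefficients.

Corneal spherical aberration is reported as the Z40 coefficient of the
optical-path-difference (OPD) map sampled at the corneal front apex plane
over a fixed 6-mm zone, independent of the pupil used for the focus search.
Coefficients follow the OSA/ANSI normalisation: the rotationally symmetric
radial polynomials on ``rho = r / (zone_radius)`` are

    R00 = 1
    R20 = sqrt(3) (2 rho^2 - 1)
    R40 = sqrt(5) (6 rho^4 - 6 rho^2 + 1)
    R60 = sqrt(7) (20 rho^6 - 30 rho^4 + 12 rho^2 - 1)

Only these even radial orders appear: a centred, rotationally symmetric
cornea produces no coma or astigmatism.  Z60 is carried along to keep
higher-order leakage out of Z40 on the discrete, area-weighted samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FitError, SurfaceExtentError
from .raytrace import CorneaModel, build_fan, trace_eye

__all__ = [
    "OPDMap",
    "ZernikeResult",
    "radial_polynomial",
    "opd_at_apex_plane",
    "fit_radial_zernikes",
]

_RADIAL_ORDERS = (0, 2, 4, 6)


def radial_polynomial(n: int, rho):
    """OSA-normalised rotationally symmetric Zernike radial polynomial."""
    rho = np.asarray(rho, dtype=float)
    r2 = rho**2
    if n == 0:
        return np.ones_like(rho)
    if n == 2:
        return np.sqrt(3.0) * (2.0 * r2 - 1.0)
    if n == 4:
        return np.sqrt(5.0) * (6.0 * r2**2 - 6.0 * r2 + 1.0)
    if n == 6:
        return np.sqrt(7.0) * (20.0 * r2**3 - 30.0 * r2**2 + 12.0 * r2 - 1.0)
    raise ValueError(f"unsupported radial order {n}")


@dataclass(frozen=True)
class OPDMap:
    """Sampled optical path difference over a zone at the apex plane.

    ``opd`` is in um with the weighted mean (piston) removed; positive OPD
    marks a phase-advanced ray.  ``radii`` span the zone diameter.
    """

    radii: np.ndarray  # mm, in [-D/2, D/2]
    opd: np.ndarray  # um, piston removed
    weights: np.ndarray
    focus_plane: float  # mm, the z_F the reference point sits on
    zone_diameter: float = 6.0


@dataclass(frozen=True)
class ZernikeResult:
    """Radial Zernike coefficients (um) and the weighted fit residual."""

    Z00: float
    Z20: float
    Z40: float
    Z60: float
    residual_rms: float  # um

    def reconstruct(self, rho):
        """Evaluate the fitted radial wavefront at normalised radius rho."""
        return sum(
            c * radial_polynomial(n, rho)
            for n, c in zip(_RADIAL_ORDERS, (self.Z00, self.Z20, self.Z40, self.Z60))
        )


def opd_at_apex_plane(
    cornea: CorneaModel,
    z_F: float,
    n_rays: int = 201,
    zone_diameter: float = 6.0,
    weighting: str = "area_linear",
) -> OPDMap:
    """OPD map of a zone-spanning fan referenced to the point ``(0, z_F)``.

    A fresh collimated fan covering the zone (default 6 mm, regardless of
    the pupil) is traced through the cornea; each ray's total optical path
    length from the z=0 plane to the focus point is compared against the
    weighted mean:  ``OPD_i = <OPL> - OPL_i`` (um).  Marginal rays of an
    SA-positive cornea arrive phase-advanced (positive OPD).
    """
    if cornea.front.max_height < zone_diameter / 2.0:
        raise SurfaceExtentError(
            f"front surface extent {cornea.front.max_height:.3f} mm < zone radius"
        )
    fan = build_fan(zone_diameter, n_rays=n_rays, weighting=weighting)
    traced = trace_eye(cornea, fan)
    y_e = traced.exit_points[:, 0]
    z_e = traced.exit_points[:, 1]
    dist = np.sqrt(y_e**2 + (z_F - z_e) ** 2)
    opl = traced.opl + cornea.constants.n_aqueous * dist
    w = traced.weights
    opd = 1000.0 * (np.sum(w * opl) - opl)
    return OPDMap(
        radii=traced.heights,
        opd=opd,
        weights=w,
        focus_plane=z_F,
        zone_diameter=zone_diameter,
    )


def fit_radial_zernikes(opd_map: OPDMap) -> ZernikeResult:
    """Weighted least-squares fit of {Z00, Z20, Z40, Z60} to an OPD map.

    Coefficients come out in um on ``rho = r / (zone_diameter/2)``.  Raises
    :class:`FitError` when the effectively weighted samples cannot resolve
    the four polynomials (rank-deficient design).
    """
    rho = np.abs(opd_map.radii) / (opd_map.zone_diameter / 2.0)
    design = np.column_stack([radial_polynomial(n, rho) for n in _RADIAL_ORDERS])
    sw = np.sqrt(opd_map.weights)
    a = design * sw[:, None]
    b = opd_map.opd * sw
    sol, _, rank, _ = np.linalg.lstsq(a, b, rcond=None)
    if rank < len(_RADIAL_ORDERS):
        raise FitError("too few distinct radii to fit radial Zernike terms")
    resid = opd_map.opd - design @ sol
    wsum = opd_map.weights.sum()
    rms = float(np.sqrt(np.sum(opd_map.weights * resid**2) / wsum))
    return ZernikeResult(*(float(c) for c in sol), residual_rms=rms)
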