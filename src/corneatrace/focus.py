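"""Best-focus search and corneal power.

Four merit functions locate the best focal plane of the traced bundle:

* ``WF``  — RMS wavefront error (total optical path length from the z=0
  plane to the candidate focus point, piston removed), reported in um;
* ``RMS`` — RMS transverse ray scatter at the plane (mm);
* ``MA``  — mean absolute transverse ray scatter (mm);
* ``TSD`` — total spot diameter, max minus min ray height (mm).

The three spot criteria are properties of the pupil-limited bundle.  The
wavefront criterion is instead evaluated over the fixed central 6-mm
corneal zone — the same zone the spherical-aberration coefficient refers
to — so the best-wavefront plane does not depend on pupil size.  This
convention reproduces the published plane ordering
``z_WF < z_TSD < z_RMS < z_MA`` for SA-positive corneas; a pupil-limited
wavefront criterion would place the balanced-defocus plane at half the
pupil's longitudinal aberration, *behind* all three spot planes.  Pass
``wf_zone_diameter=None`` to evaluate the wavefront merit over the pupil
fan itself instead.

The focal distance ``z_F`` (mm from the corneal front apex) converts to the
corneal power referenced to the front apex plane via the aqueous vergence

    CP = 1000 * n_aqueous / z_F   [dpt]

and to a per-eye keratometer index via ``n_K = 1 + CP * R_f / 1000``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import numpy as np
from scipy import optimize

from .errors import InvalidPlaneError, NoFocusError
from .raytrace import TracedFan, build_fan, trace_eye

__all__ = [
    "CRITERIA",
    "WF_ZONE_DIAMETER",
    "MetricSet",
    "FocusResult",
    "transverse_heights",
    "focus_metric",
    "metrics_at",
    "initial_focus_guess",
    "best_focus",
    "best_focus_all",
    "power_from_focus",
    "focus_from_power",
    "keratometric_power",
    "keratometer_index",
]

#: the four best-focus criteria, in the conventional reporting order
CRITERIA = ("WF", "RMS", "MA", "TSD")

N_AQUEOUS_DEFAULT = 1.336


@dataclass(frozen=True)
class MetricSet:
    """All four merit-function values evaluated at one plane."""

    WFE: float  # um
    RMSS: float  # mm
    MAS: float  # mm
    TSD: float  # mm


@dataclass(frozen=True)
class FocusResult:
    """Best-focus planes, powers and per-eye keratometer indices.

    Every dictionary is keyed by criterion label (``WF``, ``RMS``, ``MA``,
    ``TSD``).  ``CP[c] * z_F[c] == 1000 * n_aqueous`` holds by construction.
    """

    z_F: Dict[str, float]  # mm from front apex
    CP: Dict[str, float]  # dpt
    n_K: Dict[str, float]
    metrics_at: Dict[str, MetricSet]


def transverse_heights(traced: TracedFan, z):
    """Ray heights y(z) at axial plane(s) ``z`` (mm from the front apex).

    ``z`` may be a scalar or an array; the result has shape
    ``z.shape + (n_rays,)``.
    """
    z = np.asarray(z, dtype=float)
    y_e = traced.exit_points[:, 0]
    z_e = traced.exit_points[:, 1]
    slope = traced.directions[:, 0] / traced.directions[:, 1]
    return y_e + (z[..., None] - z_e) * slope


def _check_plane(traced: TracedFan, z) -> None:
    if np.any(np.asarray(z) <= traced.exit_points[:, 1].max()):
        raise InvalidPlaneError("candidate plane lies inside or before the cornea")


def focus_metric(traced: TracedFan, z, criterion: str):
    """Evaluate one merit function at plane(s) ``z``.

    Spot metrics use the fan's area weights; the wavefront metric measures
    the weighted RMS spread of the total optical path length from the z=0
    starting plane to the point ``(0, z)`` (exit segment taken in the
    aqueous), after removing the weighted mean (piston).
    """
    _check_plane(traced, z)
    z = np.asarray(z, dtype=float)
    w = traced.weights
    if criterion == "WF":
        y_e = traced.exit_points[:, 0]
        z_e = traced.exit_points[:, 1]
        dist = np.sqrt(y_e**2 + (z[..., None] - z_e) ** 2)
        opl = traced.opl + traced.cornea.constants.n_aqueous * dist
        piston = np.sum(w * opl, axis=-1, keepdims=True)
        val = 1000.0 * np.sqrt(np.sum(w * (opl - piston) ** 2, axis=-1))
    else:
        y = transverse_heights(traced, z)
        if criterion == "RMS":
            val = np.sqrt(np.sum(w * y**2, axis=-1))
        elif criterion == "MA":
            val = np.sum(w * np.abs(y), axis=-1)
        elif criterion == "TSD":
            val = y.max(axis=-1) - y.min(axis=-1)
        else:
            raise ValueError(f"unknown criterion {criterion!r}")
    return float(val) if val.ndim == 0 else val


def metrics_at(traced: TracedFan, z: float) -> MetricSet:
    """All four merit values at one plane."""
    return MetricSet(
        WFE=focus_metric(traced, z, "WF"),
        RMSS=focus_metric(traced, z, "RMS"),
        MAS=focus_metric(traced, z, "MA"),
        TSD=focus_metric(traced, z, "TSD"),
    )


_MAX_RADIUS_MM = 1e5  # beyond this the exit bundle counts as collimated


def initial_focus_guess(traced: TracedFan) -> float:
    """Preset focus from the curvature of the exit wavefront.

    Points of equal optical path length along the exit rays form the exit
    wavefront; a least-squares circle (Kasa algebraic fit) through them has
    its centre at the focus.  Exact for a stigmatic bundle.

    Raises :class:`NoFocusError` when the bundle is (nearly) afocal.
    """
    if traced.n_rays < 3:
        raise NoFocusError("need at least 3 rays to estimate wavefront curvature")
    n_aq = traced.cornea.constants.n_aqueous
    l_ref = traced.opl.max()
    pts = traced.exit_points + traced.directions * ((l_ref - traced.opl) / n_aq)[:, None]
    y, z = pts[:, 0], pts[:, 1]
    a = np.column_stack([2.0 * y, 2.0 * z, np.ones_like(y)])
    b = y**2 + z**2
    sol, _, rank, _ = np.linalg.lstsq(a, b, rcond=None)
    if rank < 3:
        raise NoFocusError("exit wavefront has no measurable curvature")
    yc, zc, c = sol
    radius = np.sqrt(max(c + yc**2 + zc**2, 0.0))
    if radius > _MAX_RADIUS_MM:
        raise NoFocusError("exit bundle is nearly collimated")
    return float(zc)


WF_ZONE_DIAMETER = 6.0  # mm; fixed corneal zone for the wavefront criterion


def _zone_traced(traced: TracedFan, zone_diameter: float) -> TracedFan:
    """Trace a fresh fan spanning the fixed wavefront zone of the same eye."""
    if abs(traced.heights.max() - traced.heights.min() - zone_diameter) < 1e-12:
        return traced
    fan = build_fan(zone_diameter, n_rays=traced.n_rays, weighting=traced.weighting)
    return trace_eye(traced.cornea, fan)


def best_focus(
    traced: TracedFan,
    criterion: str,
    method: str = "brent",
    seed: int | None = None,
    bracket_halfwidth: float = 2.0,
    wf_zone_diameter: float | None = WF_ZONE_DIAMETER,
) -> float:
    """Axial position of the plane minimising one merit function.

    The search starts from :func:`initial_focus_guess` and is confined to a
    ±``bracket_halfwidth`` mm bracket.  ``method='brent'`` (default) uses
    deterministic bounded 1-D minimisation; for the piecewise-smooth TSD
    criterion a dense scan picks the winning interval first.
    ``method='anneal'`` runs seeded simulated annealing over the same
    bracket and agrees with the deterministic optimum on smooth criteria.

    For ``criterion='WF'`` the merit is evaluated on a fan spanning the
    fixed central zone (``wf_zone_diameter``, default 6 mm) traced through
    the same cornea; set it to ``None`` to minimise the wavefront error of
    the pupil fan itself.
    """
    if criterion == "WF" and wf_zone_diameter is not None:
        traced = _zone_traced(traced, wf_zone_diameter)
    guess = initial_focus_guess(traced)
    lo = max(guess - bracket_halfwidth, traced.exit_points[:, 1].max() + 1e-6)
    hi = guess + bracket_halfwidth

    def f(z: float) -> float:
        return focus_metric(traced, z, criterion)

    if method == "anneal":
        res = optimize.dual_annealing(
            lambda x: f(float(x[0])), bounds=[(lo, hi)], seed=seed, maxiter=250
        )
        return float(res.x[0])
    if method != "brent":
        raise ValueError(f"unknown method {method!r}")

    if criterion == "TSD":
        zs = np.linspace(lo, hi, 1000)
        vals = focus_metric(traced, zs, "TSD")
        k = int(np.argmin(vals))
        lo, hi = zs[max(k - 1, 0)], zs[min(k + 1, zs.size - 1)]
    res = optimize.minimize_scalar(
        f, bounds=(lo, hi), method="bounded", options={"xatol": 1e-9}
    )
    if not res.success:
        raise NoFocusError(f"bounded minimisation failed for {criterion}")
    return float(res.x)


def best_focus_all(
    traced: TracedFan,
    method: str = "brent",
    seed: int | None = None,
    wf_zone_diameter: float | None = WF_ZONE_DIAMETER,
) -> FocusResult:
    """Run all four best-focus searches and derive powers and indices.

    In each plane's :class:`MetricSet` the spot values come from the pupil
    fan and the wavefront error from the fixed-zone fan (when
    ``wf_zone_diameter`` is set), mirroring the per-criterion searches.
    """
    n_aq = traced.cornea.constants.n_aqueous
    r_f = traced.cornea.front.R
    wf_traced = (
        traced if wf_zone_diameter is None else _zone_traced(traced, wf_zone_diameter)
    )
    z_f: Dict[str, float] = {}
    cp: Dict[str, float] = {}
    nk: Dict[str, float] = {}
    mets: Dict[str, MetricSet] = {}
    for c in CRITERIA:
        src = wf_traced if c == "WF" else traced
        z = best_focus(src, c, method=method, seed=seed, wf_zone_diameter=None)
        z_f[c] = z
        cp[c] = power_from_focus(z, n_aqueous=n_aq)
        nk[c] = keratometer_index(cp[c], r_f)
        mets[c] = MetricSet(
            WFE=focus_metric(wf_traced, z, "WF"),
            RMSS=focus_metric(traced, z, "RMS"),
            MAS=focus_metric(traced, z, "MA"),
            TSD=focus_metric(traced, z, "TSD"),
        )
    return FocusResult(z_F=z_f, CP=cp, n_K=nk, metrics_at=mets)


def power_from_focus(z_F: float, n_aqueous: float = N_AQUEOUS_DEFAULT) -> float:
    """Corneal power (dpt) referenced to the front apex: 1000 n_aq / z_F."""
    if z_F <= 0:
        raise ValueError("focal distance must be positive (mm)")
    return 1000.0 * n_aqueous / z_F


def focus_from_power(CP: float, n_aqueous: float = N_AQUEOUS_DEFAULT) -> float:
    """Inverse of :func:`power_from_focus` (exact round trip)."""
    if CP <= 0:
        raise ValueError("power must be positive (dpt)")
    return 1000.0 * n_aqueous / CP


def keratometric_power(R_f: float, n_K: float) -> float:
    """Keratometric power (n_K - 1)/R_f in dpt, R_f in mm."""
    if np.any(np.asarray(R_f) <= 0):
        raise ValueError("front radius must be positive (mm)")
    return 1000.0 * (n_K - 1.0) / R_f


def keratometer_index(CP: float, R_f: float) -> float:
    """Per-eye keratometer index reproducing power CP from radius R_f."""
    return 1.0 + CP * R_f / 1000.0
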