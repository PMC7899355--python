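"""Synthetic biometry populations, CSV ingest and batch analysis.

The study cohort itself is not redistributable, but its marginal
statistics are: each covariate is summarised by mean, SD, minimum and
maximum.  :func:`sample_population` draws truncated (multivariate) normal
samples with exactly those marginals — the default correlation matrix is
the identity because only marginals are published; a literature-style
correlation structure can be supplied but is never treated as ground
truth.

CSV ingest follows the anterior-segment OCT export dialect: one row per
eye, CCT in um, radii in mm, asphericity either directly (Q columns) or as
eccentricity (converted via Q = -e^2).  Internally CCT is always mm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import models as _models
from .errors import CorneaTraceError, FormatError, SamplingError
from .focus import CRITERIA, best_focus_all, keratometric_power
from .geometry import eccentricity_to_asphericity
from .raytrace import CorneaModel, build_fan, trace_eye
from .zernike import fit_radial_zernikes, opd_at_apex_plane

__all__ = [
    "COHORT_MARGINALS",
    "PopulationSpec",
    "sample_population",
    "read_casia_csv",
    "write_casia_csv",
    "analyze_batch",
    "summarize",
    "BatchResult",
]

log = logging.getLogger(__name__)

#: published marginal statistics of the 10,218-eye cataract cohort
#: (CCT in um as exported; converted to mm on sampling/ingest)
COHORT_MARGINALS: Dict[str, Dict[str, float]] = {
    "R_f": {"mean": 7.733, "sd": 0.283, "min": 6.770, "max": 8.800},
    "Q_f": {"mean": -0.3141, "sd": 0.249, "min": -1.486, "max": 0.584},
    "R_b": {"mean": 6.534, "sd": 0.274, "min": 5.500, "max": 7.500},
    "Q_b": {"mean": -0.007, "sd": 0.213, "min": -0.988, "max": 0.602},
    "CCT_um": {"mean": 547.0, "sd": 37.0, "min": 395.0, "max": 794.0},
    "PUP": {"mean": 4.408, "sd": 0.789, "min": 1.528, "max": 6.800},
}

_VARS = tuple(COHORT_MARGINALS)


@dataclass(frozen=True)
class PopulationSpec:
    """Marginal statistics + optional correlation for a synthetic cohort.

    Defaults reproduce the published cohort marginals; ``corr`` is a 6x6
    correlation matrix over (R_f, Q_f, R_b, Q_b, CCT, PUP), identity by
    default.
    """

    n: int
    seed: Optional[int] = None
    marginals: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in COHORT_MARGINALS.items()}
    )
    corr: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        for name, m in self.marginals.items():
            if m["sd"] <= 0:
                raise ValueError(f"{name}: SD must be positive")
            if not (m["min"] < m["mean"] < m["max"]):
                raise ValueError(f"{name}: require min < mean < max")
        if self.corr is not None:
            c = np.asarray(self.corr, dtype=float)
            if c.shape != (6, 6) or not np.allclose(c, c.T):
                raise ValueError("correlation matrix must be symmetric 6x6")
            if np.linalg.eigvalsh(c).min() <= 0:
                raise ValueError("correlation matrix must be positive definite")


def sample_population(spec: PopulationSpec) -> pd.DataFrame:
    """Draw a truncated-normal synthetic population.

    Rejection sampling against the per-variable min/max bounds keeps the
    draws inside the published ranges; correlated draws use a multivariate
    normal with covariance ``D corr D``.  Deterministic for a fixed seed.

    Returns a DataFrame with columns eye_id, R_f, Q_f, R_b, Q_b, CCT (mm),
    PUP.

    Raises :class:`SamplingError` if the truncation accepts < 1% of draws.
    """
    rng = np.random.default_rng(spec.seed)
    mu = np.array([spec.marginals[v]["mean"] for v in _VARS])
    sd = np.array([spec.marginals[v]["sd"] for v in _VARS])
    lo = np.array([spec.marginals[v]["min"] for v in _VARS])
    hi = np.array([spec.marginals[v]["max"] for v in _VARS])
    corr = np.eye(6) if spec.corr is None else np.asarray(spec.corr, dtype=float)
    cov = corr * np.outer(sd, sd)

    rows = []
    drawn = kept = 0
    while kept < spec.n:
        batch = max(spec.n - kept, 1000)
        x = rng.multivariate_normal(mu, cov, size=batch)
        ok = np.all((x >= lo) & (x <= hi), axis=1)
        drawn += batch
        kept += int(ok.sum())
        rows.append(x[ok])
        if drawn >= 10000 and kept / drawn < 0.01:
            raise SamplingError(
                f"truncation acceptance {kept / drawn:.2%} < 1%; bounds too tight"
            )
    x = np.concatenate(rows)[: spec.n]
    df = pd.DataFrame(x, columns=list(_VARS))
    df.insert(0, "eye_id", [f"syn{k:05d}" for k in range(spec.n)])
    df["CCT"] = df.pop("CCT_um") / 1000.0  # store mm internally
    return df[["eye_id", "R_f", "Q_f", "R_b", "Q_b", "CCT", "PUP"]]


#: default header map: internal name -> acceptable CSV column names
_DEFAULT_HEADER_MAP: Dict[str, tuple] = {
    "eye_id": ("eye_id", "id", "ID"),
    "R_f": ("Rf_mm", "R_f", "Rf"),
    "Q_f": ("Qf", "Q_f"),
    "ecc_f": ("ecc_f", "Ef", "e_f"),
    "R_b": ("Rb_mm", "R_b", "Rb"),
    "Q_b": ("Qb", "Q_b"),
    "ecc_b": ("ecc_b", "Eb", "e_b"),
    "CCT_um": ("CCT_um", "CCT", "Pachy_um"),
    "PUP": ("PUP_mm", "PUP", "Pupil_mm"),
}


def _resolve(columns, names) -> Optional[str]:
    for n in names:
        if n in columns:
            return n
    return None


def read_casia_csv(
    path,
    header_map: Optional[Dict[str, tuple]] = None,
    delimiter: str = ",",
    decimal: str = ".",
) -> pd.DataFrame:
    """Read an OCT biometry CSV export into the internal eye table.

    Accepts either asphericity (Q) or eccentricity (e) columns for each
    surface — eccentricities are converted via ``Q = -e^2``.  CCT is read
    in um and stored in mm.  Negative radius magnitudes (a sign convention
    occasionally seen in exports) are normalised to positive with a logged
    warning.  Rows with missing required values are dropped; the count is
    logged and stored in ``df.attrs['n_dropped']``.
    """
    hmap = dict(_DEFAULT_HEADER_MAP)
    if header_map:
        hmap.update(header_map)
    try:
        raw = pd.read_csv(path, sep=delimiter, decimal=decimal)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty CSV file: {path}") from exc
    if raw.empty:
        raise FormatError(f"CSV has no data rows: {path}")

    out = pd.DataFrame()
    idcol = _resolve(raw.columns, hmap["eye_id"])
    out["eye_id"] = raw[idcol].astype(str) if idcol else [str(k) for k in range(len(raw))]

    for qname, ename, surf in (("Q_f", "ecc_f", "front"), ("Q_b", "ecc_b", "back")):
        qcol = _resolve(raw.columns, hmap[qname])
        ecol = _resolve(raw.columns, hmap[ename])
        if qcol is not None:
            out[qname] = pd.to_numeric(raw[qcol], errors="coerce")
        elif ecol is not None:
            e = pd.to_numeric(raw[ecol], errors="coerce")
            out[qname] = eccentricity_to_asphericity(e.abs().to_numpy())
        else:
            raise FormatError(f"no asphericity or eccentricity column for {surf} surface")

    for name, scale in (("R_f", 1.0), ("R_b", 1.0), ("CCT_um", 1e-3), ("PUP", 1.0)):
        col = _resolve(raw.columns, hmap[name])
        if col is None:
            raise FormatError(f"required column {name} not found")
        vals = pd.to_numeric(raw[col], errors="coerce") * scale
        out["CCT" if name == "CCT_um" else name] = vals

    for rcol in ("R_f", "R_b"):
        neg = out[rcol] < 0
        if neg.any():
            log.warning(
                "%d negative %s values: treating magnitudes as radii", int(neg.sum()), rcol
            )
            out[rcol] = out[rcol].abs()

    required = ["R_f", "Q_f", "R_b", "Q_b", "CCT", "PUP"]
    complete = out[required].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        log.info("dropped %d incomplete rows", n_dropped)
    out = out[complete].reset_index(drop=True)
    out.attrs["n_dropped"] = n_dropped
    return out


def write_casia_csv(eyes: pd.DataFrame, path) -> None:
    """Write an internal eye table back to the CSV dialect (CCT in um)."""
    df = eyes.copy()
    df["CCT_um"] = df.pop("CCT") * 1000.0
    df = df.rename(columns={"R_f": "Rf_mm", "R_b": "Rb_mm", "PUP": "PUP_mm"})
    df.to_csv(path, index=False)


_QUANTS = (0.005, 0.05, 0.95, 0.995)


def summarize(values: pd.DataFrame) -> pd.DataFrame:
    """Descriptive statistics table: mean, SD, median, min/max, quantiles.

    Quantiles at 0.5/5/95/99.5% (90% and 99% intervals) use linear
    interpolation between order statistics.
    """
    num = values.select_dtypes(include=[np.number])
    rows = {
        "Mean": num.mean(),
        "SD": num.std(ddof=1),
        "Median": num.median(),
        "Minimum": num.min(),
        "Maximum": num.max(),
    }
    for q in _QUANTS:
        rows[f"Quantile {100 * q:g}%"] = num.quantile(q)
    return pd.DataFrame(rows).T


@dataclass
class BatchResult:
    """Everything the batch pipeline produces for one population."""

    per_eye: pd.DataFrame  # one row per eye, all four criteria
    failures: pd.DataFrame  # eye_id + reason code
    summaries: Dict[str, pd.DataFrame]  # descriptive tables
    keratometer_indices: Dict[str, float]  # population n_K per criterion
    model_fits: Dict[str, _models.PowerModelFit]  # refit power models


def analyze_batch(
    eyes: pd.DataFrame,
    n_rays: int = 1001,
    weighting: str = "area_linear",
    method: str = "brent",
    seed: Optional[int] = None,
    nk_mode: str = "least_squares",
    fit_models: bool = True,
) -> BatchResult:
    """Run the full pipeline over a population of eyes.

    Per eye: trace the pupil fan, locate all four best-focus planes,
    convert to corneal powers and per-eye keratometer indices, and fit the
    6-mm-zone Z40.  Population level: fit one keratometer index per
    criterion (``nk_mode``: ``least_squares`` or ``mean_zero``) and refit
    the multivariate power model; the deviation columns ``dCP_<c>`` hold
    ``CP - keratometric power`` under that population index.

    Eyes whose trace or focus search fails are excluded from summaries and
    listed in ``failures`` with a machine-readable reason code.
    """
    if len(eyes) == 0:
        raise ValueError("empty eye list")
    records, fails = [], []
    for row in eyes.itertuples(index=False):
        try:
            cornea = CorneaModel.from_biometry(row.R_f, row.Q_f, row.R_b, row.Q_b, row.CCT)
            traced = trace_eye(cornea, build_fan(row.PUP, n_rays=n_rays, weighting=weighting))
            fres = best_focus_all(traced, method=method, seed=seed)
            zres = fit_radial_zernikes(
                opd_at_apex_plane(cornea, fres.z_F["WF"], weighting=weighting)
            )
        except CorneaTraceError as exc:
            fails.append({"eye_id": row.eye_id, "reason": exc.reason, "detail": str(exc)})
            continue
        rec = {"eye_id": row.eye_id, **{v: getattr(row, v) for v in ("R_f", "Q_f", "R_b", "Q_b", "CCT", "PUP")}}
        for c in CRITERIA:
            rec[f"zF_{c}"] = fres.z_F[c]
            rec[f"CP_{c}"] = fres.CP[c]
            rec[f"nK_{c}"] = fres.n_K[c]
            m = fres.metrics_at[c]
            rec[f"WFE_{c}"] = m.WFE
            rec[f"RMSS_{c}"] = m.RMSS
            rec[f"MAS_{c}"] = m.MAS
            rec[f"TSD_{c}"] = m.TSD
        rec["Z40"] = zres.Z40
        records.append(rec)

    if not records:
        raise CorneaTraceError("all eyes failed; nothing to summarise")
    per_eye = pd.DataFrame(records)
    failures = pd.DataFrame(fails, columns=["eye_id", "reason", "detail"])

    nk: Dict[str, float] = {}
    fits: Dict[str, _models.PowerModelFit] = {}
    for c in CRITERIA:
        nk[c] = _models.fit_keratometer_index(per_eye[f"CP_{c}"], per_eye["R_f"], mode=nk_mode)
        per_eye[f"dCP_{c}"] = per_eye[f"CP_{c}"] - keratometric_power(
            per_eye["R_f"].to_numpy(), nk[c]
        )
        if fit_models and len(per_eye) >= 8:
            fits[c] = _models.fit_power_model(
                per_eye, per_eye[f"CP_{c}"], n_K=nk[c], criterion=c
            )

    summaries = {
        "inputs": summarize(per_eye[["R_f", "Q_f", "R_b", "Q_b", "CCT", "PUP"]]),
        "focus": summarize(per_eye[[f"zF_{c}" for c in CRITERIA] + [f"CP_{c}" for c in CRITERIA]]),
        "sa_index": summarize(per_eye[["Z40"] + [f"nK_{c}" for c in CRITERIA]]),
        "deviation": summarize(per_eye[[f"dCP_{c}" for c in CRITERIA]]),
    }
    return BatchResult(per_eye, failures, summaries, nk, fits)
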