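"""Keratometer-index fitting and multivariate corneal-power models.

A corneal-power model predicts the raytraced power CP (dpt) from six
biometric covariates as a keratometric term plus linear corrections:

    CP = 1000 (n_K - 1)/R_f + b0 + bRf R_f + bQf Q_f + bRb R_b
         + bQb Q_b + bCCT CCT + bPUP PUP

with R_f, R_b, CCT and PUP in mm and the asphericities dimensionless.
``PRINTED_MODELS`` holds the four published coefficient sets (one per
best-focus criterion), stored verbatim to all printed digits;
:func:`fit_power_model` refits the same structure to any population by
ordinary least squares on the residual ``CP - keratometric offset``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import FitError
from .focus import keratometric_power

__all__ = [
    "ModelCoefficients",
    "PowerModelFit",
    "PRINTED_MODELS",
    "COVARIATES",
    "evaluate_model",
    "evaluate_printed_model",
    "fit_keratometer_index",
    "fit_power_model",
    "save_coefficients",
    "load_coefficients",
]

#: covariate order used throughout (units: mm, -, mm, -, mm, mm)
COVARIATES = ("R_f", "Q_f", "R_b", "Q_b", "CCT", "PUP")


@dataclass(frozen=True)
class ModelCoefficients:
    """Keratometer index plus intercept and six linear effects (dpt-scale)."""

    n_K: float
    b0: float
    bRf: float
    bQf: float
    bRb: float
    bQb: float
    bCCT: float
    bPUP: float
    criterion: str = ""

    def as_dict(self) -> Dict[str, float]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Dict) -> "ModelCoefficients":
        return cls(**d)


@dataclass(frozen=True)
class PowerModelFit:
    """Fitted coefficients plus goodness-of-fit on the offset residual."""

    coefficients: ModelCoefficients
    rms_error: float  # dpt
    r_squared: float
    n_eyes: int


#: published coefficient sets, one per best-focus criterion
PRINTED_MODELS: Dict[int, ModelCoefficients] = {
    1: ModelCoefficients(1.3317, 0.86129, -0.90224, 1.7446, 0.97129, -0.33023, 0.29098, 0.062371, "WF"),
    2: ModelCoefficients(1.3309, 0.40217, -0.84386, 0.81261, 0.93662, -0.15142, 0.32146, 0.029592, "RMS"),
    3: ModelCoefficients(1.3308, 0.33451, -0.83496, 0.67492, 0.93097, -0.12361, 0.32598, 0.02504, "MA"),
    4: ModelCoefficients(1.3311, 0.50409, -0.85727, 1.0176, 0.94506, -0.19287, 0.31454, 0.036352, "TSD"),
}


def _covariate_frame(eyes) -> pd.DataFrame:
    if isinstance(eyes, pd.DataFrame):
        return eyes
    arr = np.atleast_2d(np.asarray(eyes, dtype=float))
    return pd.DataFrame(arr, columns=list(COVARIATES))


def evaluate_model(coeffs: ModelCoefficients, eyes):
    """Predicted corneal power (dpt) for one eye or a covariate table.

    ``eyes`` is either a 6-tuple/array ``(R_f, Q_f, R_b, Q_b, CCT, PUP)``
    (mm units, CCT in mm) or a DataFrame with those columns.
    """
    df = _covariate_frame(eyes)
    effects = np.array(
        [coeffs.bRf, coeffs.bQf, coeffs.bRb, coeffs.bQb, coeffs.bCCT, coeffs.bPUP]
    )
    offset = keratometric_power(df["R_f"].to_numpy(), coeffs.n_K)
    pred = offset + coeffs.b0 + df[list(COVARIATES)].to_numpy() @ effects
    return float(pred[0]) if pred.size == 1 else pred


def evaluate_printed_model(model_id: int, eye):
    """Evaluate one of the four published models (1=WF, 2=RMS, 3=MA, 4=TSD)."""
    if model_id not in PRINTED_MODELS:
        raise ValueError(f"model_id must be 1..4, got {model_id!r}")
    return evaluate_model(PRINTED_MODELS[model_id], eye)


def fit_keratometer_index(
    CP: Sequence[float], R_f: Sequence[float], mode: str = "least_squares"
) -> float:
    """Population keratometer index from raytraced powers and front radii.

    ``least_squares`` minimises ``sum (CP_i - 1000 (n_K - 1)/R_f,i)^2`` in
    closed form; ``mean_zero`` instead zeroes the mean deviation
    ``mean(CP - P_K) = 0``.  For a single eye (or identical eyes) both
    modes invert the keratometric formula exactly.
    """
    cp = np.asarray(CP, dtype=float)
    rf = np.asarray(R_f, dtype=float)
    if cp.size == 0 or cp.shape != rf.shape:
        raise ValueError("CP and R_f must be nonempty and equally sized")
    if np.any(rf <= 0):
        raise ValueError("front radii must be positive")
    x = 1000.0 / rf
    if mode == "least_squares":
        return float(1.0 + np.sum(x * cp) / np.sum(x * x))
    if mode == "mean_zero":
        return float(1.0 + np.mean(cp) / np.mean(x))
    raise ValueError(f"unknown mode {mode!r}")


def fit_power_model(
    eyes, CP: Sequence[float], n_K: float, criterion: str = ""
) -> PowerModelFit:
    """OLS fit of the corneal-power model with a fixed keratometric offset.

    The dependent variable is the deviation of raytraced power from
    keratometric power, ``y = CP - 1000 (n_K - 1)/R_f``; the design holds
    an intercept plus the six covariates.  ``rms_error`` and ``r_squared``
    describe that residual regression.
    """
    df = _covariate_frame(eyes)
    cp = np.asarray(CP, dtype=float)
    if len(df) < 8:
        raise FitError("need at least 8 eyes for a 7-parameter fit")
    y = cp - keratometric_power(df["R_f"].to_numpy(), n_K)
    x = sm.add_constant(df[list(COVARIATES)].to_numpy())
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise FitError("rank-deficient covariate design")
    res = sm.OLS(y, x).fit()
    b0, bRf, bQf, bRb, bQb, bCCT, bPUP = res.params
    coeffs = ModelCoefficients(n_K, b0, bRf, bQf, bRb, bQb, bCCT, bPUP, criterion)
    rms = float(np.sqrt(np.mean(res.resid**2)))
    return PowerModelFit(coeffs, rms_error=rms, r_squared=float(res.rsquared), n_eyes=len(df))


def save_coefficients(coeffs: ModelCoefficients, path) -> None:
    """Write coefficients to a flat JSON/YAML key-value file (by suffix)."""
    path = Path(path)
    data = coeffs.as_dict()
    if path.suffix in (".yml", ".yaml"):
        import yaml

        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2))


def load_coefficients(path) -> ModelCoefficients:
    path = Path(path)
    if path.suffix in (".yml", ".yaml"):
        import yaml

        data = yaml.safe_load(path.read_text())
    else:
        data = json.loads(path.read_text())
    return ModelCoefficients.from_dict(data)
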