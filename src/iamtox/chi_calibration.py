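"""CHI_IAM calibration of gradient retention times.

On a fast acetonitrile gradient the retention time of a compound on an IAM
(phosphatidylcholine) column is converted to the Chromatographic
Hydrophobicity Index by calibrating against standards (acetophenone
homologues) whose CHI_IAM values were established isocratically. A linear map
``CHI = slope * t_r + intercept`` is assumed — the functional form used
throughout the CHI literature.

CHI_IAM approximates the % acetonitrile at elution; values above 45 indicate
strong phospholipid binding, below 20 weak binding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateDesignError, InsufficientDataError

__all__ = [
    "CalibrationStandard",
    "CalibrationCurve",
    "fit_chi_calibration",
    "retention_to_chi",
    "binding_class",
    "STRONG_BINDING_CHI",
    "WEAK_BINDING_CHI",
]

#: CHI_IAM above this value indicates strong phospholipid binding.
STRONG_BINDING_CHI = 45.0
#: CHI_IAM below this value indicates weak phospholipid binding.
WEAK_BINDING_CHI = 20.0


@dataclass(frozen=True)
class CalibrationStandard:
    """One calibration standard: gradient retention time and reference CHI."""

    name: str
    t_r: float  # minutes
    chi_ref: float

    def __post_init__(self) -> None:
        if not (self.t_r > 0):
            raise ValueError(f"{self.name}: t_r must be > 0")
        if not math.isfinite(self.chi_ref):
            raise ValueError(f"{self.name}: chi_ref must be finite")


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear t_r → CHI map with its standard error over the standards.

    ``se_chi`` is the root-mean-square deviation between calibrated and
    reference CHI over the standards (reported runs range 0.1–0.8 CHI units).
    """

    slope: float  # CHI per minute
    intercept: float  # CHI at t_r = 0
    se_chi: float
    n_standards: int

    def __post_init__(self) -> None:
        if self.n_standards < 2:
            raise InsufficientDataError("calibration needs >= 2 standards")
        if self.se_chi < 0:
            raise ValueError("se_chi must be >= 0")


def fit_chi_calibration(standards: list[CalibrationStandard]) -> CalibrationCurve:
    """Ordinary least squares of reference CHI on gradient retention time."""
    if len(standards) < 2:
        raise InsufficientDataError(
            f"need at least 2 calibration standards, got {len(standards)}"
        )
    t_r = np.array([s.t_r for s in standards], dtype=float)
    chi = np.array([s.chi_ref for s in standards], dtype=float)
    if np.ptp(t_r) == 0.0:
        raise DegenerateDesignError("all standards have identical retention time")
    fit = stats.linregress(t_r, chi)
    predicted = fit.intercept + fit.slope * t_r
    se_chi = float(np.sqrt(np.mean((predicted - chi) ** 2)))
    return CalibrationCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        se_chi=se_chi,
        n_standards=len(standards),
    )


def retention_to_chi(curve: CalibrationCurve, t_r: float) -> float:
    """Calibrated CHI at retention time ``t_r`` (minutes).

    No clamping: values outside [0, 100] are returned as-is and the caller may
    warn (they signal extrapolation beyond the gradient).
    """
    if not (t_r > 0):
        raise ValueError(f"t_r must be > 0, got {t_r}")
    return curve.slope * t_r + curve.intercept


def binding_class(chi: float) -> str:
    """Classify phospholipid-binding strength from CHI_IAM.

    ``> 45`` → ``"strong"``; ``< 20`` → ``"weak"``; otherwise
    ``"intermediate"`` (boundary values are intermediate — the published
    thresholds are strict inequalities).
    """
    if not math.isfinite(chi):
        raise ValueError(f"chi must be finite, got {chi}")
    if chi > STRONG_BINDING_CHI:
        return "strong"
    if chi < WEAK_BINDING_CHI:
        return "weak"
    return "intermediate"
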