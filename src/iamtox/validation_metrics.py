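"""External-validation error metrics: residuals, RMSEP, RSEP %, bias.

For observed endpoint values y_i and predictions yhat_i over n test compounds:

    e_i   = y_i - yhat_i
    RMSEP = sqrt( sum e_i^2 / n )
    RSEP% = 100 * RMSEP / mean(y)
    bias  = mean( yhat_i - y_i )

The RSEP and bias conventions are pinned by consistency with the published
error tables (the daphnia CHI column reproduces 10.1 % under RMSEP/mean(y),
and the EPI bias cell reproduces +0.42 under mean(yhat − y)); alternative
textbook forms do not reproduce those cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import GroupingError, InsufficientDataError, PairingError, UndefinedMetricError

__all__ = [
    "ValidationReport",
    "residuals",
    "rmsep",
    "rsep_percent",
    "bias",
    "make_report",
    "compare_models",
]


def residuals(observed, predicted) -> np.ndarray:
    """Signed residuals e_i = y_i − yhat_i."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise PairingError(
            f"observed/predicted length mismatch: {observed.shape} vs {predicted.shape}"
        )
    return observed - predicted


def rmsep(e) -> float:
    """Root-mean-square error of prediction."""
    e = np.asarray(e, dtype=float)
    if e.size == 0:
        raise InsufficientDataError("rmsep needs at least one residual")
    return float(np.sqrt(np.mean(e**2)))


def rsep_percent(e, observed) -> float:
    """Relative standard error of prediction, % of the mean observed value."""
    observed = np.asarray(observed, dtype=float)
    mean_obs = float(np.mean(observed)) if observed.size else 0.0
    if mean_obs == 0.0:
        raise UndefinedMetricError("rsep undefined for zero-mean observed values")
    return 100.0 * rmsep(e) / mean_obs


def bias(observed, predicted) -> float:
    """Mean signed prediction error, mean(yhat − y)."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.size == 0:
        raise InsufficientDataError("bias needs at least one pair")
    if observed.shape != predicted.shape:
        raise PairingError("observed/predicted length mismatch")
    return float(np.mean(predicted - observed))


@dataclass(frozen=True)
class ValidationReport:
    """Residuals and summary errors for one (endpoint, prediction source)."""

    endpoint_id: str
    source: str
    pairs: tuple[tuple[str, float, float, float], ...]  # (name, y, yhat, e)
    rmsep: float
    rsep_percent: float
    bias: float
    n: int


def make_report(
    endpoint_id: str,
    source: str,
    names: list[str],
    observed,
    predicted,
) -> ValidationReport:
    """Assemble a full validation report for one prediction source."""
    e = residuals(observed, predicted)
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if len(names) != len(e):
        raise PairingError("names do not align with value pairs")
    return ValidationReport(
        endpoint_id=endpoint_id,
        source=source,
        pairs=tuple(
            (nm, float(y), float(yh), float(ei))
            for nm, y, yh, ei in zip(names, observed, predicted, e)
        ),
        rmsep=rmsep(e),
        rsep_percent=rsep_percent(e, observed),
        bias=bias(observed, predicted),
        n=len(e),
    )


def compare_models(reports: list[ValidationReport]) -> pd.DataFrame:
    """Side-by-side error table, one column per source, ranked by RMSEP.

    Rows are RMSEP, RSEP % and bias; columns are ordered by ascending RMSEP
    (ties keep input order), mirroring the published comparison tables.
    """
    if not reports:
        raise InsufficientDataError("need at least one report")
    endpoints = {r.endpoint_id for r in reports}
    if len(endpoints) > 1:
        raise GroupingError(f"mixed endpoints: {sorted(endpoints)}")
    ranked = sorted(enumerate(reports), key=lambda ir: (ir[1].rmsep, ir[0]))
    data = {
        r.source: {"rmsep": r.rmsep, "rsep_percent": r.rsep_percent, "bias": r.bias}
        for _, r in ranked
    }
    df = pd.DataFrame(data, index=["rmsep", "rsep_percent", "bias"])
    df.index.name = "metric"
    return df
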