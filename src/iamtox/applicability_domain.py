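"""Applicability-domain diagnostics (Williams plot).

A QSAR prediction is only trusted inside the descriptor region spanned by the
training set. Here that region is delimited by leverage: a query's hat value

    h = x' (X'X)^-1 x

over the intercept-augmented training design, with warning leverage
h* = 3k/n (k = number of model parameters plus one). Outliers among compounds
with experimental values are flagged by externally studentized residuals,

    r_i = e_i / (sigma_(-i) * sqrt(1 - h_i)),

where sigma_(-i) is the residual standard error of the fit with observation i
removed. A compound is in-domain iff h < h*, and an outlier iff |r| >= 3.

The training sets behind the published models are supplied as summaries
(n, k, descriptor mean, centered sum of squares), so real summaries can be
configured while tests use synthetic ones. Leverage for query compounds is
computed from the training design alone (queries do not augment the design).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateDesignError, InsufficientDataError

__all__ = [
    "TrainingSummary",
    "ADAssessment",
    "leverage_of",
    "warning_leverage",
    "studentized_residuals",
    "query_studentized_residual",
    "williams_classify",
    "summary_from_x",
]

OUTLIER_THRESHOLD = 3.0


@dataclass(frozen=True)
class TrainingSummary:
    """Sufficient statistics of a model's training design.

    For a single-descriptor model with intercept, ``k = p + 1 = 2`` and the
    leverage closed form is ``1/n + (x - x_mean)^2 / s_xx``. A full design
    matrix ``X`` (n rows, p columns, no intercept column) may be attached for
    multivariate use; when present it takes precedence.
    """

    n: int
    k: int
    x_mean: float
    s_xx: float
    X: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2 (parameters plus one)")
        if self.n <= self.k:
            raise InsufficientDataError(f"need n > k, got n={self.n}, k={self.k}")
        if not (self.s_xx > 0):
            raise DegenerateDesignError("s_xx must be > 0 (constant descriptor)")


def summary_from_x(x: np.ndarray, k: int = 2) -> TrainingSummary:
    """Build a summary from raw training descriptor values."""
    x = np.asarray(x, dtype=float)
    return TrainingSummary(
        n=len(x),
        k=k,
        x_mean=float(np.mean(x)),
        s_xx=float(np.sum((x - np.mean(x)) ** 2)),
        X=x.reshape(-1, 1),
    )


@dataclass(frozen=True)
class ADAssessment:
    """Williams-plot coordinates and verdict for one query compound."""

    compound: str
    h: float
    h_star: float
    r_student: float | None
    in_domain: bool
    outlier: bool


def leverage_of(summary: TrainingSummary, x_query: float | np.ndarray) -> float:
    """Leverage of a query point in the training design.

    Uses the matrix form ``x'(X'X)^-1 x`` on the intercept-augmented design
    when the summary carries ``X``; otherwise the single-descriptor closed
    form ``1/n + (x - x_mean)^2 / s_xx`` (both agree to machine precision).
    """
    if summary.X is not None:
        X = np.column_stack([np.ones(summary.X.shape[0]), summary.X])
        xq = np.atleast_1d(np.asarray(x_query, dtype=float)).ravel()
        v = np.concatenate([[1.0], xq])
        gram = X.T @ X
        try:
            sol = np.linalg.solve(gram, v)
        except np.linalg.LinAlgError as exc:
            raise DegenerateDesignError("singular training design") from exc
        return float(v @ sol)
    x = float(np.asarray(x_query, dtype=float))
    return 1.0 / summary.n + (x - summary.x_mean) ** 2 / summary.s_xx


def warning_leverage(summary: TrainingSummary) -> float:
    """Warning leverage h* = 3k/n."""
    return 3.0 * summary.k / summary.n


def studentized_residuals(
    x: np.ndarray, y: np.ndarray, method: str = "shortcut"
) -> np.ndarray:
    """Externally studentized residuals of a simple linear regression.

    ``method="refit"`` is the reference implementation: sigma_(-i) comes from
    an explicit OLS refit without observation i. ``method="shortcut"`` uses
    the algebraic identity
    ``sigma_(-i)^2 = ((n-2) s^2 - e_i^2 / (1-h_i)) / (n-3)``;
    both agree to ~1e-9 and the equivalence is exercised in the test suite.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4:
        raise InsufficientDataError("external studentization needs n >= 4")
    if np.ptp(x) == 0.0:
        raise DegenerateDesignError("constant descriptor")

    b1, b0 = np.polyfit(x, y, 1)
    e = y - (b0 + b1 * x)
    x_mean = x.mean()
    s_xx = np.sum((x - x_mean) ** 2)
    h = 1.0 / n + (x - x_mean) ** 2 / s_xx

    if method == "shortcut":
        sse = np.sum(e**2)
        sigma2_loo = (sse - e**2 / (1.0 - h)) / (n - 3)
        sigma_loo = np.sqrt(np.maximum(sigma2_loo, 0.0))
    elif method == "refit":
        sigma_loo = np.empty(n)
        for i in range(n):
            mask = np.arange(n) != i
            bi1, bi0 = np.polyfit(x[mask], y[mask], 1)
            ei = y[mask] - (bi0 + bi1 * x[mask])
            sigma_loo[i] = np.sqrt(np.sum(ei**2) / (n - 1 - 2))
    else:
        raise ValueError(f"unknown method {method!r}")

    with np.errstate(divide="ignore", invalid="ignore"):
        r = e / (sigma_loo * np.sqrt(1.0 - h))
    return np.where(e == 0.0, 0.0, r)


def query_studentized_residual(
    summary: TrainingSummary, s: float, x_query: float, residual: float
) -> float:
    """Studentized residual of an external query compound.

    For a compound outside the training set the prediction-error variance is
    ``s^2 (1 + h)``, so the residual is scaled as ``e / (s sqrt(1 + h))``
    with leverage from the training design. (Training points themselves use
    :func:`studentized_residuals`.)
    """
    return _query_studentized_residual(leverage_of(summary, x_query), s, residual)


def _query_studentized_residual(h: float, s: float, residual: float) -> float:
    if not (s > 0):
        raise ValueError("s must be > 0")
    return residual / (s * math.sqrt(1.0 + h))


def williams_classify(
    summary: TrainingSummary,
    names: list[str],
    x_values: np.ndarray,
    residuals: list[float | None] | None = None,
    s: float | None = None,
) -> list[ADAssessment]:
    """Classify query compounds against the model's applicability domain.

    Emits, per query, the (h, r) Williams-plot coordinates and the verdicts
    ``in_domain = (h < h*)`` (strict: h == h* is outside) and
    ``outlier = (|r| >= 3)`` when a residual is available. ``residuals`` are
    raw prediction errors ``y - yhat``; they are studentized with the
    training-fit standard error ``s`` when given, or taken as already
    studentized when ``s`` is None.
    """
    x_values = np.atleast_1d(np.asarray(x_values, dtype=float))
    if residuals is None:
        residuals = [None] * len(names)
    if not (len(names) == len(x_values) == len(residuals)):
        from .errors import PairingError

        raise PairingError("names, x_values and residuals must align")
    h_star = warning_leverage(summary)
    out = []
    for name, xq, e in zip(names, x_values, residuals):
        h = leverage_of(summary, xq)
        if e is None:
            r = None
        elif s is None:
            r = float(e)
        else:
            r = _query_studentized_residual(h, s, float(e))
        out.append(
            ADAssessment(
                compound=name,
                h=h,
                h_star=h_star,
                r_student=r,
                in_domain=h < h_star,
                outlier=(r is not None and abs(r) >= OUTLIER_THRESHOLD),
            )
        )
    return out
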