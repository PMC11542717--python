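"""Principal-component profiling of the compound property space.

The descriptor matrix (compounds × physicochemical descriptors) is autoscaled
— each column centered to mean 0 and scaled to unit variance, i.e. PCA on the
correlation structure — and decomposed. Constant columns (the cationic and
zwitterionic fractions are 0.00 for every UV filter) are dropped because
standardization is undefined for them, and reported.

Score-plot structure: the UV-filter panel splits into a highly lipophilic,
essentially non-ionizable cluster and a hydrophilic, anionic-at-pH-7.4
cluster. `score_groups` labels compounds by descriptor thresholds, resolving
borderline compounds with the looser charge/lipophilicity description of the
score plot (matching the published cluster membership; a strict-thresholds
mode is also available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .dataset_io import CompoundRecord
from .errors import DegenerateDesignError, PairingError

__all__ = [
    "PCAResult",
    "autoscale",
    "pca_decompose",
    "score_groups",
    "GROUP_LIPOPHILIC",
    "GROUP_ANIONIC",
    "UNGROUPED",
]

GROUP_LIPOPHILIC = "group_lipophilic"
GROUP_ANIONIC = "group_anionic"
UNGROUPED = "ungrouped"


@dataclass(frozen=True)
class PCAResult:
    """Scores, loadings and variance fractions of one decomposition."""

    scores: np.ndarray  # n_compounds x n_components
    loadings: np.ndarray  # n_variables x n_components
    explained_fraction: np.ndarray  # per component, sums to 1 over all PCs
    r2_cum: np.ndarray  # cumulative explained fraction
    variables_used: tuple[str, ...]


def autoscale(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Standardize columns to mean 0 / variance 1 (ddof=1).

    Returns (scaled matrix, retained columns, dropped zero-variance columns).
    """
    if len(matrix) < 2:
        raise DegenerateDesignError("autoscaling needs >= 2 rows")
    values = matrix.astype(float)
    std = values.std(axis=0, ddof=1)
    dropped = [c for c in values.columns if std[c] == 0.0]
    retained = [c for c in values.columns if std[c] > 0.0]
    if not retained:
        raise DegenerateDesignError("all columns are constant")
    scaled = (values[retained] - values[retained].mean(axis=0)) / std[retained]
    return scaled, retained, dropped


def pca_decompose(scaled: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """PCA of an already-scaled matrix.

    ``explained_fraction`` is taken over *all* components of the
    decomposition (eigenvalue ratios), so it sums to 1; ``scores`` and
    ``loadings`` are truncated to ``n_components``. Component signs are fixed
    so each loading column's largest-magnitude entry is positive, making
    score plots reproducible across runs and solvers.
    """
    X = np.asarray(scaled, dtype=float)
    n, p = X.shape
    max_rank = min(n - 1, p)
    if n_components is None:
        n_components = max_rank
    if not (1 <= n_components <= max_rank):
        raise ValueError(f"n_components must be in [1, {max_rank}]")

    pca = PCA(n_components=max_rank, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # p x r, unit-norm columns
    eigvals = pca.explained_variance_
    explained = eigvals / eigvals.sum()

    # deterministic sign convention
    for j in range(loadings.shape[1]):
        i_max = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i_max, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0

    return PCAResult(
        scores=scores[:, :n_components],
        loadings=loadings[:, :n_components],
        explained_fraction=explained,
        r2_cum=np.cumsum(explained),
        variables_used=tuple(scaled.columns),
    )


def score_groups(
    result: PCAResult | None,
    records: list[CompoundRecord],
    borderline: str = "relaxed",
) -> list[str]:
    """Label compounds as lipophilic / anionic / ungrouped.

    Primary thresholds: log P > 4.5 with anionic fraction < 0.5 →
    lipophilic cluster; log P < 3 with anionic fraction ≈ 1 → anionic
    cluster. With ``borderline="relaxed"`` (default) compounds matching
    neither rule are resolved by the looser score-plot description —
    hydrophilic and negatively charged at pH 7.4 (log P < 3, F⁻ > 0) vs
    moderately-to-highly lipophilic and mostly uncharged (log P > 3,
    F⁻ < 0.5) — which reproduces the published cluster membership, where a
    partially ionized member like dioxybenzone sits with the anionic cluster
    and oxybenzone (log P 3.5) with the lipophilic one.
    ``borderline="strict"`` leaves such compounds ungrouped.
    """
    if result is not None and result.scores.shape[0] != len(records):
        raise PairingError("PCA scores do not align with records")
    if borderline not in ("relaxed", "strict"):
        raise ValueError(f"unknown borderline mode {borderline!r}")

    labels: list[str] = []
    for rec in records:
        lp = rec.log_p if rec.log_p is not None else np.nan
        if lp > 4.5 and rec.f_minus < 0.5:
            labels.append(GROUP_LIPOPHILIC)
        elif lp < 3.0 and rec.f_minus >= 0.95:
            labels.append(GROUP_ANIONIC)
        elif borderline == "relaxed" and lp < 3.0 and rec.f_minus > 0.0:
            labels.append(GROUP_ANIONIC)
        elif borderline == "relaxed" and lp > 3.0 and rec.f_minus < 0.5:
            labels.append(GROUP_LIPOPHILIC)
        else:
            labels.append(UNGROUPED)
    return labels
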