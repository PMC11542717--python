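"""Concentration conversions and GHS acute aquatic hazard categories.

Endpoints circulate on the p scale (−log10 of the molar concentration);
regulatory classification needs mg/L:

    C [mg/L] = MW [g/mol] * 10^(−p) * 1000

GHS acute aquatic categories by LC50/EC50 concentration:

    <= 1 mg/L      Acute I    "Very toxic"
    (1, 10] mg/L   Acute II   "Toxic"
    (10, 100] mg/L Acute III  "Harmful"
    > 100 mg/L     not classified

Boundary values belong to the more severe class (closed upper bounds).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "HazardAssessment",
    "p_to_mg_per_l",
    "mg_per_l_to_p",
    "ghs_acute_category",
    "assess",
    "round_sig",
    "GHS_LABELS",
]

GHS_LABELS = {
    "acute_I": "Very toxic",
    "acute_II": "Toxic",
    "acute_III": "Harmful",
    "not_classified": "Not classified",
}

#: Hazard-ranking strings as printed in regulatory summaries.
GHS_RANKING_TEXT = {
    "acute_I": "Acute toxicity I / Very toxic",
    "acute_II": "Acute toxicity II / Toxic",
    "acute_III": "Acute toxicity III / Harmful",
    "not_classified": "Not classified",
}


@dataclass(frozen=True)
class HazardAssessment:
    """GHS verdict for one compound/endpoint."""

    compound: str
    endpoint_id: str
    p_value: float
    conc_mg_l: float
    ghs_category: str
    label: str


def p_to_mg_per_l(p_value: float, mw: float) -> float:
    """Convert a p-value (−log10 M) to mg/L for a compound of weight ``mw``."""
    if not (mw > 0):
        raise ValueError(f"mw must be > 0, got {mw}")
    if not math.isfinite(p_value):
        raise ValueError("p_value must be finite")
    return mw * 10.0 ** (-p_value) * 1000.0


def mg_per_l_to_p(conc_mg_l: float, mw: float) -> float:
    """Exact inverse of :func:`p_to_mg_per_l`."""
    if not (conc_mg_l > 0):
        raise ValueError(f"concentration must be > 0, got {conc_mg_l}")
    if not (mw > 0):
        raise ValueError(f"mw must be > 0, got {mw}")
    return -math.log10(conc_mg_l / (1000.0 * mw))


def ghs_acute_category(conc_mg_l: float) -> tuple[str, str]:
    """(category, label) for an acute LC50/EC50 concentration in mg/L."""
    if not (conc_mg_l > 0):
        raise ValueError(f"concentration must be > 0, got {conc_mg_l}")
    if conc_mg_l <= 1.0:
        cat = "acute_I"
    elif conc_mg_l <= 10.0:
        cat = "acute_II"
    elif conc_mg_l <= 100.0:
        cat = "acute_III"
    else:
        cat = "not_classified"
    return cat, GHS_LABELS[cat]


def assess(
    compound: str, endpoint_id: str, p_value: float, mw: float
) -> HazardAssessment:
    """Convert a p-value to mg/L and attach its GHS acute category."""
    conc = p_to_mg_per_l(p_value, mw)
    cat, label = ghs_acute_category(conc)
    return HazardAssessment(
        compound=compound,
        endpoint_id=endpoint_id,
        p_value=p_value,
        conc_mg_l=conc,
        ghs_category=cat,
        label=label,
    )


def round_sig(value: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (rounded view of mg/L columns)."""
    if value == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(value)))
    return round(value, sig - 1 - exponent)
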