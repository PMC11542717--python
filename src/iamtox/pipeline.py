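"""End-to-end orchestration: predict → domain check → hazard, and
reproduction of the published tables from the packaged fixtures.

``reproduce_tables`` writes one CSV per published results table plus a
manifest that classifies every reproduced cell as ``match``,
``known-discrepancy`` (a printed cell that is not derivable from the other
printed cells — each carries a note) or ``mismatch``. The pipeline never
reports a silent mismatch: the test suite asserts the manifest contains none.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import hazard as hz
from .applicability_domain import ADAssessment, TrainingSummary, williams_classify
from .dataset_io import (
    CompoundRecord,
    load_endpoint_table,
    load_printed_errors,
    load_printed_hazard,
    load_uv_filter_panel,
    round_half_away,
)
from .errors import IamtoxError
from .qsar_models import LinearModel, default_registry, predict_endpoint
from .validation_metrics import make_report, compare_models

logger = logging.getLogger("iamtox")

__all__ = [
    "PipelineConfig",
    "PredictionRow",
    "run_predict",
    "reproduce_tables",
    "KNOWN_DISCREPANCIES",
]


@dataclass
class PipelineConfig:
    """Run configuration: model registry plus I/O and rounding options."""

    registry: dict[tuple[str, str], LinearModel] = field(default_factory=default_registry)
    rounded_output: bool = True
    output_dir: Path = Path(".")
    log_level: str = "info"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a config file; model entries override the default registry."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for entry in raw.get("models", []):
            model = LinearModel(
                endpoint_id=entry["endpoint"],
                descriptor=entry["descriptor"],
                beta0=float(entry["beta0"]),
                beta1=float(entry["beta1"]),
            )
            cfg.registry[model.key] = model
        if "rounded_output" in raw:
            cfg.rounded_output = bool(raw["rounded_output"])
        if "output_dir" in raw:
            cfg.output_dir = Path(raw["output_dir"])
        if "log_level" in raw:
            cfg.log_level = str(raw["log_level"])
        return cfg


@dataclass(frozen=True)
class PredictionRow:
    """Per-compound, per-endpoint pipeline output."""

    compound: str
    endpoint_id: str
    descriptor: str
    descriptor_value: float | None
    p_value: float | None
    hazard: hz.HazardAssessment | None
    ad: ADAssessment | None
    error: str | None = None


def run_predict(
    records: list[CompoundRecord],
    endpoint_id: str,
    descriptor: str = "chi_iam",
    registry: dict[tuple[str, str], LinearModel] | None = None,
    training_summary: TrainingSummary | None = None,
) -> list[PredictionRow]:
    """Predict one endpoint for a compound panel; isolate per-compound errors.

    A compound missing the model descriptor yields a row with ``error`` set;
    the run continues for the remaining compounds. When a training summary is
    supplied, each row carries a leverage/in-domain verdict.
    """
    registry = registry if registry is not None else default_registry()
    model = registry[(endpoint_id, descriptor)]
    rows: list[PredictionRow] = []
    for rec in records:
        try:
            ev = predict_endpoint(model, rec)
            hazard = hz.assess(rec.name, endpoint_id, ev.p_value, rec.mw)
            ad = None
            if training_summary is not None:
                xq = float(getattr(rec, descriptor))
                observed = rec.endpoint(endpoint_id, "experimental")
                resid = None if observed is None else observed - ev.p_value
                s = model.stats.s if model.stats is not None else None
                ad = williams_classify(
                    training_summary, [rec.name], np.array([xq]),
                    residuals=[resid], s=s,
                )[0]
            rows.append(
                PredictionRow(
                    compound=rec.name,
                    endpoint_id=endpoint_id,
                    descriptor=descriptor,
                    descriptor_value=float(getattr(rec, descriptor)),
                    p_value=ev.p_value,
                    hazard=hazard,
                    ad=ad,
                )
            )
        except IamtoxError as exc:
            logger.warning("prediction failed for %s: %s", rec.name, exc)
            rows.append(
                PredictionRow(
                    compound=rec.name,
                    endpoint_id=endpoint_id,
                    descriptor=descriptor,
                    descriptor_value=getattr(rec, descriptor, None),
                    p_value=None,
                    hazard=None,
                    ad=None,
                    error=f"{type(exc).__name__}: {exc}",
                )
            )
    return rows


# ---------------------------------------------------------------------------
# published-table reproduction
# ---------------------------------------------------------------------------

#: Printed cells that are not derivable from the other printed cells.
#: (table, row, column) -> note. These are source-data inconsistencies in the
#: published tables, documented rather than silently failed.
KNOWN_DISCREPANCIES: dict[tuple[str, str, str], str] = {
    ("table4", "Octocrylene", "resid_chi"):
        "printed 0.72 but |5.65-5.29| = 0.36 from the printed columns",
    ("table4", "Padimate O", "resid_chi"):
        "printed 0.16 but |4.85-4.98| = 0.13 from the printed columns",
    ("table6", "4-Aminobenzoic Acid", "chi_model"):
        "recovered line gives 2.8145 -> 2.81; printed 2.82 (within the 0.01 "
        "refit gate but rounding differs at the low-CHI extreme)",
    ("table6", "4-Aminobenzoic Acid", "resid_chi"):
        "follows from the chi_model cell: computed 0.45 vs printed 0.44",
    ("table7", "chi_model", "bias"):
        "printed -0.17 but the printed columns give -0.37",
    ("table7", "logp_model", "rmsep"):
        "printed 0.65 but the printed columns give 0.68",
    ("table7", "logp_model", "rsep_percent"):
        "printed 14.5 but the printed columns give 15.1",
    ("table7", "logp_model", "bias"):
        "printed -0.46 but the printed columns give -0.52",
    ("table7", "external_tool", "rsep_percent"):
        "printed 19.8 but the printed columns give 19.7",
    ("table8", "Octinoxate", "p_value"):
        "recovered line gives 5.01; printed 5.00 (its mg/L cell 2.84 matches "
        "the unrounded 5.009)",
    ("table8", "Avobenzone", "conc_mg_l"):
        "printed 3.35 implies p 4.966; both the recovered line (4.970) and "
        "the printed p (4.97) give 3.32",
    ("table8", "Dioxybenzone", "conc_mg_l"):
        "full-precision prediction gives 11.6; the printed 11.7 follows from "
        "the 2-decimal p 4.32",
    ("table9", "Homosalate", "conc_mg_l"):
        "printed 3.71 implies p 4.849; the recovered line (4.851) gives 3.69",
}

# fish Table 5 is wholly not derivable from Table 4's printed values
for _src in ("chi_model", "logp_model", "external_tool"):
    for _m in ("rmsep", "rsep_percent", "bias"):
        KNOWN_DISCREPANCIES.setdefault(
            ("table5", _src, _m),
            "fish error parameters are not derivable from the printed "
            "experimental/predicted columns (see e.g. the octocrylene and "
            "padimate O residual cells)",
        )

_SCREEN_COMPOUNDS = {
    "fish_pLC50": ("Avobenzone", "Dioxybenzone", "Homosalate", "Octinoxate"),
    "daphnia_pEC50": ("Homosalate",),
}
_TABLE_TAGS = {
    "fish_pLC50": ("table4", "table5", "table8"),
    "daphnia_pEC50": ("table6", "table7", "table9"),
}


def _manifest_cell(manifest, table, row, column, computed, printed, match):
    if match:
        status = "match"
        note = ""
    elif (table, row, column) in KNOWN_DISCREPANCIES:
        status = "known-discrepancy"
        note = KNOWN_DISCREPANCIES[(table, row, column)]
    else:
        status = "mismatch"
        note = ""
    manifest.append(
        {
            "table": table,
            "row": row,
            "column": column,
            "computed": computed,
            "printed": printed,
            "status": status,
            "note": note,
        }
    )


def reproduce_tables(output_dir: str | Path, registry=None) -> pd.DataFrame:
    """Re-derive the published results tables from fixtures; write CSVs.

    Emits ``table{4,5,6,7,8,9}_repro.csv`` and ``manifest.csv`` under
    ``output_dir`` and returns the manifest. Every compared cell is either a
    match or a documented known discrepancy.
    """
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    registry = registry if registry is not None else default_registry()
    panel = {rec.name: rec for rec in load_uv_filter_panel()}
    manifest: list[dict] = []

    for endpoint_id in ("fish_pLC50", "daphnia_pEC50"):
        endpoint_tag, errors_tag, screen_tag = _TABLE_TAGS[endpoint_id]
        printed = load_endpoint_table(endpoint_id)
        chi_model = registry[(endpoint_id, "chi_iam")]

        # --- endpoint table (Tables 4 / 6) -------------------------------
        rows = []
        for _, prow in printed.iterrows():
            rec = panel[prow["name"]]
            pred_chi = chi_model.predict(rec.chi_iam)
            # the log P models fail the linear-refit gate, so their printed
            # predictions are ingested rather than recomputed
            pred_logp = float(prow["logp_model"])
            obs = float(prow["experimental"])
            row = {
                "name": rec.name,
                "experimental": obs,
                "chi_model": pred_chi,
                "logp_model": pred_logp,
                "external_tool": float(prow["external_tool"]),
                "resid_chi": abs(obs - pred_chi),
                "resid_logp": abs(obs - pred_logp),
                "resid_epi": abs(obs - float(prow["external_tool"])),
            }
            rows.append(row)
            for col in ("chi_model", "resid_chi", "resid_logp", "resid_epi"):
                computed = round_half_away(row[col], 2)
                _manifest_cell(
                    manifest, endpoint_tag, rec.name, col,
                    computed, float(prow[col]), computed == float(prow[col]),
                )
        repro = pd.DataFrame(rows)
        repro.to_csv(output_dir / f"{endpoint_tag}_repro.csv", index=False)

        # --- error-parameter table (Tables 5 / 7) ------------------------
        reports = []
        for source, col in (
            ("logp_model", "logp_model"),
            ("chi_model", "chi_model"),
            ("external_tool", "external_tool"),
        ):
            reports.append(
                make_report(
                    endpoint_id, source,
                    list(printed["name"]), printed["experimental"], printed[col],
                )
            )
        comparison = compare_models(reports)
        comparison.to_csv(output_dir / f"{errors_tag}_repro.csv")
        printed_errors = load_printed_errors(endpoint_id)
        for source in ("logp_model", "chi_model", "external_tool"):
            rep = next(r for r in reports if r.source == source)
            for metric, value, nd in (
                ("rmsep", rep.rmsep, 2),
                ("rsep_percent", rep.rsep_percent, 1),
                ("bias", rep.bias, 2),
            ):
                computed = round_half_away(value, nd)
                printed_v = float(printed_errors.loc[metric, source])
                _manifest_cell(
                    manifest, errors_tag, source, metric,
                    computed, printed_v, computed == printed_v,
                )

        # --- screening table (Tables 8 / 9) ------------------------------
        screen_printed = load_printed_hazard(endpoint_id)
        rows = []
        for name in _SCREEN_COMPOUNDS[endpoint_id]:
            rec = panel[name]
            p = chi_model.predict(rec.chi_iam)
            assessment = hz.assess(name, endpoint_id, p, rec.mw)
            ranking = hz.GHS_RANKING_TEXT[assessment.ghs_category]
            rows.append(
                {
                    "name": name,
                    "p_value": p,
                    "conc_mg_l": assessment.conc_mg_l,
                    "hazard_ranking": ranking,
                }
            )
            prow = screen_printed[screen_printed["name"] == name].iloc[0]
            p_r = round_half_away(p, 2)
            _manifest_cell(
                manifest, screen_tag, name, "p_value",
                p_r, float(prow["p_value"]), p_r == float(prow["p_value"]),
            )
            c_r = hz.round_sig(assessment.conc_mg_l, 3)
            _manifest_cell(
                manifest, screen_tag, name, "conc_mg_l",
                c_r, float(prow["conc_mg_l"]), c_r == float(prow["conc_mg_l"]),
            )
            _manifest_cell(
                manifest, screen_tag, name, "hazard_ranking",
                ranking, prow["hazard_ranking"], ranking == prow["hazard_ranking"],
            )
        pd.DataFrame(rows).to_csv(output_dir / f"{screen_tag}_repro.csv", index=False)

    manifest_df = pd.DataFrame(manifest)
    manifest_df.to_csv(output_dir / "manifest.csv", index=False)
    n_mismatch = int((manifest_df["status"] == "mismatch").sum())
    if n_mismatch:
        logger.warning("manifest contains %d undocumented mismatches", n_mismatch)
    return manifest_df
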