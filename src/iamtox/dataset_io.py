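"""Compound data model and CSV I/O.

The package ships the published UV-filter data as CSV fixtures: descriptor
table (13 sunscreen ingredients with log P, log D7.4, MW, TPSA, charged-species
fractions, Abraham A/B, HBD/HBA), the measured IAM chromatographic
hydrophobicity indices (CHI_IAM), and the experimental / model-predicted /
EPI-Suite acute-toxicity endpoint tables for fish (pLC50) and *Daphnia magna*
(pEC50). Everything is plain CSV: comma-separated, UTF-8, header row, ``.``
decimal separator.

Numbers are kept at full precision internally; a "rounded view" writer renders
2-decimal cells (half-away-from-zero) matching the published tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import ParseError, SchemaError

__all__ = [
    "ENDPOINT_IDS",
    "SOURCES",
    "CompoundRecord",
    "EndpointValue",
    "load_compound_table",
    "write_table",
    "records_to_frame",
    "round_half_away",
    "fixture_path",
    "load_table1",
    "load_table3",
    "load_table2_stats",
    "load_endpoint_table",
    "load_printed_errors",
    "load_printed_hazard",
    "load_uv_filter_panel",
    "DESCRIPTOR_COLUMNS",
]

#: Closed vocabulary of endpoint identifiers.
ENDPOINT_IDS = ("fish_pLC50", "daphnia_pEC50")

#: Closed vocabulary of prediction sources. ``external_tool`` holds ingested
#: third-party (EPI Suite / ECOSAR) predictions; they are data, never computed.
SOURCES = ("experimental", "chi_model", "logp_model", "external_tool")

#: Descriptor columns of the packaged descriptor fixture, in canonical order.
DESCRIPTOR_COLUMNS = (
    "log_p",
    "log_d74",
    "mw",
    "tpsa",
    "f_minus",
    "f_plus",
    "f_zwit",
    "abraham_a",
    "abraham_b",
    "hbd",
    "hba",
)


def round_half_away(value: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention of the printed tables).

    Python's builtin ``round`` is banker's rounding; the tables round 0.005 up.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class EndpointValue:
    """One observed or predicted toxicity endpoint on the p (−log M) scale."""

    endpoint_id: str
    source: str
    p_value: float

    def __post_init__(self) -> None:
        if self.endpoint_id not in ENDPOINT_IDS:
            raise SchemaError(f"unknown endpoint_id {self.endpoint_id!r}")
        if self.source not in SOURCES:
            raise SchemaError(f"unknown source {self.source!r}")
        if not math.isfinite(self.p_value):
            raise ParseError(f"non-finite p_value for {self.endpoint_id}")


@dataclass
class CompoundRecord:
    """One UV filter with its physicochemical descriptors and endpoints.

    ``chi_iam`` is the Chromatographic Hydrophobicity Index measured on an
    immobilized-artificial-membrane column (≈ % acetonitrile at elution,
    a phospholipid-binding proxy); it is optional because hazard screening of
    unmeasured compounds starts without it.
    """

    name: str
    mw: float
    log_p: float | None = None
    log_d74: float | None = None
    tpsa: float | None = None
    f_minus: float = 0.0
    f_plus: float = 0.0
    f_zwit: float = 0.0
    abraham_a: float | None = None
    abraham_b: float | None = None
    hbd: float | None = None
    hba: float | None = None
    chi_iam: float | None = None
    endpoints: dict[tuple[str, str], EndpointValue] = field(default_factory=dict)
    annotations: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.name:
            raise SchemaError("compound name must be non-empty")
        if not (self.mw > 0):
            raise ParseError(f"{self.name}: mw must be > 0, got {self.mw}")
        for attr in ("f_minus", "f_plus", "f_zwit"):
            v = getattr(self, attr)
            if not (0.0 <= v <= 1.0):
                raise ParseError(f"{self.name}: {attr} outside [0, 1]: {v}")
        if self.f_minus + self.f_plus + self.f_zwit > 1.0 + 1e-9:
            raise ParseError(f"{self.name}: species fractions sum above 1")
        if self.tpsa is not None and self.tpsa < 0:
            raise ParseError(f"{self.name}: tpsa must be >= 0")
        for attr in ("hbd", "hba"):
            v = getattr(self, attr)
            if v is not None and v < 0:
                raise ParseError(f"{self.name}: {attr} must be >= 0")
        if self.chi_iam is not None and not math.isfinite(self.chi_iam):
            raise ParseError(f"{self.name}: chi_iam must be finite")

    # -- endpoint helpers -------------------------------------------------
    def set_endpoint(self, value: EndpointValue) -> None:
        self.endpoints[(value.endpoint_id, value.source)] = value

    def endpoint(self, endpoint_id: str, source: str) -> float | None:
        ev = self.endpoints.get((endpoint_id, source))
        return None if ev is None else ev.p_value

    def with_chi(self, chi_iam: float) -> "CompoundRecord":
        return replace(self, chi_iam=chi_iam)


# ---------------------------------------------------------------------------
# generic CSV I/O
# ---------------------------------------------------------------------------

_NUMERIC_FIELDS = (
    "mw",
    "log_p",
    "log_d74",
    "tpsa",
    "f_minus",
    "f_plus",
    "f_zwit",
    "abraham_a",
    "abraham_b",
    "hbd",
    "hba",
    "chi_iam",
)


def load_compound_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> list[CompoundRecord]:
    """Read a compound CSV into records.

    ``schema`` maps file column names to canonical field names (identity by
    default). ``name`` and ``mw`` are required; descriptor columns are parsed
    as numbers; unrecognised columns are preserved verbatim in
    ``record.annotations``. Row order is preserved.
    """
    df = pd.read_csv(path, dtype=str)
    if schema:
        df = df.rename(columns=dict(schema))
    for required in ("name", "mw"):
        if required not in df.columns:
            raise SchemaError(f"required column {required!r} missing in {path}")

    records: list[CompoundRecord] = []
    known = set(_NUMERIC_FIELDS)
    for idx, row in df.iterrows():
        kwargs: dict[str, object] = {"name": row["name"]}
        annotations: dict[str, object] = {}
        for col in df.columns:
            if col == "name":
                continue
            raw = row[col]
            if col in known:
                if pd.isna(raw) or raw == "":
                    continue
                try:
                    kwargs[col] = float(raw)
                except ValueError as exc:
                    raise ParseError(
                        f"non-numeric value {raw!r} in column {col!r}, row {idx}"
                    ) from exc
            else:
                annotations[col] = raw
        kwargs["annotations"] = annotations
        records.append(CompoundRecord(**kwargs))  # type: ignore[arg-type]
    return records


def records_to_frame(records: Iterable[CompoundRecord]) -> pd.DataFrame:
    """Flatten records to a DataFrame with stable column order."""
    rows = []
    for rec in records:
        row: dict[str, object] = {"name": rec.name}
        for fld in _NUMERIC_FIELDS:
            v = getattr(rec, fld)
            if v is not None:
                row[fld] = v
        for (eid, src), ev in rec.endpoints.items():
            row[f"{eid}__{src}"] = ev.p_value
        row.update(rec.annotations)
        rows.append(row)
    return pd.DataFrame(rows)


def write_table(
    records: Iterable[CompoundRecord] | pd.DataFrame,
    path: str | Path,
    rounded: bool = False,
    ndigits: int = 2,
) -> None:
    """Write records (or any report DataFrame) as CSV.

    ``rounded=True`` renders every float at ``ndigits`` decimals,
    half-away-from-zero, matching the published tables; the default keeps full
    precision (``load_compound_table`` round-trips exactly in that mode).
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        records = list(records)
        if not records:
            raise SchemaError("cannot write an empty record list")
        df = records_to_frame(records)
    if rounded:
        fmt = f"%.{ndigits}f"
        for col in df.columns:
            if pd.api.types.is_float_dtype(df[col]):
                df[col] = df[col].map(
                    lambda v: "" if pd.isna(v) else fmt % round_half_away(v, ndigits)
                )
        df.to_csv(path, index=False)
    else:
        df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------

_ENDPOINT_BY_TABLE = {"table4_fish.csv": "fish_pLC50", "table6_daphnia.csv": "daphnia_pEC50"}


def fixture_path(filename: str) -> Path:
    """Path of a packaged data file."""
    return Path(resources.files("iamtox.data") / filename)


def load_table1() -> list[CompoundRecord]:
    """The 13 UV filters with their 11 physicochemical descriptor columns."""
    return load_compound_table(fixture_path("table1_descriptors.csv"))


def load_table3() -> pd.DataFrame:
    """Measured CHI_IAM of the 13 UV filters (columns ``name, chi_iam``)."""
    return pd.read_csv(fixture_path("table3_chi.csv"))


def load_table2_stats() -> pd.DataFrame:
    """Published fit statistics (R, R², R²adj, s, F) of the four models."""
    return pd.read_csv(fixture_path("table2_model_stats.csv"))


def load_endpoint_table(endpoint_id: str) -> pd.DataFrame:
    """Experimental + predicted endpoint table for one organism.

    Columns: ``name, experimental, chi_model, logp_model, external_tool`` plus
    the printed absolute residual columns ``resid_chi, resid_logp, resid_epi``.
    """
    table = {v: k for k, v in _ENDPOINT_BY_TABLE.items()}.get(endpoint_id)
    if table is None:
        raise SchemaError(f"unknown endpoint_id {endpoint_id!r}")
    return pd.read_csv(fixture_path(table))


def load_printed_errors(endpoint_id: str) -> pd.DataFrame:
    """Published RMSEP / RSEP% / bias table for one endpoint."""
    name = {
        "fish_pLC50": "table5_fish_errors.csv",
        "daphnia_pEC50": "table7_daphnia_errors.csv",
    }.get(endpoint_id)
    if name is None:
        raise SchemaError(f"unknown endpoint_id {endpoint_id!r}")
    return pd.read_csv(fixture_path(name), index_col="metric")


def load_printed_hazard(endpoint_id: str) -> pd.DataFrame:
    """Published screening predictions (p-value, mg/L, GHS ranking)."""
    name = {
        "fish_pLC50": "table8_fish_predicted.csv",
        "daphnia_pEC50": "table9_daphnia_predicted.csv",
    }.get(endpoint_id)
    if name is None:
        raise SchemaError(f"unknown endpoint_id {endpoint_id!r}")
    return pd.read_csv(fixture_path(name))


def load_uv_filter_panel() -> list[CompoundRecord]:
    """Join descriptors, CHI_IAM and all endpoint tables into 13 records."""
    records = load_table1()
    chi = dict(zip(load_table3()["name"], load_table3()["chi_iam"]))
    by_name: dict[str, CompoundRecord] = {}
    for rec in records:
        rec = rec.with_chi(float(chi[rec.name]))
        by_name[rec.name] = rec
    for table, endpoint_id in _ENDPOINT_BY_TABLE.items():
        df = pd.read_csv(fixture_path(table))
        for _, row in df.iterrows():
            rec = by_name[row["name"]]
            for source, col in (
                ("experimental", "experimental"),
                ("chi_model", "chi_model"),
                ("logp_model", "logp_model"),
                ("external_tool", "external_tool"),
            ):
                rec.set_endpoint(EndpointValue(endpoint_id, source, float(row[col])))
    return list(by_name.values())
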