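"""CSV/YAML schemas and readers for the assay tables.

All tables are comma-separated UTF-8 with a mandatory header row and "."
decimal separator. Units are embedded in column names where ambiguity is
possible (``dose_uM``, ``dna_mass_ug``, ``concentration_ug_per_L``).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .adducts import HplcRecord
from .errors import SchemaError
from .teq import DoseResponseCurve, MixtureSpec

__all__ = ["SCHEMAS", "read_table", "write_table", "read_mixtures",
           "curves_from_table", "hplc_records_from_table"]

# schema name -> {column: (dtype kind, nullable)}
SCHEMAS: dict[str, dict[str, tuple[str, bool]]] = {
    "dye_spread": {
        "experiment_id": ("str", False),
        "treatment": ("str", False),
        "dish_id": ("str", False),
        "cut_id": ("str", False),
        "area": ("float", False),
    },
    "qpcr": {
        "experiment_id": ("str", False),
        "treatment": ("str", False),
        "gene": ("str", False),
        "replicate": ("str", False),
        "ct": ("float", False),
    },
    "hplc": {
        "kind": ("str", False),
        "concentration_ug_per_L": ("float", True),
        "response": ("float", False),
        "treatment": ("str", True),
        "dna_mass_ug": ("float", True),
    },
    "dose_response": {
        "compound": ("str", False),
        "timepoint_h": ("float", False),
        "dose_uM": ("float", False),
        "inhibition_pct": ("float", False),
    },
}

_KEY_COLUMNS = {
    "dye_spread": ["experiment_id", "treatment", "dish_id", "cut_id"],
    "qpcr": ["experiment_id", "treatment", "gene", "replicate"],
    "dose_response": ["compound", "timepoint_h", "dose_uM"],
}


def _validate(df: pd.DataFrame, schema: str) -> pd.DataFrame:
    spec = SCHEMAS[schema]
    missing = set(spec) - set(df.columns)
    if missing:
        raise SchemaError(
            f"{schema}: missing column(s) {sorted(missing)}"
        )
    out = df.copy()
    for col, (kind, nullable) in spec.items():
        if kind == "float":
            coerced = pd.to_numeric(out[col], errors="coerce")
            bad = coerced.isna() & out[col].notna() & (out[col].astype(str).str.strip() != "")
            if bad.any():
                row = int(bad[bad].index[0])
                raise SchemaError(
                    f"{schema}: non-numeric value in column {col!r} at row {row}"
                )
            if not nullable and coerced.isna().any():
                row = int(coerced[coerced.isna()].index[0])
                raise SchemaError(
                    f"{schema}: missing value in column {col!r} at row {row}"
                )
            out[col] = coerced
        else:
            out[col] = out[col].astype("string").fillna("").astype(str)
    keys = _KEY_COLUMNS.get(schema)
    if keys is not None and out[keys].duplicated().any():
        row = int(out[keys][out[keys].duplicated()].index[0])
        raise SchemaError(
            f"{schema}: duplicate key {keys} at row {row}"
        )
    return out


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate one of the assay CSV schemas."""
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; one of {sorted(SCHEMAS)}")
    df = pd.read_csv(path)
    return _validate(df, schema)


def write_table(df: pd.DataFrame, path: str | Path, schema: str) -> None:
    """Validate and write an assay table as CSV."""
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; one of {sorted(SCHEMAS)}")
    _validate(df, schema)[list(SCHEMAS[schema])].to_csv(path, index=False)


def read_mixtures(path: str | Path) -> tuple[list[MixtureSpec], dict[str, float]]:
    """Read a mixtures YAML file.

    Format: a list of {label, components: {compound: dose_uM},
    observed_inhibition_pct (optional)}. Returns the mixture specs plus a
    label -> observed-% map for the mixtures that carry observations.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise SchemaError("mixtures YAML must be a list of mixture entries")
    mixtures, observed = [], {}
    for i, entry in enumerate(raw):
        try:
            label = entry["label"]
            components = {str(k): float(v) for k, v in entry["components"].items()}
        except (KeyError, TypeError, ValueError) as exc:
            raise SchemaError(f"mixtures entry {i}: {exc}") from exc
        mixtures.append(MixtureSpec(label=str(label), components=components))
        if "observed_inhibition_pct" in entry:
            observed[str(label)] = float(entry["observed_inhibition_pct"])
    return mixtures, observed


def curves_from_table(df: pd.DataFrame) -> dict[str, DoseResponseCurve]:
    """Group a validated dose_response table into per-compound curves."""
    curves = {}
    for (compound, timepoint), sub in df.groupby(["compound", "timepoint_h"]):
        sub = sub.sort_values("dose_uM")
        curves[str(compound)] = DoseResponseCurve(
            compound=str(compound),
            points=tuple(zip(sub["dose_uM"], sub["inhibition_pct"])),
            timepoint_h=float(timepoint),
        )
    return curves


def hplc_records_from_table(df: pd.DataFrame) -> list[HplcRecord]:
    """Convert a validated hplc table into typed records."""
    records = []
    for _, row in df.iterrows():
        conc = row["concentration_ug_per_L"]
        dna = row["dna_mass_ug"]
        records.append(
            HplcRecord(
                kind=str(row["kind"]),
                response=float(row["response"]),
                concentration=None if pd.isna(conc) else float(conc),
                treatment=str(row["treatment"]) or None,
                dna_mass=None if pd.isna(dna) else float(dna),
            )
        )
    return records
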