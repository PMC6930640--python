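"""Bioactivity curation: from raw assay records to a modelling-ready table.

The rules mirror standard ChEMBL-style QSAR curation practice:

1. keep only IC50 endpoints with an exact ("=" or missing) relation, a
   present positive value and a recognized concentration unit;
2. convert to pIC50 = -log10(concentration in molar);
3. collapse replicate measurements per compound to their median pIC50,
   dropping compounds whose replicates disagree by more than a concordance
   threshold (default 1.0 log unit);
4. label compounds active / intermediate / inactive by configurable pIC50
   cut points (defaults: active >= 6.0, i.e. IC50 <= 1 uM; inactive <= 5.0,
   i.e. IC50 >= 10 uM).

A curation log counts the records removed by each rule so the accounting
from raw table to modelling set is auditable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CuratedCompound",
    "UNIT_TO_MOLAR",
    "filter_records",
    "to_pic50",
    "aggregate_duplicates",
    "classify_activity",
    "curate",
    "chemical_space_summary",
    "read_bioactivity_csv",
    "write_curated_csv",
]

UNIT_TO_MOLAR = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,
    "um": 1e-6,
    "nM": 1e-9,
    "pM": 1e-12,
}

PROPERTY_COLUMNS = ["MW", "ALogP", "nHBDon", "nHBAcc"]

DEFAULT_ACTIVE_MIN = 6.0
DEFAULT_INACTIVE_MAX = 5.0


@dataclass
class CuratedCompound:
    compound_id: str
    smiles: str
    pic50: float
    activity_class: str
    properties: dict = field(default_factory=dict)


def _normalize_unit(unit) -> str | None:
    if unit is None or (isinstance(unit, float) and math.isnan(unit)):
        return None
    u = str(unit).strip()
    if u in UNIT_TO_MOLAR:
        return u
    low = u.lower()
    for known in UNIT_TO_MOLAR:
        if known.lower() == low:
            return known
    return None


def filter_records(records: pd.DataFrame) -> pd.DataFrame:
    """Keep IC50 records with an exact relation, positive value, known unit.

    A missing relation is treated as "="; qualified values (">", "<",
    ">=", "<=") are removed.  Row order is preserved.  A removal count per
    rule is attached as ``result.attrs["curation_log"]``.
    """
    df = records.copy()
    n0 = len(df)
    if n0 == 0:
        df.attrs["curation_log"] = {"input": 0, "kept": 0}
        return df

    stype = df["standard_type"].astype(str).str.strip().str.upper()
    is_ic50 = stype == "IC50"

    rel = df["relation"]
    rel_str = rel.astype(str).str.strip()
    rel_ok = rel.isna() | (rel_str == "") | (rel_str == "=") | (rel_str == "nan")

    value = pd.to_numeric(df["value"], errors="coerce")
    value_ok = value.notna() & (value > 0)

    unit_ok = df["unit"].map(_normalize_unit).notna()

    keep = is_ic50 & rel_ok & value_ok & unit_ok
    log = {
        "input": int(n0),
        "removed_non_ic50": int((~is_ic50).sum()),
        "removed_qualified": int((is_ic50 & ~rel_ok).sum()),
        "removed_missing_or_nonpositive_value": int((is_ic50 & rel_ok & ~value_ok).sum()),
        "removed_unknown_unit": int((is_ic50 & rel_ok & value_ok & ~unit_ok).sum()),
        "kept": int(keep.sum()),
    }
    out = df.loc[keep].copy()
    out.attrs["curation_log"] = log
    return out


def to_pic50(value: float, unit: str) -> float:
    """pIC50 = -log10(value converted to molar)."""
    if value is None or not np.isfinite(value) or value <= 0:
        raise ValueError(f"IC50 value must be positive and finite, got {value}")
    u = _normalize_unit(unit)
    if u is None:
        raise ValueError(f"unrecognized concentration unit: {unit!r}")
    return float(-np.log10(value * UNIT_TO_MOLAR[u]))


def aggregate_duplicates(
    records: pd.DataFrame, concordance: float = 1.0
) -> tuple[pd.DataFrame, dict]:
    """One row per compound: median pIC50 over replicates.

    Compounds whose replicate pIC50 range exceeds ``concordance`` log
    units are dropped (discordant measurements).  Input must already have
    passed :func:`filter_records`.  Returns ``(table, log)``; the table has
    columns compound_id, smiles, pIC50, n_records.
    """
    if len(records) == 0:
        empty = pd.DataFrame(columns=["compound_id", "smiles", "pIC50", "n_records"])
        return empty, {"compounds_in": 0, "compounds_dropped_discordant": 0, "compounds_out": 0}
    df = records.copy()
    df["pIC50"] = [
        to_pic50(v, u) for v, u in zip(pd.to_numeric(df["value"]), df["unit"])
    ]
    rows = []
    dropped = []
    for cid, grp in df.groupby("compound_id", sort=False):
        vals = grp["pIC50"].to_numpy()
        if vals.max() - vals.min() > concordance:
            dropped.append(cid)
            continue
        smiles = next((s for s in grp["smiles"] if isinstance(s, str) and s), "")
        rows.append(
            {
                "compound_id": cid,
                "smiles": smiles,
                "pIC50": float(np.median(vals)),
                "n_records": int(len(vals)),
            }
        )
    table = pd.DataFrame(rows, columns=["compound_id", "smiles", "pIC50", "n_records"])
    log = {
        "compounds_in": int(df["compound_id"].nunique()),
        "compounds_dropped_discordant": len(dropped),
        "discordant_ids": dropped,
        "compounds_out": len(table),
    }
    return table, log


def classify_activity(
    pic50: float,
    thresholds: tuple[float, float] = (DEFAULT_ACTIVE_MIN, DEFAULT_INACTIVE_MAX),
) -> str:
    """active if pIC50 >= active_min, inactive if <= inactive_max, else intermediate."""
    active_min, inactive_max = thresholds
    if active_min <= inactive_max:
        raise ValueError(
            f"active_min ({active_min}) must exceed inactive_max ({inactive_max})"
        )
    if pic50 >= active_min:
        return "active"
    if pic50 <= inactive_max:
        return "inactive"
    return "intermediate"


def curate(
    records: pd.DataFrame,
    properties: pd.DataFrame | None = None,
    concordance: float = 1.0,
    thresholds: tuple[float, float] = (DEFAULT_ACTIVE_MIN, DEFAULT_INACTIVE_MAX),
    standardizer=None,
) -> tuple[pd.DataFrame, dict]:
    """Full curation: filter, convert, aggregate, classify, merge properties.

    ``standardizer`` is an optional SMILES -> SMILES callable (e.g. a salt
    stripper / aromatizer for real-data mode); the default is a
    pass-through.  Returns ``(curated, log)``; curated has one row per
    compound with pIC50, activity_class and any available Lipinski
    property columns.
    """
    filtered = filter_records(records)
    if standardizer is not None and len(filtered):
        filtered = filtered.copy()
        filtered["smiles"] = [
            standardizer(s) if isinstance(s, str) and s else s
            for s in filtered["smiles"]
        ]
    table, agg_log = aggregate_duplicates(filtered, concordance=concordance)
    if len(table):
        table["activity_class"] = [
            classify_activity(v, thresholds) for v in table["pIC50"]
        ]
    else:
        table["activity_class"] = pd.Series(dtype=str)
    if properties is not None and len(table):
        cols = ["compound_id"] + [c for c in PROPERTY_COLUMNS if c in properties.columns]
        table = table.merge(properties[cols], on="compound_id", how="left")
    log = {
        "filter": filtered.attrs.get("curation_log", {}),
        "aggregate": agg_log,
        "thresholds": {"active_min": thresholds[0], "inactive_max": thresholds[1]},
    }
    return table, log


def chemical_space_summary(compounds: pd.DataFrame) -> pd.DataFrame:
    """Five-number summary of each Lipinski property per activity class.

    The numbers behind class-wise boxplots: min, Q1, median, Q3, max and n
    for every (activity_class, property) combination.  Properties absent
    from the table are reported with null quantiles rather than raised.
    """
    classes = ["active", "intermediate", "inactive"]
    rows = []
    for cls in classes:
        sub = compounds[compounds.get("activity_class") == cls] if len(compounds) else compounds
        for prop in PROPERTY_COLUMNS:
            if prop in compounds.columns:
                vals = pd.to_numeric(sub[prop], errors="coerce").dropna() if len(sub) else pd.Series(dtype=float)
            else:
                vals = pd.Series(dtype=float)
            if len(vals):
                q = np.percentile(vals, [0, 25, 50, 75, 100])
                rows.append([cls, prop, len(vals), *q])
            else:
                rows.append([cls, prop, 0, *([None] * 5)])
    return pd.DataFrame(
        rows, columns=["activity_class", "property", "n", "min", "q1", "median", "q3", "max"]
    )


def read_bioactivity_csv(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a bioactivity CSV; ``column_map`` renames export dialects
    (e.g. ChEMBL's ``molecule_chembl_id``) onto the canonical columns."""
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    required = {"compound_id", "standard_type", "relation", "value", "unit"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "smiles" not in df.columns:
        df["smiles"] = ""
    return df


def write_curated_csv(curated: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    curated.to_csv(path, index=False)
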