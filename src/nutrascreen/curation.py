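"""Bioactivity record curation: filtering, unit standardization, pActivity, labels.

Raw assay records (one row per measurement) are filtered down to reliable,
exact, concentration-based entries; concentrations are harmonized to nM,
transformed to pActivity = 9 − log10(value in nM), aggregated per compound
(max by default), and thresholded into binary interaction labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CurationConfig",
    "filter_records",
    "standardize_to_nM",
    "to_pactivity",
    "aggregate_and_label",
    "curate",
    "REQUIRED_COLUMNS",
    "REJECTION_ORDER",
]

REQUIRED_COLUMNS = (
    "compound_id",
    "smiles",
    "assay_type",
    "relation",
    "value",
    "unit",
    "confidence",
    "standardization_flag",
)

# First-failing-predicate order used for the rejection log.
REJECTION_ORDER = ("type", "unit", "confidence", "value", "relation", "smiles", "flag")

# Accept both the micro sign and the plain-ASCII spelling.
_MICROMOLAR = {"µM", "uM"}
_NANOMOLAR = {"nM"}


@dataclass(frozen=True)
class CurationConfig:
    """Settings for record filtering, aggregation, and labeling."""

    allowed_types: frozenset = frozenset({"IC50", "Ki", "Kd", "EC50"})
    allowed_units: frozenset = frozenset(_NANOMOLAR | _MICROMOLAR)
    min_confidence: int = 7
    allowed_flags: frozenset = frozenset({"validated", "unassigned"})
    aggregation: str = "max"
    pactivity_threshold: float = 6.0
    label_stage_type: str = "IC50"

    def __post_init__(self):
        if self.aggregation not in {"max", "mean", "median"}:
            raise ValueError(f"unknown aggregation strategy: {self.aggregation!r}")
        if not math.isfinite(self.pactivity_threshold):
            raise ValueError("pactivity_threshold must be finite")


def _check_schema(records: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise KeyError(f"activity table missing required columns: {missing}")


def _first_failure(row: pd.Series, config: CurationConfig) -> str | None:
    """Return the first failing predicate name in documented order, or None."""
    if row["assay_type"] not in config.allowed_types:
        return "type"
    if row["unit"] not in config.allowed_units:
        return "unit"
    try:
        conf = float(row["confidence"])
    except (TypeError, ValueError):
        return "confidence"
    if not (conf >= config.min_confidence):
        return "confidence"
    try:
        val = float(row["value"])
    except (TypeError, ValueError):
        return "value"
    if not (math.isfinite(val) and val > 0):
        return "value"
    if str(row["relation"]) != "=":
        return "relation"
    smi = row["smiles"]
    if smi is None or (isinstance(smi, float) and math.isnan(smi)) or str(smi) == "":
        return "smiles"
    if row["standardization_flag"] not in config.allowed_flags:
        return "flag"
    return None


def filter_records(
    records: pd.DataFrame, config: CurationConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the reliability filter; return (retained rows, rejection log).

    Retained rows satisfy all predicates: allowed assay type, nM/µM unit,
    confidence ≥ min_confidence, positive numeric value, exact ("=") relation,
    SMILES present, standardization flag validated or unassigned. The log has
    one row per rejected record with the first failing predicate as reason.
    """
    config = config or CurationConfig()
    _check_schema(records)
    reasons = records.apply(_first_failure, axis=1, config=config) if len(records) else pd.Series(dtype=object)
    keep = reasons.isna() if len(records) else pd.Series(dtype=bool)
    retained = records.loc[keep].copy() if len(records) else records.copy()
    rejected = records.loc[~keep] if len(records) else records.iloc[0:0]
    log = pd.DataFrame(
        {
            "row_index": rejected.index.to_numpy(),
            "compound_id": rejected["compound_id"].to_numpy() if len(rejected) else [],
            "reason": reasons.loc[~keep].to_numpy() if len(records) else [],
        }
    )
    return retained, log


def standardize_to_nM(value: float, unit: str) -> float:
    """Convert a concentration to nanomolar (µM values multiplied by 1000)."""
    if value is None or not math.isfinite(float(value)) or float(value) <= 0:
        raise ValueError(f"concentration must be positive and finite, got {value!r}")
    if unit in _NANOMOLAR:
        return float(value)
    if unit in _MICROMOLAR:
        return float(value) * 1000.0
    raise ValueError(f"unknown concentration unit: {unit!r}")


def to_pactivity(value_nM: float) -> float:
    """pActivity = −log10(molar concentration) = 9 − log10(value in nM)."""
    v = float(value_nM)
    if not math.isfinite(v) or v <= 0:
        raise ValueError(f"value must be positive and finite, got {value_nM!r}")
    return 9.0 - math.log10(v)


def aggregate_and_label(
    records: pd.DataFrame, config: CurationConfig | None = None
) -> pd.DataFrame:
    """Aggregate per-compound pActivity and assign binary labels.

    Input needs columns ``compound_id`` and ``pactivity`` (finite); an optional
    ``smiles`` column is carried through (first occurrence). Aggregation is
    max (default), mean, or median; label is positive iff the aggregate meets
    the threshold (inclusive ≥).
    """
    config = config or CurationConfig()
    if "compound_id" not in records.columns or "pactivity" not in records.columns:
        raise KeyError("need columns compound_id and pactivity")
    if len(records) and not np.isfinite(records["pactivity"].to_numpy(float)).all():
        raise ValueError("pactivity values must be finite")
    agg_fn = {"max": "max", "mean": "mean", "median": "median"}[config.aggregation]
    grouped = records.groupby("compound_id", sort=False)
    out = grouped["pactivity"].agg(agg_fn).rename("pactivity").reset_index()
    out["n_records"] = grouped.size().to_numpy()
    if "smiles" in records.columns:
        out.insert(1, "smiles", grouped["smiles"].first().to_numpy())
    out["label"] = (out["pactivity"] >= config.pactivity_threshold).astype(int)
    return out


def curate(
    records: pd.DataFrame, config: CurationConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full curation chain: filter → labeling-stage type restriction →
    nM standardization → pActivity → per-compound aggregation and labels.

    Only records of ``label_stage_type`` (IC50 by default) contribute to the
    compound-level labels; other assay types pass the filter but are not used
    for labeling. Returns (compound table, rejection log).
    """
    config = config or CurationConfig()
    retained, log = filter_records(records, config)
    stage = retained[retained["assay_type"] == config.label_stage_type].copy()
    if len(stage):
        stage["value_nM"] = [
            standardize_to_nM(v, u) for v, u in zip(stage["value"], stage["unit"])
        ]
        stage["pactivity"] = [to_pactivity(v) for v in stage["value_nM"]]
    else:
        stage["value_nM"] = pd.Series(dtype=float)
        stage["pactivity"] = pd.Series(dtype=float)
    compounds = aggregate_and_label(stage, config)
    return compounds, log
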