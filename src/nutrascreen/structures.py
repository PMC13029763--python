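"""Structure-level processing: canonicalization audit, deduplication, library prep.

Canonical isomeric SMILES is the sole structural identifier downstream.
Deduplication merges records mapping to the same canonical structure under
fixed rules (max pIC50, OR of positive labels, median of auxiliary numerics,
representative record for everything else) and emits a machine-readable audit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from .features import mol_from_smiles

__all__ = [
    "CanonicalizationFailure",
    "canonicalize",
    "keep_largest_fragment",
    "deduplicate_structures",
    "prepare_screening_library",
    "audit_structures",
    "sha256_file",
]

FAILURE_CATEGORIES = ("parse_error", "sanitize_error", "empty_after_fragment_keep")


@dataclass(frozen=True)
class CanonicalizationFailure:
    """Failure value (not exception) so structure audits can continue."""

    category: str
    input_smiles: str

    def __post_init__(self):
        if self.category not in FAILURE_CATEGORIES:
            raise ValueError(f"unknown failure category {self.category!r}")


def canonicalize(smiles: str) -> str | CanonicalizationFailure:
    """Isomeric canonical SMILES for a valid input, else a categorized failure.

    Canonical output is a fixed point: re-canonicalizing it returns the same
    string. Parse failures (bad syntax) and sanitization failures (valence or
    aromaticity problems) are distinguished in the audit category.
    """
    if smiles is None or not isinstance(smiles, str) or not smiles:
        return CanonicalizationFailure("parse_error", str(smiles))
    mol = Chem.MolFromSmiles(smiles, sanitize=False)
    if mol is None or mol.GetNumAtoms() == 0:
        return CanonicalizationFailure("parse_error", smiles)
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return CanonicalizationFailure("sanitize_error", smiles)
    return Chem.MolToSmiles(mol)


def keep_largest_fragment(smiles: str) -> str | CanonicalizationFailure:
    """Keep only the fragment with the most heavy atoms (salt/mixture stripping).

    Ties are broken by taking the fragment whose canonical SMILES sorts first
    lexicographically, so the result does not depend on fragment order in the
    input. Single-fragment inputs pass through canonicalized.
    """
    canon = canonicalize(smiles)
    if isinstance(canon, CanonicalizationFailure):
        return canon
    mol = Chem.MolFromSmiles(canon)
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if not frags:
        return CanonicalizationFailure("empty_after_fragment_keep", smiles)
    scored = sorted(
        ((-f.GetNumHeavyAtoms(), Chem.MolToSmiles(f)) for f in frags),
        key=lambda t: (t[0], t[1]),
    )
    return scored[0][1]


def audit_structures(
    smiles_series: pd.Series, keep_largest: bool = False
) -> tuple[pd.Series, pd.DataFrame]:
    """Canonicalize a column of SMILES; return (canonical series, audit table).

    The audit table has one row per dropped input with its original row index,
    input SMILES, and failure category. Valid rows keep their index.
    """
    canonical: dict = {}
    failures: list[dict] = []
    for idx, smi in smiles_series.items():
        result = keep_largest_fragment(smi) if keep_largest else canonicalize(smi)
        if isinstance(result, CanonicalizationFailure):
            failures.append(
                {
                    "row_index": idx,
                    "input_smiles": result.input_smiles,
                    "failure_category": result.category,
                }
            )
        else:
            canonical[idx] = result
    audit = pd.DataFrame(failures, columns=["row_index", "input_smiles", "failure_category"])
    return pd.Series(canonical, name="canonical_smiles", dtype=object), audit


def deduplicate_structures(
    table: pd.DataFrame,
    key: str = "canonical_smiles",
    pic50_col: str = "pic50",
    label_col: str = "label",
    aux_numeric: tuple[str, ...] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Merge rows sharing a canonical structure under fixed aggregation rules.

    pIC50 → maximum over contributing rows; label → positive if any row is
    positive; auxiliary numeric columns → median; all other columns → value of
    the representative record (first contributing row in input order);
    ``n_source_records`` counts contributors. Returns (table, audit dict).
    """
    for col in (key, pic50_col, label_col):
        if col not in table.columns:
            raise KeyError(f"deduplication requires column {col!r}")
    if aux_numeric is None:
        skip = {key, pic50_col, label_col}
        aux_numeric = tuple(
            c
            for c in table.columns
            if c not in skip and pd.api.types.is_numeric_dtype(table[c])
        )
    grouped = table.groupby(key, sort=False)
    out = grouped.first().reset_index()  # representative (first) record values
    out[pic50_col] = grouped[pic50_col].max().to_numpy()
    out[label_col] = grouped[label_col].max().astype(int).to_numpy()
    for col in aux_numeric:
        out[col] = grouped[col].median().to_numpy()
    out["n_source_records"] = grouped.size().to_numpy()
    audit = {
        "n_input_rows": int(len(table)),
        "n_output_structures": int(len(out)),
        "n_duplicate_rows_merged": int(len(table) - len(out)),
        "settings": {
            "key": key,
            "pic50_rule": "max",
            "label_rule": "any-positive",
            "aux_numeric_rule": "median",
            "aux_numeric_columns": list(aux_numeric),
            "representative_rule": "first-in-input-order",
        },
    }
    return out, audit


def prepare_screening_library(
    raw: pd.DataFrame,
    smiles_col: str = "smiles",
    id_col: str | None = "id",
    name_col: str | None = "name",
    keep_largest: bool = True,
    id_prefix: str = "FDB",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Clean a screening library to (public_id, name, canonical_smiles).

    Invalid structures are dropped and logged; multi-fragment records are
    optionally reduced to their largest fragment before canonicalization;
    duplicates on canonical SMILES keep the first occurrence. Missing ids are
    generated sequentially as zero-padded six-digit identifiers.
    """
    if smiles_col not in raw.columns:
        raise KeyError(f"screening table needs a {smiles_col!r} column")
    canonical, dropped = audit_structures(raw[smiles_col], keep_largest=keep_largest)
    kept = raw.loc[canonical.index].copy()
    kept["canonical_smiles"] = canonical
    if id_col is not None and id_col in raw.columns and raw[id_col].notna().all():
        kept["public_id"] = kept[id_col].astype(str)
    else:
        kept["public_id"] = [f"{id_prefix}{i + 1:06d}" for i in range(len(kept))]
    if name_col is not None and name_col in raw.columns:
        kept["name"] = kept[name_col].astype(str)
    else:
        kept["name"] = kept["public_id"]
    kept = kept.drop_duplicates(subset="canonical_smiles", keep="first")
    library = kept[["public_id", "name", "canonical_smiles"]].reset_index(drop=True)
    return library, dropped


def sha256_file(path: str | Path) -> str:
    """SHA-256 hex digest of a file's raw bytes (provenance checksums)."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_audit_json(audit: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(audit, indent=2, sort_keys=True) + "\n")
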