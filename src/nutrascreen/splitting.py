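"""Scaffold-grouped train/validation/test partitioning.

All molecules sharing a Bemis–Murcko scaffold are assigned to the same
subset. Groups are ordered by size, permuted under a fixed seed, and
assigned greedily: each group goes to the subset whose compound count is
furthest below its target (0.8/0.1/0.1 of the dataset by default), with ties
resolved in train > val > test priority. No scaffold group ever spans
subsets; empty scaffolds (acyclic molecules) form one shared group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import murcko_scaffold

__all__ = ["ScaffoldSplit", "group_by_scaffold", "assign_split", "summarize_split", "split_dataset"]

SUBSETS = ("train", "val", "test")
DEFAULT_FRACTIONS = (0.8, 0.1, 0.1)


@dataclass
class ScaffoldSplit:
    """Compound → subset assignment for one seed with scaffold integrity."""

    assignments: dict
    seed: int
    fractions: tuple = DEFAULT_FRACTIONS

    def subset_ids(self, subset: str) -> list:
        return [cid for cid, s in self.assignments.items() if s == subset]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "compound_id": list(self.assignments.keys()),
                "subset": list(self.assignments.values()),
                "seed": self.seed,
            }
        )


def group_by_scaffold(
    table: pd.DataFrame, id_col: str = "compound_id", scaffold_col: str = "scaffold"
) -> dict[str, list]:
    """Map scaffold SMILES → member compound ids (insertion-ordered).

    If the table lacks a scaffold column it is computed from ``smiles``.
    The empty scaffold is one ordinary group.
    """
    work = table
    if scaffold_col not in work.columns:
        if "smiles" not in work.columns:
            raise KeyError("need a scaffold column or a smiles column")
        work = work.copy()
        work[scaffold_col] = [murcko_scaffold(s) for s in work["smiles"]]
    groups: dict[str, list] = {}
    for cid, scaf in zip(work[id_col], work[scaffold_col]):
        key = "" if pd.isna(scaf) else str(scaf)
        groups.setdefault(key, []).append(cid)
    return groups


def assign_split(
    groups: dict[str, list],
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS,
    seed: int = 1,
    strategy: str = "largest_deficit",
) -> ScaffoldSplit:
    """Assign whole scaffold groups to train/val/test.

    Groups are ranked by size (descending, scaffold string as tie-break),
    permuted by a generator seeded with ``seed``, and assigned in that order.
    ``largest_deficit`` (default) sends each group to the subset whose current
    compound count is furthest below its target count; ``sequential_fill``
    fills train to its target, then val, then test.
    """
    if not groups:
        raise ValueError("cannot split an empty dataset")
    if abs(sum(fractions) - 1.0) > 1e-9 or len(fractions) != 3:
        raise ValueError("fractions must be three values summing to 1")
    items = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(items))
    n_total = sum(len(v) for _, v in items)
    targets = np.array(fractions, dtype=float) * n_total
    counts = np.zeros(3)
    assignments: dict = {}
    for pos in order:
        scaffold, members = items[pos]
        if strategy == "largest_deficit":
            deficits = targets - counts
            subset_idx = int(np.argmax(deficits))  # argmax → train > val > test on ties
        elif strategy == "sequential_fill":
            subset_idx = int(np.argmax(counts < targets)) if (counts < targets).any() else 2
        else:
            raise ValueError(f"unknown assignment strategy {strategy!r}")
        counts[subset_idx] += len(members)
        for cid in members:
            assignments[cid] = SUBSETS[subset_idx]
    return ScaffoldSplit(assignments=assignments, seed=seed, fractions=tuple(fractions))


def summarize_split(split: ScaffoldSplit, table: pd.DataFrame) -> pd.DataFrame:
    """Per-subset compound, scaffold, and positive counts.

    ``table`` needs ``compound_id``; ``scaffold`` and ``label`` columns are
    used when present. Subsets with no members are reported with zeros.
    """
    work = table.copy()
    work["subset"] = work["compound_id"].map(split.assignments)
    rows = []
    for subset in SUBSETS:
        sub = work[work["subset"] == subset]
        rows.append(
            {
                "subset": subset,
                "seed": split.seed,
                "n_compounds": int(len(sub)),
                "n_scaffolds": int(sub["scaffold"].nunique()) if "scaffold" in sub else np.nan,
                "n_positive": int(sub["label"].sum()) if "label" in sub else np.nan,
            }
        )
    return pd.DataFrame(rows)


def split_dataset(
    table: pd.DataFrame,
    seeds: tuple[int, ...] = (1, 2, 3),
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS,
    smiles_col: str = "canonical_smiles",
) -> dict[int, pd.DataFrame]:
    """Convenience wrapper: compute scaffolds once, split for each seed.

    Returns seed → copy of ``table`` with added ``scaffold`` and ``subset``
    columns (plus ``seed``), mirroring an exported split table.
    """
    work = table.copy()
    if "scaffold" not in work.columns:
        work["scaffold"] = [murcko_scaffold(s) for s in work[smiles_col]]
    groups = group_by_scaffold(work)
    out = {}
    for seed in seeds:
        split = assign_split(groups, fractions=fractions, seed=seed)
        frame = work.copy()
        frame["subset"] = frame["compound_id"].map(split.assignments)
        frame["seed"] = seed
        out[seed] = frame
    return out
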