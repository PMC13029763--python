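"""Applicability domain and stratified error analysis.

Domain membership is defined by the maximum Tanimoto similarity of a query
fingerprint to the combined train+val reference set: max_sim ≥ 0.35 is
in-domain (inclusive). Performance is additionally stratified over fixed
similarity bins, descriptor and probability quartiles, and the frequency of
each test scaffold within train+val.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .features import tanimoto_matrix
from .modeling import evaluate

__all__ = [
    "AD_THRESHOLD",
    "SIMILARITY_BIN_EDGES",
    "SCAFFOLD_FREQUENCY_BINS",
    "similarity_to_reference",
    "classify_domain",
    "scaffold_frequency",
    "stratify_performance",
    "aggregate_strata",
]

AD_THRESHOLD = 0.35

# Half-open [lo, hi) bins, last bin closed at 1.0. The 0.35 edge aligns the
# third bin's onset exactly with in-domain membership.
SIMILARITY_BIN_EDGES = (0.0, 0.20, 0.35, 0.50, 0.70, 1.00)
SIMILARITY_BIN_LABELS = ("0.00-0.20", "0.20-0.35", "0.35-0.50", "0.50-0.70", "0.70-1.00")

SCAFFOLD_FREQUENCY_BINS = ("0 (unseen scaffold)", "1", "2-5", "6-20", ">=21")

DESCRIPTOR_DIMENSIONS = ("mw", "logp", "tpsa", "hbd", "hba", "rotatable_bonds", "ring_count")


def similarity_to_reference(
    query_fps: np.ndarray, reference_fps: np.ndarray, query_ids=None
) -> pd.DataFrame:
    """Exact max and top-5-mean Tanimoto of each query against the reference.

    With fewer than five reference compounds the top-5 mean is the mean over
    all of them, so top5_mean ≤ max_sim always holds.
    """
    ref = np.atleast_2d(np.asarray(reference_fps))
    if ref.shape[0] == 0:
        raise ValueError("reference fingerprint set must be non-empty")
    sims = tanimoto_matrix(np.atleast_2d(np.asarray(query_fps)), ref)
    k = min(5, sims.shape[1])
    top_k = -np.partition(-sims, k - 1, axis=1)[:, :k]
    out = pd.DataFrame(
        {
            "max_sim": sims.max(axis=1),
            "top5_mean": top_k.mean(axis=1),
        }
    )
    if query_ids is not None:
        out.insert(0, "compound_id", list(query_ids))
    return out


def classify_domain(max_sim, threshold: float = AD_THRESHOLD) -> np.ndarray:
    """In-domain flag per compound: inclusive max_sim ≥ threshold."""
    sims = np.asarray(max_sim, dtype=float)
    if ((sims < 0) | (sims > 1)).any():
        raise ValueError("similarities must lie in [0, 1]")
    return sims >= threshold


def similarity_bin(max_sim) -> pd.Categorical:
    """Assign each similarity to its fixed bin; every value maps to one bin."""
    sims = np.asarray(max_sim, dtype=float)
    edges = np.asarray(SIMILARITY_BIN_EDGES)
    idx = np.clip(np.searchsorted(edges, sims, side="right") - 1, 0, 4)
    return pd.Categorical(
        [SIMILARITY_BIN_LABELS[i] for i in idx], categories=SIMILARITY_BIN_LABELS
    )


def scaffold_frequency(
    test_scaffolds, trainval_scaffolds
) -> pd.DataFrame:
    """Occurrence count of each test scaffold within train+val, with its bin.

    The empty scaffold is treated as one shared group: its count is the
    number of empty-scaffold train+val compounds.
    """
    ref_counts = pd.Series(list(trainval_scaffolds)).fillna("").value_counts()
    counts = [int(ref_counts.get("" if pd.isna(s) else s, 0)) for s in test_scaffolds]
    bins = []
    for c in counts:
        if c == 0:
            bins.append(SCAFFOLD_FREQUENCY_BINS[0])
        elif c == 1:
            bins.append(SCAFFOLD_FREQUENCY_BINS[1])
        elif c <= 5:
            bins.append(SCAFFOLD_FREQUENCY_BINS[2])
        elif c <= 20:
            bins.append(SCAFFOLD_FREQUENCY_BINS[3])
        else:
            bins.append(SCAFFOLD_FREQUENCY_BINS[4])
    return pd.DataFrame({"scaffold_count": counts, "scaffold_bin": bins})


def _quartile_bins(values: pd.Series, prefix: str) -> pd.Series:
    """Quartile labels on the given distribution; duplicate edges merged."""
    try:
        binned = pd.qcut(values, 4, duplicates="drop")
    except (ValueError, IndexError):
        return pd.Series([f"{prefix}:all"] * len(values), index=values.index)
    return binned.apply(lambda iv: f"{prefix}:{iv}").astype(str)


def stratify_performance(
    predictions: pd.DataFrame, seed: int | None = None, threshold: float = 0.5
) -> pd.DataFrame:
    """Per-stratum metrics across all slicing dimensions.

    ``predictions`` needs ``probability`` and ``label``; optional columns
    enable dimensions: ``max_sim`` (similarity bins and binary domain),
    descriptor columns (quartiles on this set's distribution),
    ``scaffold_count``/``scaffold_bin`` (frequency bins). Probability
    quartiles are always computed. AUC/AP are the undefined marker in
    single-class strata; MCC and balanced accuracy are always reported.
    Empty strata appear with n=0.
    """
    df = predictions.copy()
    dims: dict[str, pd.Series] = {}
    if "max_sim" in df.columns:
        dims["similarity"] = pd.Series(similarity_bin(df["max_sim"]), index=df.index)
        dims["domain"] = pd.Series(
            np.where(classify_domain(df["max_sim"]), "in-domain", "out-of-domain"),
            index=df.index,
        )
    for col in DESCRIPTOR_DIMENSIONS:
        if col in df.columns:
            dims[col] = _quartile_bins(df[col].astype(float), col)
    dims["probability"] = _quartile_bins(df["probability"].astype(float), "prob")
    if "scaffold_bin" in df.columns:
        dims["scaffold_frequency"] = df["scaffold_bin"]
    rows = []
    for dim, labels in dims.items():
        observed = pd.Series(labels)
        if isinstance(labels.dtype, pd.CategoricalDtype):
            categories = list(labels.dtype.categories)
        elif dim == "scaffold_frequency":
            categories = [b for b in SCAFFOLD_FREQUENCY_BINS]
        else:
            categories = sorted(observed.dropna().unique())
        for stratum in categories:
            mask = (observed == stratum).to_numpy()
            if mask.sum() == 0:
                rows.append(
                    {
                        "dimension": dim,
                        "stratum": str(stratum),
                        "seed": seed,
                        "n": 0,
                        "auc": None,
                        "ap": None,
                        "mcc": None,
                        "balanced_accuracy": None,
                    }
                )
                continue
            ev = evaluate(
                df.loc[mask, "probability"], df.loc[mask, "label"], threshold=threshold
            )
            rows.append(
                {
                    "dimension": dim,
                    "stratum": str(stratum),
                    "seed": seed,
                    "n": int(mask.sum()),
                    "auc": ev["auc"],
                    "ap": ev["ap"],
                    "mcc": ev["mcc"],
                    "balanced_accuracy": ev["balanced_accuracy"],
                }
            )
    return pd.DataFrame(rows)


def aggregate_strata(per_seed_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Mean ± sample SD of each metric per (dimension, stratum) across seeds."""
    allrows = pd.concat(per_seed_tables, ignore_index=True)
    rows = []
    for (dim, stratum), grp in allrows.groupby(["dimension", "stratum"], sort=False):
        row = {"dimension": dim, "stratum": stratum, "n_total": int(grp["n"].sum())}
        for metric in ("auc", "ap", "mcc", "balanced_accuracy"):
            vals = grp[metric].dropna().astype(float)
            row[f"{metric}_mean"] = float(vals.mean()) if len(vals) else None
            row[f"{metric}_sd"] = (
                float(vals.std(ddof=1)) if len(vals) > 1 else (0.0 if len(vals) else None)
            )
        rows.append(row)
    return pd.DataFrame(rows)
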