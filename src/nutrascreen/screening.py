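"""Ensemble virtual screening, ranking, AD annotation, embedding, diversity picks.

Per-seed models score the prepared library; per-compound mean probability
and inter-seed SD drive a deterministic ranking. Applicability domain labels
reuse the similarity machinery against the seed-1 train+val reference.
Redundancy among candidates is reduced with sphere-exclusion (Butina)
clustering at Tanimoto distance 0.35, keeping the highest-scoring compound
of each cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .domain import AD_THRESHOLD, classify_domain, similarity_to_reference
from .features import tanimoto_matrix

__all__ = [
    "ensemble_score",
    "select_top",
    "ad_annotate",
    "embed",
    "butina_select",
    "ClusterSelection",
]


def ensemble_score(models: list, library_fps: np.ndarray, public_ids) -> pd.DataFrame:
    """Mean and inter-seed SD of predicted probabilities, with ranks.

    SD is the sample SD across seed models (0 for a single model). Ranking is
    by descending mean probability with ties broken by public id, so the
    output order is fully deterministic.
    """
    if not models:
        raise ValueError("need at least one seed model")
    X = np.asarray(library_fps)
    if X.ndim != 2:
        raise ValueError("library fingerprints must be a 2-D matrix")
    probs = np.stack([m.predict_proba(X)[:, 1] for m in models])
    mean = probs.mean(axis=0)
    sd = probs.std(axis=0, ddof=1) if probs.shape[0] > 1 else np.zeros_like(mean)
    out = pd.DataFrame({"public_id": list(public_ids), "mean_prob": mean, "sd_prob": sd})
    out = out.sort_values(
        ["mean_prob", "public_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def select_top(scores: pd.DataFrame, n: int = 200) -> pd.DataFrame:
    """Top-n rows by rank (everything if n exceeds the library size)."""
    return scores.nsmallest(min(n, len(scores)), "rank").reset_index(drop=True)


def ad_annotate(
    scores: pd.DataFrame,
    library_fps: np.ndarray,
    reference_fps: np.ndarray,
    public_ids,
    threshold: float = AD_THRESHOLD,
) -> tuple[pd.DataFrame, dict]:
    """Attach max similarity and in-domain flags to the score table.

    The reference is the combined train+val fingerprint set of the seed-1
    scaffold split. Returns the annotated table and in/out counts (overall);
    in + out always equals the library size.
    """
    sims = similarity_to_reference(library_fps, reference_fps, query_ids=public_ids)
    sims["in_domain"] = classify_domain(sims["max_sim"], threshold=threshold)
    out = scores.merge(
        sims[["compound_id", "max_sim", "in_domain"]],
        left_on="public_id",
        right_on="compound_id",
        how="left",
    ).drop(columns="compound_id")
    counts = {
        "in_domain": int(out["in_domain"].sum()),
        "out_of_domain": int((~out["in_domain"]).sum()),
        "total": int(len(out)),
    }
    return out, counts


def embed(
    library_fps: np.ndarray,
    public_ids,
    seed: int = 1,
    subsample_size: int | None = None,
    top_ids=(),
    n_neighbors: int = 25,
    min_dist: float = 0.10,
    max_pca_components: int = 50,
) -> pd.DataFrame:
    """2-D chemical-space embedding: PCA (≤50 components) then UMAP.

    Large libraries are embedded on a seeded random subsample with forced
    inclusion of all ``top_ids``. Rows flag subsample membership; compounds
    outside the subsample are absent from the output.
    """
    import umap

    from sklearn.decomposition import PCA

    X = np.asarray(library_fps, dtype=float)
    ids = list(public_ids)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 compounds to embed")
    rng = np.random.default_rng(seed)
    idx = np.arange(X.shape[0])
    if subsample_size is not None and subsample_size < X.shape[0]:
        forced = np.flatnonzero(np.isin(ids, list(top_ids)))
        others = np.setdiff1d(idx, forced)
        n_extra = max(0, subsample_size - forced.size)
        extra = rng.choice(others, size=min(n_extra, others.size), replace=False)
        idx = np.sort(np.concatenate([forced, extra]))
    Xs = X[idx]
    n_comp = min(max_pca_components, Xs.shape[0] - 1, Xs.shape[1])
    reduced = PCA(n_components=n_comp, random_state=seed).fit_transform(Xs)
    reducer = umap.UMAP(
        n_neighbors=min(n_neighbors, Xs.shape[0] - 1),
        min_dist=min_dist,
        random_state=seed,
    )
    coords = reducer.fit_transform(reduced)
    return pd.DataFrame(
        {
            "public_id": [ids[i] for i in idx],
            "x": coords[:, 0],
            "y": coords[:, 1],
            "in_subsample": True,
        }
    )


@dataclass
class ClusterSelection:
    """One sphere-exclusion cluster with its centroid and best-scoring member."""

    cluster_id: int
    centroid_id: str
    member_ids: list
    representative_id: str


def butina_select(
    candidate_fps: np.ndarray,
    scores: pd.DataFrame,
    cutoff: float = 0.35,
    shortlist_n: int = 20,
) -> tuple[list[ClusterSelection], pd.DataFrame]:
    """Sphere-exclusion diversity selection over scored candidates.

    Neighbor lists are built at Tanimoto distance ≤ cutoff. Iteratively, the
    unassigned compound with the most unassigned neighbors becomes a
    centroid (ties → higher ensemble score, then smaller public id) and
    claims its unassigned neighbors as a cluster. Every member therefore
    lies within the cutoff of its centroid. Per cluster the highest-scoring
    member is the representative; the shortlist is the top ``shortlist_n``
    representatives by score.

    ``scores`` rows must align with ``candidate_fps`` rows and carry
    ``public_id`` and ``mean_prob``.
    """
    X = np.asarray(candidate_fps)
    n = X.shape[0]
    if n == 0:
        raise ValueError("no candidates to cluster")
    if len(scores) != n:
        raise ValueError("scores and fingerprints must align row-for-row")
    ids = scores["public_id"].astype(str).to_numpy()
    prob = scores["mean_prob"].to_numpy(float)
    dist = 1.0 - tanimoto_matrix(X, X)
    neighbors = [set(np.flatnonzero(dist[i] <= cutoff)) - {i} for i in range(n)]
    unassigned = set(range(n))
    clusters: list[ClusterSelection] = []
    while unassigned:
        # most unassigned neighbors; ties → higher score, then smaller id
        best = min(
            unassigned,
            key=lambda i: (-len(neighbors[i] & unassigned), -prob[i], ids[i]),
        )
        members = ({best} | (neighbors[best] & unassigned))
        order = sorted(members, key=lambda i: (-prob[i], ids[i]))
        clusters.append(
            ClusterSelection(
                cluster_id=len(clusters),
                centroid_id=ids[best],
                member_ids=[ids[i] for i in sorted(members)],
                representative_id=ids[order[0]],
            )
        )
        unassigned -= members
    rep_ids = [c.representative_id for c in clusters]
    shortlist = (
        scores[scores["public_id"].astype(str).isin(rep_ids)]
        .sort_values(["mean_prob", "public_id"], ascending=[False, True], kind="mergesort")
        .head(shortlist_n)
        .reset_index(drop=True)
    )
    return clusters, shortlist
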