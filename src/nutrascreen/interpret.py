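"""Model interpretation: feature attribution, bit environments, R-group series.

Attribution is exactly additive per sample (base value plus the per-feature
contributions reconstruct the model output). The route is matched to the
model family: tree-path attribution for tree ensembles — contributions
accumulate the change in node value along each decision path — exact linear
attribution for logistic models, the native per-feature contribution output
for xgboost, and a seeded permutation-sampling estimator otherwise.
Fingerprint bits are mapped back to the atom-centered environments that set
them, and top-scoring screening series are summarized by R-group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline

from .features import (
    DEFAULT_FP_PARAMS,
    FingerprintParams,
    fingerprint_bit_info,
    mol_from_smiles,
    murcko_scaffold,
)

__all__ = [
    "AttributionMatrix",
    "RGroupResult",
    "attribute",
    "attribution_output",
    "global_importance",
    "map_bit_environments",
    "rgroup_series",
]


@dataclass
class AttributionMatrix:
    """Signed per-sample, per-feature attributions for the positive class.

    ``scale`` records the output scale on which additivity holds:
    ``probability`` for forests and the sampling route, ``log_odds`` for
    boosted trees and linear models.
    """

    values: np.ndarray
    base_value: float
    sample_indices: np.ndarray
    seed: int
    scale: str

    @property
    def mean_abs(self) -> np.ndarray:
        return np.abs(self.values).mean(axis=0)


def _unwrap(model, X_explain, X_background):
    """Push data through pipeline transforms so attribution sees the final step."""
    if isinstance(model, Pipeline):
        transformer = model[:-1]
        if len(transformer) > 0:
            X_explain = transformer.transform(X_explain)
            X_background = transformer.transform(X_background)
        return model[-1], np.asarray(X_explain, float), np.asarray(X_background, float)
    return model, np.asarray(X_explain, float), np.asarray(X_background, float)


def _tree_path_single(tree, X, values_per_node, phi, scale=1.0):
    """Accumulate path contributions of one fitted tree into ``phi``.

    Walks all samples level-synchronously; at each internal node the change
    in node value toward the taken child is credited to the split feature.
    Returns the per-sample leaf values (for base/consistency computations).
    """
    left = tree.children_left
    right = tree.children_right
    feat = tree.feature
    thresh = tree.threshold
    n = X.shape[0]
    cur = np.zeros(n, dtype=np.int64)
    active = left[cur] != -1
    while active.any():
        idx = np.flatnonzero(active)
        nodes = cur[idx]
        f = feat[nodes]
        go_left = X[idx, f] <= thresh[nodes]
        nxt = np.where(go_left, left[nodes], right[nodes])
        np.add.at(phi, (idx, f), scale * (values_per_node[nxt] - values_per_node[nodes]))
        cur[idx] = nxt
        active[idx] = left[nxt] != -1
    return values_per_node[cur]


def _attribute_forest(model: RandomForestClassifier, X):
    phi = np.zeros_like(X, dtype=float)
    base = 0.0
    for est in model.estimators_:
        t = est.tree_
        v = t.value[:, 0, :]
        prob1 = v[:, 1] / v.sum(axis=1)
        _tree_path_single(t, X, prob1, phi, scale=1.0 / len(model.estimators_))
        base += prob1[0] / len(model.estimators_)
    return phi, float(base), "probability"


def _attribute_gbm(model: GradientBoostingClassifier, X):
    lr = model.learning_rate
    phi = np.zeros_like(X, dtype=float)
    leaf_sum = np.zeros(X.shape[0])
    root_sum = 0.0
    for stage in model.estimators_[:, 0]:
        t = stage.tree_
        v = t.value[:, 0, 0]
        leaf_sum += lr * _tree_path_single(t, X, v, phi, scale=lr)
        root_sum += lr * v[0]
    # constant initial raw score, recovered from any sample
    c0 = float(model.decision_function(X[:1])[0] - leaf_sum[0])
    return phi, c0 + float(root_sum), "log_odds"


def _attribute_linear(model: LogisticRegression, X, background):
    mu = background.mean(axis=0)
    coef = model.coef_[0]
    phi = (X - mu) * coef
    base = float(model.intercept_[0] + coef @ mu)
    return phi, base, "log_odds"


def _attribute_xgb(model, X):
    import xgboost as xgb

    contribs = model.get_booster().predict(
        xgb.DMatrix(np.asarray(X, dtype=np.float32)), pred_contribs=True
    )
    return contribs[:, :-1].astype(float), float(contribs[0, -1]), "log_odds"


def _attribute_sampling(model, X, background, rng, n_permutations=32):
    """Permutation-sampling Shapley estimate on the probability scale.

    Only features where the sample differs from the drawn background row can
    receive credit, which keeps the cost proportional to the Hamming
    distance — appropriate for sparse binary fingerprints.
    """

    def f(rows):
        return model.predict_proba(rows)[:, 1]

    phi = np.zeros_like(X, dtype=float)
    base = float(f(background).mean())
    for i in range(X.shape[0]):
        x = X[i]
        for _ in range(n_permutations):
            z = background[rng.integers(0, background.shape[0])].copy()
            diff = np.flatnonzero(x != z)
            order = rng.permutation(diff)
            prev = f(z[None, :])[0]
            for j in order:
                z[j] = x[j]
                nxt = f(z[None, :])[0]
                phi[i, j] += (nxt - prev) / n_permutations
                prev = nxt
    return phi, base, "probability"


def attribute(
    model,
    X_pool: np.ndarray,
    seed: int,
    max_explain: int = 2000,
    max_background: int = 200,
) -> AttributionMatrix:
    """Attribute positive-class output over a sampled explain set.

    Up to ``max_explain`` rows of ``X_pool`` are sampled without replacement
    for explanation and up to ``max_background`` rows as the reference
    distribution, both under ``seed``. The explainer route is dispatched on
    the (possibly pipeline-wrapped) final estimator class.
    """
    X_pool = np.asarray(X_pool)
    n = X_pool.shape[0]
    if n == 0:
        raise ValueError("empty explanation pool")
    rng = np.random.default_rng(seed)
    explain_idx = np.sort(rng.choice(n, size=min(n, max_explain), replace=False))
    background_idx = np.sort(rng.choice(n, size=min(n, max_background), replace=False))
    if background_idx.size == 0:
        raise ValueError("empty background set")
    est, X, bg = _unwrap(model, X_pool[explain_idx], X_pool[background_idx])
    if isinstance(est, RandomForestClassifier):
        phi, base, scale = _attribute_forest(est, X)
    elif isinstance(est, GradientBoostingClassifier):
        phi, base, scale = _attribute_gbm(est, X)
    elif isinstance(est, LogisticRegression):
        phi, base, scale = _attribute_linear(est, X, bg)
    elif type(est).__name__ == "XGBClassifier":
        phi, base, scale = _attribute_xgb(est, X)
    else:
        phi, base, scale = _attribute_sampling(est, X, bg, rng)
    return AttributionMatrix(
        values=phi, base_value=base, sample_indices=explain_idx, seed=seed, scale=scale
    )


def attribution_output(model, X_pool: np.ndarray, matrix: AttributionMatrix) -> np.ndarray:
    """Model output on the attribution scale for the explained samples.

    Use to check additivity: base + row-sum of attributions ≈ this output.
    """
    est, X, _ = _unwrap(model, X_pool[matrix.sample_indices], X_pool[matrix.sample_indices])
    if matrix.scale == "probability":
        return est.predict_proba(X)[:, 1]
    return est.decision_function(X)


def global_importance(matrices: list[AttributionMatrix]) -> pd.DataFrame:
    """Cross-seed feature importance: mean and sample SD of within-seed mean |φ|.

    One row per feature, ranked by descending cross-seed mean.
    """
    if not matrices:
        raise ValueError("need at least one attribution matrix")
    per_seed = np.stack([m.mean_abs for m in matrices])
    mean = per_seed.mean(axis=0)
    sd = per_seed.std(axis=0, ddof=1) if per_seed.shape[0] > 1 else np.zeros_like(mean)
    out = pd.DataFrame(
        {
            "feature": np.arange(per_seed.shape[1]),
            "mean_abs": mean,
            "sd_abs": sd,
        }
    )
    return out.sort_values(
        ["mean_abs", "feature"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def map_bit_environments(
    bit: int,
    smiles_list,
    params: FingerprintParams = DEFAULT_FP_PARAMS,
    ids=None,
) -> pd.DataFrame:
    """Atom-centered environments that set ``bit`` across a compound set.

    For every compound activating the bit, each (center atom, radius) pair
    hashing to it is reported with the induced substructure as SMILES. Hash
    collisions are expected: one bit may map to several distinct
    environments, and all are reported. An unactivated bit yields an empty
    table.
    """
    if not (0 <= bit < params.n_bits):
        raise IndexError(f"bit {bit} outside [0, {params.n_bits})")
    ids = list(ids) if ids is not None else list(range(len(smiles_list)))
    rows = []
    for cid, smi in zip(ids, smiles_list):
        _, bitinfo = fingerprint_bit_info(smi, params)
        if bit not in bitinfo:
            continue
        mol = mol_from_smiles(smi)
        for atom, radius in bitinfo[bit]:
            if radius == 0:
                env_smiles = Chem.MolFragmentToSmiles(mol, atomsToUse=[atom])
            else:
                bonds = Chem.FindAtomEnvironmentOfRadiusN(mol, radius, atom)
                submol = Chem.PathToSubmol(mol, bonds)
                env_smiles = Chem.MolToSmiles(submol)
            rows.append(
                {
                    "bit": bit,
                    "compound_id": cid,
                    "center_atom": int(atom),
                    "radius": int(radius),
                    "environment_smiles": env_smiles,
                }
            )
    return pd.DataFrame(
        rows, columns=["bit", "compound_id", "center_atom", "radius", "environment_smiles"]
    )


@dataclass
class RGroupResult:
    """R-group series summary around a modal scaffold core."""

    core: str | None
    n_series: int
    n_unmatched: int
    series_mean_score: float | None
    positions: dict = field(default_factory=dict)
    grid: pd.DataFrame | None = None

    @property
    def has_series(self) -> bool:
        return self.core is not None


def _canonical_fragment(frag_smiles: str) -> str:
    mol = Chem.MolFromSmiles(frag_smiles)
    return Chem.MolToSmiles(mol) if mol is not None else frag_smiles


def rgroup_series(
    scored: pd.DataFrame,
    smiles_col: str = "canonical_smiles",
    score_col: str = "mean_prob",
    scaffold_col: str = "scaffold",
    min_series_size: int = 10,
    min_substituent_count: int = 2,
    pair_support: int = 3,
) -> RGroupResult:
    """Decompose the dominant scaffold series of a scored compound set.

    The core is the most frequent non-empty Murcko scaffold meeting
    ``min_series_size`` (ties → higher mean score, then lexicographically
    smaller SMILES). Members are decomposed against the core; substituents
    are canonicalized so identical fragments unify across members. Each
    position gets per-substituent counts and mean scores (substituents under
    ``min_substituent_count`` are flagged as excluded from comparisons), and
    the R1×R2 grid reports mean scores only for combinations observed in at
    least ``pair_support`` compounds.
    """
    from rdkit.Chem import rdRGroupDecomposition as rgd

    df = scored.copy()
    if scaffold_col not in df.columns:
        df[scaffold_col] = [murcko_scaffold(s) for s in df[smiles_col]]
    counts = df[df[scaffold_col] != ""][scaffold_col].value_counts()
    eligible = counts[counts >= min_series_size]
    if eligible.empty:
        return RGroupResult(core=None, n_series=0, n_unmatched=0, series_mean_score=None)
    top_count = eligible.max()
    tied = eligible[eligible == top_count].index
    if len(tied) > 1:
        means = {
            s: df.loc[df[scaffold_col] == s, score_col].mean() for s in tied
        }
        best_mean = max(means.values())
        tied = sorted(s for s, m in means.items() if m == best_mean)
    core = sorted(tied)[0] if len(tied) > 1 else tied[0]
    members = df[df[scaffold_col] == core].reset_index(drop=True)
    mols = [mol_from_smiles(s) for s in members[smiles_col]]
    decomposed, unmatched = rgd.RGroupDecompose(
        [Chem.MolFromSmiles(core)], mols, asSmiles=True
    )
    matched_idx = [i for i in range(len(mols)) if i not in set(unmatched)]
    scores = members.loc[matched_idx, score_col].to_numpy(float)
    series_mean = float(scores.mean()) if len(scores) else None
    rg_rows = pd.DataFrame(decomposed)
    positions = {}
    pos_cols = [c for c in rg_rows.columns if c.startswith("R")]
    for pos in pos_cols:
        frags = rg_rows[pos].map(_canonical_fragment)
        tbl = (
            pd.DataFrame({"substituent": frags, "score": scores})
            .groupby("substituent", sort=False)
            .agg(count=("score", "size"), mean_score=("score", "mean"))
            .reset_index()
        )
        tbl["included"] = tbl["count"] >= min_substituent_count
        positions[pos] = tbl.sort_values(
            ["count", "substituent"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
    grid = None
    if {"R1", "R2"}.issubset(rg_rows.columns):
        pairs = pd.DataFrame(
            {
                "R1": rg_rows["R1"].map(_canonical_fragment),
                "R2": rg_rows["R2"].map(_canonical_fragment),
                "score": scores,
            }
        )
        grid = (
            pairs.groupby(["R1", "R2"], sort=False)
            .agg(support=("score", "size"), mean_score=("score", "mean"))
            .reset_index()
        )
        grid = grid[grid["support"] >= pair_support].reset_index(drop=True)
    return RGroupResult(
        core=core,
        n_series=len(matched_idx),
        n_unmatched=len(unmatched),
        series_mean_score=series_mean,
        positions=positions,
        grid=grid,
    )
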