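"""Shared fixtures.

``default_study`` runs the full default-conditions modeling study once per
session (synthetic data at default generator settings, scaffold splits for
seeds 1–3, a tuned random forest per seed, permuted-label controls, and
per-seed attribution matrices); several end-to-end tests share it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from nutrascreen.curation import curate
from nutrascreen.features import fingerprint_matrix, murcko_scaffold
from nutrascreen.interpret import attribute
from nutrascreen.modeling import ModelConfig, evaluate, oof_predict, tune_and_fit
from nutrascreen.splitting import assign_split, group_by_scaffold
from nutrascreen.structures import audit_structures, deduplicate_structures
from nutrascreen.synth import SyntheticSpec, generate_activity_table


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    return SyntheticSpec(n_compounds=200, n_scaffold_families=30, n_library=120, seed=11)


@pytest.fixture(scope="session")
def small_tables(small_spec):
    activity, truth = generate_activity_table(small_spec)
    return activity, truth


def _modeling_table(spec: SyntheticSpec) -> pd.DataFrame:
    activity, truth = generate_activity_table(spec)
    compounds, _ = curate(activity)
    canonical, _ = audit_structures(compounds["smiles"], keep_largest=True)
    valid = compounds.loc[canonical.index].copy()
    valid["canonical_smiles"] = canonical
    valid = valid.rename(columns={"pactivity": "pic50"})
    dedup, _ = deduplicate_structures(valid)
    dedup["scaffold"] = [murcko_scaffold(s) for s in dedup["canonical_smiles"]]
    return dedup, truth


@pytest.fixture(scope="session")
def default_study():
    """Default-conditions study: 3 scaffold-split seeds, tuned random forest.

    Search effort is reduced relative to the library default (5 sampled
    configurations instead of 25) to keep the session tractable; the data
    conditions themselves are the generator defaults.
    """
    spec = SyntheticSpec()
    dedup, truth = _modeling_table(spec)
    fps = fingerprint_matrix(dedup["canonical_smiles"])
    labels = dedup["label"].to_numpy(int)
    groups = group_by_scaffold(dedup)
    per_seed = {}
    for seed in (1, 2, 3):
        split = assign_split(groups, seed=seed)
        subset = dedup["compound_id"].map(split.assignments)
        trainval = subset.isin(["train", "val"]).to_numpy()
        test = (subset == "test").to_numpy()
        config = ModelConfig(family="random_forest", n_iter=5, cv_folds=5, seed=seed)
        tuned = tune_and_fit(fps[trainval], labels[trainval], config)
        test_probs = tuned.model.predict_proba(fps[test])[:, 1]
        test_eval = evaluate(test_probs, labels[test])
        # permuted-label control: same architecture, shuffled training labels
        rng = np.random.default_rng(seed)
        permuted = rng.permutation(labels[trainval])
        control = clone(tuned.model).fit(fps[trainval], permuted)
        control_eval = evaluate(control.predict_proba(fps[test])[:, 1], labels[test])
        attribution = attribute(tuned.model, fps[trainval], seed=seed)
        per_seed[seed] = {
            "split": split,
            "subset": subset,
            "trainval_mask": trainval,
            "test_mask": test,
            "tuned": tuned,
            "test_probs": test_probs,
            "test_eval": test_eval,
            "control_eval": control_eval,
            "attribution": attribution,
        }
    return {
        "spec": spec,
        "dedup": dedup,
        "truth": truth,
        "fps": fps,
        "labels": labels,
        "per_seed": per_seed,
    }
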