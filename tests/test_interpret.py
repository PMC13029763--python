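"""Attribution additivity and recovery, bit environments, R-group series."""

import numpy as np
import pandas as pd
import pytest
from rdkit import Chem
from sklearn.dummy import DummyClassifier
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from nutrascreen.features import fingerprint_bit_info
from nutrascreen.interpret import (
    attribute,
    attribution_output,
    global_importance,
    map_bit_environments,
    rgroup_series,
)


@pytest.fixture(scope="module")
def binary_data():
    rng = np.random.default_rng(0)
    X = rng.integers(0, 2, (150, 24)).astype(np.uint8)
    y = ((X[:, 3] == 1) | ((X[:, 7] == 1) & (X[:, 11] == 1))).astype(int)
    return X, y


class TestAttribution:
    def test_constant_model_attributes_nothing(self, binary_data):
        X, y = binary_data
        model = DummyClassifier(strategy="prior").fit(X, y)
        mat = attribute(model, X, seed=1, max_explain=10, max_background=20)
        assert np.abs(mat.values).max() < 1e-12

    def test_stump_attribution_sign_matches_effect_direction(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 2, (200, 4)).astype(np.uint8)
        y = X[:, 2]
        model = RandomForestClassifier(n_estimators=20, max_depth=1, random_state=0).fit(X, y)
        mat = attribute(model, X, seed=1, max_explain=100, max_background=50)
        on = X[mat.sample_indices][:, 2] == 1
        assert mat.values[on, 2].mean() > 0
        assert mat.values[~on, 2].mean() < 0

    @pytest.mark.parametrize(
        "factory",
        [
            lambda: RandomForestClassifier(n_estimators=30, random_state=0),
            lambda: GradientBoostingClassifier(n_estimators=30, random_state=0),
            lambda: LogisticRegression(max_iter=500),
        ],
        ids=["forest", "boosting", "linear"],
    )
    def test_additivity_reconstructs_model_output(self, binary_data, factory):
        X, y = binary_data
        model = factory().fit(X, y)
        mat = attribute(model, X, seed=2, max_explain=40, max_background=40)
        out = attribution_output(model, X, mat)
        residual = np.abs(mat.base_value + mat.values.sum(axis=1) - out)
        assert residual.max() < 1e-6

    def test_sampling_fallback_is_approximately_additive(self, binary_data):
        X, y = binary_data
        from sklearn.neighbors import KNeighborsClassifier

        model = KNeighborsClassifier(n_neighbors=5).fit(X, y)
        mat = attribute(model, X, seed=3, max_explain=4, max_background=20)
        assert mat.scale == "probability"
        out = attribution_output(model, X, mat)
        residual = np.abs(mat.base_value + mat.values.sum(axis=1) - out)
        assert residual.max() < 0.2  # sampling estimate, documented looser tolerance

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            attribute(DummyClassifier(), np.zeros((0, 4)), seed=1)


class TestGlobalImportance:
    def test_identical_seeds_have_zero_sd(self, binary_data):
        X, y = binary_data
        model = RandomForestClassifier(n_estimators=10, random_state=0).fit(X, y)
        mat = attribute(model, X, seed=4, max_explain=30, max_background=30)
        imp = global_importance([mat, mat, mat])
        assert (imp["sd_abs"] < 1e-12).all()

    def test_informative_features_rank_first_and_null_last(self, binary_data):
        X, y = binary_data
        X = X.copy()
        X[:, 23] = 0  # constant feature can never split
        model = RandomForestClassifier(n_estimators=50, random_state=0).fit(X, y)
        mat = attribute(model, X, seed=5, max_explain=100, max_background=50)
        imp = global_importance([mat])
        assert {3, 7, 11} & set(imp.head(5)["feature"])
        null_row = imp[imp["feature"] == 23]
        assert null_row["mean_abs"].iloc[0] == 0.0
        assert null_row.index[-1] >= len(imp) - X.shape[1] // 2  # ranked at the bottom


class TestBitEnvironments:
    def test_benzene_bit_lists_all_six_carbons(self):
        _, info = fingerprint_bit_info("c1ccccc1")
        bit = next(b for b, envs in info.items() if envs[0][1] == 0)
        table = map_bit_environments(bit, ["c1ccccc1"], ids=["benzene"])
        assert len(table) == 6
        assert set(table["center_atom"]) == set(range(6))

    def test_out_of_range_bit_raises(self):
        with pytest.raises(IndexError):
            map_bit_environments(2048, ["CCO"])

    def test_unactivated_bit_yields_empty_table(self):
        _, info_benzene = fingerprint_bit_info("c1ccccc1")
        _, info_methane = fingerprint_bit_info("C")
        unused = next(b for b in info_benzene if b not in info_methane)
        assert map_bit_environments(unused, ["C"]).empty

    def test_environment_substructure_matches_and_bit_round_trips(self):
        smiles = ["Cc1ccc(O)cc1", "OCCN", "c1ccncc1C(=O)O"]
        for smi in smiles:
            _, info = fingerprint_bit_info(smi)
            some_bits = sorted(info)[:5]
            mol = Chem.MolFromSmiles(smi)
            for bit in some_bits:
                table = map_bit_environments(bit, [smi])
                assert not table.empty
                for _, row in table.iterrows():
                    # round trip: the recorded (atom, radius) regenerates the bit
                    assert (row["center_atom"], row["radius"]) in info[bit]
                    query = Chem.MolFromSmarts(row["environment_smiles"])
                    if query is not None and row["environment_smiles"]:
                        assert mol.HasSubstructMatch(query)


class TestRGroupSeries:
    def _scored(self, smiles, scores):
        return pd.DataFrame({"canonical_smiles": smiles, "mean_prob": scores})

    def test_degenerate_identical_series(self):
        df = self._scored(["Cc1ccccc1"] * 3, [0.5, 0.5, 0.5])
        res = rgroup_series(df, min_series_size=3, min_substituent_count=1, pair_support=1)
        assert res.has_series and res.core == "c1ccccc1"
        for pos, tbl in res.positions.items():
            assert len(tbl) == 1 and tbl["count"].iloc[0] == 3

    def test_position_counts_sum_to_series_size(self):
        smis = [f"c1ccc({a})cc1{b}" for a in ("C", "O", "N") for b in ("F", "Cl")]
        df = self._scored(smis, np.linspace(0.2, 0.9, len(smis)))
        res = rgroup_series(df, min_series_size=4, min_substituent_count=1, pair_support=1)
        assert res.has_series
        for pos, tbl in res.positions.items():
            assert tbl["count"].sum() == res.n_series

    def test_sparse_pairs_excluded_from_grid(self):
        # each (R1, R2) combination appears exactly twice → below support 3
        smis = [f"c1ccc({a})cc1{b}" for a in ("C", "O") for b in ("F", "Cl")] * 2
        df = self._scored(smis, np.linspace(0.1, 0.9, len(smis)))
        res = rgroup_series(df, min_series_size=4, min_substituent_count=1, pair_support=3)
        if res.grid is not None:
            assert res.grid.empty

    def test_adequately_supported_pairs_appear(self):
        smis = ["c1ccc(C)cc1F"] * 3 + ["c1ccc(O)cc1Cl"] * 3
        df = self._scored(smis, [0.9, 0.8, 0.85, 0.3, 0.2, 0.25])
        res = rgroup_series(df, min_series_size=4, min_substituent_count=1, pair_support=3)
        assert res.grid is not None and len(res.grid) == 2
        assert (res.grid["support"] >= 3).all()

    def test_no_series_when_below_minimum_size(self):
        df = self._scored(["Cc1ccccc1", "CCO"], [0.5, 0.6])
        res = rgroup_series(df, min_series_size=10)
        assert not res.has_series

    def test_beneficial_substituent_scores_above_series_mean(self):
        # carboxyl-bearing members scored high, others low
        smis = ["c1ccc(C(=O)O)cc1"] * 4 + ["c1ccc(C)cc1"] * 4 + ["c1ccc(F)cc1"] * 4
        scores = [0.9] * 4 + [0.4] * 4 + [0.35] * 4
        df = self._scored(smis, scores)
        res = rgroup_series(df, min_series_size=6, min_substituent_count=2, pair_support=3)
        assert res.has_series
        r1 = res.positions["R1"]
        carboxyl = r1[r1["substituent"].str.contains("C\\(=O\\)O|OC\\(.*\\)=O|O=C")]
        assert not carboxyl.empty
        assert carboxyl["mean_score"].iloc[0] > res.series_mean_score
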