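"""Applicability domain, similarity summaries, stratified performance."""

import numpy as np
import pandas as pd
import pytest

from oracles import tanimoto_loops

from nutrascreen.domain import (
    aggregate_strata,
    classify_domain,
    scaffold_frequency,
    similarity_bin,
    similarity_to_reference,
    stratify_performance,
)
from nutrascreen.modeling import evaluate


def _fps(rng, n, width=32):
    return rng.integers(0, 2, (n, width)).astype(np.uint8)


class TestSimilaritySummaries:
    def test_identical_query_has_max_one(self):
        rng = np.random.default_rng(0)
        ref = _fps(rng, 5)
        out = similarity_to_reference(ref[2:3], ref)
        assert out["max_sim"].iloc[0] == pytest.approx(1.0)

    def test_small_reference_uses_all_for_top5(self):
        rng = np.random.default_rng(1)
        ref = _fps(rng, 3)
        query = _fps(rng, 1)
        out = similarity_to_reference(query, ref)
        sims = [tanimoto_loops(query[0], r) for r in ref]
        assert out["top5_mean"].iloc[0] == pytest.approx(np.mean(sims), abs=1e-12)
        assert out["top5_mean"].iloc[0] <= out["max_sim"].iloc[0] + 1e-12

    def test_exhaustive_double_loop_oracle_agreement(self):
        rng = np.random.default_rng(2)
        query, ref = _fps(rng, 8), _fps(rng, 8)
        out = similarity_to_reference(query, ref)
        for i in range(8):
            sims = sorted((tanimoto_loops(query[i], r) for r in ref), reverse=True)
            assert out["max_sim"].iloc[i] == pytest.approx(sims[0], abs=1e-12)
            assert out["top5_mean"].iloc[i] == pytest.approx(np.mean(sims[:5]), abs=1e-12)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            similarity_to_reference(np.ones((1, 8)), np.zeros((0, 8)))


class TestDomainClassification:
    @pytest.mark.parametrize(
        "sim, expected", [(0.35, True), (0.3499, False), (1.0, True), (0.0, False)]
    )
    def test_inclusive_boundary(self, sim, expected):
        assert classify_domain([sim])[0] == expected

    def test_counts_partition_any_library(self):
        rng = np.random.default_rng(3)
        sims = rng.random(200)
        flags = classify_domain(sims)
        assert flags.sum() + (~flags).sum() == 200

    def test_every_similarity_maps_to_exactly_one_bin(self):
        values = [0.0, 0.1999, 0.2, 0.3499, 0.35, 0.4999, 0.5, 0.6999, 0.7, 1.0]
        bins = similarity_bin(values)
        expected = [
            "0.00-0.20", "0.00-0.20", "0.20-0.35", "0.20-0.35", "0.35-0.50",
            "0.35-0.50", "0.50-0.70", "0.50-0.70", "0.70-1.00", "0.70-1.00",
        ]
        assert list(bins) == expected

    def test_bin_onset_aligns_with_domain_threshold(self):
        assert classify_domain([0.35])[0]
        assert similarity_bin([0.35])[0] == "0.35-0.50"


class TestScaffoldFrequency:
    def test_bins_follow_count_edges(self):
        trainval = ["A"] * 6 + ["B"] * 1 + ["C"] * 3 + [""] * 2
        out = scaffold_frequency(["A", "B", "C", "D", ""], trainval)
        assert out["scaffold_count"].tolist() == [6, 1, 3, 0, 2]
        assert out["scaffold_bin"].tolist() == [
            "6-20", "1", "2-5", "0 (unseen scaffold)", "2-5"
        ]

    def test_high_frequency_bin(self):
        out = scaffold_frequency(["A"], ["A"] * 25)
        assert out["scaffold_bin"].iloc[0] == ">=21"


class TestStratification:
    @pytest.fixture()
    def predictions(self):
        rng = np.random.default_rng(4)
        n = 120
        labels = rng.integers(0, 2, n)
        probs = np.clip(labels * 0.5 + rng.random(n) * 0.5, 0, 1)
        return pd.DataFrame(
            {
                "probability": probs,
                "label": labels,
                "max_sim": rng.random(n),
                "mw": rng.normal(300, 60, n),
                "logp": rng.normal(2, 1, n),
                "scaffold_bin": rng.choice(["0 (unseen scaffold)", "1", "2-5"], n),
            }
        )

    def test_stratum_sizes_sum_per_dimension(self, predictions):
        table = stratify_performance(predictions, seed=1)
        for dim, grp in table.groupby("dimension"):
            assert grp["n"].sum() == len(predictions)

    def test_degenerate_single_stratum_equals_global_metrics(self, predictions):
        df = predictions.copy()
        df["max_sim"] = 0.1  # everything in the lowest similarity bin
        table = stratify_performance(df, seed=1)
        sim_rows = table[(table["dimension"] == "similarity") & (table["n"] > 0)]
        assert len(sim_rows) == 1
        global_eval = evaluate(df["probability"], df["label"])
        assert sim_rows["auc"].iloc[0] == pytest.approx(global_eval["auc"])
        assert sim_rows["mcc"].iloc[0] == pytest.approx(global_eval["mcc"])

    def test_single_class_stratum_reports_undefined_auc_but_keeps_mcc(self):
        df = pd.DataFrame(
            {
                "probability": [0.9, 0.8, 0.2, 0.3],
                "label": [1, 1, 0, 1],
                "max_sim": [0.9, 0.9, 0.1, 0.1],
            }
        )
        table = stratify_performance(df, seed=1)
        high = table[(table["dimension"] == "similarity") & (table["stratum"] == "0.70-1.00")]
        assert pd.isna(high["auc"].iloc[0])
        assert pd.notna(high["mcc"].iloc[0])

    def test_probability_quartiles_near_equal_occupancy(self, predictions):
        table = stratify_performance(predictions, seed=1)
        prob_rows = table[table["dimension"] == "probability"]
        # quantile bins: each holds about a quarter (ties allowed)
        direct = pd.qcut(predictions["probability"], 4).value_counts()
        assert sorted(prob_rows["n"]) == sorted(direct)

    def test_empty_stratum_rows_present_with_zero_n(self, predictions):
        df = predictions.copy()
        df["scaffold_bin"] = "1"
        table = stratify_performance(df, seed=1)
        freq = table[table["dimension"] == "scaffold_frequency"]
        assert (freq["n"] == 0).sum() == 4  # other four bins reported empty


def test_aggregate_strata_mean_and_sd():
    per_seed = []
    for seed, auc in zip((1, 2), (0.8, 0.9)):
        per_seed.append(
            pd.DataFrame(
                [{"dimension": "domain", "stratum": "in-domain", "seed": seed, "n": 10,
                  "auc": auc, "ap": 0.9, "mcc": 0.5, "balanced_accuracy": 0.7}]
            )
        )
    agg = aggregate_strata(per_seed)
    assert agg["auc_mean"].iloc[0] == pytest.approx(0.85)
    assert agg["auc_sd"].iloc[0] == pytest.approx(np.std([0.8, 0.9], ddof=1))
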