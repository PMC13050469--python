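"""Interaction scoring: mean-product definition, batch sweep, permutation p."""

import numpy as np
import pandas as pd
import pytest

import herbscreen as hs
from herbscreen.expression import TypeMeanTable

from _naive import naive_interaction_scores
from conftest import make_adata


def _mean_table(data: dict, n_cells=50):
    """Hand-built TypeMeanTable; data maps gene -> {(type, cond): mean}."""
    cols = sorted({k for v in data.values() for k in v})
    means = pd.DataFrame(
        {col: [data[g].get(col, 0.0) for g in sorted(data)] for col in cols},
        index=sorted(data),
    )
    means.columns = pd.MultiIndex.from_tuples(cols, names=["cell_type", "condition"])
    n = pd.Series(n_cells, index=means.columns)
    return TypeMeanTable(means=means, n_cells=n)


class TestInteractionScore:
    def test_direct_product(self):
        table = _mean_table({"L": {("S", "Nor"): 2.0, ("T", "Nor"): 0.5},
                             "R": {("S", "Nor"): 1.0, ("T", "Nor"): 3.0}})
        pair = {"ligand": "L", "receptor": "R"}
        assert hs.interaction_score(table, pair, "S", "T", "Nor") == pytest.approx(6.0)

    def test_zero_mean_annihilates(self):
        table = _mean_table({"L": {("S", "Nor"): 0.0, ("T", "Nor"): 5.0},
                             "R": {("S", "Nor"): 9.0, ("T", "Nor"): 7.0}})
        pair = {"ligand": "L", "receptor": "R"}
        assert hs.interaction_score(table, pair, "S", "T", "Nor") == 0.0

    def test_missing_stratum_raises(self):
        table = _mean_table({"L": {("S", "Nor"): 1.0}, "R": {("S", "Nor"): 1.0}})
        with pytest.raises(KeyError):
            hs.interaction_score(table, {"ligand": "L", "receptor": "R"}, "S", "T", "Nor")

    def test_role_swap_is_directional(self):
        table = _mean_table({"L": {("S", "Nor"): 2.0, ("T", "Nor"): 0.5},
                             "R": {("S", "Nor"): 1.0, ("T", "Nor"): 3.0}})
        pair = {"ligand": "L", "receptor": "R"}
        forward = hs.interaction_score(table, pair, "S", "T", "Nor")
        backward = hs.interaction_score(table, pair, "T", "S", "Nor")
        assert forward != backward


class TestScoreAll:
    def test_counting_two_types_one_pair(self):
        adata = make_adata(n_cells=40, n_genes=4, conditions=("Nor",), types=("T1", "T2"))
        norm = hs.normalize(adata)
        ref = pd.DataFrame({"pair_id": ["P1"], "ligand": ["g00"], "receptor": ["g01"]})
        rec = hs.score_all(norm, ref, min_cells=1)
        assert len(rec) == 4  # 2 x 2 type combinations, autocrine included
        assert set(zip(rec["source"], rec["target"])) == {("T1", "T1"), ("T1", "T2"), ("T2", "T1"), ("T2", "T2")}

    def test_missing_gene_pair_skipped_with_warning(self, small_adata, caplog):
        norm = hs.normalize(small_adata)
        ref = pd.DataFrame({"pair_id": ["P1", "P2"],
                            "ligand": ["g00", "ABSENT"],
                            "receptor": ["g01", "g02"]})
        with caplog.at_level("WARNING"):
            rec = hs.score_all(norm, ref, min_cells=1)
        assert set(rec["pair_id"]) == {"P1"}
        assert "absent" in caplog.text

    def test_requires_normalized_matrix(self, small_adata, small_reference):
        with pytest.raises(ValueError, match="normalized"):
            hs.score_all(small_adata, small_reference)

    def test_deterministic_ordering(self, small_adata, small_reference):
        norm = hs.normalize(small_adata)
        rec = hs.score_all(norm, small_reference, min_cells=1)
        keys = list(zip(rec["pair_id"], rec["source"], rec["target"], rec["condition"]))
        assert keys == sorted(keys)

    def test_matches_naive_recomputation(self, small_adata, small_reference):
        norm = hs.normalize(small_adata)
        rec = hs.score_all(norm, small_reference, min_cells=1)
        naive = naive_interaction_scores(
            np.asarray(norm.X).tolist(),
            list(norm.obs["cell_type"].astype(str)),
            list(norm.obs["condition"].astype(str)),
            list(norm.var_names),
            small_reference,
        )
        assert len(rec) == len(naive)
        for row in rec.itertuples():
            assert row.score == pytest.approx(
                naive[(row.pair_id, row.source, row.target, row.condition)], abs=1e-12
            )

    def test_quadratic_scaling_on_raw_values(self, small_adata):
        """Scaling all (pre-log) expression by c scales every score by c^2."""
        table1 = hs.type_means(small_adata, min_cells=1)
        scaled = small_adata.copy()
        scaled.X = np.asarray(scaled.X) * 3.0
        table2 = hs.type_means(scaled, min_cells=1)
        pair = {"ligand": small_adata.var_names[0], "receptor": small_adata.var_names[1]}
        ct, cond = table1.strata[0]
        s1 = hs.interaction_score(table1, pair, ct, ct, cond)
        s2 = hs.interaction_score(table2, pair, ct, ct, cond)
        assert s2 == pytest.approx(9.0 * s1, rel=1e-12)

    def test_planted_pairs_score_higher_in_effect_conditions(self, default_sim, default_records):
        cfg, _, truth, _ = default_sim
        rec = default_records.set_index(["pair_id", "source", "target", "condition"])["score"]
        better = 0
        for p in truth.planted_pairs.values():
            eff = np.mean([rec[(p.pair_id, p.source, p.target, c)] for c in sorted(p.effect_conditions)])
            ref = rec[(p.pair_id, p.source, p.target, cfg.reference_condition)]
            better += eff > ref
        assert better / len(truth.planted_pairs) >= 0.9


class TestPermutationTest:
    def test_all_ties_give_p_one(self):
        adata = make_adata(n_cells=30, n_genes=2, conditions=("Nor",), types=("T1", "T2"))
        adata.X = np.ones_like(np.asarray(adata.X))
        adata.uns["normalized"] = True
        record = {"ligand": "g00", "receptor": "g01", "source": "T1", "target": "T2", "condition": "Nor"}
        p = hs.permutation_test(adata, record, n_perm=200, seed=0)
        assert p == pytest.approx(1.0)

    def test_extreme_observation_attains_minimum_p(self):
        # ligand expressed only in source cells: observed score is the unique maximum
        adata = make_adata(n_cells=40, n_genes=2, conditions=("Nor",), types=("T1", "T2"), seed=9)
        x = np.zeros((40, 2))
        src = adata.obs["cell_type"] == "T1"
        x[src.to_numpy(), 0] = 10.0
        x[:, 1] = 1.0
        adata.X = x
        adata.uns["normalized"] = True
        record = {"ligand": "g00", "receptor": "g01", "source": "T1", "target": "T2", "condition": "Nor"}
        p = hs.permutation_test(adata, record, n_perm=300, seed=1)
        assert p == pytest.approx(1 / 301)

    def test_input_validation(self, small_adata):
        record = {"ligand": "g00", "receptor": "g01", "source": "T1", "target": "T2", "condition": "Nor"}
        with pytest.raises(ValueError, match="n_perm"):
            hs.permutation_test(small_adata, record, n_perm=10)
        mono = make_adata(n_cells=20, n_genes=2, conditions=("Nor",), types=("T1",))
        with pytest.raises(ValueError, match="cell types"):
            hs.permutation_test(mono, record, n_perm=100)


class TestInteractionCounts:
    def test_threshold_above_all_scores(self, default_records):
        counts = hs.interaction_counts(default_records, threshold=default_records["score"].max() + 1)
        assert (counts["n_interactions"] == 0).all()

    def test_zero_threshold_counts_positive_records(self):
        rec = pd.DataFrame({
            "source": ["A", "A", "B"], "target": ["B", "B", "A"],
            "condition": ["Nor"] * 3, "score": [1.0, 2.0, 3.0],
        })
        counts = hs.interaction_counts(rec, threshold=0.0)
        lut = counts.set_index(["source", "target"])["n_interactions"]
        assert lut[("A", "B")] == 2 and lut[("B", "A")] == 1

    def test_planted_axis_gains_interactions(self):
        """At a stringent score threshold, the planted source->target channels
        accumulate more interactions in effect conditions than at the
        reference (averaged over seeds to beat background fluctuation)."""
        gains = []
        for seed in (7, 8, 9):
            cfg = hs.SimConfig(seed=seed)
            adata, truth = hs.generate_expression(cfg)
            rec = hs.score_all(hs.normalize(adata), hs.generate_lr_reference(cfg))
            thresh = rec.loc[rec["condition"] == cfg.reference_condition, "score"].quantile(0.9)
            counts = hs.interaction_counts(rec, threshold=thresh)
            lut = counts.set_index(["source", "target", "condition"])["n_interactions"]
            for p in truth.planted_pairs.values():
                for c in sorted(p.effect_conditions):
                    gains.append(
                        lut[(p.source, p.target, c)]
                        - lut[(p.source, p.target, cfg.reference_condition)]
                    )
        assert np.mean(gains) > 0
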