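"""Hypergeometric screening, BH adjustment, ranking and standardization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import herbscreen as hs
from herbscreen.enrichment import TargetProfile, profiles_from_table

from _naive import enum_hypergeom_upper, step_up_bh


class TestHypergeomUpper:
    def test_zero_overlap_is_certain(self):
        assert hs.hypergeom_upper(0, 5, 4, 10) == 1.0

    def test_enumerated_examples(self):
        assert hs.hypergeom_upper(4, 5, 4, 10) == pytest.approx(5 / 210, abs=1e-12)
        assert hs.hypergeom_upper(1, 3, 3, 6) == pytest.approx(0.95, abs=1e-12)

    def test_matches_enumeration_small_universes(self):
        for N in range(1, 10):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(K, n) + 1):
                        assert hs.hypergeom_upper(k, K, n, N) == pytest.approx(
                            enum_hypergeom_upper(k, K, n, N), abs=1e-12
                        )

    def test_bounds_validated(self):
        with pytest.raises(ValueError):
            hs.hypergeom_upper(3, 2, 5, 10)
        with pytest.raises(ValueError):
            hs.hypergeom_upper(0, 11, 5, 10)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert hs.bh_adjust([0.037])[0] == pytest.approx(0.037)

    def test_hand_step_up(self):
        np.testing.assert_allclose(hs.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_equal_p_fixed_point(self):
        np.testing.assert_allclose(hs.bh_adjust([0.2] * 7), [0.2] * 7)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            hs.bh_adjust([0.0, 0.5])
        with pytest.raises(ValueError):
            hs.bh_adjust([1.5])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=60))
    def test_matches_independent_step_up(self, p):
        np.testing.assert_allclose(hs.bh_adjust(p), step_up_bh(p), rtol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.uniform(1e-8, 1.0, size=int(rng.integers(1, 200)))
            _, expected, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(hs.bh_adjust(p), expected, rtol=1e-10)


class TestEnrichPanel:
    def test_disjoint_profile_gives_certain_p(self):
        panel = [TargetProfile("e1", frozenset({"a", "b"}))]
        res = hs.enrich_panel(panel, {"S": {"c", "d"}}, {"a", "b", "c", "d", "e"})
        row = res.iloc[0]
        assert row["k"] == 0 and row["p_raw"] == 1.0

    def test_full_containment_attains_enumerated_minimum(self):
        # profile covers the whole set: K = n = k inside a 10-gene universe
        universe = {f"u{i}" for i in range(10)}
        genes = {"u0", "u1", "u2"}
        panel = [TargetProfile("e1", frozenset(genes))]
        res = hs.enrich_panel(panel, {"S": genes}, universe)
        assert res.iloc[0]["p_raw"] == pytest.approx(enum_hypergeom_upper(3, 3, 3, 10), abs=1e-12)

    def test_counts_measured_inside_universe(self):
        panel = [TargetProfile("e1", frozenset({"a", "b", "zz"}))]
        res = hs.enrich_panel(panel, {"S": {"b", "c", "yy"}}, {"a", "b", "c", "d"})
        row = res.iloc[0]
        assert (row["K"], row["n"], row["N"], row["k"]) == (2, 2, 4, 1)

    def test_empty_universe_and_out_of_universe_profile(self, caplog):
        with pytest.raises(ValueError):
            hs.enrich_panel([], {"S": {"a"}}, set())
        with caplog.at_level("WARNING"):
            res = hs.enrich_panel([TargetProfile("gone", frozenset({"zz"}))], {"S": {"a"}}, {"a", "b"})
        assert res.empty and "gone" in caplog.text

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        universe = [f"u{i}" for i in range(40)]
        panel = [TargetProfile(f"e{j}", frozenset(rng.choice(universe, 8, replace=False))) for j in range(4)]
        sets = {"S1": set(rng.choice(universe, 10, replace=False)),
                "S2": set(rng.choice(universe, 6, replace=False))}
        res1 = hs.enrich_panel(panel, sets, universe)
        res2 = hs.enrich_panel(panel[::-1], sets, universe[::-1])
        pd.testing.assert_frame_equal(
            res1.sort_values(["entity_id", "set_label"]).reset_index(drop=True),
            res2.sort_values(["entity_id", "set_label"]).reset_index(drop=True),
        )

    def test_bh_applied_within_each_set_label(self):
        panel = [TargetProfile(f"e{j}", frozenset({f"u{j}"})) for j in range(3)]
        universe = {f"u{i}" for i in range(6)}
        res = hs.enrich_panel(panel, {"S1": {"u0"}, "S2": {"u1"}}, universe)
        for label, sub in res.groupby("set_label"):
            np.testing.assert_allclose(sub["p_adj"], hs.bh_adjust(sub["p_raw"]))


class TestRankEntities:
    def _results(self, rows):
        return pd.DataFrame(rows, columns=["entity_id", "set_label", "k", "K", "n", "N", "p_raw", "p_adj"])

    def test_significant_set_count_dominates(self):
        rows = [("a", l, 1, 5, 5, 50, 0.01, 0.01) for l in "ABCD"]
        rows += [("b", l, 9, 5, 5, 50, 0.001, 0.001) for l in "ABC"] + [("b", "D", 0, 5, 5, 50, 1.0, 1.0)]
        table = hs.rank_entities(self._results(rows), alpha=0.05)
        assert list(table["entity_id"]) == ["a", "b"]

    def test_complete_tie_breaks_lexicographically(self):
        rows = [(e, l, 2, 5, 5, 50, 0.5, 0.5) for e in ("zeta", "alpha") for l in "AB"]
        table = hs.rank_entities(self._results(rows))
        assert list(table["entity_id"]) == ["alpha", "zeta"]

    def test_true_hit_ranks_first_and_tops_strong_sets(self):
        """Planted herb wins the screen; in the fructose-specific sets (B, D)
        it also attains the smallest adjusted p."""
        first, minp = 0, 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = hs.SimConfig(seed=seed)
            adata, truth = hs.generate_expression(cfg)
            ref = hs.generate_lr_reference(cfg)
            sets = hs.derive_sets(hs.score_all(hs.normalize(adata), ref), ref)
            res = hs.enrich_panel(
                profiles_from_table(hs.generate_target_profiles(cfg, truth)),
                {k: v.gene_members for k, v in sets.items()},
                set(adata.var_names),
            )
            table = hs.rank_entities(res)
            first += table.iloc[0]["entity_id"] == truth.true_hit_herb
            minp += all(
                res[res.set_label == l].set_index("entity_id")["p_adj"].idxmin() == truth.true_hit_herb
                for l in "BD"
            )
        assert first >= 0.9 * n_seeds
        assert minp >= 0.9 * n_seeds


class TestPathwayStandardize:
    def _results(self, ps, label="S"):
        return pd.DataFrame({
            "entity_id": [f"path{i}" for i in range(len(ps))],
            "set_label": label, "k": 1, "K": 5, "n": 5, "N": 50,
            "p_raw": ps, "p_adj": ps,
        })

    def test_two_point_z(self):
        out = hs.pathway_enrich_standardize(self._results([0.1, 0.001]))
        z = dict(zip(out["entity_id"], out["z"]))
        assert z["path0"] == pytest.approx(-np.sqrt(0.5), abs=1e-9)  # weaker enrichment
        assert z["path1"] == pytest.approx(np.sqrt(0.5), abs=1e-9)

    def test_zero_variance_yields_zeros(self, caplog):
        with caplog.at_level("WARNING"):
            out = hs.pathway_enrich_standardize(self._results([0.2, 0.2, 0.2]))
        np.testing.assert_allclose(out["z"], 0.0)
        assert "zero variance" in caplog.text

    def test_mean_zero_unit_sd(self):
        rng = np.random.default_rng(2)
        out = hs.pathway_enrich_standardize(self._results(list(rng.uniform(1e-6, 1, 20))))
        assert out["z"].mean() == pytest.approx(0.0, abs=1e-12)
        assert out["z"].std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_single_pathway_label_rejected(self):
        with pytest.raises(ValueError):
            hs.pathway_enrich_standardize(self._results([0.1]))
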