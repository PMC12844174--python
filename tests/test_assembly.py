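import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cryoassembly.assembly import (
    PROCESSES,
    assemble_pairs,
    beta_mntd,
    beta_nti,
    classify_process,
    pnst,
    process_fractions,
    rc_bray,
    scale_trend,
)
from cryoassembly.phylo import patristic_distance_matrix
from conftest import tree_from_newick
from oracles import beta_mntd_brute, classify_brute
from test_io import make_table


class TestBetaMNTD:
    def test_identical_communities_zero(self):
        tree = tree_from_newick("((A:1,B:1):1,C:2);")
        table = make_table([[3, 1, 2], [30, 10, 20]], taxa=["A", "B", "C"])
        out = beta_mntd(table, tree)
        assert out.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_singletons(self):
        # A and B are each other's only counterparts at patristic distance 3
        tree = tree_from_newick("(A:1,B:2);")
        table = make_table([[5, 0], [0, 7]], taxa=["A", "B"])
        assert beta_mntd(table, tree).iloc[0, 1] == pytest.approx(3.0, abs=1e-12)

    def test_three_taxon_toy_by_hand(self):
        # A,B sisters at distance 1; C at distance 4 from both;
        # {A} vs {B:1, C:1}: 0.5*[1 + (0.5*1 + 0.5*4)] = 1.75
        tree = tree_from_newick("((A:0.5,B:0.5):1.75,C:1.75);")
        table = make_table([[1, 0, 0], [0, 1, 1]], taxa=["A", "B", "C"])
        assert beta_mntd(table, tree).iloc[0, 1] == pytest.approx(1.75, abs=1e-12)

    def test_matches_exhaustive_brute_force(self):
        from cryoassembly.synthetic import simulate_tree

        rng = np.random.default_rng(2)
        tree = simulate_tree(10, seed=9)
        pat = patristic_distance_matrix(tree)
        counts = rng.integers(0, 12, size=(6, 10))
        counts[:, 0] += 1
        table = make_table(counts, taxa=list(pat.index))
        out = beta_mntd(table, pat)
        dist = pat.to_numpy().tolist()
        for i in range(6):
            for j in range(i + 1, 6):
                expected = beta_mntd_brute(counts[i].tolist(), counts[j].tolist(), dist)
                assert out.iloc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_unweighted_mode_ignores_abundance(self):
        tree = tree_from_newick("((A:0.5,B:0.5):1.75,C:1.75);")
        skewed = make_table([[1, 0, 0], [0, 99, 1]], taxa=["A", "B", "C"])
        even = make_table([[1, 0, 0], [0, 1, 1]], taxa=["A", "B", "C"])
        assert beta_mntd(skewed, tree, weighted=False).iloc[0, 1] == pytest.approx(
            beta_mntd(even, tree, weighted=False).iloc[0, 1], abs=1e-12
        )

    def test_missing_taxon_named_in_error(self):
        tree = tree_from_newick("(A:1,B:2);")
        table = make_table([[1, 1], [1, 1]], taxa=["A", "Z"])
        with pytest.raises(KeyError, match="Z"):
            beta_mntd(table, tree)

    def test_empty_sample_rejected(self):
        tree = tree_from_newick("(A:1,B:2);")
        with pytest.raises(ValueError, match="empty"):
            beta_mntd(make_table([[0, 0], [1, 1]], taxa=["A", "B"]), tree)


class TestBetaNTI:
    def test_star_tree_degenerate_null_flagged(self):
        tree = tree_from_newick("(A:1,B:1,C:1,D:1);")
        table = make_table([[1, 1, 0, 0], [0, 0, 1, 1]], taxa=list("ABCD"))
        with pytest.warns(UserWarning, match="zero spread"):
            res = beta_nti(table, tree, n_null=19, seed=0)
        assert res.degenerate
        assert np.isnan(res.beta_nti.iloc[0, 1])

    def test_deterministic_under_seed(self, mixed_dataset):
        ds, pat = mixed_dataset
        sub = ds.table.filter_samples(ds.table.sample_ids[:6]).drop_empty_taxa()
        a = beta_nti(sub, pat, n_null=29, seed=3).beta_nti
        b = beta_nti(sub, pat, n_null=29, seed=3).beta_nti
        pd.testing.assert_frame_equal(a, b)

    def test_null_consistency_under_drift(self):
        # communities assembled by random multinomial draws from one pool
        # should look null: mean betaNTI near 0, most pairs inside (-2, 2)
        from cryoassembly.synthetic import ScenarioConfig, simulate_metacommunity

        ds = simulate_metacommunity(
            ScenarioConfig(n_sites=14, n_taxa=120, depth=800, regime="drift",
                           selection_strength=0.0, seed=21)
        )
        pat = patristic_distance_matrix(ds.tree, ds.table.taxon_ids)
        res = beta_nti(ds.table, pat, n_null=99, seed=5)
        tri = np.triu_indices(14, k=1)
        values = res.beta_nti.to_numpy()[tri]
        assert abs(np.nanmean(values)) < 0.5
        assert np.mean(np.abs(values) < 2) >= 0.8


class TestRCBray:
    def test_identical_rich_samples_more_similar_than_null(self, toy_table):
        counts = toy_table.counts.copy()
        counts.iloc[1] = counts.iloc[0]  # duplicate one sample
        table = make_table(counts.to_numpy(), samples=toy_table.sample_ids, taxa=toy_table.taxon_ids)
        rc = rc_bray(table, n_null=99, seed=2)
        assert rc.iloc[0, 1] == pytest.approx(-1.0, abs=0.05)

    def test_bounded_symmetric(self, toy_table):
        rc = rc_bray(toy_table, n_null=49, seed=7)
        arr = rc.to_numpy()
        assert np.allclose(arr, arr.T)
        assert (np.abs(arr) <= 1).all()

    def test_degenerate_pool_rejected(self):
        with pytest.raises(ValueError, match="pool"):
            rc_bray(make_table([[5, 0], [3, 0]]), n_null=9)


class TestClassifyProcess:
    @pytest.mark.parametrize(
        "bnti,rc,expected",
        [
            (-2.5, 0.1, "HoS"),
            (2.5, 0.1, "HeS"),
            (0.5, 0.97, "DL"),
            (0.5, -0.97, "HD"),
            (0.5, 0.2, "DR"),
            (-2.0, 0.99, "HoS"),  # boundary goes to the selection side
            (2.0, -0.99, "HeS"),
            (0.0, 0.95, "DR"),  # |RC| boundary stays undominated
            (0.0, -0.95, "DR"),
        ],
    )
    def test_rule_table(self, bnti, rc, expected):
        assert classify_process(bnti, rc) == expected

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            classify_process(np.nan, 0.5)

    @settings(max_examples=300, derandomize=True)
    @given(
        st.floats(min_value=-6, max_value=6, allow_nan=False),
        st.floats(min_value=-1, max_value=1, allow_nan=False),
    )
    def test_partition_matches_independent_rule(self, bnti, rc):
        label = classify_process(bnti, rc)
        assert label in PROCESSES
        assert label == classify_brute(bnti, rc)


class TestProcessFractions:
    def test_single_process(self):
        pairs = pd.DataFrame({"process": ["DL"] * 4})
        out = process_fractions(pairs)
        assert out.loc["all", "DL"] == 1.0
        assert out.loc["all", ["HoS", "HeS", "HD", "DR"]].sum() == 0

    def test_even_split(self):
        pairs = pd.DataFrame({"process": ["HeS", "HeS", "DL", "DL"]})
        out = process_fractions(pairs)
        assert out.loc["all", "HeS"] == 0.5
        assert out.loc["all", "DL"] == 0.5
        assert out.loc["all", "n_pairs"] == 4

    def test_fractions_sum_to_one_per_group(self):
        rng = np.random.default_rng(0)
        pairs = pd.DataFrame({"process": rng.choice(PROCESSES, 60)})
        grouping = pd.Series(rng.choice(["x", "y"], 60), index=pairs.index)
        out = process_fractions(pairs, grouping)
        assert np.allclose(out[list(PROCESSES)].sum(axis=1), 1.0, atol=1e-12)

    def test_undefined_pairs_excluded(self):
        pairs = pd.DataFrame({"process": ["DL", "undefined", "DL"]})
        assert process_fractions(pairs).loc["all", "n_pairs"] == 2


class TestScaleTrend:
    @staticmethod
    def _pairs(distances, processes):
        return pd.DataFrame({"geo_km": distances, "process": processes})

    def test_bin_convention_half_open(self):
        pairs = self._pairs([10, 59.9, 60.0, 150], ["DL"] * 4)
        trend = scale_trend(pairs, min_pairs=1)
        assert trend.units["unit_index"].tolist() == [1, 2, 3]
        assert trend.units["n_pairs"].tolist() == [2, 1, 1]

    def test_constant_fraction_flat_trend(self):
        distances = [10] * 5 + [70] * 5 + [130] * 5
        trend = scale_trend(self._pairs(distances, ["DL"] * 15), min_pairs=5)
        fits = trend.fits.set_index("process")
        assert fits.loc["DL", "slope"] == 0
        assert fits.loc["DL", "r_squared"] == 0

    def test_increasing_dl_fraction_detected(self):
        distances, processes = [], []
        for unit, frac in enumerate([0.2, 0.4, 0.6, 0.8], start=1):
            for i in range(10):
                distances.append(60 * (unit - 1) + 30)
                processes.append("DL" if i < frac * 10 else "DR")
        trend = scale_trend(self._pairs(distances, processes))
        fits = trend.fits.set_index("process")
        assert fits.loc["DL", "slope"] > 0
        assert fits.loc["DL", "p_value"] < 0.05

    def test_sparse_units_excluded_and_too_few_error(self):
        pairs = self._pairs([10] * 5 + [70] * 2 + [130] * 5, ["DL"] * 12)
        with pytest.raises(ValueError, match="populated scale units"):
            scale_trend(pairs, min_pairs=5)


class TestPNST:
    def test_identical_samples_fully_deterministic(self):
        tree = tree_from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        table = make_table([[2, 1, 3, 1]] * 3, taxa=list("ABCD"))
        groups = pd.Series(["g"] * 3, index=table.sample_ids)
        out = pnst(table, tree, groups, n_null=19, seed=0)
        assert out["g"] == pytest.approx(0.0, abs=1e-12)

    def test_small_groups_excluded_with_warning(self, mixed_dataset):
        ds, pat = mixed_dataset
        groups = pd.Series(
            ["a"] * 2 + ["b"] * (len(ds.table.sample_ids) - 2), index=ds.table.sample_ids
        )
        with pytest.warns(UserWarning, match="fewer than 3"):
            out = pnst(ds.table, pat, groups, n_null=19, seed=0)
        assert list(out.index) == ["b"]
        assert 0 <= out["b"] <= 1

    def test_drift_scores_more_stochastic_than_selection(self):
        from cryoassembly.synthetic import ScenarioConfig, simulate_metacommunity

        values = {}
        for regime, strength in (("drift", 0.0), ("selection", 1.0)):
            ds = simulate_metacommunity(
                ScenarioConfig(n_sites=14, n_taxa=150, depth=1500, regime=regime,
                               selection_strength=strength, n_continents=1, seed=33)
            )
            pat = patristic_distance_matrix(ds.tree, ds.table.taxon_ids)
            groups = pd.Series("all", index=ds.table.sample_ids)
            values[regime] = pnst(ds.table, pat, groups, n_null=99, seed=1)["all"]
        assert values["drift"] > values["selection"]


class TestAssemblePairs:
    def test_pair_table_contract(self, mixed_dataset):
        from cryoassembly.biogeography import geographic_distance_matrix

        ds, pat = mixed_dataset
        geo = geographic_distance_matrix(ds.metadata)
        pairs = assemble_pairs(ds.table, pat, geo_dm=geo, n_null=29, seed=4)
        n = len(ds.table.sample_ids)
        assert len(pairs) == n * (n - 1) // 2
        classified = pairs[pairs["process"] != "undefined"]
        finite = classified.dropna(subset=["beta_nti"])
        np.testing.assert_array_equal(
            classify_process(finite["beta_nti"].to_numpy(), finite["rc_bray"].to_numpy()),
            finite["process"].to_numpy(),
        )
        assert (pairs["geo_km"] >= 0).all()
        assert pairs["rc_bray"].abs().le(1).all()
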