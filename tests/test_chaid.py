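"""CHAID building blocks and tree growth: binning, chi-square, Bonferroni
multipliers, category merging, fitting, prediction, serialization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import helpers_oracles as oracles
from zhengmine.chaid import (
    ChaidConfig,
    TreeSchemaError,
    apply_bins,
    bin_continuous,
    bonferroni_multiplier,
    export_tree,
    fit_chaid,
    import_tree,
    merge_categories,
    pearson_chi2,
    predict,
    render_tree,
)


class TestBinning:
    def test_deciles_of_1_to_100(self):
        codes, edges = bin_continuous(np.arange(1, 101), max_bins=10)
        assert codes.nunique() == 10
        assert codes.value_counts().eq(10).all()
        assert np.isneginf(edges[0]) and np.isposinf(edges[-1])

    def test_constant_vector_gives_single_bin(self):
        codes, edges = bin_continuous(np.full(20, 3.14), max_bins=10)
        assert codes.nunique() == 1
        assert len(edges) == 2

    def test_normal_draws_balanced_within_one(self):
        rng = np.random.default_rng(0)
        codes, _ = bin_continuous(rng.normal(size=1000), max_bins=10)
        counts = codes.value_counts()
        assert len(counts) == 10
        assert counts.between(99, 101).all()

    def test_binning_reproducible_from_edges(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=500)
        codes, edges = bin_continuous(values, max_bins=8)
        assert apply_bins(values, edges).equals(codes)

    def test_missing_values_get_code_minus_one(self):
        codes, _ = bin_continuous([1.0, np.nan, 2.0, 3.0], max_bins=2)
        assert codes.iloc[1] == -1

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            bin_continuous([np.nan, np.nan])


class TestPearsonChi2:
    def test_perfect_independence(self):
        res = pearson_chi2([[10, 10], [10, 10]])
        assert res.chi2 == 0.0 and res.p == 1.0 and res.df == 1

    def test_hand_summed_example(self):
        # E = 12.5 in every cell; chi2 = 4 * 7.5^2 / 12.5 = 18
        res = pearson_chi2([[20, 5], [5, 20]])
        assert res.chi2 == pytest.approx(18.0)
        assert res.df == 1

    @given(
        st.lists(
            st.lists(st.integers(0, 40), min_size=2, max_size=4),
            min_size=2, max_size=4,
        ).filter(
            lambda t: len({len(r) for r in t}) == 1
            and sum(map(sum, t)) > 0
            and all(any(r) for r in t)
            and all(any(row[j] for row in t) for j in range(len(t[0])))
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_transpose_symmetry_and_scipy_agreement(self, table):
        from scipy.stats import chi2_contingency

        res = pearson_chi2(table)
        res_t = pearson_chi2(np.array(table).T)
        assert res.chi2 == pytest.approx(res_t.chi2)
        ref_chi2, ref_p, ref_df, _ = chi2_contingency(table, correction=False)
        assert res.chi2 == pytest.approx(ref_chi2)
        assert res.p == pytest.approx(ref_p)
        assert res.df == ref_df

    def test_2x2_closed_form(self):
        a, b, c, d = 13, 7, 4, 26
        res = pearson_chi2([[a, b], [c, d]])
        n = a + b + c + d
        closed = n * (a * d - b * c) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d)
        )
        assert res.chi2 == pytest.approx(closed)

    def test_zero_margin_dropped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            res = pearson_chi2([[5, 0, 5], [5, 0, 5], [0, 0, 0]])
        assert res.df == 1
        assert any("dropping" in rec.message for rec in caplog.records)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            pearson_chi2([[1, -2], [3, 4]])


class TestBonferroniMultiplier:
    @pytest.mark.parametrize("c,r", [(3, 2), (4, 2), (4, 3), (5, 3), (6, 4)])
    def test_nominal_matches_partition_enumeration(self, c, r):
        assert bonferroni_multiplier(c, r, "nominal") == (
            oracles.count_partitions(c, r)
        )

    @pytest.mark.parametrize("c,r", [(3, 2), (5, 3), (6, 2), (6, 5)])
    def test_ordinal_matches_contiguous_enumeration(self, c, r):
        assert bonferroni_multiplier(c, r, "ordinal") == (
            oracles.count_contiguous_groupings(c, r)
        )

    def test_known_small_values(self):
        assert bonferroni_multiplier(3, 2, "nominal") == 3
        assert bonferroni_multiplier(5, 3, "ordinal") == 6

    @pytest.mark.parametrize("c", range(1, 7))
    def test_identity_partition_is_unique(self, c):
        assert bonferroni_multiplier(c, c, "nominal") == 1
        assert bonferroni_multiplier(c, c, "ordinal") == 1

    def test_nominal_agrees_with_sympy_stirling(self):
        sympy = pytest.importorskip("sympy")
        from sympy.functions.combinatorial.numbers import stirling

        for c in range(2, 7):
            for r in range(1, c + 1):
                assert bonferroni_multiplier(c, r, "nominal") == int(
                    stirling(c, r)
                )

    def test_ordinal_never_exceeds_nominal(self):
        for c in range(3, 8):
            for r in range(2, c):
                assert bonferroni_multiplier(c, r, "ordinal") <= (
                    bonferroni_multiplier(c, r, "nominal")
                )

    def test_r_above_c_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_multiplier(3, 4, "ordinal")


class TestMergeCategories:
    def test_indistinguishable_categories_collapse_to_one_group(self):
        rng = np.random.default_rng(2)
        pred = np.repeat([0, 1, 2], 60)
        resp = rng.binomial(1, 0.5, 180)
        merged = merge_categories(pred, resp, ChaidConfig(), "ordinal")
        assert len(merged.groups) == 1
        assert merged.result.p_adjusted == 1.0

    def test_strongly_different_categories_stay_apart(self):
        pred = np.repeat([0, 1], 100)
        resp = np.concatenate([
            np.repeat([1, 0], [90, 10]), np.repeat([1, 0], [10, 90]),
        ])
        merged = merge_categories(pred, resp, ChaidConfig(), "ordinal")
        assert merged.groups == [(0,), (1,)]
        assert merged.result.p_adjusted < 1e-6
        assert merged.result.bonferroni_B == 1  # r == c

    def test_step_pattern_recovers_the_contiguous_cut(self):
        rng = np.random.default_rng(3)
        pred = np.repeat([0, 1, 2, 3], 50)
        resp = np.concatenate(
            [rng.binomial(1, p, 50) for p in (0.1, 0.1, 0.8, 0.8)]
        )
        merged = merge_categories(pred, resp, ChaidConfig(), "ordinal")
        assert merged.groups == [(0, 1), (2, 3)]
        # exhaustive search over contiguous 2-groupings finds the same cut
        counts = np.array(
            [[np.sum((pred == c) & (resp == y)) for y in (0, 1)]
             for c in range(4)]
        )
        best, _ = oracles.best_contiguous_grouping_by_chi2(counts, 2)
        assert merged.groups == best

    def test_single_category_yields_no_test(self):
        merged = merge_categories(
            np.zeros(50, dtype=int), np.tile([0, 1], 25), ChaidConfig()
        )
        assert merged.result.p_adjusted == 1.0
        assert merged.result.r == 1

    def test_adjusted_p_at_least_raw_p(self):
        rng = np.random.default_rng(4)
        pred = rng.integers(0, 5, 300)
        resp = rng.binomial(1, 0.3 + 0.1 * (pred > 2), 300)
        merged = merge_categories(pred, resp, ChaidConfig(), "ordinal")
        assert merged.result.p_adjusted >= merged.result.p


def separable_data(n=200):
    y = pd.Series(np.repeat([0, 1], n // 2))
    x = pd.DataFrame({"flag": y.map({0: "no", 1: "yes"})})
    return x, y


class TestFit:
    small = ChaidConfig(parent_min=10, child_min=5)

    def test_perfect_predictor_gives_depth1_pure_tree(self):
        x, y = separable_data()
        tree = fit_chaid(x, y, self.small)
        assert tree.depth == 1
        assert tree.n_terminal == 2
        calls, _ = predict(tree, x)
        assert (calls == y).all()

    def test_constant_target_flagged_root_only(self):
        x, _ = separable_data()
        tree = fit_chaid(x, pd.Series(np.ones(len(x), dtype=int)), self.small)
        assert tree.constant_target
        assert tree.n_nodes == 1

    def test_zero_split_alpha_gives_root_only(self):
        x, y = separable_data()
        cfg = ChaidConfig(parent_min=10, child_min=5, alpha_split=0.0)
        assert fit_chaid(x, y, cfg).n_nodes == 1

    def test_looser_size_limits_grow_at_least_as_large(self, default_cohort):
        y = default_cohort.labels["qi deficiency"]
        x = default_cohort.biomarkers[["X TAL", "RDW-CV", "MONO", "K"]]
        strict = fit_chaid(x, y, ChaidConfig(parent_min=50, child_min=25))
        loose = fit_chaid(
            x, y,
            ChaidConfig(parent_min=2, child_min=1, alpha_merge=0.05,
                        alpha_split=0.05),
        )
        assert loose.n_nodes >= strict.n_nodes

    def test_row_permutation_leaves_tree_unchanged(self, default_cohort):
        y = default_cohort.labels["qi deficiency"]
        x = default_cohort.biomarkers[["X TAL", "RDW-CV", "MONO"]]
        rng = np.random.default_rng(5)
        perm = rng.permutation(len(y))
        t1 = fit_chaid(x, y)
        t2 = fit_chaid(x.iloc[perm], y.iloc[perm])
        def shape(t):
            return [
                (n.depth, n.n, n.split_predictor, tuple(map(tuple, n.groups)))
                for n in t.nodes()
            ]
        assert shape(t1) == shape(t2)

    def test_child_counts_partition_parents(self, default_cohort):
        y = default_cohort.labels["qi deficiency"]
        tree = fit_chaid(default_cohort.biomarkers, y)
        for node in tree.nodes():
            if node.children:
                assert sum(ch.n for ch in node.children) == node.n
        leaves = [n for n in tree.nodes() if n.is_terminal]
        assert sum(n.n for n in leaves) == len(y)
        assert tree.depth <= tree.config.max_depth

    def test_split_nodes_respect_size_minimums(self, default_cohort):
        y = default_cohort.labels["qi deficiency"]
        tree = fit_chaid(default_cohort.biomarkers, y)
        for node in tree.nodes():
            if node.children:
                assert node.n >= tree.config.parent_min
                for ch in node.children:
                    assert ch.n >= tree.config.child_min
                assert node.split_result.p_adjusted >= node.split_result.p

    def test_noise_predictors_rarely_split(self):
        """Family-wise error control: pure-noise predictors should leave
        most replicate trees root-only at alpha 0.05."""
        non_root = 0
        reps = 40
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            x = pd.DataFrame(
                rng.normal(size=(200, 5)), columns=list("abcde")
            )
            y = pd.Series(rng.binomial(1, 0.5, 200))
            if fit_chaid(x, y).n_nodes > 1:
                non_root += 1
        assert non_root / reps < 0.5


class TestPredict:
    def test_training_data_reaggregates_leaf_counts(self, default_cohort):
        y = default_cohort.labels["qi deficiency"]
        tree = fit_chaid(default_cohort.biomarkers, y)
        calls, probs = predict(tree, default_cohort.biomarkers)
        leaves = [n for n in tree.nodes() if n.is_terminal]
        assert sum(n.n for n in leaves) == len(calls)
        # every case's class probabilities come from a real leaf
        assert probs.sum(axis=1).round(9).eq(1.0).all()

    def test_root_only_tree_predicts_majority(self):
        x = pd.DataFrame({"a": np.zeros(30)})
        y = pd.Series([1] * 20 + [0] * 10)
        tree = fit_chaid(x, y, ChaidConfig(parent_min=50, child_min=25))
        assert tree.n_nodes == 1
        calls, _ = predict(tree, x)
        assert (calls == 1).all()

    def test_missing_split_column_rejected(self):
        x, y = separable_data()
        tree = fit_chaid(x, y, ChaidConfig(parent_min=10, child_min=5))
        with pytest.raises(KeyError, match="flag"):
            predict(tree, pd.DataFrame({"other": [1, 2]}))

    def test_unseen_category_routes_to_largest_child(self):
        x, y = separable_data()
        tree = fit_chaid(x, y, ChaidConfig(parent_min=10, child_min=5))
        calls, _ = predict(tree, pd.DataFrame({"flag": ["unheard-of"]}))
        assert calls.iloc[0] in (0, 1)


class TestSerialization:
    def test_json_round_trip_preserves_structure(self, default_cohort, tmp_path):
        y = default_cohort.labels["qi deficiency"]
        tree = fit_chaid(default_cohort.biomarkers, y)
        path = tmp_path / "tree.json"
        export_tree(tree, path)
        back = import_tree(path)
        assert back.n_nodes == tree.n_nodes
        assert back.classes == tree.classes
        assert back.bin_edges == tree.bin_edges
        calls_a, _ = predict(tree, default_cohort.biomarkers.head(20))
        calls_b, _ = predict(back, default_cohort.biomarkers.head(20))
        assert calls_a.equals(calls_b)

    def test_truncated_file_is_schema_error(self, tmp_path):
        path = tmp_path / "broken.json"
        path.write_text('{"schema_version": 1, "config": {')
        with pytest.raises(TreeSchemaError):
            import_tree(path)

    def test_wrong_schema_version_rejected(self, tmp_path):
        path = tmp_path / "old.json"
        path.write_text('{"schema_version": 99}')
        with pytest.raises(TreeSchemaError, match="version"):
            import_tree(path)

    def test_rendering_prints_one_block_per_node(self):
        x, y = separable_data()
        tree = fit_chaid(x, y, ChaidConfig(parent_min=10, child_min=5))
        text = render_tree(tree)
        assert text.count("node ") == tree.n_nodes
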