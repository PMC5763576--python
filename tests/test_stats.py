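"""Trimming, Box-Cox, skewness, model ranking, ANOVA, t tests, KS, folds."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mscmorph import stats
from mscmorph.stats import TransformSpec, TrimSpec


class TestTrimming:
    @pytest.mark.parametrize(
        "n,expected",
        [(313_141, 281_827), (100, 90), (40, 36)],
    )
    def test_retained_counts_at_default_fractions(self, n, expected):
        out = stats.trim_outliers(np.arange(n, dtype=float))
        assert out.size == expected

    def test_values_removed_from_both_tails(self):
        out = stats.trim_outliers(np.arange(100.0))
        assert out.min() == 5.0 and out.max() == 94.0

    def test_retained_order_is_input_order(self, rng):
        x = rng.permutation(100).astype(float)
        out = stats.trim_outliers(x)
        kept = x[(x >= 5) & (x <= 94)]
        assert np.array_equal(out, kept)

    def test_ties_broken_by_stable_input_order(self):
        x = np.array([1.0, 1.0, 1.0, 2.0, 3.0, 4.0, 5.0, 5.0, 5.0, 9.0])
        out = stats.trim_outliers(x, TrimSpec(0.1, 0.1))
        # the first 1.0 and the last 9.0 are removed
        assert out.tolist() == [1.0, 1.0, 2.0, 3.0, 4.0, 5.0, 5.0, 5.0]

    def test_degenerate_trims_rejected(self):
        # fractions summing to 1 are illegal at construction; floor
        # arithmetic guarantees any legal spec leaves at least one value
        with pytest.raises(ValueError):
            TrimSpec(0.5, 0.5)
        with pytest.raises(ValueError):
            stats.trim_outliers(np.array([]))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        n=st.integers(1, 2000),
        f_lo=st.floats(0, 0.45),
        f_hi=st.floats(0, 0.45),
    )
    def test_retained_count_identity(self, n, f_lo, f_hi):
        # retained = N - floor(f_lo*N) - floor(f_hi*N), whenever legal
        k = int(np.floor(f_lo * n)) + int(np.floor(f_hi * n))
        if k >= n:
            return
        out = stats.trim_outliers(np.arange(float(n)), TrimSpec(f_lo, f_hi))
        assert out.size == n - k


class TestBoxCox:
    @pytest.mark.parametrize(
        "lam,y,expected",
        [(0.0, np.e, 1.0), (1.0, 5.0, 4.0), (2.0, 3.0, 4.0)],
    )
    def test_closed_form_values(self, lam, y, expected):
        out = stats.box_cox([y], TransformSpec("v", lam))
        assert out[0] == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_value_names_offending_index(self):
        with pytest.raises(ValueError, match="index 2"):
            stats.box_cox([1.0, 2.0, -1.0], TransformSpec("v", 0.0))

    def test_continuity_at_lambda_zero(self, rng):
        y = rng.uniform(0.2, 50, 200)
        near = stats.box_cox(y, TransformSpec("v", 1e-6))
        exact = stats.box_cox(y, TransformSpec("v", 0.0))
        assert np.max(np.abs(near - exact)) < 1e-4

    def test_nonfinite_lambda_rejected(self):
        with pytest.raises(ValueError):
            TransformSpec("v", float("nan"))


class TestGroupSkewness:
    def test_symmetric_sample_near_zero(self, rng):
        df = pd.DataFrame({"donor": "d", "passage": "p", "area": rng.normal(10, 1, 10_000)})
        out = stats.group_skewness(df, "area", TransformSpec("area", 1.0))
        assert abs(out.skewness[0]) < 0.1

    def test_lognormal_collapses_under_log_transform(self, rng):
        df = pd.DataFrame(
            {"donor": "d", "passage": "p", "area": rng.lognormal(7.5, 0.5, 10_000)}
        )
        out = stats.group_skewness(df, "area", TransformSpec("area", 0.0))
        assert out.raw_skewness[0] > 1.0
        assert abs(out.skewness[0]) < 0.05

    def test_constant_sample_flagged_degenerate(self):
        df = pd.DataFrame({"donor": "d", "passage": "p", "area": [2.0] * 10})
        out = stats.group_skewness(df, "area")
        assert out.skewness[0] == 0.0
        assert bool(out.degenerate[0])

    def test_undersized_group_skipped_with_warning(self):
        df = pd.DataFrame(
            {"donor": ["d1"] * 10 + ["d2"] * 2, "passage": "p", "area": np.arange(12) + 1.0}
        )
        with pytest.warns(UserWarning, match="skipped"):
            out = stats.group_skewness(df, "area")
        assert list(out.donor) == ["d1"]


class TestRankPDModels:
    @staticmethod
    def _summaries(rng, n_groups=8, driver_sd=True):
        rows, pd_rows = [], []
        for g in range(n_groups):
            donor, passage = f"d{g % 2}", f"p{g // 2}"
            sd_area = 1.0 + g * 0.5
            rows.append(
                dict(donor=donor, passage=passage, variable="area", n=100,
                     mean=rng.normal(7.5, 0.1), sd=sd_area, skewness=0.0)
            )
            rows.append(
                dict(donor=donor, passage=passage, variable="length_width_ratio", n=100,
                     mean=rng.normal(0.9, 0.2), sd=rng.normal(0.3, 0.05), skewness=0.0)
            )
            pd_rows.append(dict(donor=donor, passage=passage, pd=10 + 4 * sd_area))
        return pd.DataFrame(rows), pd.DataFrame(pd_rows)

    def test_perfect_linear_relation_gives_r2_one(self, rng):
        summaries, pd_table = self._summaries(rng)
        ranking = stats.rank_pd_models(summaries, pd_table)
        top = ranking.iloc[0]
        assert (top.variable, top.summary_kind) == ("area", "sd")
        assert top.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_noise_variable_never_outranks_true_driver(self):
        wins = 0
        n_sims = 200
        for seed in range(n_sims):
            rng = np.random.default_rng(5000 + seed)
            summaries, pd_table = self._summaries(rng)
            # true driver with observation noise
            pd_table["pd"] += rng.normal(0, 0.4, len(pd_table))
            ranking = stats.rank_pd_models(summaries, pd_table)
            top = ranking.iloc[0]
            wins += (top.variable, top.summary_kind) == ("area", "sd")
        assert wins / n_sims >= 0.95

    def test_null_r2_is_small_on_average(self):
        r2s = []
        for seed in range(300):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=6)
            y = rng.normal(size=6)
            from scipy.stats import linregress

            r2s.append(linregress(x, y).rvalue ** 2)
        # E[R²] = 1/(k-1) for independent normals with k=6 points
        assert np.mean(r2s) == pytest.approx(0.2, abs=0.05)

    def test_constant_explanatory_variable_skipped(self, rng):
        summaries, pd_table = self._summaries(rng)
        summaries.loc[summaries.variable == "length_width_ratio", "sd"] = 0.3
        with pytest.warns(UserWarning, match="constant explanatory"):
            ranking = stats.rank_pd_models(summaries, pd_table)
        assert not (
            (ranking.variable == "length_width_ratio") & (ranking.summary_kind == "sd")
        ).any()

    def test_too_few_groups_rejected(self, rng):
        summaries, pd_table = self._summaries(rng, n_groups=2)
        with pytest.raises(ValueError):
            stats.rank_pd_models(summaries, pd_table)


def _balanced_design(rng, shift=0.0, n_per_cell=10):
    rows = []
    for d in range(3):
        for p in range(4):
            x = rng.lognormal(7.5 + (shift if p == 3 else 0.0), 0.3, n_per_cell)
            rows.append(pd.DataFrame({"donor": f"d{d}", "passage": f"p{p}", "area": x}))
    return pd.concat(rows, ignore_index=True)


class TestAnova:
    def test_strong_passage_effect_detected(self):
        detected = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            df = _balanced_design(rng, shift=0.6)  # 2 SD on the log scale
            tab = stats.anova_two_way(df, "area")
            p = tab.loc[tab.effect == "passage", "p_value"].iloc[0]
            detected += p < 0.05
        assert detected >= 49

    def test_single_replicate_interaction_unidentifiable(self):
        df = _balanced_design(np.random.default_rng(0), n_per_cell=1)
        with pytest.raises(ValueError, match="interaction"):
            stats.anova_two_way(df, "area")

    def test_empty_design_cell_named_in_error(self):
        df = _balanced_design(np.random.default_rng(0))
        df = df[~((df.donor == "d2") & (df.passage == "p3"))]
        with pytest.raises(ValueError, match="d2"):
            stats.anova_two_way(df, "area")

    def test_reports_all_three_effects(self):
        tab = stats.anova_two_way(_balanced_design(np.random.default_rng(1)), "area")
        assert set(tab.effect) == {"donor", "passage", "donor:passage", "residual"}


class TestPairwiseBonferroni:
    def test_identical_groups_adjusted_p_near_one(self, rng):
        df = pd.DataFrame(
            {"passage": np.repeat(["a", "b"], 200), "area": rng.lognormal(7.5, 0.3, 400)}
        )
        out = stats.pairwise_bonferroni(df, "area", "passage")
        assert out.p_adjusted.iloc[0] > 0.2

    def test_four_groups_give_six_comparisons(self, rng):
        df = pd.DataFrame(
            {
                "passage": np.repeat(["a", "b", "c", "d"], 50),
                "area": rng.lognormal(7.5, 0.3, 200),
            }
        )
        out = stats.pairwise_bonferroni(df, "area", "passage")
        assert len(out) == 6
        assert (out.n_comparisons == 6).all()

    def test_separated_groups_all_significant(self, rng):
        df = pd.DataFrame(
            {
                "passage": np.repeat(["a", "b", "c"], 100),
                "area": np.concatenate(
                    [rng.normal(m, 1.0, 100) for m in (10.0, 13.0, 16.0)]
                ),
            }
        )
        out = stats.pairwise_bonferroni(df, "area", "passage", TransformSpec("area", 1.0))
        assert (out.p_adjusted < 0.001).all()

    def test_gate_blocks_tests_when_anova_not_significant(self, rng):
        df = pd.DataFrame(
            {"passage": np.repeat(["a", "b"], 50), "area": rng.lognormal(7.5, 0.3, 100)}
        )
        out = stats.pairwise_bonferroni(df, "area", "passage", anova_p=0.4)
        assert out.empty
        assert out.attrs["run"] is False


class TestKS:
    def test_sample_against_itself_d_zero(self, rng):
        x = rng.lognormal(7.5, 0.3, 500)
        df = pd.DataFrame(
            {"passage": ["p1"] * 500 + ["p3"] * 500, "area": np.concatenate([x, x])}
        )
        out = stats.ks_between_passages(df, "area", "p1")
        assert out.D.iloc[0] == 0.0

    def test_monotone_transform_invariance_exact(self, rng):
        df = pd.DataFrame(
            {
                "passage": np.repeat(["p1", "p3"], 400),
                "area": rng.lognormal(7.5, 0.4, 800),
            }
        )
        raw = stats.ks_between_passages(df, "area", "p1")
        logged = df.assign(area=np.log(df.area))
        log_out = stats.ks_between_passages(logged, "area", "p1")
        assert raw.D.iloc[0] == log_out.D.iloc[0]
        assert raw.p_value.iloc[0] == log_out.p_value.iloc[0]

    def test_disjoint_support_d_one(self, rng):
        df = pd.DataFrame(
            {
                "passage": np.repeat(["p1", "p3"], 100),
                "area": np.concatenate([rng.uniform(0, 1, 100), rng.uniform(5, 6, 100)]),
            }
        )
        out = stats.ks_between_passages(df, "area", "p1")
        assert out.D.iloc[0] == 1.0

    def test_tiny_sample_rejected(self):
        df = pd.DataFrame({"passage": ["p1", "p3"], "area": [1.0, 2.0]})
        with pytest.raises(ValueError):
            stats.ks_between_passages(df, "area", "p1")


class TestFoldChange:
    def test_published_passage_means_reproduce_printed_folds(self):
        out = stats.fold_change_table(
            {"p1": 1827.0, "p3": 2352.0, "p5": 4198.0, "pSEN": 8744.0}, "p1"
        )
        folds = dict(zip(out.group, out.fold_change))
        assert folds == {"p1": 1.0, "p3": 1.3, "p5": 2.3, "pSEN": 4.8}

    def test_reference_against_itself_is_one(self):
        out = stats.fold_change_table({"a": 123.0}, "a")
        assert out.fold_change.iloc[0] == 1.0

    def test_simple_ratio(self):
        out = stats.fold_change_table({"a": 100.0, "b": 250.0}, "a")
        assert out.set_index("group").fold_change_raw["b"] == 2.5

    def test_missing_or_zero_reference_rejected(self):
        with pytest.raises(KeyError):
            stats.fold_change_table({"a": 1.0}, "b")
        with pytest.raises(ValueError):
            stats.fold_change_table({"a": 0.0}, "a")
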