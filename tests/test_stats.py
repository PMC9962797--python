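import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from mmnet import (
    FeatureTable,
    boxplot_summaries,
    differential_abundance,
    fold_change,
    mann_whitney_exact,
    volcano_stats,
)
from mmnet.stats import impute_pseudo_intensity, median_scale, stars


def enumeration_oracle(x, y):
    """Independent U + exact two-sided p by direct pair counting per labeling."""
    def u_stat(a, b):
        return sum(
            1.0 if ai > bi else 0.5 if ai == bi else 0.0 for ai in a for bi in b
        )

    pooled = list(x) + list(y)
    u_obs = u_stat(x, y)
    n = len(pooled)
    us = []
    for idx in combinations(range(n), len(x)):
        xa = [pooled[i] for i in idx]
        ya = [pooled[i] for i in range(n) if i not in idx]
        us.append(u_stat(xa, ya))
    us = np.array(us)
    p = min(1.0, 2.0 * min((us <= u_obs + 1e-9).mean(), (us >= u_obs - 1e-9).mean()))
    return u_obs, p


class TestMannWhitneyExact:
    def test_separated_groups_give_enumeration_p(self):
        u, p = mann_whitney_exact([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2/20 labelings

    def test_complete_overlap_ties(self):
        u, p = mann_whitney_exact([5], [5])
        assert u == 0.5
        assert p == 1.0

    @pytest.mark.parametrize("na,nb", [(na, nb) for na in range(1, 5) for nb in range(1, 5)])
    def test_exact_p_matches_independent_enumeration(self, na, nb):
        rng = np.random.default_rng(100 * na + nb)
        for _ in range(5):
            pooled = rng.permutation(np.arange(1, na + nb + 1))  # tie-free integers
            x, y = pooled[:na], pooled[na:]
            u, p = mann_whitney_exact(x, y)
            u_ref, p_ref = enumeration_oracle(x, y)
            assert u == pytest.approx(u_ref)
            assert p == pytest.approx(p_ref)

    @pytest.mark.parametrize("na,nb", [(3, 4), (4, 4), (2, 5)])
    def test_agrees_with_scipy_exact(self, na, nb):
        rng = np.random.default_rng(7)
        for _ in range(5):
            pooled = rng.permutation(np.arange(na + nb)).astype(float)
            x, y = pooled[:na], pooled[na:]
            u, p = mann_whitney_exact(x, y)
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert u == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)

    @given(
        st.lists(st.integers(0, 20), min_size=1, max_size=6),
        st.lists(st.integers(0, 20), min_size=1, max_size=6),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_rank_sum_identity(self, x, y):
        u_xy, _ = mann_whitney_exact(x, y)
        u_yx, _ = mann_whitney_exact(y, x)
        assert u_xy + u_yx == pytest.approx(len(x) * len(y))

    def test_minimum_attainable_p_six_vs_six(self):
        u, p = mann_whitney_exact(np.arange(6), np.arange(10, 16))
        assert u == 0.0
        assert p == pytest.approx(2 / 924)
        assert stars(p) == 2  # two-star results are attainable at n=6 vs 6

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_exact([], [1.0])

    def test_large_sample_normal_approximation_close_to_scipy(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 25), rng.normal(0.8, 1, 25)
        _, p = mann_whitney_exact(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(ref.pvalue, rel=0.05)


class TestFoldChange:
    @pytest.fixture
    def two_group_table(self):
        samples = [f"a{i}" for i in range(3)] + [f"b{i}" for i in range(3)]
        design_s = pd.Series(["A"] * 3 + ["B"] * 3, index=samples)
        from mmnet import GroupDesign

        design = GroupDesign(design_s, group_order=("A", "B"))
        vals = pd.DataFrame(
            [[2.0, 2.0, 2.0, 1.0, 1.0, 1.0], [3.0, 3.0, 3.0, 3.0, 3.0, 3.0]],
            index=["m1", "m2"],
            columns=samples,
        )
        return FeatureTable(vals, "metabolite"), design

    def test_doubled_means_give_log2fc_one(self, two_group_table):
        table, design = two_group_table
        fc = fold_change(table, design, ("A", "B"), median_scaling=False)
        assert fc.loc["m1", "fc"] == pytest.approx(2.0)
        assert fc.loc["m1", "log2_fc"] == pytest.approx(1.0)

    def test_identical_groups_give_zero_log2fc(self, two_group_table):
        table, design = two_group_table
        fc = fold_change(table, design, ("A", "B"))
        assert fc.loc["m2", "log2_fc"] == pytest.approx(0.0)

    def test_swapping_groups_negates_log2fc_and_preserves_p(
        self, small_metabolite_table, small_design
    ):
        fwd = differential_abundance(
            small_metabolite_table, small_design, ("WD", "Chow")
        )
        rev = differential_abundance(
            small_metabolite_table, small_design, ("Chow", "WD")
        )
        np.testing.assert_allclose(fwd["log2_fc"], -rev["log2_fc"])
        np.testing.assert_allclose(fwd["p"], rev["p"])

    def test_zero_denominator_flagged_undefined(self, small_design):
        samples = small_design.assignments.index
        vals = pd.DataFrame(
            [[0.0] * len(samples)], index=["m1"], columns=samples
        )
        table = FeatureTable(vals, "metabolite")
        fc = fold_change(table, small_design, ("WD", "Chow"))
        assert not fc.loc["m1", "fc_defined"]
        assert np.isnan(fc.loc["m1", "log2_fc"])

    def test_median_scaling_sets_feature_median_to_one(self, small_metabolite_table):
        scaled = median_scale(small_metabolite_table.values)
        np.testing.assert_allclose(scaled.median(axis=1), 1.0)

    def test_pseudo_intensity_is_half_min_positive(self):
        df = pd.DataFrame([[0.0, 4.0, 8.0]], index=["m"], columns=list("abc"))
        out = impute_pseudo_intensity(df)
        assert out.loc["m", "a"] == 2.0


class TestVolcano:
    def test_neg_log10_of_p(self, small_metabolite_table, small_design):
        v = volcano_stats(small_metabolite_table, small_design, ("WD", "Chow"))
        np.testing.assert_allclose(v["neg_log10_p"], -np.log10(v["p"]))

    def test_undefined_fold_change_excluded(self, small_design):
        samples = small_design.assignments.index
        vals = pd.DataFrame(
            [[0.0] * len(samples), [1.0] * 6 + [2.0] * 6],
            index=["dead", "ok"],
            columns=samples,
        )
        table = FeatureTable(vals, "metabolite")
        v = volcano_stats(table, small_design, ("WD", "Chow"))
        assert "dead" not in v.index
        assert "ok" in v.index


class TestBoxplotSummaries:
    def _one_feature_table(self, values):
        samples = [f"s{i}" for i in range(len(values))]
        from mmnet import GroupDesign

        design = GroupDesign(
            pd.Series(["A"] * len(values), index=samples), group_order=("A",)
        )
        table = FeatureTable(
            pd.DataFrame([values], index=["m"], columns=samples), "metabolite"
        )
        return table, design

    def test_symmetric_sample_median_equals_mean(self):
        table, design = self._one_feature_table([1.0, 2.0, 3.0, 4.0, 5.0])
        row = boxplot_summaries(table, design, log=False).iloc[0]
        assert row["median"] == pytest.approx(np.mean([1, 2, 3, 4, 5]))

    def test_constant_feature_has_no_outliers(self):
        table, design = self._one_feature_table([2.0] * 6)
        row = boxplot_summaries(table, design, log=False).iloc[0]
        assert row["q3"] - row["q1"] == 0.0
        assert row["outliers"] == []

    def test_extreme_point_flagged_by_tukey_rule(self):
        # Q3 + 1.5 IQR = 4 + 3 < 100 by hand
        table, design = self._one_feature_table([1.0, 2.0, 3.0, 4.0, 100.0])
        row = boxplot_summaries(table, design, log=False).iloc[0]
        assert row["outliers"] == [100.0]
        assert row["whisker_high"] == 4.0

    def test_all_zero_feature_flagged(self):
        table, design = self._one_feature_table([0.0, 0.0, 0.0])
        row = boxplot_summaries(table, design).iloc[0]
        assert row["all_zero"]


def test_stars_thresholds():
    assert stars(0.049) == 1
    assert stars(0.009) == 2
    assert stars(0.05) == 0
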