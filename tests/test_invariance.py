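"""Wilcoxon signed-rank machinery and group-invariance reporting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from symptomnet import (
    invariance_report,
    make_ground_truth,
    simulate_responses,
    split_and_fit,
    wilcoxon_signed_rank,
)
from _oracles import brute_force_wilcoxon_p
from _reference import EXPECTED_W, GROUPS


class TestWilcoxonStatistics:
    @pytest.mark.parametrize("grouping, index", sorted(EXPECTED_W))
    def test_reproduces_published_rank_sums(self, grouping, index):
        a, b = GROUPS[grouping][index]
        res = wilcoxon_signed_rank(np.array(a, float), np.array(b, float))
        w_plus, w_minus = EXPECTED_W[(grouping, index)]
        assert res.w_plus == w_plus
        assert res.w_minus == w_minus

    def test_rank_sum_identity_on_published_profiles(self):
        for grouping, index in EXPECTED_W:
            a, b = GROUPS[grouping][index]
            res = wilcoxon_signed_rank(np.array(a, float), np.array(b, float))
            n = res.n_effective
            assert res.w_plus + res.w_minus == n * (n + 1) / 2

    def test_identical_vectors_degenerate(self):
        x = np.arange(5.0)
        res = wilcoxon_signed_rank(x, x)
        assert (res.w_plus, res.w_minus, res.p_value) == (0.0, 0.0, 1.0)
        assert res.method == "degenerate"

    def test_antisymmetry(self, rng):
        x = rng.random(12)
        y = rng.random(12)
        fwd = wilcoxon_signed_rank(x, y)
        rev = wilcoxon_signed_rank(y, x)
        assert fwd.w_plus == rev.w_minus
        assert fwd.w_minus == rev.w_plus
        assert fwd.p_value == pytest.approx(rev.p_value, abs=1e-12)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        st.lists(
            st.floats(-5, 5, allow_nan=False, allow_infinity=False),
            min_size=2,
            max_size=15,
        ),
        st.integers(0, 2**31 - 1),
    )
    def test_rank_sum_identity_property(self, x, seed):
        y = np.random.default_rng(seed).normal(size=len(x))
        res = wilcoxon_signed_rank(np.asarray(x), y)
        n = res.n_effective
        assert res.w_plus + res.w_minus == pytest.approx(n * (n + 1) / 2, abs=1e-9)
        assert res.w_plus >= 0 and res.w_minus >= 0
        assert 0 < res.p_value <= 1

    @pytest.mark.parametrize("n", [3, 6, 9, 12])
    def test_exact_p_matches_sign_enumeration(self, n):
        r = np.random.default_rng(n)
        for _ in range(3):
            x = r.normal(size=n)
            y = r.normal(size=n)
            res = wilcoxon_signed_rank(x, y)
            if res.method != "exact":
                continue
            d = (x - y)[(x - y) != 0]
            p_oracle = brute_force_wilcoxon_p(res.w_plus, np.abs(d))
            assert res.p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_exact_p_agrees_with_scipy(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        res = wilcoxon_signed_rank(x, y)
        ref = stats.wilcoxon(x, y, zero_method="wilcox", method="exact")
        assert res.method == "exact"
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_ties_use_normal_approximation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = x - np.array([0.5, 0.5, 1.0, -1.0, 2.0, -2.0])
        res = wilcoxon_signed_rank(x, y)
        assert res.method == "normal_approximation"

    def test_published_closeness_p_value_normal_approximation(self):
        # the no-ties gender closeness profile: normal approximation with
        # continuity correction gives the published two-sided p of 0.64
        a, b = GROUPS["gender"]["closeness"]
        from symptomnet.invariance import _normal_approx_p

        d = np.array(a) - np.array(b)
        p = _normal_approx_p(18.0, 9, np.abs(d[d != 0]))
        assert round(p, 2) == 0.64

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0])


class TestSplitAndFit:
    @pytest.fixture(scope="class")
    def grouped_table(self):
        spec = make_ground_truth(
            "chain", 9, (0.3, 0.3), seed=2, n_respondents=2000, gender_split=0.5
        )
        return simulate_responses(spec)

    def test_per_group_tables(self, grouped_table):
        out = split_and_fit(grouped_table, "gender")
        assert set(out) == {"female", "male"}
        for tab in out.values():
            assert len(tab) == 9

    def test_single_level_group_rejected(self, grouped_table):
        data = grouped_table.data.copy()
        data["gender"] = "female"
        from symptomnet.datatypes import ItemResponseTable

        with pytest.raises(ValueError, match="level"):
            split_and_fit(ItemResponseTable(data, list(grouped_table.item_columns)), "gender")

    def test_deterministic(self, grouped_table):
        a = split_and_fit(grouped_table, "gender")
        b = split_and_fit(grouped_table, "gender")
        for label in a:
            assert a[label].equals(b[label])

    def test_degenerate_item_dropped_from_both_groups(self, grouped_table):
        data = grouped_table.data.copy()
        data.loc[data["gender"] == "male", "D5"] = 0  # constant within one group
        from symptomnet.datatypes import ItemResponseTable

        table = ItemResponseTable(data, list(grouped_table.item_columns))
        with pytest.warns(UserWarning, match="dropped"):
            out = split_and_fit(table, "gender")
        for tab in out.values():
            assert "D5" not in set(tab["symptom"])


class TestInvarianceReport:
    def test_report_layout(self):
        spec = make_ground_truth(
            "chain", 9, (0.3, 0.3), seed=3, n_respondents=1500, gender_split=0.5
        )
        rep = invariance_report(simulate_responses(spec), "gender")
        assert list(rep.tests.index) == [
            "in_strength", "out_strength", "betweenness", "closeness",
        ]
        for _, row in rep.tests.iterrows():
            n = row["n_effective"]
            assert row["W_plus"] + row["W_minus"] == pytest.approx(n * (n + 1) / 2)
            assert 0 < row["p_value"] <= 1

    def test_null_calibration_median_p(self):
        # same latent structure in both groups: p-values concentrate well
        # above the rejection region even though profile-level tests share
        # sampling error across symptoms
        ps = []
        for seed in range(1, 7):
            spec = make_ground_truth(
                "chain", 9, (0.3, 0.3), seed=seed, n_respondents=3000, gender_split=0.5
            )
            rep = invariance_report(simulate_responses(spec), "gender")
            ps.extend(rep.tests["p_value"].tolist())
        assert np.median(ps) >= 0.2

    def test_power_against_strong_group_difference(self):
        spec = make_ground_truth(
            "chain", 9, (0.3, 0.3), seed=1, n_respondents=4000,
            gender_split=0.5, group_effect=0.3,
        )
        rep = invariance_report(simulate_responses(spec), "gender")
        strength_p = rep.tests.loc[["in_strength", "out_strength"], "p_value"]
        assert (strength_p < 0.05).any()
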