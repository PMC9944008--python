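"""Stoichiometry, two-group tests, factorial ANOVA and assumption checks."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from grazetrack.stats import (
    GroupSummary,
    assumption_checks,
    compare_two_groups,
    factorial_anova,
    grazing_rate,
    molar_cp,
    percent_reduction,
)


def exact_wilcoxon_p(a, b):
    """Enumeration oracle: two-sided exact Mann-Whitney p over all
    C(n1+n2, n1) relabellings of the pooled sample."""
    pooled = list(a) + list(b)
    n1, n = len(a), len(pooled)

    def u1(selection):
        sel = set(selection)
        x = [pooled[i] for i in sel]
        y = [pooled[i] for i in range(n) if i not in sel]
        gt = sum(1 for xi in x for yi in y if xi > yi)
        eq = sum(1 for xi in x for yi in y if xi == yi)
        return gt + 0.5 * eq

    obs = u1(range(n1))
    us = [u1(s) for s in itertools.combinations(range(n), n1)]
    p_le = sum(u <= obs for u in us) / len(us)
    p_ge = sum(u >= obs for u in us) / len(us)
    return min(1.0, 2 * min(p_le, p_ge))


class TestMolarCP:
    def test_one_mole_each_is_unity(self):
        assert molar_cp(12.011, 30.974) == pytest.approx(1.0)

    def test_ten_moles_carbon(self):
        assert molar_cp(120.11, 30.974) == pytest.approx(10.0)

    def test_hand_arithmetic(self):
        # (100 / 12.011) / (2.237 / 30.974) = 115.28...
        assert molar_cp(100.0, 2.237) == pytest.approx(115.3, abs=0.05)

    def test_zero_phosphorus_rejected(self):
        with pytest.raises(ValueError):
            molar_cp(10.0, 0.0)

    @given(st.floats(0.01, 1e4), st.floats(0.01, 1e4), st.floats(0.01, 100))
    def test_homogeneous_under_common_scaling(self, c, p, k):
        assert molar_cp(k * c, k * p) == pytest.approx(molar_cp(c, p), rel=1e-9)


class TestPercentReduction:
    @pytest.mark.parametrize(
        "control,treated,expected_round",
        [(1.33, 0.23, 83), (3.18, 2.48, 22), (5.0, 5.0, 0)],
    )
    def test_worked_examples(self, control, treated, expected_round):
        assert round(percent_reduction(control, treated)) == expected_round

    def test_non_positive_control_rejected(self):
        with pytest.raises(ValueError):
            percent_reduction(0.0, 1.0)


class TestGrazingRate:
    def test_no_difference_no_rate(self):
        assert grazing_rate(1.0, 1.0, 158.7, 8, 336) == 0.0

    def test_unit_check(self):
        assert grazing_rate(2.0, 1.0, 1.0, 1, 1.0) == pytest.approx(1000.0)

    def test_hand_arithmetic_full_scale(self):
        # 1.10 mg/cm2 over 158.7 cm2 shared by 8 grazers over 336 h
        rate = grazing_rate(1.33, 0.23, 158.7, 8, 336.0)
        assert rate == pytest.approx(64.9, abs=0.05)

    def test_negative_difference_clipped_with_warning(self):
        with pytest.warns(UserWarning):
            assert grazing_rate(1.0, 2.0, 158.7, 8, 336.0) == 0.0


class TestCompareTwoGroups:
    def test_identical_groups_null_result(self):
        r = compare_two_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "student")
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_summary_mode_matches_printed_resting_test(self):
        r = compare_two_groups(
            GroupSummary(27_741, 1_718, 3), GroupSummary(6_550, 2_380, 3), "student"
        )
        assert r.statistic == pytest.approx(12.50, abs=0.005)
        assert r.df == 4

    def test_raw_and_summary_student_agree(self, rng):
        a = rng.normal(10, 2, 8)
        b = rng.normal(12, 3, 6)
        raw = compare_two_groups(a, b, "student")
        summ = compare_two_groups(GroupSummary.from_data(a), GroupSummary.from_data(b), "student")
        assert raw.statistic == pytest.approx(summ.statistic, rel=1e-9)
        assert raw.p_value == pytest.approx(summ.p_value, rel=1e-9)

    def test_welch_satterthwaite_df_fractional(self):
        r = compare_two_groups(GroupSummary(10, 1, 5), GroupSummary(12, 4, 5), "welch")
        assert r.df < 8  # less than the pooled df
        assert not float(r.df).is_integer()

    def test_wilcoxon_textbook_case(self):
        r = compare_two_groups([1, 2, 3], [4, 5, 6], "wilcoxon")
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(0.10)

    @pytest.mark.parametrize("n", [2, 3, 4, 5])
    def test_wilcoxon_exact_p_equals_enumeration(self, n, rng):
        for _ in range(15):
            pool = rng.choice(10_000, size=2 * n, replace=False).astype(float)
            a, b = pool[:n], pool[n:]
            r = compare_two_groups(a, b, "wilcoxon")
            assert r.p_value == pytest.approx(exact_wilcoxon_p(a, b), abs=1e-12)

    def test_zero_variance_equal_means_reported_undefined(self):
        r = compare_two_groups(GroupSummary(5, 0, 3), GroupSummary(5, 0, 3), "student")
        assert math.isnan(r.statistic)
        assert "undefined" in r.note


class TestFactorialAnova:
    @pytest.fixture()
    def hand_fixture(self):
        return pd.DataFrame(
            {
                "y": [1, 3, 2, 4, 5, 7, 6, 8],
                "A": ["A1"] * 4 + ["A2"] * 4,
                "B": ["B1", "B1", "B2", "B2"] * 2,
            }
        )

    def test_hand_computed_sums_of_squares(self, hand_fixture):
        table, _ = factorial_anova(hand_fixture, "y", "A", "B")
        assert table.factors["A"].ss == pytest.approx(32.0)
        assert table.factors["B"].ss == pytest.approx(2.0)
        assert table.factors["A:B"].ss == pytest.approx(0.0, abs=1e-12)
        assert table.residual_ss / table.residual_df == pytest.approx(2.0)
        assert table.factors["A"].F == pytest.approx(16.0)
        assert table.factors["B"].F == pytest.approx(1.0)
        assert table.factors["A:B"].F == pytest.approx(0.0, abs=1e-12)

    def test_location_invariance(self, hand_fixture):
        shifted = hand_fixture.assign(y=hand_fixture["y"] + 1000)
        t1, _ = factorial_anova(hand_fixture, "y", "A", "B")
        t2, _ = factorial_anova(shifted, "y", "A", "B")
        for k in t1.factors:
            assert t1.factors[k].F == pytest.approx(t2.factors[k].F, rel=1e-9)

    def test_sum_of_squares_decomposition(self, rng):
        y = rng.normal(size=12)
        df = pd.DataFrame(
            {"y": y, "A": ["a", "b"] * 6, "B": ["x"] * 6 + ["z"] * 6}
        )
        table, _ = factorial_anova(df, "y", "A", "B")
        ss_total = ((y - y.mean()) ** 2).sum()
        ss_parts = sum(e.ss for e in table.factors.values()) + table.residual_ss
        assert ss_parts == pytest.approx(ss_total, rel=1e-9)

    def test_tukey_null_contrast_p_is_1(self):
        df = pd.DataFrame(
            {
                "y": [1.0, 2.0] * 4,
                "A": ["A1"] * 4 + ["A2"] * 4,
                "B": ["B1", "B1", "B2", "B2"] * 2,
            }
        )
        _, tukey = factorial_anova(df, "y", "A", "B")
        assert (tukey["p_adj"] > 0.999).all()

    def test_unbalanced_design_rejected(self, hand_fixture):
        with pytest.raises(ValueError, match="balanced"):
            factorial_anova(hand_fixture.iloc[:-1], "y", "A", "B")

    def test_degrees_of_freedom_sum_to_n_minus_1(self, hand_fixture):
        table, _ = factorial_anova(hand_fixture, "y", "A", "B")
        df_sum = sum(e.df_num for e in table.factors.values()) + table.residual_df
        assert df_sum == len(hand_fixture) - 1


class TestAssumptionChecks:
    def test_identical_groups_levene_zero(self):
        out = assumption_checks({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert out["levene"]["F"] == pytest.approx(0.0)

    def test_constant_group_shapiro_undefined(self):
        out = assumption_checks({"a": [2.0, 2.0, 2.0], "b": [1.0, 2.0, 4.0]})
        assert "note" in out["shapiro"]["a"]
        assert "p" in out["shapiro"]["b"]

    def test_small_group_skipped_with_notice(self):
        out = assumption_checks({"a": [1.0, 2.0]})
        assert "note" in out["shapiro"]["a"]

    def test_shapiro_holds_level_under_null(self):
        rng = np.random.default_rng(2024)
        rejections = 0
        for _ in range(100):
            out = assumption_checks({"g": rng.normal(size=5000)})
            rejections += out["shapiro"]["g"]["p"] <= 0.05
        assert rejections <= 10  # >= 90% of replicates keep p > 0.05
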