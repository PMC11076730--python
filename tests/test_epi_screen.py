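"""Epidemiology engine: prevalence, tests on printed summaries, classes."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oracles import fisher_enumeration_oracle
from scoliomir.datasets import (load_anthropometric_summaries,
                                load_prevalence_by_age_sex)
from scoliomir.epi_screen import (GroupSummary, ScreeningRecord, classify_management,
                                  curve_profile_table, fisher_exact_2x2,
                                  pearson_chi_square, prevalence_table, severity_of,
                                  stratum_counts_from_records, welch_t_from_summary)


def make_record(subject_id="S1", age=12, sex="female", **kwargs) -> ScreeningRecord:
    return ScreeningRecord(subject_id=subject_id, age=age, sex=sex, **kwargs)


class TestPearsonChiSquare:
    @pytest.mark.parametrize("table,expected,tol", [
        ([[357, 40758], [572, 42773]], 39.51, 0.01),       # sex difference, totals
        ([[48, 3029], [82, 3152]], 7.439, 0.01),           # sex difference at age 13
        ([[262, 369, 298], [38915, 18342, 25965]], 197.4, 0.05),  # education stage
        ([[496, 43752], [433, 39470]], 0.2466, 0.01),      # BMI category
    ])
    def test_reproduces_printed_statistics(self, table, expected, tol):
        res = pearson_chi_square(table)
        assert res.statistic == pytest.approx(expected, abs=tol)

    def test_proportional_rows_give_zero(self):
        res = pearson_chi_square([[10, 90], [20, 180]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            pearson_chi_square([[0, 0], [5, 5]])

    @given(st.lists(st.lists(st.integers(1, 200), min_size=2, max_size=4),
                    min_size=2, max_size=4).filter(
                        lambda t: len({len(r) for r in t}) == 1))
    @settings(max_examples=50, deadline=None)
    def test_permutation_invariance(self, table):
        base = pearson_chi_square(table).statistic
        rows = pearson_chi_square(table[::-1]).statistic
        cols = pearson_chi_square([r[::-1] for r in table]).statistic
        assert rows == pytest.approx(base, rel=1e-9)
        assert cols == pytest.approx(base, rel=1e-9)

    def test_agrees_with_fisher_at_large_expected_counts(self, rng):
        # asymptotic consistency: the exact and asymptotic tests converge;
        # the gap decays like 1/sqrt(N), so cells in the thousands keep it
        # below 0.02
        for _ in range(25):
            table = rng.integers(1500, 8000, size=(2, 2))
            p_chi = pearson_chi_square(table).p_value
            p_fis = fisher_exact_2x2(table).p_value
            assert abs(p_chi - p_fis) < 0.02


class TestFisherExact:
    def test_symmetric_table_p_one(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]).p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("table", [
        [[10, 990], [40, 960]],
        [[0, 10], [10, 0]],
        [[3, 7], [9, 1]],
        [[1, 1], [1, 1]],
    ])
    def test_matches_enumeration_oracle(self, table):
        (a, b), (c, d) = table
        assert fisher_exact_2x2(table).p_value == pytest.approx(
            fisher_enumeration_oracle(a, b, c, d), abs=1e-12)

    def test_degenerate_cross_table_odds_ratio_zero(self):
        res = fisher_exact_2x2([[0, 10], [10, 0]])
        assert res.odds_ratio == 0.0

    def test_infinite_odds_ratio(self):
        assert fisher_exact_2x2([[10, 0], [0, 10]]).odds_ratio == math.inf

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1.5, 2], [3, 4]])

    @given(st.tuples(st.integers(0, 25), st.integers(0, 25),
                     st.integers(0, 25), st.integers(0, 25)).filter(
                         lambda t: (t[0] + t[1]) and (t[2] + t[3])
                         and (t[0] + t[2]) and (t[1] + t[3])))
    @settings(max_examples=150, deadline=None)
    def test_random_tables_match_oracle(self, cells):
        a, b, c, d = cells
        assert fisher_exact_2x2([[a, b], [c, d]]).p_value == pytest.approx(
            fisher_enumeration_oracle(a, b, c, d), abs=1e-12)


class TestWelchT:
    @pytest.mark.parametrize("variable,expected", [
        ("height_cm", 0.650),
        ("sitting_height_cm", 2.923),
        ("weight_kg", 1.835),
    ])
    def test_reproduces_printed_t(self, variable, expected):
        groups = load_anthropometric_summaries()[variable]
        res = welch_t_from_summary(groups["is"], groups["normal"])
        assert abs(res.t) == pytest.approx(expected, abs=0.005)

    def test_equal_means_t_zero(self):
        res = welch_t_from_summary(GroupSummary(10, 5.0, 1.0), GroupSummary(20, 5.0, 2.0))
        assert res.t == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_matches_raw_data_welch(self, rng):
        a = rng.normal(10, 2, size=40)
        b = rng.normal(11, 3, size=25)
        from scipy import stats
        direct = stats.ttest_ind(a, b, equal_var=False)
        res = welch_t_from_summary(
            GroupSummary(len(a), a.mean(), a.std(ddof=1)),
            GroupSummary(len(b), b.mean(), b.std(ddof=1)))
        assert res.t == pytest.approx(direct.statistic, abs=1e-10)
        assert res.p_value == pytest.approx(direct.pvalue, abs=1e-10)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            GroupSummary(1, 0.0, 1.0)


class TestManagementClassification:
    @pytest.mark.parametrize("cobb,expected", [
        (0.0, "negative"), (9.9, "negative"),
        (10.0, "observation"), (15.0, "observation"), (19.99, "observation"),
        (20.0, "rehabilitation_or_brace"), (39.99, "rehabilitation_or_brace"),
        (40.0, "surgery"), (66.0, "surgery"),
    ])
    def test_interval_boundaries(self, cobb, expected):
        assert classify_management(cobb) == expected

    def test_severity_aliases(self):
        assert severity_of(15) == "mild"
        assert severity_of(25) == "moderate"
        assert severity_of(40) == "severe"
        assert severity_of(5) is None

    def test_negative_cobb_rejected(self):
        with pytest.raises(ValueError):
            classify_management(-1.0)

    @given(st.floats(min_value=0, max_value=200, allow_nan=False))
    @settings(max_examples=100, deadline=None)
    def test_classes_partition_nonnegative_angles(self, cobb):
        assert classify_management(cobb) in (
            "negative", "observation", "rehabilitation_or_brace", "surgery")


class TestPrevalenceTable:
    def test_reproduces_published_totals(self):
        table = prevalence_table(load_prevalence_by_age_sex())
        total = table[table["stratum"] == "total"].iloc[0]
        assert total["rate"] == pytest.approx(1.10, abs=0.005)
        assert total["male_rate"] == pytest.approx(0.87, abs=0.005)
        assert total["female_rate"] == pytest.approx(1.32, abs=0.005)
        assert total["chi_square"] == pytest.approx(39.51, abs=0.01)
        age13 = table[table["stratum"] == "13"].iloc[0]
        assert age13["male_rate"] == pytest.approx(1.56, abs=0.005)
        assert age13["female_rate"] == pytest.approx(2.54, abs=0.005)
        assert age13["chi_square"] == pytest.approx(7.439, abs=0.01)

    def test_zero_positive_stratum(self):
        counts = pd.DataFrame({
            "age": [12, 12], "sex": ["male", "female"],
            "n_screened": [100, 100], "n_positive": [0, 5]})
        row = prevalence_table(counts).iloc[0]
        assert row["male_rate"] == 0.0
        assert np.isfinite(row["chi_square"])

    def test_empty_stratum_rejected(self):
        counts = pd.DataFrame({
            "age": [12], "sex": ["male"], "n_screened": [0], "n_positive": [0]})
        with pytest.raises(ValueError, match="empty stratum"):
            prevalence_table(counts)

    def test_accepts_records(self):
        records = [make_record(f"S{i}", age=12, sex="female") for i in range(9)]
        records.append(make_record("S9", age=12, sex="female", cobb=25.0))
        records += [make_record(f"S{i}", age=12, sex="male") for i in range(10, 20)]
        table = prevalence_table(records)
        total = table[table["stratum"] == "total"].iloc[0]
        assert total["n_positive"] == 1
        assert total["female_rate"] == pytest.approx(10.0)
        counts = stratum_counts_from_records(records)
        assert counts["n_screened"].sum() == 20


class TestCurveProfile:
    def _toy_records(self):
        spec = [
            ("P1", 15.0, "single", "thoracolumbar", "left"),
            ("P2", 15.0, "single", "thoracic", "right"),
            ("P3", 25.0, "double", None, "right"),
            ("P4", 25.0, "single", "thoracolumbar", "left"),
            ("P5", 45.0, "double", None, "right"),
            ("P6", 45.0, "single", "thoracolumbar", "right"),
        ]
        return [make_record(sid, cobb=cobb, curve_pattern=pat, curve_region=reg,
                            convexity=conv)
                for sid, cobb, pat, reg, conv in spec]

    def test_cross_tab_equals_hand_count(self):
        profile = curve_profile_table(self._toy_records())
        tab = profile["severity_by_pattern"]
        assert tab.loc["mild", "single"] == 2
        assert tab.loc["moderate", "double"] == 1
        assert tab.loc["severe", "single"] == 1
        region = profile["severity_by_region"]
        assert region.loc["mild", "thoracolumbar"] == 1
        assert region["thoracolumbar"].sum() == 3
        assert profile["severity_counts"].to_dict() == {
            "mild": 2, "moderate": 2, "severe": 2}

    def test_all_double_gives_empty_single_marginals(self):
        records = [make_record(f"D{i}", cobb=30.0, curve_pattern="double",
                               convexity="left") for i in range(4)]
        profile = curve_profile_table(records)
        assert profile["severity_by_region"].to_numpy().sum() == 0

    def test_single_without_region_rejected(self):
        rec = make_record("X", cobb=30.0, curve_pattern="single", convexity="left")
        with pytest.raises(ValueError, match="lacks a region"):
            curve_profile_table([rec])

    def test_negative_record_rejected(self):
        with pytest.raises(ValueError, match="not a confirmed positive"):
            curve_profile_table([make_record("N", cobb=5.0)])


class TestScreeningRecord:
    def test_age_bounds(self):
        with pytest.raises(ValueError):
            ScreeningRecord("S", age=6, sex="male")

    def test_region_requires_single_pattern(self):
        with pytest.raises(ValueError):
            ScreeningRecord("S", age=12, sex="male", cobb=20.0,
                            curve_pattern="double", curve_region="lumbar")
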