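"""Relative quantification (2^-ddCt) and ROC diagnostics."""

import itertools

import numpy as np
import pytest
from scipy import stats

from oracles import auc_pair_counting_oracle, youden_scan_oracle
from scoliomir.qpcr_roc import (auc_confidence_interval, compare_groups,
                                delta_delta_ct, evaluate_marker, roc_auc,
                                youden_cutoff)
from scoliomir.synthetic_data import QpcrSample


def sample(sid, group, target_ct, ref_ct=20.0, target="t1"):
    return QpcrSample(subject_id=sid, group=group,
                      targets={target: (target_ct,) * 3},
                      reference=(ref_ct,) * 3)


class TestDeltaDeltaCt:
    def test_uniform_ct_gives_unit_rq(self):
        samples = [sample(f"c{i}", "case", 25.0) for i in range(3)]
        samples += [sample(f"n{i}", "control", 25.0) for i in range(3)]
        rel = delta_delta_ct(samples)
        assert np.allclose(rel["rq"], 1.0)

    def test_one_cycle_difference_halves_rq(self):
        samples = [sample("c1", "case", 25.0), sample("c2", "case", 25.0),
                   sample("n1", "control", 24.0), sample("n2", "control", 24.0)]
        rel = delta_delta_ct(samples)
        assert np.allclose(rel.loc[rel["group"] == "case", "rq"], 0.5)
        assert np.allclose(rel.loc[rel["group"] == "control", "rq"], 1.0)

    def test_calibrator_geometric_mean_is_one(self, rng):
        samples = []
        for i in range(8):
            group = "case" if i < 4 else "control"
            tct = tuple(rng.normal(25, 1, 3))
            rct = tuple(rng.normal(20, 1, 3))
            samples.append(QpcrSample(f"s{i}", group, {"t1": tct}, rct))
        rel = delta_delta_ct(samples)
        calib = rel[rel["group"] == "control"]
        assert np.exp2(np.log2(calib["rq"]).mean()) == pytest.approx(1.0, abs=1e-12)

    def test_plate_offset_cancels(self, rng):
        base = []
        shifted = []
        for i in range(6):
            group = "case" if i < 3 else "control"
            tct = rng.normal(25, 1, 3)
            rct = rng.normal(20, 1, 3)
            offset = rng.normal(0, 5)
            base.append(QpcrSample(f"s{i}", group, {"t1": tuple(tct)}, tuple(rct)))
            shifted.append(QpcrSample(f"s{i}", group, {"t1": tuple(tct + offset)},
                                      tuple(rct + offset)))
        a = delta_delta_ct(base)
        b = delta_delta_ct(shifted)
        assert np.allclose(a["rq"], b["rq"])

    def test_mismatched_target_panel_rejected(self):
        a = sample("s1", "case", 25.0, target="t1")
        b = sample("s2", "control", 25.0, target="t2")
        with pytest.raises(ValueError, match="target panel"):
            delta_delta_ct([a, b])


class TestCompareGroups:
    def test_identical_groups_p_one(self):
        stat, p = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_exact_rank_sum_matches_permutation_enumeration(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        _, p = compare_groups(a, b, test="rank_sum")
        pooled = a + b
        observed = sum(pooled.index(x) + 1 for x in a)  # rank sum of group a
        count = 0
        total = 0
        for idx in itertools.combinations(range(6), 3):
            rank_sum = sum(i + 1 for i in idx)
            total += 1
            if abs(rank_sum - 10.5) >= abs(observed - 10.5):
                count += 1
        assert p == pytest.approx(count / total)  # = 0.1
        assert p == pytest.approx(0.1)

    def test_degenerate_rank_sum(self):
        _, p = compare_groups([2.0, 2.0], [2.0, 2.0], test="rank_sum")
        assert p == 1.0

    def test_welch_log_scale_consistency(self, rng):
        from scoliomir.epi_screen import GroupSummary, welch_t_from_summary
        a = np.exp2(rng.normal(0, 1, 15))
        b = np.exp2(rng.normal(1, 2, 12))
        stat, p = compare_groups(a, b)
        la, lb = np.log2(a), np.log2(b)
        ref = welch_t_from_summary(GroupSummary(15, la.mean(), la.std(ddof=1)),
                                   GroupSummary(12, lb.mean(), lb.std(ddof=1)))
        assert stat == pytest.approx(ref.t, abs=1e-10)
        assert p == pytest.approx(ref.p_value, abs=1e-10)


class TestRocAuc:
    def test_perfect_separation(self):
        scores = [1, 2, 3, 10, 11, 12]
        labels = ["control"] * 3 + ["case"] * 3
        assert roc_auc(scores, labels, "high_predicts_case") == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([5] * 6, ["case"] * 3 + ["control"] * 3,
                       "high_predicts_case") == 0.5

    def test_hand_counted_nine_pairs(self):
        scores = [1, 2, 3, 2, 3, 4]
        labels = ["case"] * 3 + ["control"] * 3
        # 6 of 9 (case, control) pairs have case < control, 2 are ties
        assert roc_auc(scores, labels, "low_predicts_case") == pytest.approx(7 / 9)

    def test_orientation_flip_complements(self, rng):
        scores = rng.normal(size=30)
        labels = rng.choice(["case", "control"], size=30)
        while len(set(labels)) < 2:
            labels = rng.choice(["case", "control"], size=30)
        hi = roc_auc(scores, labels, "high_predicts_case")
        lo = roc_auc(scores, labels, "low_predicts_case")
        assert hi + lo == pytest.approx(1.0, abs=1e-12)

    def test_equals_mann_whitney_u(self, rng):
        case = rng.normal(1, 1, 17)
        control = rng.normal(0, 1, 23)
        u = stats.mannwhitneyu(case, control, alternative="two-sided").statistic
        auc = roc_auc(np.concatenate([case, control]),
                      ["case"] * 17 + ["control"] * 23, "high_predicts_case")
        assert auc == pytest.approx(u / (17 * 23), abs=1e-12)

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(50):
            case = rng.integers(0, 8, size=rng.integers(2, 10)).astype(float)
            control = rng.integers(0, 8, size=rng.integers(2, 10)).astype(float)
            scores = np.concatenate([case, control])
            labels = ["case"] * len(case) + ["control"] * len(control)
            assert roc_auc(scores, labels, "high_predicts_case") == pytest.approx(
                auc_pair_counting_oracle(case, control), abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2], ["case", "case"], "high_predicts_case")


class TestConfidenceInterval:
    def test_symmetric_construction_centres_on_half(self):
        scores = [1, 2, 3, 4, 1, 2, 3, 4]
        labels = ["case"] * 4 + ["control"] * 4
        lo, hi = auc_confidence_interval(scores, labels)
        assert lo + hi == pytest.approx(1.0, abs=1e-9)

    def test_delong_close_to_bootstrap(self):
        # bootstrap quantiles carry Monte-Carlo noise, so the 0.02 agreement
        # is asserted on the median gap over several independent instances
        gaps = []
        for seed in range(9):
            r = np.random.default_rng(seed)
            case = r.normal(1.0, 1.0, 23)
            control = r.normal(0.0, 1.0, 23)
            scores = np.concatenate([case, control])
            labels = ["case"] * 23 + ["control"] * 23
            d_lo, d_hi = auc_confidence_interval(scores, labels, method="delong")
            b_lo, b_hi = auc_confidence_interval(scores, labels, method="bootstrap",
                                                 n_boot=2000, seed=seed + 1)
            gaps.append(max(abs(d_lo - b_lo), abs(d_hi - b_hi)))
        assert np.median(gaps) < 0.02

    def test_perfect_separation_degenerates(self):
        scores = [0, 1, 2, 10, 11, 12]
        labels = ["control"] * 3 + ["case"] * 3
        lo, hi = auc_confidence_interval(scores, labels)
        assert lo == hi == 1.0

    def test_orientation_flip_reverses_interval(self, rng):
        case = rng.normal(1, 1, 12)
        control = rng.normal(0, 1, 15)
        scores = np.concatenate([case, control])
        labels = ["case"] * 12 + ["control"] * 15
        lo_h, hi_h = auc_confidence_interval(scores, labels, "high_predicts_case")
        lo_l, hi_l = auc_confidence_interval(scores, labels, "low_predicts_case")
        assert lo_l == pytest.approx(1 - hi_h, abs=1e-12)
        assert hi_l == pytest.approx(1 - lo_h, abs=1e-12)


class TestYoudenCutoff:
    def test_perfect_separation(self):
        scores = [1, 2, 3, 10, 11, 12]
        labels = ["control"] * 3 + ["case"] * 3
        thr, sens, spec = youden_cutoff(scores, labels, "high_predicts_case")
        assert sens == 1.0 and spec == 1.0
        assert 3 < thr < 10

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(50):
            case = rng.normal(1, 1, rng.integers(3, 12))
            control = rng.normal(0, 1, rng.integers(3, 12))
            scores = np.concatenate([case, control])
            labels = ["case"] * len(case) + ["control"] * len(control)
            thr, sens, spec = youden_cutoff(scores, labels, "high_predicts_case")
            j_best, _, _ = youden_scan_oracle(case, control)
            assert sens + spec - 1 == pytest.approx(j_best, abs=1e-12)

    def test_operating_points_on_one_over_n_grid(self, rng):
        # with 23 per group, attainable sensitivities/specificities are k/23
        case = rng.normal(-1, 1, 23)
        control = rng.normal(0, 1, 23)
        scores = np.concatenate([case, control])
        labels = ["case"] * 23 + ["control"] * 23
        _, sens, spec = youden_cutoff(scores, labels, "low_predicts_case")
        assert (sens * 23) == pytest.approx(round(sens * 23), abs=1e-9)
        assert (spec * 23) == pytest.approx(round(spec * 23), abs=1e-9)

    def test_low_orientation_threshold_on_original_scale(self):
        scores = [1.0, 2.0, 9.0, 10.0]
        labels = ["case", "case", "control", "control"]
        thr, sens, spec = youden_cutoff(scores, labels, "low_predicts_case")
        assert sens == 1.0 and spec == 1.0
        assert 2.0 < thr < 9.0


class TestEvaluateMarker:
    def test_orientation_derived_from_group_means(self, rng):
        case = rng.normal(-1.5, 0.5, 23)
        control = rng.normal(0, 0.5, 23)
        scores = np.exp2(np.concatenate([case, control]))
        labels = ["case"] * 23 + ["control"] * 23
        res = evaluate_marker(scores, labels)
        assert res.orientation == "low_predicts_case"
        assert res.ci_low <= res.auc <= res.ci_high
        assert res.auc > 0.8
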