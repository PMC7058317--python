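"""Confusion counts, accuracy, Cohen's kappa, cohort and cluster summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enfacevf.concordance import (
    ConfusionCounts,
    EstimatedField,
    ProbCategory,
    VisualFieldExam,
    accuracy_pct,
    check_reliability,
    cluster_accuracy,
    cohens_kappa,
    cohort_summary,
    confusion,
    defect_flags,
    estimated_field_from_presence,
    kappa_from_cells,
    mann_whitney_u,
    myopia_group,
    score_eye,
)
from enfacevf.mapping import map_grid


def make_exam(td_cats=None, pd_cats=None, fl=0.1, fp=0.05, fn=0.1, se=-2.0):
    n = 68
    td_cats = np.zeros(n, dtype=int) if td_cats is None else np.asarray(td_cats)
    pd_cats = td_cats.copy() if pd_cats is None else np.asarray(pd_cats)
    return VisualFieldExam(
        sensitivity_db=np.full(n, 30.0),
        td_db=np.zeros(n),
        pd_db=np.zeros(n),
        td_prob=td_cats,
        pd_prob=pd_cats,
        fixation_loss_rate=fl,
        false_pos_rate=fp,
        false_neg_rate=fn,
        md_10_2=-5.0,
        spherical_equivalent=se,
        laterality="OD",
    )


class TestReliability:
    @pytest.mark.parametrize(
        "fl,fp,fn,ok",
        [
            (0.10, 0.05, 0.10, True),
            (0.25, 0.05, 0.10, False),  # fixation-loss bound is strict
            (0.10, 0.20, 0.10, False),  # false-positive bound is strict
            (0.10, 0.05, 0.33, False),  # false-negative bound is strict
            (0.2499, 0.1999, 0.3299, True),
        ],
    )
    def test_strict_boundaries(self, fl, fp, fn, ok):
        assert check_reliability(make_exam(fl=fl, fp=fp, fn=fn)) is ok


class TestDefectFlags:
    def test_all_normal_exam_has_no_flags(self):
        exam = make_exam()
        for metric in ("TD", "PD"):
            for th in (5, 2, 1):
                assert not defect_flags(exam, metric, th).any()

    def test_deep_category_flagged_at_loose_threshold(self):
        cats = np.zeros(68, dtype=int)
        cats[0] = int(ProbCategory.P1)
        assert defect_flags(make_exam(td_cats=cats), "TD", 5)[0]

    def test_category_ladder_counts(self):
        cats = np.zeros(68, dtype=int)
        cats[:4] = [
            int(ProbCategory.NORMAL),
            int(ProbCategory.P5),
            int(ProbCategory.P2),
            int(ProbCategory.P1),
        ]
        exam = make_exam(td_cats=cats)
        assert defect_flags(exam, "TD", 5).sum() == 3
        assert defect_flags(exam, "TD", 2).sum() == 2
        assert defect_flags(exam, "TD", 1).sum() == 1

    def test_nesting_over_random_exams(self, rng):
        for _ in range(100):
            cats = rng.integers(0, 5, size=68)
            exam = make_exam(td_cats=cats, pd_cats=rng.integers(0, 5, size=68))
            for metric in ("TD", "PD"):
                f1 = defect_flags(exam, metric, 1)
                f2 = defect_flags(exam, metric, 2)
                f5 = defect_flags(exam, metric, 5)
                assert not (f1 & ~f2).any()
                assert not (f2 & ~f5).any()

    def test_unknown_metric_or_threshold_rejected(self):
        with pytest.raises(ValueError):
            defect_flags(make_exam(), "MD", 5)
        with pytest.raises(ValueError):
            defect_flags(make_exam(), "TD", 3)


class TestEstimatedField:
    def test_all_present_means_no_defect(self):
        est = estimated_field_from_presence(np.ones(68, dtype=bool))
        assert not est.defect.any()

    def test_inferior_retinal_absence_becomes_superior_field_defect(self, grid):
        pts = map_grid(grid, "OD")
        presence = np.ones(68, dtype=bool)
        for r in pts:  # NFB absent on the inferior retina (y_mm < 0)
            if r.y_mm < 0:
                presence[r.source_index] = False
        est = estimated_field_from_presence(presence, "OD")
        for p in grid:
            assert est.defect[p.index] == (p.y_deg > 0)

    def test_double_negation_is_identity(self, rng):
        presence = rng.random(68) < 0.5
        est = estimated_field_from_presence(presence)
        assert np.array_equal(~est.defect, presence)


class TestConfusionAndAccuracy:
    def test_equal_fields_count_only_diagonal(self, rng):
        flags = rng.random(68) < 0.3
        c = confusion(EstimatedField(flags), flags)
        k = int(flags.sum())
        assert (c.positive, c.negative) == (k, 68 - k)
        assert (c.false_positive, c.false_negative) == (0, 0)

    def test_all_defect_vs_all_normal(self):
        c = confusion(EstimatedField(np.ones(68, bool)), np.zeros(68, bool))
        assert c.false_positive == 68

    def test_constructed_overlap_counts(self):
        est = np.zeros(68, bool)
        act = np.zeros(68, bool)
        est[:34] = True  # 30 shared + 4 est-only
        act[:30] = True
        act[34:38] = True  # 4 actual-only
        c = confusion(EstimatedField(est), act)
        assert (c.positive, c.negative, c.false_positive, c.false_negative) == (
            30,
            30,
            4,
            4,
        )
        assert accuracy_pct(c) == pytest.approx(60 / 68 * 100, abs=1e-12)

    @pytest.mark.parametrize(
        "cells,expected",
        [((0, 68, 0, 0), 100.0), ((0, 0, 34, 34), 0.0)],
    )
    def test_accuracy_extremes(self, cells, expected):
        assert accuracy_pct(ConfusionCounts(*cells)) == expected

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion(EstimatedField(np.zeros(68, bool)), np.zeros(67, bool))


class TestKappa:
    def test_perfect_agreement_with_both_classes(self):
        assert cohens_kappa(ConfusionCounts(20, 48, 0, 0)) == 1.0

    def test_hand_computed_example(self):
        # p_o = 60/68, p_e = (24^2 + 44^2)/68^2 -> kappa = 49/66
        assert cohens_kappa(ConfusionCounts(20, 40, 4, 4)) == pytest.approx(
            49 / 66, abs=1e-12
        )

    def test_degenerate_table_is_undefined_not_zero(self):
        assert np.isnan(cohens_kappa(ConfusionCounts(0, 68, 0, 0)))
        assert np.isnan(cohens_kappa(ConfusionCounts(68, 0, 0, 0)))

    def test_independent_fields_give_near_zero_kappa(self, rng):
        # simulation oracle: independent est/actual at large n
        n = 200_000
        est = rng.random(n) < 0.4
        act = rng.random(n) < 0.3
        k = kappa_from_cells(
            np.sum(est & act),
            np.sum(~est & ~act),
            np.sum(est & ~act),
            np.sum(~est & act),
        )
        assert abs(k) < 0.01

    def test_brute_force_recount_oracle(self, rng):
        for _ in range(200):
            est = rng.random(68) < rng.uniform(0.1, 0.9)
            act = rng.random(68) < rng.uniform(0.1, 0.9)
            c = confusion(EstimatedField(est), act)
            # independent recount and direct formula evaluation
            pos = sum(1 for e, a in zip(est, act) if e and a)
            neg = sum(1 for e, a in zip(est, act) if not e and not a)
            fp = sum(1 for e, a in zip(est, act) if e and not a)
            fn = sum(1 for e, a in zip(est, act) if not e and a)
            assert (c.positive, c.negative, c.false_positive, c.false_negative) == (
                pos,
                neg,
                fp,
                fn,
            )
            assert accuracy_pct(c) == pytest.approx((pos + neg) / 68 * 100, abs=1e-12)
            p_o = (pos + neg) / 68
            p_e = ((pos + fp) * (pos + fn) + (neg + fp) * (neg + fn)) / 68**2
            if p_e < 1:
                assert cohens_kappa(c) == pytest.approx(
                    (p_o - p_e) / (1 - p_e), abs=1e-12
                )

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        est_bits=st.lists(st.booleans(), min_size=68, max_size=68),
        act_bits=st.lists(st.booleans(), min_size=68, max_size=68),
    )
    def test_agrees_with_sklearn(self, est_bits, act_bits):
        from sklearn.metrics import cohen_kappa_score

        est = np.array(est_bits)
        act = np.array(act_bits)
        mine = cohens_kappa(confusion(EstimatedField(est), act))
        if len(set(est) | set(act)) < 2:
            assert np.isnan(mine)
        else:
            ref = cohen_kappa_score(est, act)
            if np.isnan(ref):
                assert np.isnan(mine) or mine == pytest.approx(0.0)
            else:
                assert mine == pytest.approx(ref, abs=1e-10)

    def test_kappa_one_iff_no_errors(self, rng):
        flags = rng.random(68) < 0.4
        c = confusion(EstimatedField(flags), flags)
        assert cohens_kappa(c) == 1.0
        assert accuracy_pct(c) == 100.0


class TestClusterAccuracy:
    def test_perfect_agreement_everywhere(self, clustered_grid, rng):
        flags = rng.random(68) < 0.4
        acc = cluster_accuracy(EstimatedField(flags), flags, clustered_grid)
        assert acc == {"C1": 100.0, "C2": 100.0, "C3": 100.0}

    def test_errors_confined_to_c2(self, clustered_grid):
        act = np.zeros(68, bool)
        est = act.copy()
        c2 = clustered_grid.cluster_indices("C2")
        est[list(c2[:2])] = True  # two false positives inside C2
        acc = cluster_accuracy(EstimatedField(est), act, clustered_grid)
        assert acc["C1"] == 100.0 and acc["C3"] == 100.0
        assert acc["C2"] == pytest.approx((len(c2) - 2) / len(c2) * 100)

    def test_weighted_cluster_mean_equals_overall(self, clustered_grid, rng):
        for _ in range(50):
            est = rng.random(68) < 0.5
            act = rng.random(68) < 0.5
            acc = cluster_accuracy(EstimatedField(est), act, clustered_grid)
            weighted = sum(
                len(clustered_grid.cluster_indices(c)) * acc[c] for c in acc
            ) / 68
            overall = accuracy_pct(confusion(EstimatedField(est), act))
            assert weighted == pytest.approx(overall, abs=1e-9)


class TestCohortSummary:
    def _result(self, clustered_grid, est, act_cats, se):
        exam = make_exam(td_cats=act_cats, se=se)
        return {
            (m, t): score_eye(EstimatedField(est), exam, clustered_grid, m, t)
            for m in ("TD", "PD")
            for t in (5, 2, 1)
        }

    def test_single_eye_summary_equals_eye(self, clustered_grid, rng):
        est = rng.random(68) < 0.3
        cats = np.where(est, int(ProbCategory.P1), 0)
        res = {"e0": self._result(clustered_grid, est, cats, -2.0)}
        s = cohort_summary(res, {"e0": -2.0})
        assert s.loc["total", "kappa_TD_lt1"] == pytest.approx(
            res["e0"][("TD", 1)].kappa
        )
        assert s.loc["total", "accuracy_PD_lt5"] == pytest.approx(
            res["e0"][("PD", 5)].accuracy_pct
        )

    def test_mean_of_two_eyes(self, clustered_grid):
        est_a = np.zeros(68, bool)
        est_a[:20] = True
        cats_a = np.zeros(68, int)
        cats_a[:20] = int(ProbCategory.P1)  # perfect -> kappa 1
        est_b = np.zeros(68, bool)
        est_b[:24] = True
        cats_b = np.zeros(68, int)
        cats_b[:20] = int(ProbCategory.P1)  # 4 false positives
        res = {
            "a": self._result(clustered_grid, est_a, cats_a, -1.0),
            "b": self._result(clustered_grid, est_b, cats_b, -8.0),
        }
        s = cohort_summary(res, {"a": -1.0, "b": -8.0})
        ka = res["a"][("TD", 1)].kappa
        kb = res["b"][("TD", 1)].kappa
        assert s.loc["total", "kappa_TD_lt1"] == pytest.approx((ka + kb) / 2)
        assert s.loc["non_high_myopia", "n_eyes"] == 1
        assert s.loc["high_myopia", "n_eyes"] == 1

    def test_minus_six_diopters_is_non_high_myopia(self):
        assert myopia_group(-6.0) == "non_high"
        assert myopia_group(-6.01) == "high"

    def test_groups_partition_cohort(self, clustered_grid, rng):
        est = rng.random(68) < 0.3
        cats = np.where(est, int(ProbCategory.P1), 0)
        ses = {f"e{i}": float(se) for i, se in enumerate(rng.uniform(-11, 2, 9))}
        res = {k: self._result(clustered_grid, est, cats, v) for k, v in ses.items()}
        s = cohort_summary(res, ses)
        assert (
            s.loc["non_high_myopia", "n_eyes"] + s.loc["high_myopia", "n_eyes"]
            == s.loc["total", "n_eyes"]
        )


class TestMannWhitney:
    def test_identical_samples_give_p_one(self):
        out = mann_whitney_u([1.0, 2.0], [1.0, 2.0])
        assert out["p_two_sided"] == pytest.approx(1.0)

    def test_fully_separated_small_samples(self):
        out = mann_whitney_u([1, 2], [3, 4])
        assert out["U"] == 0.0
        assert out["p_two_sided"] == pytest.approx(2 / 6)

    def test_u_symmetry(self, rng):
        a = rng.normal(size=6).tolist()
        b = rng.normal(size=5).tolist()
        ab = mann_whitney_u(a, b)
        ba = mann_whitney_u(b, a)
        assert ab["U"] + ba["U"] == pytest.approx(len(a) * len(b))
        assert ab["p_two_sided"] == pytest.approx(ba["p_two_sided"])

    def test_exact_path_matches_scipy_without_ties(self, rng):
        from scipy import stats

        a = rng.normal(size=5)
        b = rng.normal(size=7) + 0.5
        mine = mann_whitney_u(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert mine["U"] == pytest.approx(float(ref.statistic))
        assert mine["p_two_sided"] == pytest.approx(float(ref.pvalue), abs=1e-12)

    def test_large_samples_use_tie_corrected_normal(self, rng):
        from scipy import stats

        a = rng.integers(0, 5, size=30).astype(float)
        b = rng.integers(0, 5, size=25).astype(float)
        mine = mann_whitney_u(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert mine["p_two_sided"] == pytest.approx(float(ref.pvalue), rel=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])
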