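"""Repeated-measures screen, BH adjustment, fold changes, marker selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xenoplasma.screen import (
    ScreenThresholds,
    bh_adjust,
    log2_fold_change,
    one_way_anova,
    pearson_with_volume,
    rm_anova,
    select_markers,
    unpaired_t,
    venn_sets,
)


def brute_force_bh(p):
    """Independently coded BH step-up: q_i = min_{j: p_j >= p_i} p_j m / rank_j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    q = np.empty(m)
    order = np.argsort(p, kind="mergesort")
    for pos, i in enumerate(order):
        candidates = [p[order[k]] * m / (k + 1) for k in range(pos, m)]
        q[i] = min(1.0, min(candidates))
    return q


class TestRmAnova:
    def test_flat_data_gives_f_zero_p_one(self):
        f, p, _ = rm_anova(np.full((4, 3), 2.5))
        assert f == 0.0 and p == 1.0

    def test_two_day_design_equals_squared_paired_t(self):
        # day0 = {1,2,3}, day1 = {2,3,5}: paired t = 4, F = t^2 = 16
        x = np.array([[1.0, 2.0], [2.0, 3.0], [3.0, 5.0]])
        f, p, df = rm_anova(x)
        assert f == pytest.approx(16.0, rel=1e-12)
        assert p == pytest.approx(0.0572, abs=2e-4)
        assert df == (1, 2)

    def test_minimal_design_matches_hand_computed_ss(self):
        x = np.array([[1.0, 3.0], [2.0, 8.0]])
        # grand 3.5; SS_subj = 2((2-3.5)^2+(5-3.5)^2) = 9; SS_time =
        # 2((1.5-3.5)^2+(5.5-3.5)^2) = 16; SS_tot = 29; SS_err = 4
        f, _, df = rm_anova(x)
        assert df == (1, 1)
        assert f == pytest.approx((16.0 / 1) / (4.0 / 1), rel=1e-12)

    def test_matches_pingouin_on_random_data(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        x = rng.normal(size=(6, 4)) + rng.normal(size=(6, 1))
        f, p, _ = rm_anova(x)
        long = pd.DataFrame({
            "y": x.ravel(),
            "subject": np.repeat(np.arange(6), 4),
            "day": np.tile(np.arange(4), 6),
        })
        ref = pingouin.rm_anova(data=long, dv="y", within="day",
                                subject="subject")
        assert f == pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)
        assert p == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-9)

    def test_incomplete_animals_dropped(self):
        x = np.array([[1.0, 2.0], [2.0, 3.0], [3.0, 5.0],
                      [np.nan, 9.0]])
        f_complete, _, _ = rm_anova(x[:3])
        f_dropped, _, _ = rm_anova(x)
        assert f_dropped == pytest.approx(f_complete)

    def test_fewer_than_two_complete_animals_is_undefined(self):
        x = np.array([[1.0, np.nan], [2.0, 3.0]])
        f, p, _ = rm_anova(x)
        assert np.isnan(f) and np.isnan(p)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_applied_step_up(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=25)
        q = bh_adjust(p)
        perm = rng.permutation(25)
        assert bh_adjust(p[perm]) == pytest.approx(q[perm])

    def test_nan_propagates_without_counting(self):
        q = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        assert q[[0, 2]] == pytest.approx(bh_adjust([0.01, 0.04]))

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=60))
    def test_matches_brute_force_step_up(self, p):
        assert np.max(np.abs(bh_adjust(p) - brute_force_bh(p))) < 1e-12

    def test_matches_statsmodels_on_large_vector(self):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(1)
        p = rng.uniform(size=1000)
        ours = bh_adjust(p)
        theirs = sm.multipletests(p, method="fdr_bh")[1]
        assert np.max(np.abs(ours - theirs)) < 1e-12


class TestFoldChange:
    def make(self, day_values):
        """3 animals; day_values maps day -> per-animal multipliers of day 0."""
        rows, sig = [], []
        for animal in range(3):
            for day, mult in day_values.items():
                rows.append({"AnimalId": f"m{animal}", "StudyDay": day})
                sig.append(100.0 * (mult[animal] if day else 1.0))
        idx = pd.Index([f"s{i}" for i in range(len(rows))])
        return (pd.Series(sig, index=idx),
                pd.DataFrame(rows, index=idx))

    def test_uniform_doubling_gives_plus_one(self):
        sig, meta = self.make({0: None, 9: [2, 2, 2]})
        fc = log2_fold_change(sig, meta)
        assert fc[9] == pytest.approx(1.0)

    def test_no_change_gives_zero(self):
        sig, meta = self.make({0: None, 9: [1, 1, 1]})
        assert log2_fold_change(sig, meta)[9] == pytest.approx(0.0)

    def test_median_of_animal_ratios(self):
        sig, meta = self.make({0: None, 9: [2, 4, 8]})
        assert log2_fold_change(sig, meta)[9] == pytest.approx(2.0)

    def test_animal_without_baseline_excluded(self):
        sig, meta = self.make({0: None, 9: [2, 4, 8]})
        keep = ~((meta["AnimalId"] == "m2") & (meta["StudyDay"] == 0))
        fc = log2_fold_change(sig[keep], meta[keep])
        assert fc[9] == pytest.approx(1.5)  # median of {1, 2}


class TestPearson:
    def test_perfect_linear_gives_one(self):
        assert pearson_with_volume([1, 2, 3, 4], [0, 10, 20, 30]) == \
            pytest.approx(1.0)

    def test_constant_signal_undefined(self):
        assert np.isnan(pearson_with_volume([5, 5, 5, 5], [0, 1, 2, 3]))

    def test_matches_direct_formula(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([1.0, 2.0, 2.0, 4.0])
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert pearson_with_volume(y, x) == pytest.approx(num / den, rel=1e-12)


class TestOneWayTests:
    def test_equal_means_f_zero(self):
        f, p = one_way_anova([np.array([1.0, 2.0]), np.array([2.0, 1.0])])
        assert f == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_unpaired_t_hand_computed(self):
        t, p = unpaired_t([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert p == pytest.approx(0.0214, abs=1e-3)

    def test_three_group_f_matches_ss_decomposition(self):
        groups = [np.array([1.0, 2.0, 3.0]), np.array([2.0, 4.0, 4.0]),
                  np.array([8.0, 9.0, 7.0])]
        allv = np.concatenate(groups)
        ss_between = sum(len(g) * (g.mean() - allv.mean()) ** 2 for g in groups)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        expect = (ss_between / 2) / (ss_within / 6)
        f, _ = one_way_anova(groups)
        assert f == pytest.approx(expect, rel=1e-12)


def make_screen_frame(rows):
    return pd.DataFrame(rows).set_index("analyte")


class TestSelectMarkers:
    base = dict(F=10.0, p=0.001)

    def frame(self, **overrides):
        row = {"analyte": "a1", **self.base, "q": 0.04, "max_abs_log2fc": 1.5,
               "pearson_r": 0.6, **overrides}
        return make_screen_frame([row])

    def test_passing_analyte_selected(self):
        ms = select_markers(self.frame(), None, "g")
        assert set(ms.analytes) == {"a1"}

    def test_weak_correlation_excluded(self):
        ms = select_markers(self.frame(pearson_r=0.2), None, "g")
        assert set(ms.analytes) == set()

    def test_negative_correlation_magnitude_counts(self):
        ms = select_markers(self.frame(pearson_r=-0.6), None, "g")
        assert set(ms.analytes) == {"a1"}

    def test_control_changes_subtracted(self):
        control = self.frame()  # same analyte significant in controls
        ms = select_markers(self.frame(), control, "g")
        assert set(ms.analytes) == set()

    def test_nan_statistics_fail_filters(self):
        ms = select_markers(self.frame(q=np.nan), None, "g")
        assert set(ms.analytes) == set()

    def test_tightening_thresholds_is_monotone(self):
        rng = np.random.default_rng(4)
        rows = [{"analyte": f"a{i}", "F": 1.0, "p": rng.uniform(),
                 "q": rng.uniform(), "max_abs_log2fc": rng.uniform(0, 3),
                 "pearson_r": rng.uniform(-1, 1)} for i in range(200)]
        frame = make_screen_frame(rows)
        loose = select_markers(frame, None, "g",
                               ScreenThresholds(0.2, 0.5, 0.1))
        for tight in [ScreenThresholds(0.1, 0.5, 0.1),
                      ScreenThresholds(0.2, 1.5, 0.1),
                      ScreenThresholds(0.2, 0.5, 0.5),
                      ScreenThresholds(0.05, 1.0, 0.25)]:
            assert select_markers(frame, None, "g", tight).analytes \
                <= loose.analytes


class TestVennSets:
    def test_two_set_algebra(self):
        res = venn_sets({"x": {"a", "b", "c"}, "y": {"b", "c", "d"}})
        assert res.intersection == {"b", "c"}
        assert res.unique["x"] == {"a"}
        assert res.unique["y"] == {"d"}
        assert res.pairwise_shared[("x", "y")] == {"b", "c"}

    def test_identical_sets_intersect_to_themselves(self):
        sets = {f"s{i}": {"a", "b"} for i in range(8)}
        assert venn_sets(sets).intersection == {"a", "b"}

    def test_order_invariance(self):
        sets = {"x": {"a", "b"}, "y": {"b", "c"}, "z": {"b"}}
        res1 = venn_sets(sets)
        res2 = venn_sets(dict(reversed(list(sets.items()))))
        assert res1.intersection == res2.intersection
        assert res1.unique == res2.unique


class TestScreenOnSynthetic:
    def test_planted_markers_recovered_exactly(self, nsclc_screens):
        """At the generator's default signal-to-noise (6 animals,
        sigma_log 0.05, A/C = 2), selection is perfectly sensitive and
        specific against the planted truth."""
        _, truth, _, screens = nsclc_screens
        for group in ("H1650", "H1975"):
            ms = select_markers(screens[group], screens["control"], group)
            assert set(ms.analytes) == truth.responders(group)

    def test_screen_invariant_to_analyte_order(self, nsclc_normalized):
        from xenoplasma.screen import screen_group

        _, _, normalized, _ = nsclc_normalized
        small = normalized.copy()
        keep = list(small.values.columns[:30]) + list(small.values.columns[-12:])
        small.values = small.values[keep]
        small.analytes = small.analytes.loc[keep]
        res = screen_group(small, "H1650")
        shuffled = small.copy()
        perm = list(np.random.default_rng(0).permutation(keep))
        shuffled.values = shuffled.values[perm]
        shuffled.analytes = shuffled.analytes.loc[perm]
        res2 = screen_group(shuffled, "H1650")
        pd.testing.assert_frame_equal(res2.sort_index(), res.sort_index())
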