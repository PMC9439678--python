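"""Circular statistics, pair correlations, association analyses."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from neuropose import circstats as cs
from neuropose import popstats as ps


class TestCircularDescriptives:
    def test_identical_angles_have_zero_variance(self):
        assert cs.circ_variance([33.0] * 10) == pytest.approx(0.0)

    def test_balanced_cross_has_unit_variance(self):
        assert cs.circ_variance([0.0, 90.0, 180.0, 270.0]) == pytest.approx(1.0)

    def test_two_angle_resultant_arithmetic(self):
        # {0, 90}: resultant length cos(45 deg)
        assert cs.circ_variance([0.0, 90.0]) == pytest.approx(
            1.0 - np.cos(np.deg2rad(45.0)), abs=1e-12)

    @given(st.lists(st.floats(0, 360), min_size=3, max_size=30),
           st.floats(-360, 360))
    def test_rotation_invariance(self, angles, shift):
        a = np.asarray(angles)
        assert cs.circ_variance(a) == pytest.approx(
            cs.circ_variance(a + shift), abs=1e-9)


class TestRayleigh:
    def test_uniform_grid_not_rejected(self):
        assert cs.rayleigh_test(np.arange(0.0, 360.0, 45.0)) > 0.9

    def test_power_against_von_mises(self):
        rng = np.random.default_rng(0)
        hits = sum(
            cs.rayleigh_test(np.rad2deg(rng.vonmises(0, 2.0, 100))) < 0.01
            for _ in range(200))
        assert hits / 200 >= 0.95

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            cs.rayleigh_test([0.0, 10.0, 20.0])


class TestCircMedianTest:
    def test_symmetric_sample_accepts_null(self):
        assert cs.circ_median_test([-30, -10, 10, 30, -5, 5], 0.0) == 1.0

    def test_shifted_sample_rejected(self):
        rng = np.random.default_rng(1)
        hits = sum(
            cs.circ_median_test(np.rad2deg(rng.vonmises(np.pi / 2, 2.0, 100)),
                                0.0) < 0.01
            for _ in range(200))
        assert hits / 200 >= 0.95

    def test_boundary_angles_excluded(self):
        # all mass exactly on the test axis: no information, p = 1
        assert cs.circ_median_test([0.0, 180.0, 0.0, 180.0, 0.0], 0.0) == 1.0


class TestConcentrationDifference:
    def test_same_sample_permutation_p_near_one(self):
        rng = np.random.default_rng(2)
        a = np.rad2deg(rng.vonmises(0, 2.0, 50))
        assert cs.concentration_difference_test(a, a, method="permutation",
                                                n_perm=200) > 0.9

    def test_power_low_vs_high_concentration(self):
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(100):
            a = np.rad2deg(rng.vonmises(0, 1.0, 100))
            b = np.rad2deg(rng.vonmises(0.5, 8.0, 100))
            hits += cs.concentration_difference_test(a, b, n_perm=500) < 0.01
        assert hits / 100 >= 0.95

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            cs.concentration_difference_test([0.0] * 5, [0.0] * 20)


class TestType2Regression:
    def test_exact_line(self):
        x = np.arange(10.0)
        slope, intercept = ps.type2_regression(x, 2.0 * x)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(0.0)

    def test_swap_inverts_slope_exactly(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 200)
        y = 0.5 * x + rng.normal(0, 0.3, 200)
        s_xy, _ = ps.type2_regression(x, y)
        s_yx, _ = ps.type2_regression(y, x)
        assert s_xy * s_yx == pytest.approx(1.0, abs=1e-12)

    def test_slope_equals_sd_ratio(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 2.0, 10_000)
        y = 0.6 * x + rng.normal(0, 1.0, 10_000)
        slope, _ = ps.type2_regression(x, y)
        assert slope == pytest.approx(np.std(y, ddof=1) / np.std(x, ddof=1),
                                      rel=1e-12)
        assert slope == pytest.approx(np.sqrt(0.36 * 4 + 1) / 2.0, rel=0.02)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            ps.type2_regression(np.ones(5), np.arange(5.0))


class TestPreferenceDifferences:
    @staticmethod
    def records(rng, n_with=60, n_without=60, aligned_kappa=4.0):
        recs = []
        for i in range(n_with):
            tilt = rng.uniform(0, 360)
            diff = np.rad2deg(rng.vonmises(0, aligned_kappa))
            recs.append(ps.AssociationRecord(
                f"c{i}", principal_tilt=tilt, tolerance=rng.uniform(0.4, 1.0),
                saccade_pref=(tilt - diff) % 360.0, has_choice=True,
                has_saccade=True))
        for i in range(n_without):
            recs.append(ps.AssociationRecord(
                f"n{i}", principal_tilt=rng.uniform(0, 360),
                tolerance=rng.uniform(0.0, 0.7),
                saccade_pref=rng.uniform(0, 360), has_choice=False,
                has_saccade=True))
        return recs

    def test_alignment_only_in_choice_flagged_split(self):
        rng = np.random.default_rng(6)
        out = ps.preference_difference_analysis(self.records(rng))
        with_c = out["splits"]["with_choice"]
        without_c = out["splits"]["without_choice"]
        assert with_c["rayleigh_p"] < 0.05
        assert without_c["rayleigh_p"] > 0.05
        assert with_c["cv"] < without_c["cv"]
        assert with_c["median_vs_zero_p"] > 0.05
        assert out["concentration_difference_p"] < 0.05

    def test_identical_preferences_give_zero_differences(self):
        recs = [ps.AssociationRecord(str(i), principal_tilt=120.0,
                                     tolerance=0.5, saccade_pref=120.0,
                                     has_choice=i % 2 == 0, has_saccade=True)
                for i in range(40)]
        out = ps.preference_difference_analysis(recs)
        for split in out["splits"].values():
            assert np.allclose(split["differences"], 0.0)
            assert split["cv"] == pytest.approx(0.0)

    def test_independent_preferences_look_uniform(self):
        rng = np.random.default_rng(7)
        uniform = 0
        n_sims = 50
        for _ in range(n_sims):
            recs = self.records(rng, aligned_kappa=0.0)
            # make the flagged split independent/uniform too
            out = ps.preference_difference_analysis(recs)
            uniform += all(s["rayleigh_p"] > 0.05
                           for s in out["splits"].values())
        assert uniform / n_sims >= 0.85


class TestModerationRegression:
    def test_flat_relation_gives_zero_slopes(self):
        rng = np.random.default_rng(8)
        recs = []
        for i in range(200):
            y = 60.0 + rng.normal(0, 5)
            recs.append(ps.AssociationRecord(
                str(i), principal_tilt=y, tolerance=rng.uniform(0, 1),
                saccade_pref=0.0, has_choice=i % 2 == 0, has_saccade=True))
        out = ps.moderation_regression(recs)
        assert abs(out["slope_without_choice"]) < 3.0
        assert abs(out["slope_with_choice"]) < 3.0
        assert out["p"]["interaction"] > 0.01

    def test_interaction_detected(self):
        rng = np.random.default_rng(9)
        recs = []
        for i in range(400):
            tol = rng.uniform(0, 1)
            flag = i % 2 == 0
            y = 90.0 + (-60.0 * tol if flag else 0.0) + rng.normal(0, 10)
            recs.append(ps.AssociationRecord(
                str(i), principal_tilt=float(np.clip(y, 0, 180)), tolerance=tol,
                saccade_pref=0.0, has_choice=flag, has_saccade=True))
        out = ps.moderation_regression(recs)
        assert out["p"]["interaction"] < 1e-6
        assert out["slope_with_choice"] < out["slope_without_choice"]

    def test_single_group_rejected(self):
        recs = [ps.AssociationRecord(str(i), principal_tilt=10.0, tolerance=0.5,
                                     saccade_pref=0.0, has_choice=True)
                for i in range(20)]
        with pytest.raises(ValueError):
            ps.moderation_regression(recs)
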