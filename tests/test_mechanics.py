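"""Tensile-test analysis: rupture detection, background, bowstring, summary."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fibrilmech import mechanics as mech
from fibrilmech import synth
from fibrilmech.mechanics import StressStrainCurve


class TestDetectRupture:
    def test_constructed_step(self):
        f = np.concatenate([np.full(50, 5.0), np.full(50, 0.5)])
        assert mech.detect_rupture(f) == 49

    def test_monotone_ramp_rejected(self):
        with pytest.raises(ValueError, match="no rupture"):
            mech.detect_rupture(np.linspace(0, 10, 100))

    def test_two_drops_takes_larger(self):
        f = np.concatenate([np.full(30, 5.0), np.full(30, 3.0),
                            np.full(30, -2.0)])
        assert mech.detect_rupture(f) == 59

    def test_small_drop_below_noise_threshold_rejected(self):
        rng = np.random.default_rng(0)
        f = rng.normal(0, 1.0, 300)
        f[:150] += 0.5  # half-sigma step is not a rupture
        with pytest.raises(ValueError, match="no rupture"):
            mech.detect_rupture(f)


class TestSubtractBackground:
    def test_step_trace_post_mean_zero(self):
        f = np.concatenate([np.full(40, 7.0), np.full(40, 2.0)])
        out = mech.subtract_background(f, 39)
        assert out[40:].mean() == pytest.approx(0.0, abs=1e-14)
        assert out[:40] == pytest.approx(5.0)

    def test_pure_friction_mean_near_zero(self, rng):
        f = rng.normal(1.3, 0.2, 2000)
        out = mech.subtract_background(f, 999)
        n = 1000
        assert abs(out[1000:].mean()) < 0.2 / np.sqrt(n) + 1e-12

    def test_zero_background_identity(self):
        f = np.concatenate([np.linspace(0, 5, 50), np.zeros(50)])
        assert np.allclose(mech.subtract_background(f, 49), f)

    def test_short_post_window_rejected(self):
        with pytest.raises(ValueError, match="post-rupture"):
            mech.subtract_background(np.ones(20), 18)


class TestSmoothAdjacent:
    def test_constant_unchanged(self):
        f = np.full(30, 4.2)
        assert np.allclose(mech.smooth_adjacent(f, 5), f)

    def test_window_one_identity(self):
        f = np.random.default_rng(1).normal(size=50)
        assert np.array_equal(mech.smooth_adjacent(f, 1), f)

    def test_impulse_plateau(self):
        f = np.zeros(21)
        f[10] = 5.0
        out = mech.smooth_adjacent(f, 5)
        assert np.allclose(out[8:13], 1.0)
        assert np.allclose(out[:8], 0.0) and np.allclose(out[13:], 0.0)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            mech.smooth_adjacent(np.ones(10), 4)

    def test_linear_ramp_preserved_interior_and_edges(self):
        # symmetric shrinking edge windows keep a linear trend exact
        f = np.linspace(0, 10, 40)
        assert np.allclose(mech.smooth_adjacent(f, 5), f)


class TestSynchronize:
    def test_identity_when_already_aligned(self):
        t = np.linspace(0, 10, 201)
        f = np.linspace(0, 5, 201)
        d = np.linspace(0, 10, 201)
        ti, di, fi, k = mech.synchronize(t, f, t, d, 100, 100)
        assert np.allclose(ti, t) and np.allclose(di, d) and np.allclose(fi, f)
        assert k == 100

    def test_rate_ratio(self):
        # 500 Hz / 20 fps puts 25 force samples in each frame interval
        exp = synth.make_pull_experiment(synth.FibrilGroundTruth(),
                                         friction_sd_un=0.0, seed=0)
        dt_force = np.diff(exp.force_time_s).mean()
        dt_video = np.diff(exp.video_time_s).mean()
        assert dt_video / dt_force == pytest.approx(25.0)

    def test_forward_simulation_pairs_recovered(self):
        truth = synth.FibrilGroundTruth()
        exp = synth.make_pull_experiment(truth, friction_level_un=0.0,
                                         friction_sd_un=0.0, seed=0)
        k = mech.detect_rupture(exp.force_un)
        ti, di, fi, ka = mech.synchronize(
            exp.force_time_s, exp.force_un, exp.video_time_s,
            exp.deflection_um, k, exp.rupture_frame_index)
        # deflection at each force time within one video-frame ramp step
        expected = 1.0 * ti  # pull speed 1 um/s from t=0
        assert np.max(np.abs(di - expected)) <= 1.0 / 20.0 + 1e-9

    def test_out_of_range_rupture_indices_rejected(self):
        t = np.linspace(0, 10, 100)
        with pytest.raises(ValueError):
            mech.synchronize(t, np.ones(100), t, np.ones(100), 150, 0)
        with pytest.raises(ValueError):
            mech.synchronize(t, np.ones(100), t, np.ones(100), 50, -1)


class TestBowstringGeometry:
    def test_zero_deflection_zero_strain(self):
        assert mech.bowstring_strain(0.0, 50.0) == 0.0

    def test_worked_strain_value(self):
        # L0 = 50 um, d = 5 um -> 2 sqrt(625+25)/50 - 1 = 1.980%
        assert mech.bowstring_strain(5.0, 50.0) == pytest.approx(1.980, abs=1e-3)

    @given(d=st.floats(0.01, 40.0), d2=st.floats(0.01, 40.0))
    @settings(max_examples=50, deadline=None)
    def test_strain_monotone_in_deflection(self, d, d2):
        lo, hi = sorted([d, d2])
        assert mech.bowstring_strain(lo, 50.0) <= mech.bowstring_strain(hi, 50.0)

    def test_tension_45_degree_arms(self):
        # d = L0/2 means 45-degree arms: T = F / (2 sin 45) = F/sqrt(2)
        assert mech.bowstring_tension(2.0, 25.0, 50.0) == \
            pytest.approx(np.sqrt(2.0), rel=1e-12)

    def test_zero_force_zero_tension(self):
        assert mech.bowstring_tension(0.0, 10.0, 50.0) == 0.0

    def test_zero_deflection_rejected(self):
        with pytest.raises(ValueError):
            mech.bowstring_tension(1.0, 0.0, 50.0)

    def test_tension_closure_with_generator(self, noiseless_pull):
        truth, exp, _, _ = noiseless_pull
        # tension computed back from the generated lateral force matches the
        # constitutive law stress x area
        t = exp.force_time_s
        d = 1.0 * t
        sel = (d > 1.0) & (t < exp.force_time_s[mech.detect_rupture(exp.force_un)])
        tension = mech.bowstring_tension(exp.force_un[sel], d[sel], 50.0)
        strain = mech.bowstring_strain(d[sel], 50.0)
        expected = truth.stress_at(strain) * truth.dry_area_um2
        assert np.allclose(tension, expected, rtol=1e-10)


class TestBuildStressStrain:
    def test_unit_arithmetic(self):
        # tension 1 uN over 0.05 um^2 is 20 MPa
        d = np.array([10.0, 12.0, 14.0])
        arm = np.hypot(25.0, d)
        f = 1.0 * 2 * d / arm  # lateral force giving tension exactly 1 uN
        curve = mech.build_stress_strain(d, f, 0, 2, 50.0, 0.05)
        assert np.allclose(curve.stress_mpa, 20.0)

    def test_last_point_is_rupture(self, noiseless_pull):
        _, exp, curve, summary = noiseless_pull
        assert curve.strain_pct[-1] == summary.rupture_strain_pct
        assert curve.stress_mpa[-1] == summary.rupture_stress_mpa

    def test_linear_elastic_closure(self, noiseless_pull):
        truth, exp, curve, _ = noiseless_pull
        # whole curve obeys sigma = E eps within discretization error
        expected = truth.modulus_mpa * curve.strain_pct / 100.0
        assert np.allclose(curve.stress_mpa, expected, rtol=0.01)

    def test_strictly_increasing_strain_enforced(self, noiseless_pull):
        _, _, curve, _ = noiseless_pull
        assert np.all(np.diff(curve.strain_pct) > 0)
        assert curve.strain_pct[0] > 0  # the low-strain gap


class TestSummarize:
    def test_triangle_curve_analytic(self):
        # sigma = 100 MPa per unit strain, sampled 5%..30%
        strain = np.linspace(5.0, 30.0, 60)
        curve = StressStrainCurve(strain, 100.0 * strain / 100.0)
        s = mech.summarize(curve)
        assert s.high_strain_modulus_mpa == pytest.approx(100.0, rel=1e-12)
        assert s.modulus_error_mpa == pytest.approx(0.0, abs=1e-9)
        assert s.rupture_stress_mpa == pytest.approx(30.0)
        # toughness = 1/2 sigma_r eps_r for a line through the origin
        assert s.toughness_mj_m3 == pytest.approx(0.5 * 30.0 * 0.30, rel=1e-10)

    def test_plateau_plus_rise_piecewise_area(self):
        # rise 0 -> 40 MPa over 5-10% strain, plateau 40 MPa to 20% strain
        strain = np.concatenate([np.linspace(5, 10, 21),
                                 np.linspace(10.25, 20, 40)])
        stress = np.concatenate([np.linspace(0, 40, 21), np.full(40, 40.0)])
        curve = StressStrainCurve(strain, stress)
        s = mech.summarize(curve)
        # extrapolation from the first point (5%, 0) with positive slope
        # clamps at its own zero crossing, adding no area below 5%
        rise = 0.5 * 40.0 * 0.05
        corner = 0.5 * (40.0 + 40.0) * 0.0025   # 10 -> 10.25% trapezoid
        plateau = 40.0 * (0.20 - 0.1025)
        expected = rise + corner + plateau
        assert s.toughness_mj_m3 == pytest.approx(expected, rel=1e-6)

    def test_rupture_within_frame_step(self, noiseless_pull):
        truth, exp, _, s = noiseless_pull
        # one 20 fps frame at 1 um/s changes strain by the frame-step below
        d_r = 1.0 * exp.video_time_s[exp.rupture_frame_index + 1]
        step = mech.bowstring_strain(d_r, 50.0) - \
            mech.bowstring_strain(d_r - 1.0 / 20.0, 50.0)
        assert abs(s.rupture_strain_pct - truth.rupture_strain_pct) <= step

    def test_noiseless_recovery_one_percent(self, noiseless_pull):
        truth, _, _, s = noiseless_pull
        sigma_r = truth.stress_at(truth.rupture_strain_pct)
        assert s.rupture_stress_mpa == pytest.approx(sigma_r, rel=0.01)
        assert s.high_strain_modulus_mpa == pytest.approx(truth.modulus_mpa,
                                                          rel=0.01)
        true_tough = 0.5 * sigma_r * truth.rupture_strain_pct / 100.0
        assert s.toughness_mj_m3 == pytest.approx(true_tough, rel=0.01)

    def test_invariant_to_time_shift(self, default_truth):
        exp = synth.make_pull_experiment(default_truth, friction_sd_un=0.02,
                                         seed=5)
        _, s1 = mech.analyze_pull(exp)
        shifted = synth.make_pull_experiment(default_truth,
                                             friction_sd_un=0.02, seed=5)
        shifted.force_time_s = shifted.force_time_s + 123.0
        shifted.video_time_s = shifted.video_time_s + 123.0
        _, s2 = mech.analyze_pull(shifted)
        # re-interpolation on the shifted axis can move the full-tension
        # breakpoint by a sample; the parameters themselves are unchanged
        assert s2.rupture_strain_pct == pytest.approx(s1.rupture_strain_pct,
                                                      rel=1e-9)
        assert s2.rupture_stress_mpa == pytest.approx(s1.rupture_stress_mpa,
                                                      rel=1e-6)
        assert s2.toughness_mj_m3 == pytest.approx(s1.toughness_mj_m3,
                                                   rel=0.01)
        assert s2.high_strain_modulus_mpa == pytest.approx(
            s1.high_strain_modulus_mpa, rel=0.01)

    def test_too_few_modulus_points_rejected(self):
        curve = StressStrainCurve(np.array([5.0, 30.0]), np.array([5.0, 30.0]))
        with pytest.raises(ValueError):
            mech.summarize(curve, modulus_window_pct=1e-6)


class TestRuptureBiasWithFriction:
    def test_bias_shrinks_with_friction_noise(self, default_truth):
        sigma_true = default_truth.stress_at(default_truth.rupture_strain_pct)
        biases = []
        for sd in (0.2, 0.05, 0.0):
            errs = []
            for seed in range(3):
                exp = synth.make_pull_experiment(default_truth,
                                                 friction_sd_un=sd, seed=seed)
                _, s = mech.analyze_pull(exp)
                errs.append(abs(s.rupture_stress_mpa - sigma_true))
            biases.append(np.mean(errs))
        assert biases[2] <= biases[0] + 1e-9
        assert biases[2] / sigma_true < 0.01


class TestBendingForceEstimate:
    def test_printed_upper_bound(self):
        # E=0.17 GPa, r=100 nm, L0=50 um, d=5 um -> ~0.1 nN
        f = mech.bending_force_estimate(0.17, 100.0, 50.0, 5.0)
        assert f == pytest.approx(0.1, abs=0.05)

    def test_zero_deflection(self):
        assert mech.bending_force_estimate(0.17, 100.0, 50.0, 0.0) == 0.0

    def test_radius_fourth_power(self):
        f1 = mech.bending_force_estimate(0.17, 100.0, 50.0, 5.0)
        f2 = mech.bending_force_estimate(0.17, 200.0, 50.0, 5.0)
        assert f2 == pytest.approx(16.0 * f1)

    def test_simply_supported_is_quarter(self):
        fc = mech.bending_force_estimate(0.17, 100.0, 50.0, 5.0, "clamped")
        fs = mech.bending_force_estimate(0.17, 100.0, 50.0, 5.0,
                                         "simply_supported")
        assert fs == pytest.approx(fc / 4.0)


class TestHydratedRescale:
    def test_default_factor_four(self):
        assert mech.hydrated_stress_rescale(100.0) == pytest.approx(25.0)

    def test_identity_factor_one(self):
        assert mech.hydrated_stress_rescale(37.0, 1.0) == 37.0

    def test_area_scales_with_square(self):
        assert mech.hydrated_stress_rescale(8.0, 2.0) == \
            pytest.approx(8.0 / 4.0)
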