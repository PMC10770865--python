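import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad

import flimphasor as fp

F_MOD = 8.0e7
OMEGA = 2 * np.pi * F_MOD


def uniform_scene(tau_ns, shape=(8, 8), amplitude=100.0):
    spec = {
        "shape": shape,
        "regions": [{"kind": "full", "tau_ns": tau_ns, "amplitude": amplitude}],
    }
    return fp.generate_scene(spec, 0)


class TestComputeGs:
    def test_equal_phases_give_zero(self):
        v = np.full((4, 5, 5), 7.0)
        meas = fp.compute_gs(fp.PhaseStack(v_if=v, f_mod_hz=F_MOD))
        assert np.all(meas.g == 0) and np.all(meas.s == 0)
        assert np.all(meas.intensity == 7.0)

    def test_ratio_equals_omega_tau(self):
        meas = fp.compute_gs(fp.simulate_fd_phases(uniform_scene(2.0), F_MOD))
        np.testing.assert_allclose(meas.s / meas.g, OMEGA * 2e-9, rtol=1e-12)

    def test_swapping_complementary_planes_negates_s_only(self):
        ph = fp.simulate_fd_phases(uniform_scene(2.0), F_MOD)
        swapped = fp.PhaseStack(v_if=ph.v_if[[2, 1, 0, 3]], f_mod_hz=F_MOD)
        a = fp.compute_gs(ph)
        b = fp.compute_gs(swapped)
        np.testing.assert_array_equal(b.s, -a.s)
        np.testing.assert_array_equal(b.g, a.g)


class TestLifetimeFromGs:
    def test_direct_substitution(self):
        meas = fp.FlimMeasurement(
            g=np.ones((2, 2)),
            s=np.full((2, 2), OMEGA * 2e-9),
            intensity=np.ones((2, 2)),
            f_mod_hz=F_MOD,
        )
        tau = fp.lifetime_from_gs(meas)
        np.testing.assert_allclose(tau.tau_ns, 2.0, rtol=1e-12)

    def test_zero_g_pixel_invalid_not_raised(self):
        g = np.ones((2, 2))
        g[0, 0] = 0.0
        meas = fp.FlimMeasurement(g=g, s=np.ones((2, 2)), intensity=np.ones((2, 2)), f_mod_hz=F_MOD)
        tau = fp.lifetime_from_gs(meas)
        assert not tau.valid[0, 0]
        assert np.isnan(tau.tau_ns[0, 0])
        assert tau.valid[1, 1]

    def test_intensity_threshold_masks(self):
        meas = fp.FlimMeasurement(
            g=np.ones((2, 2)),
            s=np.ones((2, 2)),
            intensity=np.array([[1.0, 1.0], [1.0, 0.01]]),
            f_mod_hz=F_MOD,
        )
        tau = fp.lifetime_from_gs(meas, intensity_threshold=0.1)
        assert not tau.valid[1, 1]
        assert tau.valid[0, 0]


class TestMonoExpPhasor:
    def test_limits(self):
        assert fp.mono_exp_phasor(0.0, F_MOD) == (1.0, 0.0)
        g, s = fp.mono_exp_phasor(1e12, F_MOD)
        assert g < 1e-6 and s < 1e-3

    def test_against_numerical_integration(self):
        """Closed form matches direct integration of the decay transforms."""
        omega_ns = OMEGA * 1e-9  # integrate in ns units to keep quad well-scaled
        for tau_ns in (0.5, 2.0, 4.0):
            norm = quad(lambda t: np.exp(-t / tau_ns), 0, 60 * tau_ns)[0]
            g_num = quad(lambda t: np.exp(-t / tau_ns) * np.cos(omega_ns * t), 0, 60 * tau_ns, limit=500)[0] / norm
            s_num = quad(lambda t: np.exp(-t / tau_ns) * np.sin(omega_ns * t), 0, 60 * tau_ns, limit=500)[0] / norm
            g, s = fp.mono_exp_phasor(tau_ns, F_MOD)
            np.testing.assert_allclose([g, s], [g_num, s_num], atol=1e-9)

    def test_reference_point_2ns_80mhz(self):
        g, s = fp.mono_exp_phasor(2.0, F_MOD)
        # frozen from the closed form at omega*tau = 1.00531
        np.testing.assert_allclose([g, s], [0.4973522234, 0.4999929892], atol=1e-9)

    @given(tau=st.floats(0.0, 100.0))
    def test_universal_semicircle(self, tau):
        g, s = fp.mono_exp_phasor(tau, F_MOD)
        assert abs(s**2 + (g - 0.5) ** 2 - 0.25) < 1e-12


class TestPhasorTd:
    def test_matches_closed_form(self):
        scene = uniform_scene(2.0, shape=(2, 2), amplitude=1.0)
        dec = fp.simulate_tcspc(scene, 0.001, 50000)
        cloud = fp.phasor_td(dec, F_MOD)
        g, s = fp.mono_exp_phasor(2.0, F_MOD)
        np.testing.assert_allclose(cloud.g_coord, g, atol=1e-4)
        np.testing.assert_allclose(cloud.s_coord, s, atol=1e-4)

    def test_mixture_is_midpoint(self):
        # equal integrated intensity: amplitudes ~ 1/tau so areas match
        spec = {
            "shape": (1, 1),
            "regions": [{"kind": "full", "components": [(1.0, 0.8), (4.0, 0.2)], "amplitude": 1.0}],
        }
        # fractions 0.8/0.2 of the initial amplitude give areas 0.8*1 and 0.2*4
        # = equal integrated intensity -> phasor at the chord midpoint
        dec = fp.simulate_tcspc(fp.generate_scene(spec, 0), 0.001, 50000)
        cloud = fp.phasor_td(dec, F_MOD)
        g1, s1 = fp.mono_exp_phasor(1.0, F_MOD)
        g4, s4 = fp.mono_exp_phasor(4.0, F_MOD)
        np.testing.assert_allclose(cloud.g_coord[0], 0.5 * (g1 + g4), atol=1e-4)
        np.testing.assert_allclose(cloud.s_coord[0], 0.5 * (s1 + s4), atol=1e-4)

    def test_chord_linearity_many_fractions(self):
        g1, s1 = fp.mono_exp_phasor(1.0, F_MOD)
        g4, s4 = fp.mono_exp_phasor(4.0, F_MOD)
        for f in np.linspace(0, 1, 11):
            # area fraction f on tau=1: amplitude fractions a1/(a1+a4) with
            # a1*tau1 : a4*tau4 = f : (1-f)
            a1 = f / 1.0
            a4 = (1 - f) / 4.0
            tot = a1 + a4
            if f in (0.0, 1.0):
                comps = [(1.0, 1.0)] if f == 1.0 else [(4.0, 1.0)]
            else:
                comps = [(1.0, a1 / tot), (4.0, a4 / tot)]
            spec = {"shape": (1, 1), "regions": [{"kind": "full", "components": comps, "amplitude": 1.0}]}
            dec = fp.simulate_tcspc(fp.generate_scene(spec, 0), 0.001, 50000)
            cloud = fp.phasor_td(dec, F_MOD)
            np.testing.assert_allclose(cloud.g_coord[0], f * g1 + (1 - f) * g4, atol=1e-4)
            np.testing.assert_allclose(cloud.s_coord[0], f * s1 + (1 - f) * s4, atol=1e-4)

    def test_delta_decay(self):
        counts = np.zeros((1, 1, 1000))
        counts[0, 0, 0] = 1.0
        dec = fp.TcspcStack(counts=counts, bin_width_ns=0.001, n_bins=1000)
        cloud = fp.phasor_td(dec, F_MOD)
        np.testing.assert_allclose([cloud.g_coord[0], cloud.s_coord[0]], [1.0, 0.0], atol=1e-3)

    def test_zero_pixels_excluded_and_all_zero_errors(self):
        counts = np.zeros((2, 1, 100))
        counts[0, 0, 0] = 5.0
        dec = fp.TcspcStack(counts=counts, bin_width_ns=0.1, n_bins=100)
        cloud = fp.phasor_td(dec, F_MOD)
        assert len(cloud) == 1
        with pytest.raises(ValueError):
            fp.phasor_td(fp.TcspcStack(np.zeros((1, 1, 100)), 0.1, 100), F_MOD)


class TestPhasorFd:
    def test_noiseless_field_on_reference_point(self):
        meas = fp.compute_gs(fp.simulate_fd_phases(uniform_scene(2.0), F_MOD))
        cloud = fp.phasor_fd(meas)
        g, s = fp.mono_exp_phasor(2.0, F_MOD)
        np.testing.assert_allclose(cloud.g_coord, g, atol=1e-6)
        np.testing.assert_allclose(cloud.s_coord, s, atol=1e-6)

    def test_definitional_identity(self):
        scene = uniform_scene(1.5, shape=(16, 16))
        ph = fp.add_mpg_noise(fp.simulate_fd_phases(scene, F_MOD), fp.NoiseParams(seed=1))
        cloud = fp.phasor_fd(fp.compute_gs(ph))
        np.testing.assert_allclose(cloud.g_coord, cloud.m * np.cos(cloud.phi), atol=1e-12)
        np.testing.assert_allclose(cloud.s_coord, cloud.m * np.sin(cloud.phi), atol=1e-12)

    def test_calibration_cancels_synthetic_phase_offset(self):
        tau_ref = 2.0
        meas = fp.compute_gs(fp.simulate_fd_phases(uniform_scene(tau_ref), F_MOD))
        # rotate the raw measurement by +0.1 rad to mimic an instrument offset
        z = (meas.g + 1j * meas.s) * np.exp(1j * 0.1)
        offset = fp.FlimMeasurement(g=z.real, s=z.imag, intensity=meas.intensity, f_mod_hz=F_MOD)
        cloud = fp.phasor_fd(offset, calibration=(tau_ref, offset))
        g, s = fp.mono_exp_phasor(tau_ref, F_MOD)
        np.testing.assert_allclose(cloud.g_coord, g, atol=1e-9)
        np.testing.assert_allclose(cloud.s_coord, s, atol=1e-9)

    def test_zero_modulation_reference_errors(self):
        meas = fp.compute_gs(fp.simulate_fd_phases(uniform_scene(2.0), F_MOD))
        zero = fp.FlimMeasurement(
            g=np.zeros((8, 8)), s=np.zeros((8, 8)), intensity=np.ones((8, 8)), f_mod_hz=F_MOD
        )
        with pytest.raises(ValueError):
            fp.phasor_fd(meas, calibration=(2.0, zero))

    def test_lifetime_consistency_with_phase(self):
        """arctan(s/g)/omega agrees with the ratio lifetime on noiseless data."""
        scene = uniform_scene(3.0, shape=(12, 12))
        meas = fp.compute_gs(fp.simulate_fd_phases(scene, F_MOD))
        tau = fp.lifetime_from_gs(meas)
        cloud = fp.phasor_fd(meas)
        tau_phase = np.tan(cloud.phi) / OMEGA * 1e9
        np.testing.assert_allclose(tau_phase, tau.tau_ns[tau.valid], rtol=1e-9)


class TestPhasorHistogram:
    def test_single_entry(self):
        cloud = fp.phasor_fd(fp.compute_gs(fp.simulate_fd_phases(uniform_scene(2.0, shape=(1, 1)), F_MOD)))
        hist = fp.phasor_histogram(cloud, n_bins=32)
        assert hist.counts.sum() == 1
        assert np.count_nonzero(hist.counts) == 1

    def test_conservation_with_clipping(self):
        rng = np.random.default_rng(0)
        n = 500
        g = rng.normal(0.5, 0.5, n)  # some fall outside [0, 1]
        s = rng.normal(0.3, 0.4, n)
        cloud = fp.PhasorCloud(
            g_coord=g, s_coord=s, m=np.hypot(g, s), phi=np.arctan2(s, g),
            pixel_index=np.zeros((n, 2), dtype=int), flagged=g < 0,
        )
        hist = fp.phasor_histogram(cloud, n_bins=64)
        assert hist.counts.sum() == n  # clipped entries land in edge bins
        outside = (g < 0) | (g > 1) | (s < 0) | (s > 0.6)
        assert hist.clipped == outside.sum()

    def test_two_lifetime_scene_two_bins(self):
        spec = {
            "shape": (16, 16),
            "regions": [
                {"kind": "full", "tau_ns": 1.0, "amplitude": 100.0},
                {"kind": "rect", "corner": (0, 8), "size": (16, 8), "tau_ns": 3.0, "amplitude": 100.0},
            ],
        }
        scene = fp.generate_scene(spec, 0)
        cloud = fp.phasor_fd(fp.compute_gs(fp.simulate_fd_phases(scene, F_MOD)))
        hist = fp.phasor_histogram(cloud, n_bins=256)
        assert np.count_nonzero(hist.counts) == 2

    def test_too_few_bins_error(self):
        cloud = fp.phasor_fd(fp.compute_gs(fp.simulate_fd_phases(uniform_scene(2.0), F_MOD)))
        with pytest.raises(ValueError):
            fp.phasor_histogram(cloud, n_bins=1)
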