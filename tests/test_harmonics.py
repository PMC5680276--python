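"""Spectrogram harmonic estimation and the steering correlation."""

import dataclasses

import numpy as np
import pytest

from flagbeat.core import wrap_angle
from flagbeat.harmonics import (correlation_R, optimize_phase_offset,
                                second_harmonic_intensity,
                                spectrogram_harmonics)
from flagbeat.kinematics import RotationTrace
from flagbeat.synthetic import (DriftProfile, WaveformSpec, default_grid,
                                gen_curvature_wave)


def _trace_for(spec, duration=4.0, noise_sd=0.0, seed=0, s0=15.0, **kw):
    s, t = default_grid(duration=duration)
    field, rec = gen_curvature_wave(
        spec, DriftProfile.none(spec, noise_sd=noise_sd), s=s, t=t, seed=seed)
    s_act, row = field.row(s0)
    return spectrogram_harmonics(row, field.frame_rate,
                                 wave_number=spec.k, s0=s_act, **kw), rec


class TestSpectrogram:
    def test_pure_sinusoid_amplitude_and_frequency(self):
        spec = WaveformSpec(C1=0.08, C2=0.0, freq_hz=20.0)
        tr, _ = _trace_for(spec)
        tr = tr.masked()
        assert np.all(np.abs(tr.omega0 - 20.0) < 0.5)
        assert np.all(np.abs(tr.C1 - 0.08) / 0.08 < 0.03)
        assert np.all(tr.C2 < 0.01 * 0.08)

    @pytest.mark.parametrize("phi", [1.0, -2.0])
    def test_two_harmonic_recovery(self, phi):
        spec = WaveformSpec(C1=0.1, C2=0.015, phi=phi, freq_hz=20.0)
        tr, _ = _trace_for(spec, noise_sd=0.005)
        tr = tr.masked()
        assert abs(np.median(tr.C2) - 0.015) / 0.015 < 0.05
        circ = np.arctan2(np.mean(np.sin(tr.phi)), np.mean(np.cos(tr.phi)))
        assert abs(wrap_angle(circ - phi)) < 0.1

    def test_off_bin_frequency_tracked(self):
        # 21.3 Hz is between DFT bins of the 250-frame window
        spec = WaveformSpec(C1=0.1, C2=0.02, phi=0.4, freq_hz=21.3)
        tr, _ = _trace_for(spec)
        tr = tr.masked()
        assert abs(np.median(tr.omega0) - 21.3) < 0.2
        assert abs(np.median(tr.C2) - 0.02) / 0.02 < 0.05

    def test_chirp_tracked_within_bin(self):
        s, t = default_grid(duration=8.0)
        f_inst = 15.0 + 1.25 * t  # 15→25 Hz chirp
        phase = 2 * np.pi * np.cumsum(f_inst) * (t[1] - t[0])
        row = 0.1 * np.sin(phase)
        tr = spectrogram_harmonics(row, 500.0).masked()
        f_at = np.interp(tr.t, t, f_inst)
        assert np.all(np.abs(tr.omega0 - f_at) < 2.0)  # one bin = 2 Hz

    def test_amplitude_linearity_and_phase_invariance(self):
        spec = WaveformSpec(C1=0.05, C2=0.01, phi=0.8)
        tr1, _ = _trace_for(spec)
        spec2 = dataclasses.replace(spec, C1=0.1, C2=0.02)
        tr2, _ = _trace_for(spec2)
        m = tr1.valid & tr2.valid
        np.testing.assert_allclose(tr2.C1[m], 2 * tr1.C1[m], rtol=1e-6)
        np.testing.assert_allclose(tr2.C2[m], 2 * tr1.C2[m], rtol=1e-6)
        np.testing.assert_allclose(tr2.phi[m], tr1.phi[m], atol=1e-6)

    def test_time_shift_leaves_relative_phase(self):
        """φ is the shift-invariant phase of the 2ω component relative
        to twice the fundamental's phase."""
        spec = WaveformSpec(C1=0.1, C2=0.02, phi=0.9, freq_hz=20.0)
        s, t = default_grid(duration=4.0)
        field, _ = gen_curvature_wave(spec, s=s, t=t)
        s0, row = field.row(15.0)
        tr_a = spectrogram_harmonics(row, 500.0, wave_number=spec.k, s0=s0)
        shift = 7  # frames, an arbitrary non-period offset
        tr_b = spectrogram_harmonics(row[shift:], 500.0,
                                     wave_number=spec.k, s0=s0)
        n = min(tr_a.t.size, tr_b.t.size) - 1
        m = tr_a.valid[:n] & tr_b.valid[:n]
        np.testing.assert_allclose(
            wrap_angle(tr_a.phi[:n][m] - tr_b.phi[:n][m]), 0.0, atol=1e-3)

    def test_noise_only_windows_masked(self):
        rng = np.random.default_rng(0)
        row = rng.normal(0, 0.01, 2000)
        tr = spectrogram_harmonics(row, 500.0)
        assert tr.valid.mean() < 0.5

    def test_record_shorter_than_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            spectrogram_harmonics(np.zeros(100), 500.0, window=250)


class TestIntensityAndCorrelation:
    def _mock_trace(self, t, c2, phi, f0=20.0):
        from flagbeat.harmonics import HarmonicTrace

        return HarmonicTrace(
            t=t, omega0=np.full(t.size, f0), C1=np.full(t.size, 0.1),
            C2=c2, phi=phi, valid=np.ones(t.size, bool), s0=15.0,
            window=250, step=30,
        )

    def test_intensity_zero_at_zero_effective_phase(self):
        t = np.linspace(0, 10, 200)
        tr = self._mock_trace(t, c2=np.full(t.size, 0.02),
                              phi=np.zeros(t.size))
        np.testing.assert_allclose(second_harmonic_intensity(tr, 0.0), 0.0)
        np.testing.assert_allclose(
            second_harmonic_intensity(tr, np.pi / 2), tr.C2)

    def test_intensity_sign_follows_effective_phase(self):
        t = np.linspace(0, 10, 500)
        phi = np.linspace(-1.0, 1.0, t.size)
        tr = self._mock_trace(t, c2=np.full(t.size, 0.02), phi=phi)
        I = second_harmonic_intensity(tr, 0.0)
        assert np.all(I[phi < -1e-9] < 0) and np.all(I[phi > 1e-9] > 0)

    def test_proportional_series_give_R_one(self):
        t = np.linspace(0, 30, 600)
        rng = np.random.default_rng(1)
        phi = rng.normal(0, 0.8, t.size)
        c2 = 0.02 + 0.005 * rng.normal(size=t.size)
        tr = self._mock_trace(t, c2=np.abs(c2), phi=phi)
        omega = RotationTrace(
            t=t, alpha=np.zeros_like(t),
            Omega=3.0 * np.abs(c2) * np.sin(phi) * 20.0, filter_width=0.0)
        assert correlation_R(omega, tr, 0.0) > 0.999

    def test_scale_invariance_of_R(self):
        t = np.linspace(0, 30, 600)
        rng = np.random.default_rng(2)
        phi = rng.normal(0.3, 0.7, t.size)
        c2 = np.abs(0.02 + 0.005 * rng.normal(size=t.size))
        tr = self._mock_trace(t, c2=c2, phi=phi)
        om = rng.normal(0, 0.1, t.size)
        a = RotationTrace(t=t, alpha=np.zeros_like(t), Omega=om,
                          filter_width=0.0)
        b = RotationTrace(t=t, alpha=np.zeros_like(t), Omega=5.0 * om,
                          filter_width=0.0)
        r1 = correlation_R(a, tr, 0.5)
        r2 = correlation_R(b, tr, 0.5)
        assert abs(r1 - r2) < 1e-12 and abs(r1) <= 1.0

    def test_independent_noise_gives_small_R(self):
        t = np.linspace(0, 60, 1000)
        rng = np.random.default_rng(3)
        tr = self._mock_trace(
            t, c2=np.abs(rng.normal(0.02, 0.005, t.size)),
            phi=rng.uniform(-np.pi, np.pi, t.size))
        rs = []
        for k in range(20):
            om = RotationTrace(t=t, alpha=np.zeros_like(t),
                               Omega=rng.normal(0, 0.1, t.size),
                               filter_width=0.0)
            rs.append(abs(correlation_R(om, tr, 0.0)))
        assert np.quantile(rs, 0.95) < 0.1

    def test_zero_series_rejected(self):
        t = np.linspace(0, 30, 600)
        tr = self._mock_trace(t, c2=np.zeros(t.size), phi=np.zeros(t.size))
        om = RotationTrace(t=t, alpha=np.zeros_like(t),
                           Omega=np.ones(t.size), filter_width=0.0)
        with pytest.raises(ValueError, match="zero"):
            correlation_R(om, tr, 0.0)


class TestPhaseOffset:
    def _setup(self, phi0_true, seed=0, n=800, noise=0.0):
        rng = np.random.default_rng(seed)
        t = np.linspace(0, 48, n)
        phi = np.cumsum(rng.normal(0, 0.05, n))  # slow random walk
        c2 = np.abs(0.02 + 0.004 * rng.normal(size=n))
        from flagbeat.harmonics import HarmonicTrace

        tr = HarmonicTrace(
            t=t, omega0=np.full(n, 20.0), C1=np.full(n, 0.1), C2=c2,
            phi=wrap_angle(phi), valid=np.ones(n, bool), s0=15.0,
            window=250, step=30,
        )
        om_sig = c2 * np.sin(phi + phi0_true) * 20.0
        om_sig = om_sig + noise * np.std(om_sig) * rng.normal(size=n)
        omega = RotationTrace(t=t, alpha=np.zeros_like(t), Omega=om_sig,
                              filter_width=0.0)
        return omega, tr

    def test_known_offset_recovered(self):
        omega, tr = self._setup(0.7)
        phi0, r = optimize_phase_offset(omega, tr)
        assert abs(wrap_angle(phi0 - 0.7)) < 0.03
        assert r > 0.99

    def test_recovery_with_noise(self):
        omega, tr = self._setup(-1.2, seed=5, noise=0.1)
        phi0, r = optimize_phase_offset(omega, tr)
        assert abs(wrap_angle(phi0 + 1.2)) < 0.1
        assert r > 0.9

    def test_uncorrelated_rotation_flagged(self):
        rng = np.random.default_rng(8)
        omega, tr = self._setup(0.0, seed=8)
        omega.Omega = rng.normal(0, 0.05, omega.Omega.size)
        phi0, r = optimize_phase_offset(omega, tr)
        assert abs(r) < 0.3

    def test_too_few_points_rejected(self):
        omega, tr = self._setup(0.7, n=800)
        tr.valid[40:] = False
        with pytest.raises(ValueError, match="50"):
            optimize_phase_offset(omega, tr)


class TestProbeConsistency:
    def test_R_agrees_across_probes_with_shared_offset(self):
        """φ is probe-independent by construction of the two-harmonic
        wave, so R evaluated at 15 µm with the offset optimized at
        25 µm matches the reference R closely."""
        import dataclasses

        from flagbeat.harmonics import probe_consistency
        from flagbeat.kinematics import curvature_three_point, rotation_velocity
        from flagbeat.synthetic import gen_rotating_cell
        from flagbeat.theory import DragModel, omega_second_harmonic
        from scipy.ndimage import gaussian_filter1d

        rng = np.random.default_rng(3)
        spec = WaveformSpec(C1=0.1, C2=0.02, phi=0.0, wavelength=40.0,
                            L=45.0, freq_hz=20.0)
        dur = 20.0
        s, t = default_grid(duration=dur)
        drift = DriftProfile.smoothed_random_walk(
            spec, duration=dur, rng=rng, timescale=2.0, phi_sd=0.8,
            noise_sd=0.005)
        drag = DragModel()
        unit = dataclasses.replace(spec, C2=1.0, phi=np.pi / 2)
        coef = omega_second_harmonic(unit, drag, L=40.0)

        def law(tt):
            return coef * drift.c2_of_t(tt) * np.sin(drift.phi_of_t(tt) + 0.5)

        tracks, _ = gen_rotating_cell(spec, drift, omega_of_t=law,
                                      s=s, t=t, seed=4)
        field = curvature_three_point(tracks)
        omega = rotation_velocity(tracks)
        table = probe_consistency(field, omega, s_list=(15.0, 25.0),
                                  wave_number=spec.k)
        assert len(table) == 2
        assert np.all(np.abs(table["delta_R_vs_ref"]) < 0.05)

    def test_single_probe_gives_one_row(self):
        import dataclasses

        from flagbeat.harmonics import probe_consistency
        from flagbeat.kinematics import curvature_three_point, rotation_velocity
        from flagbeat.synthetic import gen_rotating_cell
        from flagbeat.theory import DragModel, omega_second_harmonic

        rng = np.random.default_rng(5)
        spec = WaveformSpec(C1=0.1, C2=0.02, phi=0.0, wavelength=40.0,
                            L=45.0, freq_hz=20.0)
        s, t = default_grid(duration=10.0)
        drift = DriftProfile.smoothed_random_walk(
            spec, duration=10.0, rng=rng, timescale=2.0, phi_sd=0.8)
        drag = DragModel()
        unit = dataclasses.replace(spec, C2=1.0, phi=np.pi / 2)
        coef = omega_second_harmonic(unit, drag, L=40.0)
        tracks, _ = gen_rotating_cell(
            spec, drift,
            omega_of_t=lambda tt: coef * drift.c2_of_t(tt)
            * np.sin(drift.phi_of_t(tt) + 0.5),
            s=s, t=t, seed=6)
        field = curvature_three_point(tracks)
        omega = rotation_velocity(tracks)
        table = probe_consistency(field, omega, s_list=(15.0,),
                                  wave_number=spec.k)
        assert len(table) == 1
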