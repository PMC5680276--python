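"""Principal beat modes: spectra, significance, limit-cycle phase."""

import numpy as np
import pytest

from flagbeat.core import CurvatureField
from flagbeat.modes import (align_modes, beat_phase, conditional_frequency,
                            covariance_modes, reconstruct, significant_modes)
from flagbeat.synthetic import (DriftProfile, WaveformSpec, default_grid,
                                gen_curvature_wave, gen_random_curvature)


class TestCovarianceModes:
    def test_traveling_wave_gives_degenerate_mode_pair(self, short_grid):
        """A single traveling wave a·cos(ks−ωt) spans exactly the
        {sin(ks), cos(ks)} plane: two equal eigenvalues, rest zero."""
        s, t = short_grid
        k = 2 * 2 * np.pi / (s[-1] - s[0])  # two full wavelengths
        C = 0.1 * np.cos(k * s[:, None] - 2 * np.pi * 20 * t[None, :])
        field = CurvatureField(C=C, s=s, t=t)
        d = covariance_modes(field)
        assert abs(d.sigma[0] - d.sigma[1]) / d.sigma[0] < 0.01
        assert d.sigma[2] < 1e-6 * d.sigma[0]
        # the two modes span sin/cos of ks
        target = np.column_stack([np.sin(k * s), np.cos(k * s)])
        proj = np.linalg.lstsq(d.Gamma[:, :2], target, rcond=None)[1]
        assert proj.size == 0 or np.max(proj) < 1e-8

    def test_modes_orthonormal_and_energy_bookkeeping(self, two_harmonic_field):
        field, _ = two_harmonic_field
        d = covariance_modes(field)
        gram = d.Gamma.T @ (d.weights[:, None] * d.Gamma)
        np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-8)
        total = np.sum(d.weights * np.mean(field.C**2, axis=1))
        assert abs(d.sigma.sum() - total) / total < 1e-6
        assert np.all(np.diff(d.sigma) <= 1e-12)
        np.testing.assert_allclose(d.variance_fractions.sum(), 1.0, atol=1e-12)

    def test_two_harmonic_first_two_modes_dominate(self, two_harmonic_field):
        field, _ = two_harmonic_field
        d = covariance_modes(field)
        assert d.variance_fractions[:2].sum() >= 0.90

    def test_nan_rejected(self, short_grid):
        s, t = short_grid
        C = np.zeros((s.size, t.size))
        C[0, 0] = np.nan
        with pytest.raises(ValueError):
            covariance_modes(CurvatureField(C=C, s=s, t=t))


class TestReconstruction:
    def test_all_modes_reproduce_field_exactly(self, two_harmonic_field):
        field, _ = two_harmonic_field
        d = covariance_modes(field)
        rec = reconstruct(d, d.sigma.size)
        np.testing.assert_allclose(rec.C, field.C, atol=1e-8)

    def test_residual_equals_dropped_eigenvalues(self, short_grid):
        s, t = short_grid
        spec = WaveformSpec(C1=0.1, C2=0.02, phi=0.5)
        field, _ = gen_curvature_wave(
            spec, DriftProfile.none(spec, noise_sd=0.01), s=s, t=t, seed=3)
        d = covariance_modes(field)
        n = 2
        rec = reconstruct(d, n)
        resid = field.C - rec.C
        resid_energy = np.sum(d.weights * np.mean(resid**2, axis=1))
        dropped = d.sigma[n:].sum()
        assert abs(resid_energy - dropped) / dropped < 0.01
        assert resid_energy <= 0.10 * d.sigma.sum()

    def test_mode_sign_flip_does_not_change_reconstruction(
            self, two_harmonic_field):
        field, _ = two_harmonic_field
        d = covariance_modes(field)
        d.Gamma[:, 0] *= -1
        d.chi[0] *= -1
        rec = reconstruct(d, 3)
        d2 = covariance_modes(field)
        np.testing.assert_allclose(rec.C, reconstruct(d2, 3).C, atol=1e-10)


class TestSignificance:
    def test_pure_noise_has_no_significant_modes(self, short_grid):
        s, t = short_grid
        field = gen_random_curvature(0.05, s, t, seed=12)
        d = covariance_modes(field)
        assert significant_modes(d, null_replicates=40, seed=1) <= 1

    def test_two_harmonic_plus_noise_gives_two(self, short_grid):
        s, t = short_grid
        spec = WaveformSpec(C1=0.1, C2=0.02, phi=0.5)
        field, _ = gen_curvature_wave(
            spec, DriftProfile.none(spec, noise_sd=0.01), s=s, t=t, seed=5)
        d = covariance_modes(field)
        assert significant_modes(d, null_replicates=40, seed=2) == 2

    def test_offset_drift_adds_a_third_mode(self):
        s, t = default_grid(duration=4.0)
        spec = WaveformSpec(C1=0.1, C2=0.02, phi=0.5)
        field, _ = gen_curvature_wave(
            spec, DriftProfile.none(spec, noise_sd=0.01), s=s, t=t, seed=6)
        # slowly drifting uniform offset: a near-uniform third mode
        field.C += 0.05 * np.sin(2 * np.pi * t / 4.0)[None, :]
        d = covariance_modes(field)
        assert significant_modes(d, null_replicates=40, seed=3) == 3


class TestBeatPhase:
    def test_circular_cycle_gives_linear_phase_and_ring(self, short_grid):
        s, t = short_grid
        w0 = 2 * np.pi * 20.0
        k = 2 * 2 * np.pi / (s[-1] - s[0])
        C = (np.sin(k * s)[:, None] * np.cos(w0 * t)[None, :]
             + np.cos(k * s)[:, None] * np.sin(w0 * t)[None, :]) * 0.1
        field = CurvatureField(C=C, s=s, t=t)
        d = covariance_modes(field)
        ph = beat_phase(d)
        dadt = np.abs(np.gradient(ph.alpha, t)) / (2 * np.pi)
        inner = slice(5, -5)
        np.testing.assert_allclose(dadt[inner], 20.0, rtol=0.02)
        # isotropic ring: radius nearly constant
        r = np.hypot(d.chi[0], d.chi[1])
        assert np.std(r) / np.mean(r) < 0.02

    def test_mean_phase_velocity_equals_beat_frequency(
            self, two_harmonic_field):
        field, rec = two_harmonic_field
        d = covariance_modes(field)
        ph = beat_phase(d)
        t = field.t
        mean_f = abs(ph.alpha[-1] - ph.alpha[0]) / (t[-1] - t[0]) / (2 * np.pi)
        assert abs(mean_f - rec.spec.freq_hz) / rec.spec.freq_hz < 0.01

    def test_vanishing_second_mode_flagged_degenerate(self, short_grid):
        s, t = short_grid
        C = 0.1 * np.sin(0.2 * s)[:, None] * np.cos(2 * np.pi * 20 * t)[None, :]
        d = covariance_modes(CurvatureField(C=C, s=s, t=t))
        with pytest.warns(UserWarning, match="degenerate"):
            ph = beat_phase(d)
        assert ph.degenerate


class TestConditionalFrequency:
    def test_single_frequency_cycle_constant(self, short_grid):
        s, t = short_grid
        w0 = 2 * np.pi * 20.0
        k = 2 * 2 * np.pi / (s[-1] - s[0])
        C = (np.sin(k * s)[:, None] * np.cos(w0 * t)[None, :]
             + np.cos(k * s)[:, None] * np.sin(w0 * t)[None, :]) * 0.1
        d = covariance_modes(CurvatureField(C=C, s=s, t=t))
        centers, mean, sd = conditional_frequency(beat_phase(d))
        assert np.ma.allclose(mean, 20.0, atol=0.5)

    def test_two_harmonic_cycle_modulates_frequency(self, short_grid):
        """ω(α) of a two-harmonic beat oscillates between one minimum
        and one maximum per cycle, ω(α) ≈ ω0·(1 + r·cos(α−φ)) with
        modulation depth r = C2/C1; at C2/C1 = 0.3 the min/max ratio
        approaches 1:2 (the 20 vs 40 Hz extremes of real beats)."""
        s, t = short_grid
        spec = WaveformSpec(C1=0.1, C2=0.03, phi=0.5)
        field, _ = gen_curvature_wave(spec, s=s, t=t)
        d = covariance_modes(field)
        centers, mean, sd = conditional_frequency(beat_phase(d), n_bins=36)
        y = np.abs(np.ma.filled(mean, np.nan))
        good = np.isfinite(y)
        dev = y[good] - np.nanmean(y[good])
        c1 = np.abs(np.mean(dev * np.exp(-1j * centers[good])))
        c2 = np.abs(np.mean(dev * np.exp(-2j * centers[good])))
        assert c1 > 3.0 * c2  # one oscillation per cycle dominates
        ratio = np.nanmin(y) / np.nanmax(y)
        expected = (1 - 0.3) / (1 + 0.3)
        assert abs(ratio - expected) < 0.1

    def test_time_reversal_negates_frequency(self, two_harmonic_field):
        field, _ = two_harmonic_field
        d = covariance_modes(field)
        rev = CurvatureField(C=field.C[:, ::-1], s=field.s, t=field.t)
        d_rev = covariance_modes(rev)
        _, m_fwd, _ = conditional_frequency(beat_phase(d))
        _, m_rev, _ = conditional_frequency(beat_phase(d_rev))
        f_fwd, f_rev = np.ma.mean(m_fwd), np.ma.mean(m_rev)
        assert abs(f_fwd) > 15.0
        assert abs(f_rev + f_fwd) < 0.05 * abs(f_fwd)


class TestAlignModes:
    def test_self_alignment_is_identity(self, two_harmonic_field):
        field, rec = two_harmonic_field
        d = covariance_modes(field)
        lam = rec.spec.wavelength
        ref = d.Gamma[:, :2]
        out = align_modes(d, ref, d.s / lam, lam)
        np.testing.assert_allclose(out.transform, np.eye(2), atol=1e-6)
        assert out.overlap > 0.999

    def test_swapped_negated_modes_recovered_as_signed_permutation(
            self, two_harmonic_field):
        field, rec = two_harmonic_field
        d = covariance_modes(field)
        lam = rec.spec.wavelength
        ref = np.column_stack([-d.Gamma[:, 1], d.Gamma[:, 0]])
        out = align_modes(d, ref, d.s / lam, lam)
        expected = np.array([[0.0, 1.0], [-1.0, 0.0]])
        np.testing.assert_allclose(out.transform, expected, atol=1e-6)

    def test_wavelength_rescaling_collapses_two_cells(self):
        """Two cells with the same normalized waveform but different
        wavelengths superimpose after s → s/λ alignment."""
        t = np.arange(0, 2.0, 0.002)
        curves = []
        for lam, n_s in ((35.0, 30), (50.0, 42)):
            s = 0.9 * np.arange(n_s)
            spec = WaveformSpec(C1=0.1, C2=0.02, phi=0.5, wavelength=lam)
            field, _ = gen_curvature_wave(spec, s=s, t=t)
            curves.append((covariance_modes(field), lam))
        d_ref, lam_ref = curves[0]
        ref = d_ref.Gamma[:, :2]
        d2, lam2 = curves[1]
        out = align_modes(d2, ref, d_ref.s / lam_ref, lam2)
        assert out.overlap > 0.95
        # pointwise collapse on the common scaled grid
        ref_i = np.column_stack([
            np.interp(out.s_scaled, d_ref.s / lam_ref, ref[:, i])
            for i in (0, 1)
        ])
        scale = np.max(np.abs(ref_i))
        gap = np.max(np.abs(out.modes - ref_i)) / scale
        assert gap < 0.05

    def test_incompatible_modes_warn(self, two_harmonic_field):
        field, rec = two_harmonic_field
        d = covariance_modes(field)
        rng = np.random.default_rng(0)
        ref = rng.normal(size=(d.s.size, 2))
        with pytest.warns(UserWarning, match="incompatible"):
            align_modes(d, ref, d.s / 40.0, 40.0)
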