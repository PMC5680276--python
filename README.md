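# flagbeat

Tethered human sperm rotate around their attachment point even though
every snapshot of the flagellum is spatially mirror-symmetric.  The
resolution is temporal: the flagellar beat is a superposition of a
fundamental traveling bending wave (~20 Hz) and its second harmonic,

    C(s, t) = C0 + C1·sin(ks − ω0 t) + C2·sin(ks − 2ω0 t + φ),

and the second harmonic breaks the half-period mirror symmetry
C(s, t) = −C(s, t + τ/2) in *time*.  Coupled to anisotropic viscous
drag (ξ⊥ > ξ∥), this rectifies into a net torque: in the long-
wavelength limit λ → L the rotation velocity is

    Ω = −ω0 · (3L³ / 4(2π)⁴) · ((ξ⊥−ξ∥)/ξ⊥) · C1² C2 sin φ,

so the steering signal is the "second-harmonic intensity" C2·sin φ.

`flagbeat` is a tested, end-to-end implementation of this analysis for
people who study flagellar and ciliary beating: synthetic ground-truth
data (curvature waves, tracked rotating cells, rendered dark-field-like
image stacks), midline tracking, curvature kymographs and rotation
kinematics, principal beat modes with a noise-matched significance
null, time-resolved harmonic amplitude/phase estimation and its
correlation with rotation, the resistive-force-theory closed forms with
an exact torque-balance oracle, and an overdamped active elastic
filament simulator driven by two-harmonic bending torques (tethered and
free-swimming).

## Worked example

Generate a tethered cell whose rotation follows the steering law with a
slowly drifting second harmonic and a constant phase offset of 0.7 rad,
then run the full analysis chain:

```python
import numpy as np, dataclasses
from flagbeat.synthetic import (WaveformSpec, DriftProfile,
                                gen_rotating_cell, default_grid)
from flagbeat.kinematics import curvature_three_point, rotation_velocity
from flagbeat.harmonics import spectrogram_harmonics, optimize_phase_offset
from flagbeat.modes import covariance_modes, significant_modes
from flagbeat.theory import DragModel, omega_second_harmonic

rng = np.random.default_rng(1)
spec = WaveformSpec(C1=0.1, C2=0.02, freq_hz=20.0, wavelength=40.0, L=45.0)
s, t = default_grid(duration=30.0)
drift = DriftProfile.smoothed_random_walk(spec, duration=30.0, rng=rng,
                                          timescale=2.0, phi_sd=0.8,
                                          noise_sd=0.005)
drag = DragModel()
unit = dataclasses.replace(spec, C2=1.0, phi=np.pi / 2)
law = omega_second_harmonic(unit, drag, L=40.0)
omega_true = lambda tt: law * drift.c2_of_t(tt) * np.sin(drift.phi_of_t(tt) + 0.7)
tracks, record = gen_rotating_cell(spec, drift, omega_of_t=omega_true,
                                   s=s, t=t, seed=2)

field = curvature_three_point(tracks)          # curvature kymograph
omega = rotation_velocity(tracks)              # pivot rotation, rev/s
decomp = covariance_modes(field)               # principal beat modes
n_sig = significant_modes(decomp, seed=3)
s0, row = field.row(15.0)                      # probe at s = 15 µm
trace = spectrogram_harmonics(row, field.frame_rate,
                              wave_number=spec.k, s0=s0)
phi0, R = optimize_phase_offset(omega, trace)

print(f"beat frequency   : {np.nanmedian(trace.omega0):.1f} Hz")
print(f"significant modes: {n_sig} "
      f"(first two carry {100 * decomp.variance_fractions[:2].sum():.1f}% of variance)")
print(f"median C2/C1     : {np.nanmedian(trace.C2 / trace.C1):.3f}")
print(f"steering R       : {R:.3f} at phase offset {phi0:+.3f} rad")
```

which prints

```
beat frequency   : 20.0 Hz
significant modes: 2 (first two carry 99.9% of variance)
median C2/C1     : 0.192
steering R       : 0.996 at phase offset -2.434 rad
```

The beat frequency, mode count, and harmonic ratio recover the
generator settings; R ≈ 1 says the rotation is fully explained by the
second-harmonic intensity; and the recovered offset equals the injected
0.7 rad after removing the π that the steering law's leading minus sign
(positive intensity → clockwise rotation) pushes into the R-maximizing
offset: −2.434 + π ≈ 0.707.

A `flagbeat` command-line tool wraps the same machinery
(`flagbeat synth|track|analyze|theory|simulate|sweep --help`).

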