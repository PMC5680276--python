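"""Time-resolved harmonic content of the curvature at a fixed arclength.

A sliding rectangular-window DFT locates the fundamental beat peak; the
amplitudes and phases of the fundamental and second harmonic are then
re-estimated by least squares at the refined frequency, which is immune
to spectral scalloping.  The steering-relevant quantity is the
second-harmonic intensity C2·sin(φ_eff), whose correlation R with the
normalized rotation velocity Ω/ω0 is computed about zero (not about the
series means): with no second harmonic there is no rotation, so both
series are referenced to their physical null.

Phase convention
----------------
For a curvature signal written as a two-harmonic traveling wave

    C(t; s0) = C1·sin(k·s0 − ω0·t) + C2·sin(k·s0 − 2ω0·t + φ),

the shift-invariant combination measurable at one probe point is
φ − k·s0 (the two waves travel at different phase velocities, so the
apparent phase lag depends on the probe position).  ``spectrogram_
harmonics`` returns that raw combination by default; passing the wave
number restores the traveling-wave φ itself, which is how generator
round trips and parameter-recovery tests are closed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .core import CurvatureField, wrap_angle
from .kinematics import RotationTrace

__all__ = [
    "HarmonicTrace",
    "SteeringCorrelation",
    "spectrogram_harmonics",
    "second_harmonic_intensity",
    "correlation_R",
    "optimize_phase_offset",
    "probe_consistency",
]


@dataclass
class HarmonicTrace:
    """Windowed estimates of ω0(t), C1(t), C2(t) and φ(t) at one probe.

    ``phi`` follows the traveling-wave convention when the wave number
    was supplied, otherwise it is the raw probe-local phase (see module
    docstring).  ``valid`` masks windows with no credible fundamental
    peak.
    """

    t: np.ndarray  # window centers, s
    omega0: np.ndarray  # fundamental frequency, Hz
    C1: np.ndarray  # µm⁻¹
    C2: np.ndarray  # µm⁻¹
    phi: np.ndarray  # rad, wrapped to (−π, π]
    valid: np.ndarray  # bool mask
    s0: Optional[float]  # probe arclength, µm
    window: int  # frames
    step: int  # frames

    def masked(self) -> "HarmonicTrace":
        m = self.valid
        return HarmonicTrace(
            t=self.t[m], omega0=self.omega0[m], C1=self.C1[m], C2=self.C2[m],
            phi=self.phi[m], valid=self.valid[m], s0=self.s0,
            window=self.window, step=self.step,
        )


@dataclass
class SteeringCorrelation:
    """Correlation between rotation and second-harmonic intensity."""

    R: float
    phi0: float  # optimized constant phase offset, rad
    phi_eff: np.ndarray  # φ(t) + φ0
    intensity: np.ndarray  # C2(t)·sin(φ_eff)
    omega_norm: np.ndarray  # Ω(t)/ω0(t), dimensionless
    t: np.ndarray
    identifiable: bool = True


def _harmonic_lsq(x: np.ndarray, f0_cyc: np.ndarray) -> np.ndarray:
    """Least-squares fit of x_n ≈ a0 + Σ_{m=1,2} am·cos + bm·sin at m·f0.

    ``f0_cyc`` is the fundamental frequency in cycles/sample.  Returns
    the complex amplitudes A_m = a_m − i·b_m for m = 1, 2, so that
    x(t) = Re[A_m·exp(i·m·ω0·t)] per component.
    """
    n = np.arange(x.size)
    w = 2.0 * np.pi * f0_cyc
    cols = [np.ones_like(x)]
    for m in (1, 2):
        cols.append(np.cos(m * w * n))
        cols.append(np.sin(m * w * n))
    M = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(M, x, rcond=None)
    return np.array([coef[1] - 1j * coef[2], coef[3] - 1j * coef[4]])


def spectrogram_harmonics(
    c_row: np.ndarray,
    frame_rate: float,
    window: int = 250,
    step: int = 30,
    band: tuple[float, float] = (10.0, 35.0),
    wave_number: Optional[float] = None,
    s0: Optional[float] = None,
    peak_snr: float = 4.0,
) -> HarmonicTrace:
    """Sliding-window estimation of the two leading beat harmonics.

    Per window: a rectangular DFT locates the dominant peak inside
    ``band`` (Hz); the peak frequency is refined by parabolic
    interpolation of the spectrum magnitude; complex amplitudes at ω0
    and 2ω0 come from a least-squares two-harmonic fit at the refined
    frequency.  φ is the phase of the second harmonic relative to twice
    the fundamental phase (shift-invariant); adding k·s0 converts it to
    the traveling-wave convention when ``wave_number`` is given.

    Windows whose peak fails the ``peak_snr`` × median-spectrum test are
    masked rather than reported.
    """
    x_full = np.asarray(c_row, dtype=float)
    if x_full.ndim != 1:
        raise ValueError("c_row must be one-dimensional")
    if x_full.size < window:
        raise ValueError("record shorter than one analysis window")
    freqs = np.fft.rfftfreq(window, d=1.0 / frame_rate)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not np.any(in_band):
        raise ValueError("frequency band empty at this window length")
    band_idx = np.flatnonzero(in_band)

    starts = np.arange(0, x_full.size - window + 1, step)
    t_centers = (starts + window / 2.0) / frame_rate
    n_win = starts.size
    om = np.full(n_win, np.nan)
    c1 = np.full(n_win, np.nan)
    c2 = np.full(n_win, np.nan)
    ph = np.full(n_win, np.nan)
    valid = np.zeros(n_win, dtype=bool)

    for i, st in enumerate(starts):
        x = x_full[st:st + window]
        x = x - x.mean()
        X = np.fft.rfft(x)
        mag = np.abs(X)
        j = band_idx[np.argmax(mag[band_idx])]
        noise = np.median(mag[band_idx])
        if noise > 0 and mag[j] < peak_snr * noise:
            continue
        if mag[j] == 0:
            continue
        # sub-bin refinement: Jacobsen's complex-ratio estimator, which
        # is nearly unbiased for a rectangular window
        if 0 < j < X.size - 1:
            denom = 2.0 * X[j] - X[j - 1] - X[j + 1]
            delta = 0.0 if denom == 0 else float(
                np.real((X[j - 1] - X[j + 1]) / denom))
            delta = float(np.clip(delta, -0.5, 0.5))
        else:
            delta = 0.0
        f0 = (j + delta) * frame_rate / window  # Hz
        if not (band[0] * 0.8 <= f0 <= band[1] * 1.2):
            continue
        if 2.0 * f0 >= 0.5 * frame_rate:
            continue  # second harmonic not resolvable
        A1, A2 = _harmonic_lsq(x, f0 / frame_rate)
        om[i] = f0
        c1[i] = np.abs(A1)
        c2[i] = np.abs(A2)
        phi_raw = 2.0 * np.angle(A1) - np.angle(A2) - 0.5 * np.pi
        if wave_number is not None and s0 is not None:
            phi_raw += wave_number * s0
        ph[i] = wrap_angle(phi_raw)
        valid[i] = True

    return HarmonicTrace(
        t=t_centers, omega0=om, C1=c1, C2=c2, phi=ph,
        valid=valid, s0=s0, window=window, step=step,
    )


def second_harmonic_intensity(trace: HarmonicTrace, phi0: float = 0.0) -> np.ndarray:
    """Second-harmonic intensity I(t) = C2(t)·sin(φ(t) + φ0)."""
    return trace.C2 * np.sin(trace.phi + phi0)


def _common_series(omega: RotationTrace, trace: HarmonicTrace,
                   match_filter: bool = True):
    """Ω/ω0 and the intensity quadratures (C2·sin φ, C2·cos φ) resampled
    onto the valid window centers.

    The rotation velocity reaching the correlation has passed through
    the Gaussian low-pass of the rotation estimator; with
    ``match_filter`` the same Gaussian is applied to the two intensity
    quadratures so both series share one bandwidth (an unmatched filter
    biases the R-maximizing phase offset).
    """
    from scipy.ndimage import gaussian_filter1d

    m = trace.valid & np.isfinite(trace.omega0)
    if m.sum() < 2:
        raise ValueError("too few valid harmonic windows")
    t = trace.t[m]
    om_norm = omega.omega_at(t) / trace.omega0[m]
    qs = trace.C2[m] * np.sin(trace.phi[m])
    qc = trace.C2[m] * np.cos(trace.phi[m])
    if match_filter and omega.filter_width > 0 and t.size > 3:
        dt = float(np.mean(np.diff(t)))
        sig = omega.filter_width / dt
        qs = gaussian_filter1d(qs, sig, truncate=3.0, mode="nearest")
        qc = gaussian_filter1d(qc, sig, truncate=3.0, mode="nearest")
    return t, om_norm, qs, qc


def correlation_R(
    omega: RotationTrace,
    trace: HarmonicTrace,
    phi0: float,
) -> float:
    """Non-centred correlation between Ω/ω0 and C2·sin(φ+φ0).

    R = ⟨u·I⟩ / √(⟨u²⟩⟨I²⟩) with u = Ω/ω0 and both series taken about
    zero: the physically meaningful reference, since without a second
    harmonic there is no rotation.
    """
    _, u, qs, qc = _common_series(omega, trace)
    I = qs * np.cos(phi0) + qc * np.sin(phi0)  # = C2·sin(φ+φ0), filtered
    uu = float(np.mean(u * u))
    ii = float(np.mean(I * I))
    if uu == 0.0 or ii == 0.0:
        raise ValueError("correlation undefined: a series is identically zero")
    return float(np.mean(u * I) / np.sqrt(uu * ii))


def optimize_phase_offset(
    omega: RotationTrace,
    trace: HarmonicTrace,
    n_grid: int = 720,
    flat_tol: float = 1e-3,
) -> tuple[float, float]:
    """Constant phase offset φ0 maximizing R, one value per recording.

    A grid over (−π, π] (initialized near the closed-form argmax of the
    numerator, atan2(⟨u·C2 cos φ⟩, ⟨u·C2 sin φ⟩)) is refined by bounded
    scalar maximization.  Returns (φ0, R_max); warns and flags when the
    objective is flat (phase unidentifiable).
    """
    t, u, qs, qc = _common_series(omega, trace)
    if t.size < 50:
        raise ValueError("need at least 50 common time points")
    uu = float(np.mean(u * u))
    if uu == 0.0:
        raise ValueError("rotation series identically zero")

    def _R(p0: float) -> float:
        I = qs * np.cos(p0) + qc * np.sin(p0)
        ii = float(np.mean(I * I))
        if ii == 0.0:
            return 0.0
        return float(np.mean(u * I) / np.sqrt(uu * ii))

    grid = np.linspace(-np.pi, np.pi, n_grid, endpoint=False)
    vals = np.array([_R(p) for p in grid])
    if vals.max() - vals.min() < flat_tol:
        warnings.warn("phase unidentifiable: correlation flat in phi0", stacklevel=2)
        return float(grid[np.argmax(vals)]), float(vals.max())
    j = int(np.argmax(vals))
    dp = grid[1] - grid[0]
    res = minimize_scalar(
        lambda p: -_R(p), bounds=(grid[j] - dp, grid[j] + dp), method="bounded"
    )
    phi0 = float(wrap_angle(res.x))
    return phi0, float(-res.fun)


def probe_consistency(
    field: CurvatureField,
    omega: RotationTrace,
    s_list=(15.0, 25.0),
    reference: Optional[float] = None,
    **spec_kw,
) -> pd.DataFrame:
    """R at several probe arclengths using one shared phase offset.

    The offset φ0 is optimized at the ``reference`` probe (default: the
    last entry of ``s_list``, i.e. the most distal) and reused at every
    other probe; the table reports R per probe and the deltas against
    the reference.
    """
    s_list = list(s_list)
    if reference is None:
        reference = s_list[-1]
    frame_rate = field.frame_rate
    s_ref, row_ref = field.row(reference)
    tr_ref = spectrogram_harmonics(row_ref, frame_rate, s0=s_ref, **spec_kw)
    phi0, r_ref = optimize_phase_offset(omega, tr_ref)

    rows = []
    for s0 in s_list:
        s_act, crow = field.row(s0)
        tr = spectrogram_harmonics(crow, frame_rate, s0=s_act, **spec_kw)
        r = correlation_R(omega, tr, phi0)
        rows.append(
            {"s_probe": s_act, "R": r, "phi0": phi0, "delta_R_vs_ref": r - r_ref}
        )
    return pd.DataFrame(rows)
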