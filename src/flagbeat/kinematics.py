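"""Curvature and rotation kinematics of tracked flagella.

The curvature field is computed by the three-point circumcircle rule
(signed by the local turning direction, counter-clockwise positive) and
the cell rotation velocity from the pivot-to-first-point angle after
Gaussian low-pass filtering of the unwrapped angle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter1d, uniform_filter1d

from .core import CurvatureField, TrackedFlagellum

__all__ = [
    "RotationTrace",
    "curvature_three_point",
    "rotation_velocity",
    "mirror_symmetry_defect",
    "average_curvature",
]


@dataclass
class RotationTrace:
    """Pivot angle α(t) and rotation velocity Ω(t).

    ``alpha`` is the unwrapped raw angle (rad); ``Omega`` the rotation
    velocity in revolutions/s, positive counter-clockwise, obtained from
    the Gaussian-filtered angle by central differences.
    """

    t: np.ndarray
    alpha: np.ndarray
    Omega: np.ndarray
    filter_width: float

    def omega_at(self, t_query: np.ndarray) -> np.ndarray:
        return np.interp(t_query, self.t, self.Omega)


def curvature_three_point(tracks: TrackedFlagellum) -> CurvatureField:
    """Signed curvature from the circumcircle of contiguous point triples.

    C(sᵢ) = ±1/R where R is the circumradius of (pᵢ₋₁, pᵢ, pᵢ₊₁); the
    sign is the orientation of the triple (cross product), positive for
    counter-clockwise bends.  Collinear triples give exactly zero; the
    two endpoints carry no value, so the arclength grid starts at Δs.
    """
    p = tracks.points  # (n_frames, n_pts, 2)
    if p.shape[1] < 3:
        raise ValueError("need at least three points per frame")
    a = p[:, :-2, :]
    b = p[:, 1:-1, :]
    c = p[:, 2:, :]
    ab = b - a
    bc = c - b
    ca = a - c
    la = np.linalg.norm(ab, axis=-1)
    lb = np.linalg.norm(bc, axis=-1)
    lc = np.linalg.norm(ca, axis=-1)
    if np.any(la == 0) or np.any(lb == 0):
        raise ValueError("duplicate consecutive points")
    cross = ab[..., 0] * bc[..., 1] - ab[..., 1] * bc[..., 0]
    # Menger curvature: 2·area-cross / product of side lengths, signed
    C = 2.0 * cross / (la * lb * lc)
    s = tracks.ds * np.arange(1, p.shape[1] - 1)
    return CurvatureField(C=C.T, s=s, t=tracks.times)


def rotation_velocity(
    tracks: TrackedFlagellum,
    filter_width: float = 1.0,
    pivot=None,
) -> RotationTrace:
    """Rotation velocity from the angle between the x-axis and the
    pivot→first-tracked-point vector.

    The angle is unwrapped, filtered with a Gaussian of SD
    ``filter_width`` seconds (truncated at ±3 SD) to remove the fast
    beat oscillation, and differentiated by central differences.
    """
    if pivot is None:
        pivot = tracks.pivot
    if pivot is None:
        raise ValueError("pivot position unknown")
    pivot = np.asarray(pivot, float)
    dt = tracks.dt
    if filter_width > 0 and tracks.times[-1] - tracks.times[0] < 2.0 * filter_width:
        raise ValueError("record shorter than twice the filter width")
    vec = tracks.points[:, 0, :] - pivot[None, :]
    r = np.linalg.norm(vec, axis=1)
    if np.any(r < 1e-9):
        raise ValueError("pivot coincides with the first tracked point")
    alpha = np.unwrap(np.arctan2(vec[:, 1], vec[:, 0]))
    if filter_width > 0:
        alpha_f = gaussian_filter1d(
            alpha, sigma=filter_width / dt, truncate=3.0, mode="nearest"
        )
    else:
        alpha_f = alpha
    omega = np.gradient(alpha_f, tracks.times) / (2.0 * np.pi)
    return RotationTrace(
        t=tracks.times, alpha=alpha, Omega=omega, filter_width=filter_width
    )


def mirror_symmetry_defect(field: CurvatureField, tau: float) -> float:
    """How far the beat is from half-period mirror antisymmetry.

    A single-frequency planar beat satisfies C(s,t) = −C(s, t+τ/2); a
    second harmonic (or a static offset) breaks this.  Returns
    ‖C(s,t) + C(s,t+τ/2)‖₂ / (2‖C‖₂), which is 0 for a pure fundamental
    and equals C2/√(C1²+C2²) for an offset-free two-harmonic wave.
    """
    dt = field.dt
    if 0.5 * tau < 2.0 * dt:
        raise ValueError("beat period not resolvable at this frame rate")
    if field.duration < 1.5 * tau:
        raise ValueError("record shorter than 1.5 beat periods")
    # exact (bandlimited) time shift by τ/2 via the Fourier phase ramp;
    # an integer-frame shift would alias whenever τ/2 is off the grid
    n_t = field.C.shape[1]
    freqs = np.fft.rfftfreq(n_t, d=dt)
    shifted = np.fft.irfft(
        np.fft.rfft(field.C, axis=1)
        * np.exp(-2j * np.pi * freqs * 0.5 * tau)[None, :],
        n=n_t, axis=1,
    )
    num = np.sqrt(np.mean((field.C + shifted) ** 2))
    den = 2.0 * np.sqrt(np.mean(field.C**2))
    if den == 0:
        raise ValueError("zero curvature field")
    return float(num / den)


def average_curvature(
    field: CurvatureField,
    window: float = 0.5,
    step: int = 30,
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window mean curvature C0(t) over arclength and time.

    ``window`` (s) must cover at least one beat period so the harmonics
    average out; sampled every ``step`` frames to match the spectrogram
    cadence.  Returns (t_centers, C0).
    """
    w = max(1, int(round(window / field.dt)))
    mean_s = field.C.mean(axis=0)
    smoothed = uniform_filter1d(mean_s, size=w, mode="nearest")
    idx = np.arange(w // 2, field.C.shape[1] - w // 2, step)
    if idx.size == 0:
        idx = np.array([field.C.shape[1] // 2])
    return field.t[idx], smoothed[idx]
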