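"""Resistive-force-theory predictions for tethered-cell rotation.

Slender-filament drag is local and anisotropic (perpendicular
coefficient ξ⊥ exceeds the tangential ξ∥), so a time-asymmetric beat
produces a nonzero cycle-averaged force and torque.  This module holds
the closed-form results — the net transverse force density of a
small-amplitude two-harmonic wave, and the rotation velocity driven by
the second harmonic (λ→L limit) or by an intrinsic static curvature —
plus a brute-force kinematic quadrature oracle that builds the exact
shape sequence from the curvature wave and evaluates the torque balance
numerically.

Rotation velocities are returned in revolutions/s (Hz), signed positive
counter-clockwise, matching the kinematics module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .synthetic import WaveformSpec

__all__ = [
    "DragModel",
    "net_transverse_force",
    "net_transverse_force_numeric",
    "omega_second_harmonic",
    "omega_intrinsic_curvature",
    "kinematic_omega_oracle",
]


@dataclass
class DragModel:
    """Anisotropic local drag coefficients per unit length, fN·s·µm⁻².

    Defaults are the values used for human sperm in aqueous buffer:
    ξ∥ = 0.69 fN·s·µm⁻² and ξ⊥/ξ∥ = 1.81.
    """

    xi_par: float = 0.69
    xi_perp: float = 0.69 * 1.81

    def __post_init__(self):
        if self.xi_par <= 0 or self.xi_perp <= 0:
            raise ValueError("drag coefficients must be positive")
        if self.xi_perp <= self.xi_par:
            warnings.warn(
                "xi_perp <= xi_par: anisotropy ratio <= 1 produces no propulsion",
                stacklevel=2,
            )

    @property
    def ratio(self) -> float:
        return self.xi_perp / self.xi_par

    @property
    def anisotropy(self) -> float:
        """(ξ⊥ − ξ∥)/ξ⊥, the factor entering every rotation formula."""
        return (self.xi_perp - self.xi_par) / self.xi_perp


def net_transverse_force(spec: WaveformSpec, drag: DragModel, x) -> np.ndarray:
    """Cycle-averaged transverse RFT force density of the small-amplitude
    two-harmonic wave, fN·µm⁻¹:

        f_y(x) = ω0·k²·(ξ⊥ − ξ∥)·y1²·y2·cos(kx − φ).

    Vanishes identically for y2 = 0 (single harmonic is time-mirror
    symmetric) or isotropic drag.  Valid at leading order in k·y1.
    """
    if spec.y1 is None or spec.y2 is None:
        raise ValueError("y-form amplitudes y1, y2 required")
    x = np.asarray(x, dtype=float)
    return (
        spec.omega0
        * spec.k**2
        * (drag.xi_perp - drag.xi_par)
        * spec.y1**2
        * spec.y2
        * np.cos(spec.k * x - spec.phi)
    )


def net_transverse_force_numeric(
    spec: WaveformSpec, drag: DragModel, x, n_t: int = 10_000
) -> np.ndarray:
    """Direct time average of the ŷ-projected RFT drag force density.

    Evaluates f = −ξ⊥·v⊥ − ξ∥·v∥ with v = (0, ∂t y) and the exact unit
    tangent of y(x, t), averaged over one beat period with ``n_t``
    uniform samples.  Used as the independent check of the closed form
    at small amplitude.
    """
    if spec.y1 is None or spec.y2 is None:
        raise ValueError("y-form amplitudes y1, y2 required")
    x = np.asarray(x, dtype=float)[:, None]
    t = (np.arange(n_t) / n_t * spec.period)[None, :]
    k, w, phi = spec.k, spec.omega0, spec.phi
    arg1 = k * x - w * t
    arg2 = k * x - 2.0 * w * t + phi
    vy = -w * spec.y1 * np.cos(arg1) - 2.0 * w * spec.y2 * np.cos(arg2)
    yx = k * spec.y1 * np.cos(arg1) + k * spec.y2 * np.cos(arg2)
    norm2 = 1.0 + yx**2
    # v·t̂ = vy·yx/√(1+yx²);  t̂_y = yx/√(1+yx²)
    f_y = -drag.xi_perp * vy + (drag.xi_perp - drag.xi_par) * vy * yx**2 / norm2
    return f_y.mean(axis=1)


def omega_second_harmonic(
    spec: WaveformSpec, drag: DragModel, L: float | None = None
) -> float:
    """Rotation velocity (rev/s) from the second harmonic, λ→L limit:

        Ω = −ω0 · (3L³ / 4(2π)⁴) · ((ξ⊥−ξ∥)/ξ⊥) · C1²·C2·sin φ.

    Linear in C2 and in sin φ; zero at φ ∈ {0, π}.  Warns outside the
    published validity window λ/L ∈ [0.8, 1.25].
    """
    L = spec.L if L is None else L
    lam_ratio = spec.wavelength / L
    if not (0.8 <= lam_ratio <= 1.25):
        warnings.warn(
            f"lambda/L = {lam_ratio:.2f} outside the published validity limit",
            stacklevel=2,
        )
    return (
        -spec.freq_hz
        * (3.0 * L**3 / (4.0 * (2.0 * np.pi) ** 4))
        * drag.anisotropy
        * spec.C1**2
        * spec.C2
        * np.sin(spec.phi)
    )


def omega_intrinsic_curvature(
    C0: float, C1: float, drag: DragModel, L: float, freq_hz: float
) -> float:
    """Rotation velocity (rev/s) from a static intrinsic curvature C0:

        Ω = ω0 · (L³/(2π)⁶) · ((ξ⊥−ξ∥)/ξ⊥) · C1²·C0 · π(π²−3).

    The small-curvature companion of the second-harmonic formula; for
    equal |C0| and |C2| both mechanisms contribute at the same order.
    """
    return (
        freq_hz
        * (L**3 / (2.0 * np.pi) ** 6)
        * drag.anisotropy
        * C1**2
        * C0
        * np.pi
        * (np.pi**2 - 3.0)
    )


def kinematic_omega_oracle(
    spec: WaveformSpec,
    drag: DragModel,
    L: float | None = None,
    n_s: int = 400,
    n_t: int = 400,
    n_periods: int = 1,
) -> float:
    """Numerical torque-balance rotation velocity (rev/s), no
    small-amplitude expansion.

    A planar shape sequence splits exactly into the prescribed curvature
    wave (pinned base, zero base tangent) plus one rigid-rotation degree
    of freedom γ(t) about the pivot.  RFT drag is linear in velocity, so
    the instantaneous torque balance about the pivot closes in γ̇:

        γ̇(t) = T_beat(t) / ξ_rot(t),

    where T_beat is the torque of the pure shape-change motion and
    ξ_rot(t) = ∫ (ẑ×r)·Ξ·(ẑ×r) ds the rotational drag of the current
    shape.  The net rotation is the period average of γ̇.  This is the
    exact overdamped dynamics of a tethered filament with prescribed
    curvature evolution, and serves as the independent oracle for the
    asymptotic closed forms.  Resolution must be ≥ 200 points per period
    and along the filament.
    """
    if n_s < 200 or n_t < 200:
        raise ValueError("resolution must be >= 200 points per period and per L")
    if n_periods < 1 or int(n_periods) != n_periods:
        raise ValueError("n_periods must be a positive integer")
    L = spec.L if L is None else L
    s = np.linspace(0.0, L, n_s)[:, None]
    # uniform samples over integer periods, endpoint excluded (periodic mean)
    t = (np.arange(n_t * n_periods) / n_t * spec.period)[None, :]
    k, w, phi = spec.k, spec.omega0, spec.phi

    # θ(s,t) = ∫0^s C ds′, analytic for the three-term curvature wave
    def theta(tt):
        return (
            spec.C0 * s
            - spec.C1 / k * (np.cos(k * s - w * tt) - np.cos(-w * tt))
            - spec.C2 / k * (np.cos(k * s - 2 * w * tt + phi) - np.cos(-2 * w * tt + phi))
        )

    th = theta(t)
    cx, sx = np.cos(th), np.sin(th)
    ds = s[1, 0] - s[0, 0]
    x = np.vstack([np.zeros((1, th.shape[1])), np.cumsum((cx[1:] + cx[:-1]) / 2, 0) * ds])
    y = np.vstack([np.zeros((1, th.shape[1])), np.cumsum((sx[1:] + sx[:-1]) / 2, 0) * ds])

    # velocities by spectral-accuracy central differences in time (periodic)
    dt = spec.period / n_t
    vx = (np.roll(x, -1, axis=1) - np.roll(x, 1, axis=1)) / (2 * dt)
    vy = (np.roll(y, -1, axis=1) - np.roll(y, 1, axis=1)) / (2 * dt)

    tx, ty = cx, sx
    vt = vx * tx + vy * ty
    fx = -drag.xi_perp * vx + (drag.xi_perp - drag.xi_par) * vt * tx
    fy = -drag.xi_perp * vy + (drag.xi_perp - drag.xi_par) * vt * ty
    torque_beat = np.trapezoid(x * fy - y * fx, dx=ds, axis=0)

    # rotational drag of the instantaneous shape: u = ẑ×r = (−y, x)
    ut = -y * tx + x * ty
    dens = drag.xi_perp * (x**2 + y**2) - (drag.xi_perp - drag.xi_par) * ut**2
    xi_rot_t = np.trapezoid(dens, dx=ds, axis=0)

    gamma_dot = torque_beat / xi_rot_t
    return float(np.mean(gamma_dot)) / (2.0 * np.pi)
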