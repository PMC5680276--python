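"""Synthetic flagellar-beat data with known ground truth.

Generates curvature kymographs built from a fundamental traveling wave
plus a second harmonic whose amplitude and phase drift slowly, tracked
point series of tethered rotating cells, and rendered dark-field-like
image stacks.  Every generator returns a :class:`GroundTruthRecord` so
downstream estimators (tracking, kinematics, harmonics, modes) can be
validated by parameter recovery.

The default waveform mirrors typical tethered human sperm recordings:
beat frequency ≈ 20 Hz, sampling at 500 frames/s, arclength sampling
Δs = 0.9 µm over ~30 points, fundamental curvature amplitude
~0.1 µm⁻¹ and relative second-harmonic amplitude 0.1–0.3.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.ndimage import gaussian_filter1d

from .core import CurvatureField, TrackedFlagellum, wrap_angle

__all__ = [
    "WaveformSpec",
    "DriftProfile",
    "GroundTruthRecord",
    "SyntheticScene",
    "Optics",
    "default_grid",
    "gen_curvature_wave",
    "integrate_shape",
    "gen_rotating_cell",
    "gen_random_curvature",
    "render_frames",
]


@dataclass
class WaveformSpec:
    """Two-harmonic traveling-wave parameters.

    In curvature form the waveform is

        C(s, t) = C0 + C1·sin(k·s − ω0·t) + C2·sin(k·s − 2ω0·t + φ)

    with curvature amplitudes in µm⁻¹.  ``y1``/``y2`` are the optional
    transverse displacement amplitudes of the equivalent small-amplitude
    form y(x,t) = y1 sin(kx − ω0 t) + y2 sin(kx − 2ω0 t + φ).
    """

    C0: float = 0.0
    C1: float = 0.1
    C2: float = 0.02
    wavelength: float = 40.0  # µm
    freq_hz: float = 20.0  # fundamental beat frequency ω0 / 2π
    phi: float = 0.0  # second-harmonic phase shift, rad
    L: float = 45.0  # flagellar length, µm
    y1: Optional[float] = None
    y2: Optional[float] = None

    def __post_init__(self):
        if self.C1 < 0 or self.C2 < 0:
            raise ValueError("harmonic amplitudes C1, C2 must be >= 0")
        if self.L <= 0 or self.wavelength <= 0:
            raise ValueError("L and wavelength must be positive")
        self.phi = float(wrap_angle(self.phi))

    @property
    def k(self) -> float:
        """Wave number, rad/µm."""
        return 2.0 * np.pi / self.wavelength

    @property
    def omega0(self) -> float:
        """Fundamental angular frequency, rad/s."""
        return 2.0 * np.pi * self.freq_hz

    @property
    def period(self) -> float:
        return 1.0 / self.freq_hz


@dataclass
class DriftProfile:
    """Slow temporal drift of the second-harmonic amplitude and phase.

    ``c2_of_t`` and ``phi_of_t`` map an array of times (s) to C2(t)
    (µm⁻¹, clipped non-negative) and φ(t) (rad).  The stock constructor
    :meth:`smoothed_random_walk` draws mean-reverting (Ornstein–
    Uhlenbeck) traces with a correlation time much longer than the beat
    period, emulating the smooth second-by-second variation of rotation
    seen in tethered cells.
    """

    c2_of_t: Callable[[np.ndarray], np.ndarray]
    phi_of_t: Callable[[np.ndarray], np.ndarray]
    timescale: float = 2.0  # s
    noise_sd: float = 0.0  # additive curvature noise, µm⁻¹

    @classmethod
    def none(cls, spec: WaveformSpec, noise_sd: float = 0.0) -> "DriftProfile":
        """Constant C2 and φ taken from the spec (no drift)."""
        return cls(
            c2_of_t=lambda t: np.full(np.shape(t), spec.C2, dtype=float),
            phi_of_t=lambda t: np.full(np.shape(t), spec.phi, dtype=float),
            timescale=np.inf,
            noise_sd=noise_sd,
        )

    @classmethod
    def smoothed_random_walk(
        cls,
        spec: WaveformSpec,
        duration: float,
        rng: np.random.Generator,
        timescale: float = 2.0,
        c2_rel_sd: float = 0.3,
        phi_sd: float = 0.5,
        noise_sd: float = 0.0,
        dt: float = 0.01,
    ) -> "DriftProfile":
        """Mean-reverting drift around the spec values.

        The stationary SD of C2(t) is ``c2_rel_sd * spec.C2`` and of
        φ(t) is ``phi_sd`` rad; ``timescale`` must exceed several beat
        periods for the harmonic analysis to remain quasi-static.
        """
        if timescale < 3.0 * spec.period:
            raise ValueError("drift timescale must be >> beat period")
        tgrid = np.arange(0.0, duration + 4 * dt, dt)
        n = tgrid.size

        def _ou(sd: float) -> np.ndarray:
            theta = 1.0 / timescale
            x = np.empty(n)
            x[0] = rng.normal(0.0, sd)
            f = np.exp(-theta * dt)
            g = sd * np.sqrt(1.0 - f * f)
            innov = rng.normal(0.0, 1.0, n - 1)
            for i in range(1, n):
                x[i] = x[i - 1] * f + g * innov[i - 1]
            # light smoothing removes the residual small-scale roughness
            return gaussian_filter1d(x, max(1.0, 0.05 * timescale / dt))

        c2_trace = np.clip(spec.C2 + _ou(c2_rel_sd * spec.C2), 0.0, None)
        phi_trace = spec.phi + _ou(phi_sd)
        return cls(
            c2_of_t=lambda t: np.interp(t, tgrid, c2_trace),
            phi_of_t=lambda t: np.interp(t, tgrid, phi_trace),
            timescale=timescale,
            noise_sd=noise_sd,
        )


@dataclass
class GroundTruthRecord:
    """Everything needed to score an estimator against the generator."""

    spec: WaveformSpec
    s: np.ndarray
    t: np.ndarray
    C_true: np.ndarray  # noiseless curvature field (n_s, n_t)
    C2_t: np.ndarray  # true second-harmonic amplitude per frame
    phi_t: np.ndarray  # true second-harmonic phase per frame
    noise_sd: float
    seed: Optional[int] = None
    omega_t: Optional[np.ndarray] = None  # true rotation velocity, rev/s
    rotation_angle: Optional[np.ndarray] = None  # rad, about the pivot
    points_true: Optional[np.ndarray] = None  # (n_frames, n_pts, 2) µm


def default_grid(
    duration: float = 10.0,
    frame_rate: float = 500.0,
    ds: float = 0.9,
    n_s: int = 30,
) -> tuple[np.ndarray, np.ndarray]:
    """Arclength/time grid matching the experimental sampling."""
    s = ds * np.arange(n_s)
    t = np.arange(0.0, duration, 1.0 / frame_rate)
    return s, t


def _closed_form(spec, s, t, c2_t, phi_t):
    ks = spec.k * s[:, None]
    wt = spec.omega0 * t[None, :]
    return (
        spec.C0
        + spec.C1 * np.sin(ks - wt)
        + c2_t[None, :] * np.sin(ks - 2.0 * wt + phi_t[None, :])
    )


def gen_curvature_wave(
    spec: WaveformSpec,
    drift: Optional[DriftProfile] = None,
    s: Optional[np.ndarray] = None,
    t: Optional[np.ndarray] = None,
    seed: Optional[int] = None,
) -> tuple[CurvatureField, GroundTruthRecord]:
    """Two-harmonic curvature kymograph, optionally with drift and noise.

    With no drift and zero noise the field equals the closed form
    exactly at the grid nodes.  Records shorter than two beat periods
    are refused: the windowed harmonic analysis is undefined there.
    """
    if s is None or t is None:
        sd_, td_ = default_grid()
        s = sd_ if s is None else np.asarray(s, float)
        t = td_ if t is None else np.asarray(t, float)
    s = np.asarray(s, float)
    t = np.asarray(t, float)
    if t[-1] - t[0] < 2.0 * spec.period:
        raise ValueError("time grid must span at least two beat periods")
    if np.any(np.diff(s) <= 0) or np.any(np.diff(t) <= 0):
        raise ValueError("grids must be strictly increasing")

    rng = np.random.default_rng(seed)
    if drift is None:
        drift = DriftProfile.none(spec)
    c2_t = np.clip(np.asarray(drift.c2_of_t(t), float), 0.0, None)
    phi_t = np.asarray(drift.phi_of_t(t), float)
    C_true = _closed_form(spec, s, t, c2_t, phi_t)
    C = C_true.copy()
    if drift.noise_sd > 0:
        C = C + rng.normal(0.0, drift.noise_sd, C.shape)
    record = GroundTruthRecord(
        spec=spec,
        s=s,
        t=t,
        C_true=C_true,
        C2_t=c2_t,
        phi_t=phi_t,
        noise_sd=drift.noise_sd,
        seed=seed,
    )
    return CurvatureField(C=C, s=s, t=t), record


def integrate_shape(
    C,
    s: Optional[np.ndarray] = None,
    pivot=(0.0, 0.0),
    theta0: float = 0.0,
    head_offset: float = 0.0,
) -> np.ndarray:
    """Reconstruct midline points from curvature by tangent-angle quadrature.

    θ(s) = θ0 + ∫₀ˢ C ds′ and positions follow by trapezoid quadrature of
    (cos θ, sin θ).  ``head_offset`` places the first point that far from
    the pivot along the θ0 direction (head of length > 0).  Accepts a
    :class:`CurvatureField` or an (n_s, n_t) array with an explicit
    ``s`` grid.  Returns points with shape (n_t, n_s, 2) in µm.
    """
    if isinstance(C, CurvatureField):
        s = C.s
        Cm = C.C
    else:
        Cm = np.atleast_2d(np.asarray(C, float))
        if s is None:
            raise ValueError("s grid required when C is a bare array")
        s = np.asarray(s, float)
    if not np.all(np.isfinite(Cm)):
        raise ValueError("NaN or infinite curvature")
    ds = np.diff(s)
    if np.any(np.abs(Cm[:-1, :]) * ds[:, None] >= 0.5 * np.pi):
        raise ValueError("curvature step |C|*ds exceeds pi/2; grid too coarse")

    theta = theta0 + np.vstack(
        [np.zeros(Cm.shape[1]), cumulative_trapezoid(Cm, s, axis=0)]
    )  # (n_s, n_t)
    cx = np.cos(theta)
    cy = np.sin(theta)
    x = cumulative_trapezoid(cx, s, axis=0, initial=0.0)
    y = cumulative_trapezoid(cy, s, axis=0, initial=0.0)
    base = np.asarray(pivot, float) + head_offset * np.array(
        [np.cos(theta0), np.sin(theta0)]
    )
    pts = np.stack([x + base[0], y + base[1]], axis=-1)  # (n_s, n_t, 2)
    return np.transpose(pts, (1, 0, 2))


def gen_rotating_cell(
    spec: WaveformSpec,
    drift: Optional[DriftProfile] = None,
    omega_of_t: Optional[Callable[[np.ndarray], np.ndarray]] = None,
    s: Optional[np.ndarray] = None,
    t: Optional[np.ndarray] = None,
    seed: Optional[int] = None,
    head_offset: float = 4.0,
    tracking_noise_sd: float = 0.0,
    tail_dropout: int = 0,
    wobble: float = 0.05,
) -> tuple[TrackedFlagellum, GroundTruthRecord]:
    """Tethered beating cell: the waveform of :func:`gen_curvature_wave`
    rotated rigidly about the pivot by 2π∫Ω dt.

    ``omega_of_t`` gives the rotation velocity in revolutions/s (positive
    counter-clockwise); ``tail_dropout`` emulates frame-to-frame tracking
    length variation by truncating 0..tail_dropout tail points uniformly
    at random (the common-window rule then applies downstream).
    ``wobble`` adds a beat-frequency rigid oscillation of the body frame
    (rad amplitude) — the fast recoil that the 1-s Gaussian filter of the
    rotation-velocity estimator must suppress.
    """
    field, record = gen_curvature_wave(spec, drift=drift, s=s, t=t, seed=seed)
    t = field.t
    rng = np.random.default_rng(None if seed is None else seed + 1)
    if omega_of_t is None:
        omega = np.zeros_like(t)
    else:
        omega = np.asarray(omega_of_t(t), float)
    if np.max(np.abs(omega)) > 1.0:
        raise ValueError("|Omega| above 1 rev/s violates the filtering assumptions")

    pts_body = integrate_shape(field, pivot=(0.0, 0.0), head_offset=head_offset)
    beta = 2.0 * np.pi * cumulative_trapezoid(omega, t, initial=0.0)  # rad
    beta_total = beta + wobble * np.sin(spec.omega0 * t)
    cb, sb = np.cos(beta_total), np.sin(beta_total)
    x, y = pts_body[..., 0], pts_body[..., 1]
    pts_lab = np.stack(
        [cb[:, None] * x - sb[:, None] * y, sb[:, None] * x + cb[:, None] * y],
        axis=-1,
    )
    record = dataclasses.replace(
        record, omega_t=omega, rotation_angle=beta, points_true=pts_lab
    )
    pts = pts_lab
    if tracking_noise_sd > 0:
        pts = pts + rng.normal(0.0, tracking_noise_sd, pts.shape)
    n_pts = pts.shape[1]
    if tail_dropout > 0:
        drops = rng.integers(0, tail_dropout + 1, size=pts.shape[0])
        n_common = n_pts - int(drops.max())
        pts = pts[:, :n_common, :]
    tracks = TrackedFlagellum(
        points=pts, times=t, ds=float(np.mean(np.diff(field.s))), pivot=np.zeros(2)
    )
    return tracks, record


def gen_random_curvature(
    sigma: float,
    s: np.ndarray,
    t: np.ndarray,
    seed: Optional[int] = None,
) -> CurvatureField:
    """δ-correlated random curvature C_ran = η(s,t)·σ, the null model for
    the mode-significance test."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = np.random.default_rng(seed)
    s = np.asarray(s, float)
    t = np.asarray(t, float)
    C = rng.normal(0.0, sigma, size=(s.size, t.size))
    return CurvatureField(C=C, s=s, t=t)


# ---------------------------------------------------------------------------
# rendering


@dataclass
class Optics:
    """Rendering parameters for synthetic dark-field-like frames."""

    pixel_size: float = 0.2  # µm/px
    psf_sigma: float = 0.45  # Gaussian line-spread SD, µm
    head_axes: tuple[float, float] = (2.5, 1.5)  # semi-axes, µm
    filament_peak: float = 12000.0  # counts above background
    head_peak: float = 30000.0
    background: float = 900.0
    noise_sd: float = 120.0  # additive Gaussian counts
    shape: tuple[int, int] = (512, 512)  # rows, cols


@dataclass
class SyntheticScene:
    """Rendered image stack plus its full ground truth."""

    images: np.ndarray  # (n_frames, H, W) uint16
    pixel_size: float  # µm/px
    dt: float  # frame interval, s
    tracks: TrackedFlagellum  # true midline points (µm)
    record: GroundTruthRecord
    optics: Optics
    head_center: np.ndarray  # (2,) µm
    head_orientation: np.ndarray  # per frame, rad

    @property
    def n_frames(self) -> int:
        return self.images.shape[0]


def _um_to_px(xy, pixel_size, n_rows):
    """µm (x right, y up) -> (row, col) with pixel centers at half-integers."""
    col = xy[..., 0] / pixel_size - 0.5
    row = (n_rows - 1) - (xy[..., 1] / pixel_size - 0.5)
    return row, col


def px_to_um(row, col, pixel_size, n_rows):
    """Inverse of the rendering coordinate convention."""
    x = (col + 0.5) * pixel_size
    y = ((n_rows - 1) - row + 0.5) * pixel_size
    return x, y


def _splat_gaussian_line(img, row, col, sigma_px, amplitude):
    """Accumulate a Gaussian ridge along densely sampled (row, col) points."""
    H, W = img.shape
    half = int(np.ceil(4 * sigma_px))
    for r, c in zip(row, col):
        r0 = int(np.floor(r)) - half
        c0 = int(np.floor(c)) - half
        r1, c1 = r0 + 2 * half + 1, c0 + 2 * half + 1
        r0c, c0c = max(r0, 0), max(c0, 0)
        r1c, c1c = min(r1, H), min(c1, W)
        if r0c >= r1c or c0c >= c1c:
            continue
        rr = np.arange(r0c, r1c)[:, None] - r
        cc = np.arange(c0c, c1c)[None, :] - c
        img[r0c:r1c, c0c:c1c] += amplitude * np.exp(
            -(rr**2 + cc**2) / (2.0 * sigma_px**2)
        )


def render_frames(
    tracks: TrackedFlagellum,
    record: GroundTruthRecord,
    optics: Optional[Optics] = None,
    seed: Optional[int] = None,
    head_center=(0.0, 0.0),
    center_in_fov: bool = True,
) -> SyntheticScene:
    """Render a bright filament ridge plus head blob on a dark background.

    The midline intensity ridge of each frame peaks within half a pixel
    of the true points (Gaussian line-spread splatting at 0.25·σ sample
    spacing).  The head is an anisotropic Gaussian blob whose long axis
    follows the proximal tangent of the flagellum.
    """
    optics = optics or Optics()
    rng = np.random.default_rng(seed)
    H, W = optics.shape
    px = optics.pixel_size
    ds = tracks.ds
    if ds < px:
        import warnings

        warnings.warn("pixel size coarser than the point spacing Δs", stacklevel=2)

    pts = tracks.points
    offset = np.zeros(2)
    if center_in_fov:
        fov_center = np.array([W * px / 2.0, H * px / 2.0])
        offset = fov_center - np.asarray(head_center, float)
        pts = pts + offset
    head_c = np.asarray(head_center, float) + offset

    sigma_px = optics.psf_sigma / px
    sub = max(1, int(np.ceil(ds / (0.25 * optics.psf_sigma))))
    n_frames = pts.shape[0]
    images = np.empty((n_frames, H, W), dtype=np.uint16)
    head_orient = np.empty(n_frames)
    a_px = optics.head_axes[0] / px
    b_px = optics.head_axes[1] / px
    rows_g = np.arange(H)[:, None]
    cols_g = np.arange(W)[None, :]

    for f in range(n_frames):
        img = np.zeros((H, W), dtype=float)
        p = pts[f]
        # dense resampling along the polyline for ridge splatting
        seglen = np.linalg.norm(np.diff(p, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seglen)])
        s_fine = np.linspace(0.0, cum[-1], sub * (p.shape[0] - 1) + 1)
        xf = np.interp(s_fine, cum, p[:, 0])
        yf = np.interp(s_fine, cum, p[:, 1])
        row, col = _um_to_px(np.stack([xf, yf], -1), px, H)
        _splat_gaussian_line(img, row, col, sigma_px, 1.0)
        peak = img.max()
        if peak > 0:
            img *= optics.filament_peak / peak

        # head blob oriented along the proximal tangent
        tangent = p[1] - p[0]
        phi_h = float(np.arctan2(tangent[1], tangent[0]))
        head_orient[f] = phi_h
        hr, hc = _um_to_px(head_c, px, H)
        # image rows run downward: a +φ (ccw in µm frame) is -φ in row/col
        cphi, sphi = np.cos(-phi_h), np.sin(-phi_h)
        dr = rows_g - hr
        dc = cols_g - hc
        u = cphi * dc + sphi * dr
        v = -sphi * dc + cphi * dr
        img += optics.head_peak * np.exp(
            -0.5 * ((u / a_px) ** 2 + (v / b_px) ** 2)
        )

        img += optics.background
        if optics.noise_sd > 0:
            img += rng.normal(0.0, optics.noise_sd, img.shape)
        images[f] = np.clip(img, 0, 65535).astype(np.uint16)

    shifted = TrackedFlagellum(
        points=pts, times=tracks.times, ds=tracks.ds,
        pivot=None if tracks.pivot is None else tracks.pivot + offset,
    )
    return SyntheticScene(
        images=images,
        pixel_size=px,
        dt=tracks.dt,
        tracks=shifted,
        record=record,
        optics=optics,
        head_center=head_c,
        head_orientation=head_orient,
    )
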