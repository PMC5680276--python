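"""Shared containers for the flagellar-beat analysis pipeline.

Package-wide unit conventions: lengths in µm, times in s, curvature in
µm⁻¹, reported frequencies and rotation velocities in Hz (revolutions/s);
angular quantities are kept in radians internally.  Torques are in
fN·µm (= 10⁻³ nN·µm) and drag coefficients per unit length in
fN·s·µm⁻².  The curvature sign convention is positive for
counter-clockwise bends in a right-handed frame (x rightward, y upward).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "CurvatureField",
    "TrackedFlagellum",
    "wrap_angle",
]


def wrap_angle(phi):
    """Wrap angle(s) to the interval (−π, π]."""
    phi = np.asarray(phi, dtype=float)
    wrapped = -((-phi + np.pi) % (2.0 * np.pi) - np.pi)
    return wrapped if wrapped.ndim else float(wrapped)


@dataclass
class CurvatureField:
    """Curvature kymograph C(s, t) on a fixed arclength/time grid.

    Attributes
    ----------
    C : ndarray, shape (n_s, n_t)
        Signed curvature in µm⁻¹; positive for counter-clockwise bends.
    s : ndarray, shape (n_s,)
        Arclength grid in µm, measured from the first tracking point.
    t : ndarray, shape (n_t,)
        Time grid in s.
    """

    C: np.ndarray
    s: np.ndarray
    t: np.ndarray
    sign_convention: str = "ccw_positive"

    def __post_init__(self):
        self.C = np.asarray(self.C, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        if self.C.shape != (self.s.size, self.t.size):
            raise ValueError(
                f"C has shape {self.C.shape}, expected ({self.s.size}, {self.t.size})"
            )

    @property
    def ds(self) -> float:
        return float(np.mean(np.diff(self.s)))

    @property
    def dt(self) -> float:
        return float(np.mean(np.diff(self.t)))

    @property
    def frame_rate(self) -> float:
        return 1.0 / self.dt

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def row(self, s0: float) -> tuple[float, np.ndarray]:
        """Return (actual arclength, curvature time series) at the grid
        point nearest to ``s0``."""
        i = int(np.argmin(np.abs(self.s - s0)))
        return float(self.s[i]), self.C[i]

    def total_variance(self) -> float:
        """Mean squared curvature over the whole field — the scalar
        variance used to scale the random-curvature significance null."""
        return float(np.mean(self.C**2))


@dataclass
class TrackedFlagellum:
    """Ordered flagellar midline points per frame, resampled at Δs.

    ``points`` is (n_frames, n_points, 2) in µm, ordered head → tip over
    the arclength window tracked in all frames.  ``pivot`` is the head
    tethering point (shared for a tethered recording).
    """

    points: np.ndarray
    times: np.ndarray
    ds: float
    pivot: Optional[np.ndarray] = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.points.ndim != 3 or self.points.shape[2] != 2:
            raise ValueError("points must have shape (n_frames, n_points, 2)")
        if self.points.shape[0] != self.times.size:
            raise ValueError("times length must match number of frames")
        if self.pivot is not None:
            self.pivot = np.asarray(self.pivot, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.points.shape[0]

    @property
    def n_points(self) -> int:
        return self.points.shape[1]

    @property
    def dt(self) -> float:
        return float(np.mean(np.diff(self.times)))

    @property
    def arclength(self) -> np.ndarray:
        """Nominal arclength grid (µm) from the first tracked point."""
        return self.ds * np.arange(self.n_points)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns frame, time_s, point_index, x_um, y_um."""
        nf, npts, _ = self.points.shape
        frame = np.repeat(np.arange(nf), npts)
        return pd.DataFrame(
            {
                "frame": frame,
                "time_s": np.repeat(self.times, npts),
                "point_index": np.tile(np.arange(npts), nf),
                "x_um": self.points[:, :, 0].ravel(),
                "y_um": self.points[:, :, 1].ravel(),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, ds: float, pivot=None) -> "TrackedFlagellum":
        nf = df["frame"].nunique()
        counts = df.groupby("frame")["point_index"].size().unique()
        if counts.size != 1:
            raise ValueError("frames have unequal point counts; resample first")
        npts = int(counts[0])
        dfs = df.sort_values(["frame", "point_index"])
        pts = np.column_stack([dfs["x_um"], dfs["y_um"]]).reshape(nf, npts, 2)
        times = dfs.groupby("frame")["time_s"].first().to_numpy()
        return cls(points=pts, times=times, ds=ds, pivot=pivot)
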