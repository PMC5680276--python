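"""File formats: curvature fields and tracks in HDF5/CSV, scenes as TIFF.

Tracked points use the long-format table (frame, time_s, point_index,
x_um, y_um) in CSV or an HDF5 group, so synthetic and image-derived
tracks are interchangeable downstream.  Image stacks are multi-page
16-bit TIFF with a JSON sidecar holding pixel size and frame interval.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import CurvatureField, TrackedFlagellum

__all__ = [
    "save_curvature_h5",
    "load_curvature_h5",
    "save_curvature_csv",
    "save_tracks",
    "load_tracks",
    "save_scene_tiff",
    "load_scene_tiff",
]


def save_curvature_h5(field: CurvatureField, path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("C", data=field.C)
        d.attrs["sign_convention"] = field.sign_convention
        f.create_dataset("s", data=field.s)
        f.create_dataset("t", data=field.t)


def load_curvature_h5(path) -> CurvatureField:
    with h5py.File(path, "r") as f:
        return CurvatureField(
            C=f["C"][...],
            s=f["s"][...],
            t=f["t"][...],
            sign_convention=f["C"].attrs.get("sign_convention", "ccw_positive"),
        )


def save_curvature_csv(field: CurvatureField, path) -> None:
    """Small fields only: long format (s_um, time_s, curvature)."""
    s = np.repeat(field.s, field.t.size)
    t = np.tile(field.t, field.s.size)
    pd.DataFrame(
        {"s_um": s, "time_s": t, "curvature": field.C.ravel()}
    ).to_csv(path, index=False)


def save_tracks(tracks: TrackedFlagellum, path) -> None:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("points", data=tracks.points)
            f.create_dataset("times", data=tracks.times)
            f.attrs["ds"] = tracks.ds
            if tracks.pivot is not None:
                f.create_dataset("pivot", data=tracks.pivot)
    else:
        tracks.to_frame().to_csv(path, index=False)


def load_tracks(path, ds: float | None = None) -> TrackedFlagellum:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            pivot = f["pivot"][...] if "pivot" in f else None
            return TrackedFlagellum(
                points=f["points"][...],
                times=f["times"][...],
                ds=float(f.attrs["ds"]),
                pivot=pivot,
            )
    if ds is None:
        raise ValueError("ds required when loading from CSV")
    return TrackedFlagellum.from_frame(pd.read_csv(path), ds=ds)


def save_scene_tiff(scene, path) -> None:
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, scene.images)
    meta = {
        "pixel_size_um": scene.pixel_size,
        "frame_interval_s": scene.dt,
        "n_frames": int(scene.n_frames),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_scene_tiff(path):
    """Returns (images, metadata dict) from a TIFF + JSON sidecar."""
    import tifffile

    path = Path(path)
    images = tifffile.imread(path)
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return images, meta
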