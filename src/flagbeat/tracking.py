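"""Flagellum tracking on dark-field-like image stacks.

Per frame: the image is binarized by iteratively lowering an intensity
threshold until the foreground area and coarse skeleton length reach
their expected values; the head is located by fitting an ellipse to the
compact bright blob; the flagellar midline is the pruned skeleton path
ordered from the head-adjacent endpoint, refined to sub-pixel accuracy
by intensity-weighted centroids across the local normal, and resampled
at Δs.  Only the arclength window tracked in every frame is kept.

Image coordinate convention: origin at the top-left pixel, x rightward
and y upward after conversion to µm (so counter-clockwise bends are
positive), pixel centers at half-integer µm positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import map_coordinates
from skimage import measure, morphology

from .core import TrackedFlagellum

__all__ = [
    "TrackingError",
    "HeadPose",
    "TrackConfig",
    "binarize_adaptive",
    "fit_head_ellipse",
    "skeletonize_and_order",
    "track_movie",
]


class TrackingError(RuntimeError):
    """Raised when a frame cannot be tracked (message says why)."""


@dataclass
class HeadPose:
    """Fitted head ellipse; the tethering point defaults to its center."""

    center: np.ndarray  # (x, y) µm
    semi_axes: tuple[float, float]  # (major, minor) µm
    orientation: float  # rad, ccw from +x
    tether: np.ndarray  # (x, y) µm
    degenerate: bool = False  # circle: orientation undefined


@dataclass
class TrackConfig:
    """Tracking parameters (µm unless noted)."""

    pixel_size: float = 0.2
    ds: float = 0.9
    expected_area: float = 120.0  # cell area, µm²
    coarse_length: float = 35.0  # expected flagellar length
    area_tol: float = 0.15
    threshold_decrement: float = 0.98
    start_percentile: float = 99.5
    prune_length: float = 2.0  # skeleton spur pruning
    min_head_area: float = 3.0  # µm²
    normal_halfwidth: int = 2  # px, sub-pixel refinement window
    smooth_window: int = 7  # points, Savitzky-Golay along arclength
    max_failed_frames: float = 0.05
    # the skeleton's head-adjacent endpoint jitters with the beat, which
    # would let the arclength origin slide along the filament and alias
    # beat-frequency motion into the second-harmonic band; the origin is
    # therefore re-anchored where the path first reaches this distance
    # from the (stable) head centre
    origin_radius: float = 7.0  # µm


def _px_to_um(rows, cols, pixel_size, n_rows):
    x = (np.asarray(cols) + 0.5) * pixel_size
    y = (n_rows - 1 - np.asarray(rows) + 0.5) * pixel_size
    return x, y


def binarize_adaptive(
    frame: np.ndarray,
    config: TrackConfig,
) -> np.ndarray:
    """Binarize by descending threshold until area and skeleton length
    reach their expected values.

    Starting at the ``start_percentile`` intensity, the threshold is
    multiplied by ``threshold_decrement`` until the foreground area is
    within tolerance of ``expected_area`` AND the skeleton is at least
    (1 − tol)·``coarse_length`` long.  Raises "target area unreachable"
    when the area overshoots or the threshold bottoms out first.
    """
    frame = np.asarray(frame, dtype=float)
    px_area = config.pixel_size**2
    if not (0 < config.expected_area < frame.size * px_area):
        raise ValueError("expected area outside (0, frame area)")
    thr = np.percentile(frame, config.start_percentile)
    floor = frame.min()
    if thr <= floor:
        raise TrackingError("target area unreachable")
    lo_area = (1.0 - config.area_tol) * config.expected_area
    hi_area = (1.0 + config.area_tol) * config.expected_area
    lo_len = (1.0 - config.area_tol) * config.coarse_length
    while thr > floor:
        mask = frame >= thr
        area = mask.sum() * px_area
        if area >= lo_area:
            if area > hi_area:
                break
            skel = morphology.skeletonize(mask)
            if skel.sum() * config.pixel_size >= lo_len:
                return mask
        thr *= config.threshold_decrement
    raise TrackingError("target area unreachable")


def fit_head_ellipse(
    mask: np.ndarray,
    config: TrackConfig,
) -> HeadPose:
    """Least-squares ellipse of the compact head blob.

    The thin flagellum is removed by a morphological opening with a
    ~1 µm disk; the largest remaining component is the head.  A circle
    (axis ratio within 5%) has no defined orientation: it is reported
    as 0 with the degenerate flag set.
    """
    px = config.pixel_size
    radius = max(2, int(round(1.0 / px)))
    blob = morphology.opening(mask, morphology.disk(radius))
    lab = measure.label(blob)
    if lab.max() == 0:
        raise TrackingError("no head")
    props = max(measure.regionprops(lab), key=lambda p: p.area)
    if props.area * px**2 < config.min_head_area:
        raise TrackingError("no head")
    r0, c0 = props.centroid
    x, y = _px_to_um(r0, c0, px, mask.shape[0])
    a = props.axis_major_length / 2.0 * px
    b = props.axis_minor_length / 2.0 * px
    # regionprops orientation: angle of major axis from the row axis,
    # ccw in (row, col); convert to ccw-from-+x in the y-up µm frame
    orient = float(np.mod(props.orientation + np.pi / 2.0, np.pi))
    degenerate = b > 0 and (a - b) / a < 0.05
    if degenerate:
        orient = 0.0
    center = np.array([float(x), float(y)])
    return HeadPose(
        center=center, semi_axes=(float(a), float(b)),
        orientation=orient, tether=center.copy(), degenerate=degenerate,
    )


def _neighbors(idx_set, p):
    r, c = p
    out = []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            q = (r + dr, c + dc)
            if q in idx_set:
                out.append(q)
    return out


def _prune_spurs(pixels: set, min_keep: int) -> set:
    """Iteratively remove endpoint branches shorter than ``min_keep``."""
    px = set(pixels)
    changed = True
    while changed:
        changed = False
        endpoints = [p for p in px if len(_neighbors(px, p)) == 1]
        for e in endpoints:
            # walk from the endpoint to the next junction
            branch = [e]
            prev = None
            cur = e
            while True:
                nbrs = [n for n in _neighbors(px, cur) if n != prev]
                if len(nbrs) != 1:
                    break
                nxt = nbrs[0]
                if len(_neighbors(px, nxt)) > 2:
                    break
                branch.append(nxt)
                prev, cur = cur, nxt
                if len(branch) > min_keep:
                    break
            if len(branch) <= min_keep and len(_neighbors(px, branch[-1])) != 1:
                for b in branch[:-1] if len(branch) > 1 else branch:
                    px.discard(b)
                changed = True
    return px


def skeletonize_and_order(
    mask: np.ndarray,
    head: HeadPose,
    config: TrackConfig,
) -> np.ndarray:
    """Skeletonize the mask and return the flagellar path as ordered
    (row, col) pixels starting at the head-adjacent endpoint.

    Skeleton pixels inside the head ellipse are discarded; spurs
    shorter than ``prune_length`` are pruned.  A skeleton that remains
    branched is topologically ambiguous; an empty one means no
    flagellum.
    """
    px = config.pixel_size
    skel = morphology.skeletonize(mask)
    rows, cols = np.nonzero(skel)
    if rows.size == 0:
        raise TrackingError("no flagellum")
    x, y = _px_to_um(rows, cols, px, mask.shape[0])
    # discard pixels inside the (slightly inflated) head ellipse
    ca, sa = np.cos(head.orientation), np.sin(head.orientation)
    dx, dy = x - head.center[0], y - head.center[1]
    u = ca * dx + sa * dy
    v = -sa * dx + ca * dy
    a, b = head.semi_axes
    inside = (u / (1.15 * a)) ** 2 + (v / (1.15 * b)) ** 2 <= 1.0
    pts = set(zip(rows[~inside].tolist(), cols[~inside].tolist()))
    if not pts:
        raise TrackingError("no flagellum")

    # keep the connected component nearest the head
    comps = []
    remaining = set(pts)
    while remaining:
        seed = next(iter(remaining))
        comp = {seed}
        stack = [seed]
        while stack:
            cur = stack.pop()
            for n in _neighbors(remaining, cur):
                if n not in comp:
                    comp.add(n)
                    stack.append(n)
        comps.append(comp)
        remaining -= comp
    hx, hy = head.center

    def comp_dist(comp):
        rr = np.array([p[0] for p in comp])
        cc = np.array([p[1] for p in comp])
        cx, cy = _px_to_um(rr, cc, px, mask.shape[0])
        return np.min((cx - hx) ** 2 + (cy - hy) ** 2)

    comp = max(
        (c for c in comps if len(c) * px >= 0.3 * config.coarse_length),
        key=len,
        default=None,
    )
    if comp is None:
        comp = min(comps, key=comp_dist)
    if len(comp) * px < 3.0:
        raise TrackingError("no flagellum")

    min_keep = max(2, int(round(config.prune_length / px)))
    comp = _prune_spurs(comp, min_keep)
    if not comp:
        raise TrackingError("no flagellum")
    endpoints = [p for p in comp if len(_neighbors(comp, p)) == 1]
    if len(endpoints) != 2:
        raise TrackingError("ambiguous topology")

    def pt_dist(p):
        xx, yy = _px_to_um(p[0], p[1], px, mask.shape[0])
        return (xx - hx) ** 2 + (yy - hy) ** 2

    start = min(endpoints, key=pt_dist)
    path = [start]
    prev = None
    cur = start
    while True:
        nbrs = [n for n in _neighbors(comp, cur) if n != prev]
        if not nbrs:
            break
        if len(nbrs) > 1:
            raise TrackingError("ambiguous topology")
        prev, cur = cur, nbrs[0]
        path.append(cur)
    return np.array(path, dtype=float)


def _refine_subpixel(frame, path_px, halfwidth):
    """Shift each path pixel to the intensity-weighted centroid along
    the local normal (window ±halfwidth px, bilinear sampling)."""
    p = path_px
    tang = np.gradient(p, axis=0)
    tang /= np.maximum(np.linalg.norm(tang, axis=1, keepdims=True), 1e-12)
    normal = np.column_stack([-tang[:, 1], tang[:, 0]])
    offsets = np.arange(-halfwidth, halfwidth + 1, 0.5)
    sample_r = p[:, 0:1] + offsets[None, :] * normal[:, 0:1]
    sample_c = p[:, 1:2] + offsets[None, :] * normal[:, 1:2]
    vals = map_coordinates(
        frame.astype(float), [sample_r.ravel(), sample_c.ravel()],
        order=1, mode="nearest",
    ).reshape(sample_r.shape)
    vals = vals - vals.min(axis=1, keepdims=True)
    wsum = vals.sum(axis=1)
    good = wsum > 0
    shift = np.zeros(p.shape[0])
    shift[good] = (vals[good] * offsets[None, :]).sum(axis=1) / wsum[good]
    return p + shift[:, None] * normal


def _anchor_origin(pts: np.ndarray, head_center, radius: float) -> np.ndarray:
    """Trim the path to start exactly where it first crosses the circle
    of ``radius`` around the head center (linear interpolation between
    the bracketing points).  Falls back to the raw start when the whole
    path lies outside already."""
    d = np.linalg.norm(pts - np.asarray(head_center)[None, :], axis=1)
    inside = d < radius
    if not inside[0]:
        return pts
    crossings = np.flatnonzero(inside[:-1] & ~inside[1:])
    if crossings.size == 0:
        return pts
    i = int(crossings[0])
    f = (radius - d[i]) / (d[i + 1] - d[i])
    start = pts[i] + f * (pts[i + 1] - pts[i])
    return np.vstack([start, pts[i + 1:]])


def _resample_polyline(points_um: np.ndarray, ds: float) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points_um, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    n = int(np.floor(cum[-1] / ds)) + 1
    s_new = ds * np.arange(n)
    return np.column_stack(
        [np.interp(s_new, cum, points_um[:, i]) for i in (0, 1)]
    )


def track_frame(frame: np.ndarray, config: TrackConfig):
    """Track one frame: returns (points µm at Δs spacing, HeadPose)."""
    from scipy.signal import savgol_filter

    mask = binarize_adaptive(frame, config)
    head = fit_head_ellipse(mask, config)
    path_px = skeletonize_and_order(mask, head, config)
    path_px = _refine_subpixel(frame, path_px, config.normal_halfwidth)
    x, y = _px_to_um(path_px[:, 0], path_px[:, 1], config.pixel_size,
                     frame.shape[0])
    pts = np.column_stack([x, y])
    pts = _anchor_origin(pts, head.center, config.origin_radius)
    pts = _resample_polyline(pts, config.ds)
    w = config.smooth_window
    if w >= 5 and pts.shape[0] > w:
        pts = savgol_filter(pts, w, 2, axis=0)
    return pts, head


def track_movie(
    scene,
    config: Optional[TrackConfig] = None,
) -> TrackedFlagellum:
    """Track a full stack and apply the common-arclength-window rule.

    ``scene`` may be a :class:`flagbeat.synthetic.SyntheticScene` or an
    (n_frames, H, W) array (then ``config`` must carry the pixel size
    and a ``dt`` attribute is taken as 1/500 s).  Frames are tracked
    independently, resampled to Δs, and truncated to the arclength
    window tracked in all frames; arclength is measured from the first
    tracking point.  Aborts when more than ``max_failed_frames`` of the
    frames fail, with per-frame diagnostics.
    """
    config = config or TrackConfig()
    if hasattr(scene, "images"):
        frames = scene.images
        dt = scene.dt
        config.pixel_size = scene.pixel_size
    else:
        frames = np.asarray(scene)
        dt = 1.0 / 500.0
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need a stack of at least 2 frames")

    all_pts = []
    heads = []
    failures = []
    for i, frame in enumerate(frames):
        try:
            pts, head = track_frame(frame, config)
            all_pts.append(pts)
            heads.append(head)
        except TrackingError as exc:
            failures.append((i, str(exc)))
            all_pts.append(None)
    if len(failures) > config.max_failed_frames * frames.shape[0]:
        detail = "; ".join(f"frame {i}: {msg}" for i, msg in failures[:10])
        raise TrackingError(
            f"{len(failures)}/{frames.shape[0]} frames failed: {detail}"
        )
    ok = [p for p in all_pts if p is not None]
    n_common = min(p.shape[0] for p in ok)
    # fill failed frames by nearest tracked neighbour
    filled = []
    last = None
    for p in all_pts:
        if p is not None:
            last = p
        filled.append(last)
    for j in range(len(filled)):
        if filled[j] is None:
            filled[j] = next(p for p in filled if p is not None)
    points = np.stack([p[:n_common] for p in filled])
    times = dt * np.arange(frames.shape[0])
    tether = np.mean([h.tether for h in heads], axis=0)
    return TrackedFlagellum(
        points=points, times=times, ds=config.ds, pivot=tether
    )
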