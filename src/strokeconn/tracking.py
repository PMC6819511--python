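"""Deterministic FACT streamline tracking on principal-direction volumes.

FACT (fiber assignment by continuous tracking) advances a streamline by a
fixed step along the principal diffusion direction of the *current* voxel —
nearest-voxel lookup, no interpolation, which is the defining property of
the method.  Tracking stops on leaving the volume, entering a voxel whose
FA falls below a stopping threshold, or turning more sharply than the
configured angle (45 degrees by convention) between consecutive steps.

Coordinates are voxel-indexed and 0-based with each point at a voxel
center; a point ``p`` lies in voxel ``round(p)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import interp1d, splev, splprep

logger = logging.getLogger(__name__)


@dataclass
class TrackingVolume:
    """Principal-direction field + FA scalar + ROI label map on one grid."""

    directions: np.ndarray   # (nx, ny, nz, 3) unit vectors where FA >= threshold
    fa: np.ndarray           # (nx, ny, nz) in [0, 1]
    labels: np.ndarray       # (nx, ny, nz) non-negative ints, 0 = unlabeled

    def __post_init__(self) -> None:
        if self.directions.shape[:3] != self.fa.shape or self.fa.shape != self.labels.shape:
            raise ValueError("directions, fa and labels must share one grid")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.fa.shape


@dataclass
class TrackingConfig:
    fa_stop_threshold: float = 0.15
    angle_stop_deg: float = 45.0
    step_size: float = 0.5        # voxels
    min_length: float = 2.0       # voxel units
    max_length: float = 1000.0
    seeds_per_voxel: int = 1

    def __post_init__(self) -> None:
        if not (0 < self.step_size <= 1):
            raise ValueError("step_size must be in (0, 1]")
        if not (0 < self.angle_stop_deg < 90):
            raise ValueError("angle_stop_deg must be in (0, 90)")
        if self.seeds_per_voxel < 1:
            raise ValueError("seeds_per_voxel must be positive")


@dataclass
class Streamline:
    """A tracked fiber: ordered 3D points plus summary attributes.

    ``length`` is always the sum of Euclidean segment lengths of ``points``;
    ``mean_fa`` is the average FA sampled at the voxels the points fall in.
    """

    points: np.ndarray                       # (n, 3), n >= 2
    mean_fa: float = 0.0
    endpoint_labels: tuple[int, int] | None = None
    excluded: bool = False
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) < 2:
            raise ValueError("a streamline needs >= 2 three-dimensional points")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


def _voxel_of(point: np.ndarray) -> np.ndarray:
    return np.round(point).astype(int)


def _in_grid(vox: np.ndarray, dims: tuple[int, int, int]) -> bool:
    return bool(np.all(vox >= 0) and np.all(vox < dims))


def _trace_one_direction(
    volume: TrackingVolume,
    start: np.ndarray,
    initial_dir: np.ndarray,
    config: TrackingConfig,
) -> list[np.ndarray]:
    """March from ``start`` along the field; returns points after the start."""
    dims = volume.dims
    cos_limit = np.cos(np.deg2rad(config.angle_stop_deg))
    pts: list[np.ndarray] = []
    point = start.copy()
    prev_step = np.asarray(initial_dir, dtype=float)
    traveled = 0.0
    max_iters = int(np.ceil(config.max_length / config.step_size)) + 1
    for _ in range(max_iters):
        vox = _voxel_of(point)
        d = volume.directions[tuple(vox)].astype(float)
        nrm = np.linalg.norm(d)
        if abs(nrm - 1.0) > 1e-6:
            raise ValueError(
                f"non-unit principal direction (|d|={nrm:.6g}) in voxel "
                f"{tuple(int(v) for v in vox)}"
            )
        if d @ prev_step < 0:      # sign-align with the travel direction
            d = -d
        if d @ prev_step < cos_limit:
            break                  # turning sharper than the angle threshold
        nxt = point + config.step_size * d
        nvox = _voxel_of(nxt)
        if not _in_grid(nvox, dims) or volume.fa[tuple(nvox)] < config.fa_stop_threshold:
            break
        pts.append(nxt)
        traveled += config.step_size
        if traveled >= config.max_length:
            break
        prev_step = d
        point = nxt
    return pts


def _seed_points(volume: TrackingVolume, config: TrackingConfig) -> np.ndarray:
    mask = volume.fa >= config.fa_stop_threshold
    centers = np.argwhere(mask).astype(float)
    if config.seeds_per_voxel == 1:
        return centers
    # deterministic sub-voxel offsets along the main diagonal
    offs = (np.arange(config.seeds_per_voxel) + 0.5) / config.seeds_per_voxel - 0.5
    seeds = [centers + o * 0.9 for o in offs]
    return np.concatenate(seeds, axis=0)


def fact_track(volume: TrackingVolume, config: TrackingConfig | None = None) -> list[Streamline]:
    """Whole-volume deterministic FACT tracking.

    One seed per voxel with FA at or above the stopping threshold (more if
    ``seeds_per_voxel`` > 1), traced bidirectionally; streamlines shorter
    than ``min_length`` are discarded.  Output order follows the fixed
    lexicographic seed order, so the result is fully deterministic.
    """
    config = config or TrackingConfig()
    streamlines: list[Streamline] = []
    for seed in _seed_points(volume, config):
        svox = _voxel_of(seed)
        d0 = volume.directions[tuple(svox)].astype(float)
        fwd = _trace_one_direction(volume, seed, d0, config)
        bwd = _trace_one_direction(volume, seed, -d0, config)
        pts = bwd[::-1] + [seed] + fwd
        if len(pts) < 2:
            continue
        arr = np.array(pts)
        sl = Streamline(points=arr)
        if sl.length < config.min_length:
            continue
        vox = np.round(arr).astype(int)
        sl.mean_fa = float(volume.fa[vox[:, 0], vox[:, 1], vox[:, 2]].mean())
        streamlines.append(sl)
    return streamlines


def smooth_streamline(points: np.ndarray, control_spacing: float = 1.0) -> np.ndarray:
    """Smooth a polyline by least-squares projection onto a coarse cubic
    B-spline space.

    The spline's interior knots are uniform in (chord-length) parameter
    with spacing of roughly four output samples, so vertex-to-vertex
    jitter is averaged away while the large-scale geometry is kept; since
    the operation is a projection, re-smoothing an already-smooth track
    changes it only through re-parametrization (well under 1% in length
    for tracks respecting the turning-angle rule).  The curve is resampled
    uniformly in arc length at approximately ``control_spacing`` and the
    two endpoints are preserved exactly.

    Inputs with fewer than 4 points are returned unchanged (a cubic needs
    four control points).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be an (n, 3) array")
    n = len(pts)
    if n < 4:
        logger.info("smoothing skipped: %d points (< 4), returned unchanged", n)
        return pts.copy()
    seg_in = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total_in = float(seg_in.sum())
    if total_in == 0:
        return np.vstack([pts[0], pts[-1]])
    u = np.concatenate([[0.0], np.cumsum(seg_in)]) / total_in
    u = np.maximum.accumulate(u + np.arange(n) * 1e-12)   # strictly increasing
    n_interior = max(0, min(int(total_in / (4.0 * control_spacing)), n // 3, n - 4))
    interior = np.linspace(0.0, 1.0, n_interior + 2)[1:-1]
    knots = np.concatenate([np.zeros(4), interior, np.ones(4)])
    w = np.ones(n)
    w[0] = w[-1] = 1e3     # pin the endpoints in the least-squares fit
    tck, _ = splprep(pts.T, u=u, w=w, k=3, task=-1, t=knots)
    t = np.linspace(0, 1, max(10 * n, 200))
    dense = np.array(splev(t, tck)).T
    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total == 0:
        return np.vstack([pts[0], pts[-1]])
    m = max(2, int(round(total / control_spacing)) + 1)
    targets = np.linspace(0, total, m)
    out = interp1d(arc, dense, axis=0)(targets)
    out[0], out[-1] = pts[0], pts[-1]    # clamp endpoints exactly
    return out


def assign_endpoints(
    streamlines: Sequence[Streamline],
    label_volume: np.ndarray,
) -> list[Streamline]:
    """Map each streamline's terminal points to ROI labels.

    Streamlines with an endpoint outside the grid or in background (label
    0), or with both endpoints in the same ROI (self-connections), are kept
    in the output but flagged ``excluded`` with a reason; counts are logged.
    """
    dims = label_volume.shape
    out: list[Streamline] = []
    n_out_of_grid = n_background = n_self = 0
    for sl in streamlines:
        ends = [sl.points[0], sl.points[-1]]
        labels = []
        reason = ""
        for p in ends:
            vox = _voxel_of(p)
            if not _in_grid(vox, dims):
                reason = "endpoint outside grid"
                break
            labels.append(int(label_volume[tuple(vox)]))
        if reason:
            n_out_of_grid += 1
        elif 0 in labels:
            reason = "endpoint in background"
            n_background += 1
        elif labels[0] == labels[1]:
            reason = "self-connection"
            n_self += 1
        sl2 = Streamline(
            points=sl.points, mean_fa=sl.mean_fa,
            endpoint_labels=tuple(labels) if not reason else None,
            excluded=bool(reason), exclusion_reason=reason,
        )
        out.append(sl2)
    logger.info(
        "endpoint assignment: %d retained, %d out-of-grid, %d background, %d self",
        sum(not s.excluded for s in out), n_out_of_grid, n_background, n_self,
    )
    return out
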