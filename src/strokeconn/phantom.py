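"""Synthetic principal-direction phantoms for validating the tracking stage.

A phantom is a voxel grid carrying a unit principal-direction field, an FA
scalar map and an ROI label map.  Fiber bundles are tubes of configurable
radius around waypoint polylines; inside a tube the direction is the local
path tangent and FA is ``fa_inside``, outside it FA is ``background_fa``
(below any sensible stopping threshold).  ROI label blocks are spheres at
the two ends of each bundle, so streamlines traced through the tube
terminate inside labeled voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tracking import TrackingVolume


@dataclass(frozen=True)
class Bundle:
    start_label: int
    end_label: int
    waypoints: tuple          # sequence of 3D points (voxel coordinates)
    radius: float = 1.0       # voxels
    fa_inside: float = 0.8


@dataclass(frozen=True)
class PhantomSpec:
    grid_dims: tuple[int, int, int]
    bundles: tuple[Bundle, ...]
    background_fa: float = 0.05
    direction_noise_sd: float = 0.0   # radians, isotropic perturbation
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.grid_dims):
            raise ValueError("grid_dims must be positive")
        labels = [l for b in self.bundles for l in (b.start_label, b.end_label)]
        if any(l <= 0 for l in labels):
            raise ValueError("ROI labels must be positive integers")
        if len(set(labels)) != len(labels):
            raise ValueError(f"ROI labels must be distinct, got {labels}")
        for b in self.bundles:
            if b.radius < 1:
                raise ValueError("bundle radius must be >= 1 voxel")
            if not (0 <= self.background_fa < b.fa_inside <= 1):
                raise ValueError("need 0 <= background_fa < fa_inside <= 1")
            if len(b.waypoints) < 2:
                raise ValueError("a bundle needs >= 2 waypoints")


def _densify(waypoints: np.ndarray, step: float = 0.25) -> tuple[np.ndarray, np.ndarray]:
    """Resample a polyline at ``step`` spacing; returns (points, unit tangents)."""
    pts = [waypoints[0]]
    tans = []
    for a, b in zip(waypoints[:-1], waypoints[1:]):
        seg = b - a
        L = np.linalg.norm(seg)
        if L == 0:
            continue
        t = seg / L
        n = max(1, int(np.ceil(L / step)))
        for k in range(1, n + 1):
            pts.append(a + seg * k / n)
            tans.append(t)
    tans.insert(0, tans[0])
    return np.array(pts), np.array(tans)


def bundle_path_length(bundle: Bundle) -> float:
    w = np.asarray(bundle.waypoints, dtype=float)
    return float(np.linalg.norm(np.diff(w, axis=0), axis=1).sum())


def make_phantom(spec: PhantomSpec) -> TrackingVolume:
    """Rasterize the bundles of ``spec`` into a tracking volume.

    Deterministic given ``rng_seed``; direction noise (if any) perturbs the
    tangent by independent Gaussian offsets of SD ``direction_noise_sd``
    radians before renormalization.  Overlapping label spheres from
    different bundles raise an error naming the colliding labels.
    """
    rng = np.random.default_rng(spec.rng_seed)
    dims = spec.grid_dims
    fa = np.full(dims, spec.background_fa, dtype=float)
    directions = np.zeros(dims + (3,), dtype=float)
    directions[..., 0] = 1.0     # unit placeholder outside bundles
    labels = np.zeros(dims, dtype=int)

    grid = np.stack(np.meshgrid(*[np.arange(d) for d in dims], indexing="ij"), axis=-1)

    for b in spec.bundles:
        pts, tans = _densify(np.asarray(b.waypoints, dtype=float))
        for p, t in zip(pts, tans):
            lo = np.maximum(np.floor(p - b.radius).astype(int), 0)
            hi = np.minimum(np.ceil(p + b.radius).astype(int) + 1, dims)
            sub = grid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
            inside = np.linalg.norm(sub - p, axis=-1) <= b.radius
            view_fa = fa[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
            view_d = directions[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
            view_fa[inside] = b.fa_inside
            d = t
            if spec.direction_noise_sd > 0:
                d = t + rng.normal(0.0, spec.direction_noise_sd, size=3)
                d = d / np.linalg.norm(d)
            view_d[inside] = d

        # label spheres at the two path ends, overlaid on the tube
        ends = np.asarray([b.waypoints[0], b.waypoints[-1]], dtype=float)
        for lab, end in zip((b.start_label, b.end_label), ends):
            r_lab = b.radius + 1.5
            lo = np.maximum(np.floor(end - r_lab).astype(int), 0)
            hi = np.minimum(np.ceil(end + r_lab).astype(int) + 1, dims)
            sub = grid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
            inside = np.linalg.norm(sub - end, axis=-1) <= r_lab
            view_l = labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
            clash = np.unique(view_l[inside & (view_l != 0) & (view_l != lab)])
            if clash.size:
                raise ValueError(
                    f"ROI label block {lab} overlaps blocks {clash.tolist()}"
                )
            view_l[inside] = lab

    return TrackingVolume(directions=directions, fa=fa, labels=labels)
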