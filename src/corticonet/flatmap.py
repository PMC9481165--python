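"""Interareal connection geometry from a voxel-level connectome.

Fits a sphere to voxel positions, flat-maps 3D positions to 2D arc-length
coordinates, estimates region surface areas as convex hulls, and estimates
interareal Gaussian connection widths (weighted std about the center of mass)
and peak probabilities from aggregate connection strengths.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares
from scipy.spatial import ConvexHull, QhullError

from .errors import EstimationError, InvalidInputError, SingularProjectionError

log = logging.getLogger(__name__)

#: Voxel edge length of the mesoscale connectome, in micrometers.
VOXEL_SIZE_UM = 100.0


@dataclass(frozen=True)
class FlatMap:
    """Sphere-fit flat projection.

    All coordinates are in micrometers; the projected coordinates are arc
    lengths on the fitted sphere (the voxel-size factor of the printed
    projection is absorbed by working in micrometers throughout).
    """

    center: np.ndarray
    radius: float
    voxel_size: float = VOXEL_SIZE_UM


@dataclass
class VoxelConnectome:
    """Voxel positions [um], region label per voxel, nonnegative weights.

    ``weights[l, k]`` is the connection strength from source voxel ``l`` to
    target voxel ``k``.
    """

    positions: np.ndarray
    labels: np.ndarray
    weights: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.labels = np.asarray(self.labels)
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.positions)
        if self.positions.shape != (n, 3):
            raise InvalidInputError("positions must be an (N, 3) array")
        if self.labels.shape != (n,):
            raise InvalidInputError("labels must be length N")
        if self.weights.shape != (n, n):
            raise InvalidInputError("weights must be (N, N)")
        if np.any(self.weights < 0):
            raise InvalidInputError("weights must be nonnegative")

    def voxels_of(self, region: str) -> np.ndarray:
        return np.flatnonzero(self.labels == region)

    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.labels.tolist()))


def fit_sphere(points: np.ndarray, refine: bool = False) -> tuple[np.ndarray, float]:
    """Least-squares sphere fit.

    Uses the algebraic linearization ``|x|^2 = 2 c.x + (r^2 - |c|^2)``, which
    is exact for noiseless data, with optional geometric refinement of
    ``sum (|x - c| - r)^2``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 4:
        raise EstimationError("sphere fit needs at least 4 points in 3D")
    A = np.hstack([2.0 * pts, np.ones((len(pts), 1))])
    b = np.sum(pts**2, axis=1)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4:
        raise EstimationError("degenerate (coplanar) point set: sphere underdetermined")
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise EstimationError("sphere fit produced nonpositive radius")
    radius = float(np.sqrt(r2))
    if refine:

        def residual(p):
            return np.linalg.norm(pts - p[:3], axis=1) - p[3]

        res = least_squares(residual, np.append(center, radius))
        center, radius = res.x[:3], float(res.x[3])
    return center, radius


def project_flat(points: np.ndarray, flatmap: FlatMap) -> np.ndarray:
    """Map 3D positions [um] to 2D arc-length coordinates [um].

    ``x1 = r * arctan((p1-c1)/(p2-c2))`` and
    ``x2 = r * arctan((p3-c3)/hypot(p1-c1, p2-c2))``, with plain (quadrant-
    naive) arctangents; callers must keep regions on one hemisphere-quadrant.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    d = pts - flatmap.center
    rho = np.hypot(d[:, 0], d[:, 1])
    if np.any(rho == 0):
        raise SingularProjectionError(
            "point on the projection axis (x1=c1, x2=c2)"
        )
    x1 = flatmap.radius * np.arctan(d[:, 0] / d[:, 1])
    x2 = flatmap.radius * np.arctan(d[:, 2] / rho)
    out = np.column_stack([x1, x2])
    return out[0] if np.asarray(points).ndim == 1 else out


def estimate_area(flat_positions: np.ndarray) -> float:
    """Convex-hull area [mm^2] of a region's 2D flat positions [um]."""
    pts = np.asarray(flat_positions, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise EstimationError("area estimate needs at least 3 points in 2D")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise EstimationError(f"degenerate point set for convex hull: {exc}") from exc
    return float(hull.volume) / 1e6  # um^2 -> mm^2


def _unimodal(
    source_flat: np.ndarray,
    w: np.ndarray,
    pitch: float,
    bandwidth_voxels: float,
    threshold: float,
) -> bool:
    """True when the inbound weight field has a single dominant local maximum.

    The weights are binned onto a grid at the connectome pitch, smoothed with
    a Gaussian of the given bandwidth (in voxels), and local maxima above
    ``threshold`` times the global maximum are counted.
    """
    lo = source_flat.min(axis=0)
    ij = np.floor((source_flat - lo) / pitch + 0.5).astype(int)
    shape = ij.max(axis=0) + 1
    grid = np.zeros(shape)
    np.add.at(grid, (ij[:, 0], ij[:, 1]), w)
    smooth = ndimage.gaussian_filter(grid, sigma=bandwidth_voxels)
    peak = smooth.max()
    if peak <= 0:
        return False
    local_max = (smooth == ndimage.maximum_filter(smooth, size=3)) & (
        smooth > threshold * peak
    )
    # plateau-merge: count connected components of the maximum set
    n_modes = ndimage.label(local_max)[1]
    return n_modes <= 1


def estimate_interareal_width(
    connectome: VoxelConnectome,
    flatmap: FlatMap,
    source: str,
    target: str,
    unimodality_bandwidth: float = 1.0,
    unimodality_threshold: float = 0.1,
) -> float:
    """Gaussian width d_w [um] of the source -> target connection profile.

    For each target voxel, the width is the weighted standard deviation of the
    flat-mapped source positions about their center of mass; the region-level
    width is the unweighted mean over target voxels whose inbound profile
    passes the unimodality filter.  This is an upper bound on the per-neuron
    width, because one 100-um voxel pools several neurons with partially
    overlapping input fields.
    """
    src_idx = connectome.voxels_of(source)
    tgt_idx = connectome.voxels_of(target)
    if len(src_idx) == 0 or len(tgt_idx) == 0:
        raise EstimationError(f"no voxels for {source!r} or {target!r}")
    src_flat = project_flat(connectome.positions[src_idx], flatmap)
    W = connectome.weights[np.ix_(src_idx, tgt_idx)]
    if not np.any(W > 0):
        raise EstimationError(f"no nonzero weights from {source!r} to {target!r}")

    widths = []
    for k in range(len(tgt_idx)):
        w = W[:, k]
        total = w.sum()
        if total <= 0:
            continue
        pitch = connectome.meta.get("pitch_um", VOXEL_SIZE_UM)
        if not _unimodal(
            src_flat, w, pitch, unimodality_bandwidth, unimodality_threshold,
        ):
            continue
        com = (w[:, None] * src_flat).sum(axis=0) / total
        d2 = np.sum((src_flat - com) ** 2, axis=1)
        widths.append(np.sqrt((w * d2).sum() / total))
    if not widths:
        raise EstimationError(
            f"every target voxel of {target!r} failed the unimodality filter"
        )
    return float(np.mean(widths))


def estimate_interareal_peak(
    w_ij: float,
    w_total_into_j: float,
    in_degree: float,
    dw_pixels: float,
    source_channels: float,
) -> float:
    """Peak connection probability d_p for an interareal edge.

    Solves ``e * w_ij / sum_i w_ij = 2 pi dw_px^2 * d_p * c_i`` for d_p.
    Values above 1 are capped to 1 (with a warning); the architecture is then
    inconsistent with the in-degree assumption for that edge.
    """
    if w_ij < 0:
        raise InvalidInputError("aggregate weight must be nonnegative")
    if w_total_into_j <= 0 or in_degree <= 0 or dw_pixels <= 0 or source_channels <= 0:
        raise InvalidInputError("denominator terms must be positive")
    d_p = (in_degree * w_ij / w_total_into_j) / (
        2.0 * np.pi * dw_pixels**2 * source_channels
    )
    if d_p > 1.0:
        warnings.warn(
            f"interareal peak probability {d_p:.3f} > 1; capped to 1",
            stacklevel=2,
        )
        return 1.0
    return float(d_p)


def aggregate_strength(
    connectome: VoxelConnectome, source: str, target: str
) -> float:
    """Total connection strength w_ij from source region to target region."""
    src = connectome.voxels_of(source)
    tgt = connectome.voxels_of(target)
    return float(connectome.weights[np.ix_(src, tgt)].sum())


@dataclass(frozen=True)
class InterarealProfile:
    """Aggregate strength, Gaussian width [um] and peak probability for one
    directed region pair."""

    source: str
    target: str
    strength: float
    d_w: float
    d_p: float


def estimate_profiles(
    connectome: VoxelConnectome,
    edges: list[tuple[str, str]],
    pixel_scales: Mapping[str, float],
    source_channels: Mapping[str, float],
    in_degree: float = 1000.0,
    flatmap: FlatMap | None = None,
) -> dict[tuple[str, str], InterarealProfile]:
    """Estimate (w_ij, d_w, d_p) for a list of directed region pairs.

    ``pixel_scales`` maps source region -> sigma_i [pixels/um] and
    ``source_channels`` maps source region -> channel count; both are needed
    to express the width in pixels inside the in-degree relation.
    """
    if flatmap is None:
        center, radius = fit_sphere(connectome.positions)
        flatmap = FlatMap(center=center, radius=radius)
    strengths = {e: aggregate_strength(connectome, *e) for e in edges}
    totals: dict[str, float] = {}
    for (src, tgt), s in strengths.items():
        totals[tgt] = totals.get(tgt, 0.0) + s
    profiles = {}
    for src, tgt in edges:
        d_w = estimate_interareal_width(connectome, flatmap, src, tgt)
        dw_px = pixel_scales[src] * d_w
        d_p = estimate_interareal_peak(
            strengths[(src, tgt)], totals[tgt], in_degree, dw_px,
            source_channels[src],
        )
        profiles[(src, tgt)] = InterarealProfile(
            source=src, target=tgt, strength=strengths[(src, tgt)],
            d_w=d_w, d_p=d_p,
        )
    return profiles
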