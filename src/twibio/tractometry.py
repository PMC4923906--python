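"""Streamline geometry and track-weighted map construction.

A track-weighted image assigns to each voxel the mean, over all streamlines
passing through that voxel, of a whole-track scalar — here the track's
total pathlength (mm) or its mean curvature (mm⁻¹). Curvature of a polyline
is estimated pointwise by the Menger curvature, the reciprocal circumradius
of each interior point triple; this is exact for points on a circle.
Streamline-to-voxel membership is computed by exact traversal of the
half-open voxel cells [c−0.5, c+0.5)³ crossed by each segment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_imaging import ROIMask, ScalarVolume

__all__ = [
    "StreamlineSet",
    "TrackWeightedMap",
    "streamline_length",
    "streamline_mean_curvature",
    "menger_curvatures",
    "voxels_traversed",
    "track_weighted_map",
    "twi_roi_stats",
]

STATISTICS = ("pathlength", "mean_curvature")


@dataclass
class StreamlineSet:
    """A tractogram: streamlines as (n_points, 3) world-mm arrays."""

    streamlines: list
    space_tag: str = "world-mm"

    def __post_init__(self) -> None:
        self.streamlines = [np.asarray(s, dtype=float).reshape(-1, 3) for s in self.streamlines]
        for i, s in enumerate(self.streamlines):
            if s.shape[0] < 1:
                raise ValueError(f"streamline {i} has no points")
            if not np.all(np.isfinite(s)):
                raise ValueError(f"streamline {i} contains non-finite coordinates")

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)


@dataclass
class TrackWeightedMap:
    """values: per-voxel mean whole-track scalar; counts: streamlines/voxel."""

    values: ScalarVolume
    counts: ScalarVolume
    statistic: str


def streamline_length(points: np.ndarray) -> float:
    """Total pathlength in mm: sum of Euclidean segment lengths."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if pts.shape[0] < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def menger_curvatures(points: np.ndarray) -> np.ndarray:
    """Pointwise Menger curvature κᵢ = 4·Area(pᵢ₋₁,pᵢ,pᵢ₊₁)/(a·b·c) at each
    interior point, where a, b, c are the triangle side lengths.

    A degenerate triple (any zero-length side) contributes κ = 0.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if pts.shape[0] < 3:
        return np.empty(0)
    p0, p1, p2 = pts[:-2], pts[1:-1], pts[2:]
    a = np.linalg.norm(p1 - p0, axis=1)
    b = np.linalg.norm(p2 - p1, axis=1)
    c = np.linalg.norm(p2 - p0, axis=1)
    cross = np.cross(p1 - p0, p2 - p0)
    area2 = np.linalg.norm(cross, axis=1)  # = 2 * triangle area
    denom = a * b * c
    with np.errstate(invalid="ignore", divide="ignore"):
        kappa = np.where(denom > 0, 2.0 * area2 / np.where(denom > 0, denom, 1.0), 0.0)
    return kappa


def streamline_mean_curvature(
    points: np.ndarray, arclength_weighted: bool = False
) -> float:
    """Mean Menger curvature over interior points (mm⁻¹); NaN if < 3 points.

    The default is the unweighted mean; ``arclength_weighted=True`` weights
    each interior point by half the length of its two adjacent segments.
    Returns NaN as the "curvature undefined" sentinel for < 3 points —
    such streamlines are excluded from curvature maps.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if pts.shape[0] < 3:
        return math.nan
    kappa = menger_curvatures(pts)
    if not arclength_weighted:
        return float(kappa.mean())
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    w = 0.5 * (seg[:-1] + seg[1:])
    total = w.sum()
    if total == 0:
        return float(kappa.mean())
    return float((kappa * w).sum() / total)


# ---------------------------------------------------------------------------
# Voxel traversal
# ---------------------------------------------------------------------------


def _boundary_axes(p: np.ndarray, d: np.ndarray) -> list[int]:
    # axes along which the segment lies exactly on a voxel face
    return [a for a in range(3) if d[a] == 0.0 and (p[a] + 0.5) == math.floor(p[a] + 0.5)]


def _segment_voxels(p: np.ndarray, q: np.ndarray, out: set) -> None:
    """Exact voxels crossed by one segment, in continuous voxel coordinates.

    Cells are half-open [c−0.5, c+0.5): a point exactly on the upper face
    belongs to the next voxel. A segment lying exactly in a face plane
    contributes both adjacent voxels along that axis.
    """
    d = q - p
    ts = [0.0, 1.0]
    for a in range(3):
        if d[a] != 0.0:
            # planes at half-integers k + 0.5 strictly between endpoints
            lo, hi = (p[a], q[a]) if p[a] < q[a] else (q[a], p[a])
            k0 = math.floor(lo + 0.5)
            k1 = math.floor(hi + 0.5)
            for k in range(k0, k1 + 1):
                plane = k + 0.5
                if lo < plane < hi:
                    ts.append((plane - p[a]) / d[a])
    ts = sorted(set(ts))
    baxes = _boundary_axes(p, d)
    for t0, t1 in zip(ts[:-1], ts[1:]):
        m = p + 0.5 * (t0 + t1) * d
        idx = (
            math.floor(m[0] + 0.5),
            math.floor(m[1] + 0.5),
            math.floor(m[2] + 0.5),
        )
        out.add(idx)
        for a in baxes:
            lower = list(idx)
            lower[a] -= 1
            out.add(tuple(lower))
    # endpoints exactly on crossing planes are covered: the half-open rule
    # assigns them to the upper cell, which the midpoint of the adjacent
    # sub-interval reproduces.


def voxels_traversed(points: np.ndarray, grid: ScalarVolume) -> set[tuple[int, int, int]]:
    """Set of voxel indices whose cells a streamline's segments intersect.

    Each voxel appears at most once regardless of re-entries; portions of
    the streamline outside the grid contribute nothing. A single-point
    streamline contributes the voxel containing the point.
    """
    vox = grid.world_to_voxel(np.asarray(points, dtype=float).reshape(-1, 3))
    out: set[tuple[int, int, int]] = set()
    if vox.shape[0] == 1:
        p = vox[0]
        out.add((math.floor(p[0] + 0.5), math.floor(p[1] + 0.5), math.floor(p[2] + 0.5)))
    else:
        # fast path: consecutive points in the same cell and not on a face
        idx = np.floor(vox + 0.5).astype(np.int64)
        on_face = np.any((vox + 0.5) == np.floor(vox + 0.5), axis=1)
        same = np.all(idx[:-1] == idx[1:], axis=1) & ~on_face[:-1] & ~on_face[1:]
        for i in range(vox.shape[0] - 1):
            if same[i]:
                out.add(tuple(int(v) for v in idx[i]))
            else:
                _segment_voxels(vox[i], vox[i + 1], out)
    nx, ny, nz = grid.shape
    return {
        (i, j, k)
        for (i, j, k) in out
        if 0 <= i < nx and 0 <= j < ny and 0 <= k < nz
    }


# ---------------------------------------------------------------------------
# Map construction
# ---------------------------------------------------------------------------


def track_weighted_map(
    ts: StreamlineSet,
    grid: ScalarVolume,
    statistic: str,
    arclength_weighted: bool = False,
) -> TrackWeightedMap:
    """Build an average-pathlength or mean-curvature track-weighted map.

    Each streamline contributes its whole-track scalar once to every voxel
    it traverses; a voxel's value is the mean over contributing streamlines
    and its count the number of them. Streamlines with undefined curvature
    (< 3 points) are excluded from mean_curvature maps but still counted in
    pathlength maps. Voxels no streamline touches hold value 0, count 0.
    """
    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; expected one of {STATISTICS}")
    if len(ts) == 0:
        raise ValueError("cannot build a map from an empty streamline set")

    shape = grid.shape
    acc = np.zeros(shape, dtype=float)
    counts = np.zeros(shape, dtype=np.int64)

    for s in ts:
        if statistic == "pathlength":
            value = streamline_length(s)
        else:
            value = streamline_mean_curvature(s, arclength_weighted=arclength_weighted)
            if math.isnan(value):
                continue
        vox = voxels_traversed(s, grid)
        if not vox:
            continue
        ii, jj, kk = zip(*vox)
        acc[ii, jj, kk] += value
        counts[ii, jj, kk] += 1

    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(counts > 0, acc / np.maximum(counts, 1), 0.0)
    return TrackWeightedMap(
        values=ScalarVolume(values, grid.affine),
        counts=ScalarVolume(counts.astype(float), grid.affine),
        statistic=statistic,
    )


def twi_roi_stats(
    twm: TrackWeightedMap, mask: ROIMask, include_empty: bool = False
) -> pd.DataFrame:
    """Per-label medians of a track-weighted map.

    Voxels with zero streamline count are excluded by default (the map is
    undefined there); ``include_empty`` keeps them at value 0. Labels whose
    ROI contains no traversed voxel get a missing (NaN) median, never 0.
    Columns: roi, label, statistic, median, n_voxels, coverage.
    """
    if not twm.values.same_lattice(mask):
        raise ValueError("map and mask are on different lattices")
    rows = []
    for label in mask.present_labels():
        sel = mask.labels == label
        n_roi = int(np.count_nonzero(sel))
        covered = sel & (twm.counts.data >= 1)
        n_cov = int(np.count_nonzero(covered))
        use = sel if include_empty else covered
        n_used = int(np.count_nonzero(use))
        median = float(np.median(twm.values.data[use])) if n_used else math.nan
        rows.append(
            {
                "roi": mask.label_names.get(label, str(label)),
                "label": label,
                "statistic": twm.statistic,
                "median": median,
                "n_voxels": n_used,
                "coverage": n_cov / n_roi if n_roi else math.nan,
            }
        )
    return pd.DataFrame(rows)
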