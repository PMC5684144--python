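"""Pairwise microtubule overlap detection and statistics.

Two microtubules *overlap* where they run within a lateral distance cutoff
(default 45 nm, centerline-to-centerline) of each other for at least a
minimum stretch (default 200 nm).  The length floor excludes microtubules
crossing at steep angles, which are proximal only around the crossing
point: for two straight lines within a cone of half-angle ``alpha`` the
proximal stretch is at most ``2 * cutoff / tan(alpha)`` — 156 nm for 45 nm
and 30 degrees — so requiring >= 200 nm keeps only near-parallel runs.

Detection resamples both polylines at a fine step (default 5 nm), marks
the sample points of one filament lying within the cutoff of the *other
polyline* (point-to-segment distance), and emits every maximal contiguous
run whose stretch — the minimum of the two per-filament arclength spans,
a conservative symmetric choice — reaches the floor.  A uniform-grid/KD
prefilter keeps the pair loop near-linear, but the result is contractually
identical to the dense all-pairs computation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import Filament, SpindleScene, resample_filament

__all__ = [
    "OverlapParams",
    "OverlapSegment",
    "min_expected_overlap",
    "detect_overlaps",
    "overlap_fraction_table",
    "overlap_spatial_map",
]


@dataclass
class OverlapParams:
    """Thresholds of the overlap rule (all nm)."""

    lateral_cutoff: float = 45.0
    min_length: float = 200.0
    resample_step: float = 5.0

    def __post_init__(self):
        if min(self.lateral_cutoff, self.min_length, self.resample_step) <= 0:
            raise ValueError("overlap parameters must be > 0")
        if self.min_length <= self.lateral_cutoff:
            raise ValueError("min_length must exceed lateral_cutoff")


@dataclass(frozen=True)
class OverlapSegment:
    """A detected proximity stretch between two filaments.

    ``length`` = min of the two per-filament stretch lengths;
    ``stretch_a`` / ``stretch_b`` are arclength intervals (nm) on each
    filament; the pair (id_a, id_b) is stored in sorted order.
    """

    id_a: object
    id_b: object
    length: float
    midpoint: tuple
    stretch_a: tuple
    stretch_b: tuple

    @property
    def pair(self) -> tuple:
        return (self.id_a, self.id_b)


def min_expected_overlap(lateral_cutoff: float = 45.0, cone_half_angle: float = 30.0) -> float:
    """Maximal proximal stretch of two straight lines crossing at the cone
    half-angle: 2 * cutoff / tan(angle).  Overlap calls longer than this
    cannot be crossing artifacts."""
    if not (0.0 < cone_half_angle < 90.0):
        raise ValueError("cone_half_angle must lie in (0, 90) degrees")
    if lateral_cutoff <= 0:
        raise ValueError("lateral_cutoff must be > 0")
    return 2.0 * lateral_cutoff / np.tan(np.radians(cone_half_angle))


def _point_segment_distances(points: np.ndarray, seg_a: np.ndarray, seg_b: np.ndarray):
    """(n, m) distances from each point to each segment, plus the
    projection parameter t in [0, 1] of the closest point on each segment."""
    d = seg_b - seg_a  # (m, 3)
    dd = np.einsum("ij,ij->j", d.T, d.T)  # |d|^2, (m,)
    dd = np.where(dd == 0, 1.0, dd)
    w = points[:, None, :] - seg_a[None, :, :]  # (n, m, 3)
    t = np.clip(np.einsum("nmk,mk->nm", w, d) / dd[None, :], 0.0, 1.0)
    closest = seg_a[None, :, :] + t[:, :, None] * d[None, :, :]
    dist = np.linalg.norm(points[:, None, :] - closest, axis=2)
    return dist, t


def _polyline_proximity(pts: np.ndarray, other_pts: np.ndarray, other_arc: np.ndarray):
    """Per point of ``pts``: (min distance to the other polyline, arclength
    position on the other polyline of the closest point)."""
    seg_a, seg_b = other_pts[:-1], other_pts[1:]
    dist, t = _point_segment_distances(pts, seg_a, seg_b)
    j = np.argmin(dist, axis=1)
    n = np.arange(len(pts))
    seg_len = other_arc[1:] - other_arc[:-1]
    s_other = other_arc[j] + t[n, j] * seg_len[j]
    return dist[n, j], s_other


def _runs(mask: np.ndarray):
    """Maximal [start, stop] index runs of True."""
    if not mask.any():
        return []
    idx = np.flatnonzero(mask)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    stops = np.concatenate([idx[breaks], [idx[-1]]])
    return list(zip(starts, stops))


def _pair_overlaps(fa, fb, params: OverlapParams):
    pa, aa = fa
    pb, ab = fb
    dist, s_other = _polyline_proximity(pa["pts"], pb["pts"], ab)
    segments = []
    for i0, i1 in _runs(dist < params.lateral_cutoff):
        if i1 == i0:
            continue
        stretch_a = (float(aa[i0]), float(aa[i1]))
        s_b = s_other[i0 : i1 + 1]
        stretch_b = (float(s_b.min()), float(s_b.max()))
        length = min(stretch_a[1] - stretch_a[0], stretch_b[1] - stretch_b[0])
        if length < params.min_length:
            continue
        mid_s = 0.5 * (stretch_a[0] + stretch_a[1])
        k = int(np.searchsorted(aa, mid_s))
        k = min(max(k, 0), len(pa["pts"]) - 1)
        segments.append((stretch_a, stretch_b, length, tuple(pa["pts"][k])))
    return segments


def detect_overlaps(scene: SpindleScene, params: OverlapParams | None = None) -> list[OverlapSegment]:
    """All overlap segments in a scene.

    Filaments are processed in sorted-id order so the result is independent
    of input ordering; a KD-tree over the resampled points prefilters
    candidate pairs (anything with no sample point within
    ``cutoff + step`` of the other filament cannot contain a valid run).
    A pair may contribute several disjoint segments; self-overlaps are
    never reported.
    """
    params = params or OverlapParams()
    fils = sorted(scene.filaments, key=lambda f: str(f.id))
    sampled = []
    for f in fils:
        rf = resample_filament(f, params.resample_step)
        sampled.append({"id": f.id, "pts": rf.points, "arc": rf.arclengths()})

    # candidate pairs via one global KD-tree
    all_pts = np.concatenate([s["pts"] for s in sampled]) if sampled else np.empty((0, 3))
    owner = np.concatenate(
        [np.full(len(s["pts"]), k, dtype=int) for k, s in enumerate(sampled)]
    ) if sampled else np.empty(0, dtype=int)
    candidates = set()
    if len(all_pts):
        tree = cKDTree(all_pts)
        for i, j in tree.query_pairs(params.lateral_cutoff + params.resample_step):
            a, b = owner[i], owner[j]
            if a != b:
                candidates.add((min(a, b), max(a, b)))

    out = []
    for a, b in sorted(candidates):
        sa, sb = sampled[a], sampled[b]
        segs = _pair_overlaps((sa, sa["arc"]), (sb, sb["arc"]), params)
        for stretch_a, stretch_b, length, mid in segs:
            out.append(
                OverlapSegment(
                    id_a=sa["id"],
                    id_b=sb["id"],
                    length=length,
                    midpoint=mid,
                    stretch_a=stretch_a,
                    stretch_b=stretch_b,
                )
            )
    return out


def overlap_fraction_table(overlaps, labels) -> pd.DataFrame:
    """Counts and fractions of overlaps per unordered label pair.

    ``labels`` maps filament id -> class label (population or array);
    every id appearing in an overlap must be labeled.  Fractions sum to 1.
    """
    overlaps = list(overlaps)
    if isinstance(labels, pd.Series):
        labels = labels.to_dict()
    rows = {}
    for ov in overlaps:
        for fid in (ov.id_a, ov.id_b):
            if fid not in labels:
                raise ValueError(f"overlap references unlabeled filament {fid!r}")
        key = tuple(sorted((str(labels[ov.id_a]), str(labels[ov.id_b]))))
        rows[key] = rows.get(key, 0) + 1
    total = sum(rows.values())
    table = pd.DataFrame(
        [
            {"label_a": k[0], "label_b": k[1], "count": v, "fraction": v / total}
            for k, v in sorted(rows.items())
        ]
    )
    return table


def overlap_spatial_map(overlaps, bounds_min, bounds_max, bin_nm: float = 500.0):
    """3D occupancy of overlap midpoints on a ``bin_nm`` grid, plus a
    deterministic length class (``floor(length / bin_nm)``) per overlap.

    Returns ``(occupancy: ndarray, classes: list[int])``; the occupancy
    total equals the number of overlaps (midpoints outside the bounds are
    clipped into the edge cells).
    """
    if bin_nm <= 0:
        raise ValueError("bin_nm must be > 0")
    lo = np.asarray(bounds_min, dtype=float)
    hi = np.asarray(bounds_max, dtype=float)
    nbins = np.maximum(1, np.ceil((hi - lo) / bin_nm).astype(int))
    occupancy = np.zeros(tuple(nbins), dtype=int)
    classes = []
    for ov in overlaps:
        idx = np.floor((np.asarray(ov.midpoint) - lo) / bin_nm).astype(int)
        idx = np.clip(idx, 0, nbins - 1)
        occupancy[tuple(idx)] += 1
        classes.append(int(np.floor(ov.length / bin_nm)))
    return occupancy, classes
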