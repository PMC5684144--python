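"""Per-filament geometry and summary statistics.

Orientation convention
----------------------
Each filament's direction is its end-to-end chord (traced microtubules are
short, mostly < 1 µm, and near-straight).  The chord is first *folded* into
the hemisphere with a non-negative component along the segregation axis —
microtubules carry no sign here, parallel and antiparallel are equivalent —
and then decomposed into two signed planar angles:

* inclination ``theta``: angle of the chord's projection in the plane
  spanned by the segregation axis and the reconstruction Z axis,
* azimuth ``phi``: angle in the plane spanned by the axis and the
  reconstruction Y axis,

both in degrees in (-90, 90].  A chord parallel to the axis gives (0, 0).

Spindle tilt (the small misalignment of the true spindle axis with the
reconstruction frame) is estimated as the mean signed planar angles of the
central-spindle population relative to the frame X axis, and can be removed
by rigidly rotating the scene before measuring angles.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core import (
    ChromosomeMass,
    Ellipsoid,
    Filament,
    SpindleScene,
    VoxelMask,
)

__all__ = [
    "AngleRecord",
    "LengthSummary",
    "filament_length",
    "filament_angles",
    "angle_table",
    "estimate_tilt",
    "tilt_correct",
    "rotate_scene",
    "fraction_within_cone",
    "containment",
    "percent_change",
    "length_histogram",
    "spatial_length_map",
]


@dataclass(frozen=True)
class AngleRecord:
    """Signed planar orientation angles of one filament (degrees)."""

    filament_id: object
    theta: float  # inclination, axis-Z plane, (-90, 90]
    phi: float  # azimuth, axis-Y plane, (-90, 90]


@dataclass
class LengthSummary:
    """Counts and length statistics for a filament collection.

    ``total_length_um`` sums *all* members; ``mean_length_nm`` averages the
    fully-contained subset when containment is known (lengths of truncated
    filaments are lower bounds, so they are excluded from means).
    """

    n_total: int
    n_fully_contained: int | None = None
    total_length_um: float = 0.0
    mean_length_nm: float = float("nan")
    hist_edges_nm: np.ndarray | None = None
    hist_counts: np.ndarray | None = None


def filament_length(f: Filament) -> float:
    """Arclength in nm: the sum of consecutive point distances."""
    return f.length


def _planar_basis(axis: np.ndarray):
    """Orthonormal in-plane reference vectors for theta (from lab Z) and
    phi (from lab Y), each orthogonalized against the axis."""
    axis = np.asarray(axis, dtype=float)
    out = []
    for ref in (np.array([0.0, 0.0, 1.0]), np.array([0.0, 1.0, 0.0])):
        v = ref - (ref @ axis) * axis
        n = np.linalg.norm(v)
        if n < 1e-8:
            raise ValueError(
                "segregation axis is parallel to a reference frame axis; "
                "the planar angle convention is degenerate"
            )
        out.append(v / n)
    return out[0], out[1]  # e_theta, e_phi


def _fold_planar_angle(v_axis: float, v_perp: float) -> float:
    ang = np.degrees(np.arctan2(v_perp, v_axis))
    if ang <= -90.0:
        ang += 180.0
    elif ang > 90.0:
        ang -= 180.0
    return float(ang)


def filament_angles(f: Filament, axis: np.ndarray) -> AngleRecord:
    """Inclination/azimuth of the chord relative to the segregation axis.

    Invariant under reversal of the filament's point order (the chord is
    folded into the +axis hemisphere first).
    """
    axis = np.asarray(axis, dtype=float)
    chord = f.chord
    norm = np.linalg.norm(chord)
    if norm == 0:
        raise ValueError(f"filament {f.id!r}: zero end-to-end chord (closed loop)")
    v = chord / norm
    if v @ axis < 0:
        v = -v
    e_theta, e_phi = _planar_basis(axis)
    theta = _fold_planar_angle(v @ axis, v @ e_theta)
    phi = _fold_planar_angle(v @ axis, v @ e_phi)
    return AngleRecord(f.id, theta, phi)


def angle_table(scene: SpindleScene, filaments=None) -> pd.DataFrame:
    """Per-filament angle/length table (id, length_nm, theta_deg, phi_deg)."""
    filaments = scene.filaments if filaments is None else filaments
    rows = []
    for f in filaments:
        rec = filament_angles(f, scene.axis)
        rows.append((f.id, f.length, rec.theta, rec.phi))
    return pd.DataFrame(rows, columns=["filament_id", "length_nm", "theta_deg", "phi_deg"])


def fraction_within_cone(records, bound: float = 30.0) -> float:
    """Fraction of angle records with both |theta| and |phi| <= ``bound``.

    This is the double-planar-cone criterion used to call a population
    "axis-aligned" (paper-style reporting uses bound = 30 degrees).
    """
    records = list(records)
    if not records:
        raise ValueError("fraction_within_cone: empty record list")
    ok = sum(
        1 for r in records if abs(r.theta) <= bound and abs(r.phi) <= bound
    )
    return ok / len(records)


# -- tilt estimation -------------------------------------------------------


def estimate_tilt(scene: SpindleScene, central_ids) -> tuple[float, float]:
    """Mean tilt of the central-spindle population relative to the
    reconstruction Y and Z axes.

    Returns ``(tilt_Y, tilt_Z)`` in degrees: the mean signed chord angle in
    the X-Z plane (rotation about Y) and in the X-Y plane (rotation about
    Z), chords folded into the +X hemisphere.  Rotating the scene by the
    inverse angles aligns the central population's mean direction with X.
    """
    central_ids = set(central_ids)
    if not central_ids:
        raise ValueError("estimate_tilt: empty central-spindle id set")
    tilt_y = []
    tilt_z = []
    for f in scene.filaments:
        if f.id not in central_ids:
            continue
        v = f.chord
        if v[0] < 0:
            v = -v
        tilt_y.append(np.degrees(np.arctan2(v[2], v[0])))
        tilt_z.append(np.degrees(np.arctan2(v[1], v[0])))
    if not tilt_y:
        raise ValueError("estimate_tilt: no filament matches the central ids")
    return float(np.mean(tilt_y)), float(np.mean(tilt_z))


def _rot_y(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _rot_z(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rotate_scene(scene: SpindleScene, R: np.ndarray, center=None) -> SpindleScene:
    """Rigidly rotate filaments, masses and axis by matrix ``R`` about
    ``center`` (default: origin).  Slab bounds are left untouched — an
    axis-aligned box cannot be rotated — so containment statistics should
    be computed before rotating."""
    center = np.zeros(3) if center is None else np.asarray(center, dtype=float)

    def xf(points):
        return (np.atleast_2d(points) - center) @ R.T + center

    filaments = [Filament(f.id, xf(f.points), dict(f.metadata)) for f in scene.filaments]
    masses = []
    for m in scene.masses:
        g = m.geometry
        if isinstance(g, Ellipsoid):
            g2 = Ellipsoid(xf(g.center)[0], g.semi_axes.copy(), R @ g.rotation)
        else:
            raise NotImplementedError("rigid rotation of voxel-mask geometry")
        masses.append(ChromosomeMass(m.label, g2))
    return SpindleScene(
        slab=scene.slab,
        axis=R @ scene.axis,
        masses=masses,
        filaments=filaments,
        stage_tag=scene.stage_tag,
    )


def tilt_correct(scene: SpindleScene, central_ids) -> SpindleScene:
    """Estimate the spindle tilt from the central population and rotate the
    scene so the population mean direction coincides with the frame X axis.
    """
    ty, tz = estimate_tilt(scene, central_ids)
    # undo the Z-rotation first (it was measured in the X-Y plane), then Y;
    # Ry(+ty) zeroes a positive X-Z-plane angle, Rz(-tz) a positive X-Y one
    R = _rot_y(ty) @ _rot_z(-tz)
    out = rotate_scene(scene, R)
    out.slab = replace(scene.slab, tilt=(ty, tz))
    return out


# -- containment and length statistics -------------------------------------


def containment(scene: SpindleScene) -> tuple[pd.Series, LengthSummary]:
    """Fully-contained flag per filament + length summary.

    A filament is fully contained iff *both* endpoints lie strictly inside
    the slab bounds; an endpoint on the boundary marks a microtubule
    truncated by sectioning.  ``total_length_um`` sums every filament;
    the mean is over the fully-contained subset.
    """
    flags = {}
    lengths = []
    contained_lengths = []
    for f in scene.filaments:
        inside = bool(np.all(scene.slab.contains_strict(f.endpoints)))
        flags[f.id] = inside
        L = f.length
        lengths.append(L)
        if inside:
            contained_lengths.append(L)
    series = pd.Series(flags, name="fully_contained", dtype=bool)
    summary = LengthSummary(
        n_total=len(lengths),
        n_fully_contained=len(contained_lengths),
        total_length_um=float(np.sum(lengths)) / 1000.0,
        mean_length_nm=float(np.mean(contained_lengths)) if contained_lengths else float("nan"),
    )
    return series, summary


def percent_change(before: float, after: float) -> float:
    """Percent reduction from ``before`` to ``after``: 100 (b - a) / b."""
    if before <= 0:
        raise ValueError("percent_change: 'before' must be > 0")
    return 100.0 * (before - after) / before


def length_histogram(filaments, bin_width: float = 500.0) -> LengthSummary:
    """Histogram of filament lengths with left-closed right-open bins
    ``[k*w, (k+1)*w)`` starting at zero."""
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    lengths = np.array([f.length for f in filaments], dtype=float)
    if len(lengths) == 0:
        edges = np.array([0.0, bin_width])
        return LengthSummary(
            n_total=0,
            total_length_um=0.0,
            hist_edges_nm=edges,
            hist_counts=np.zeros(1, dtype=int),
        )
    nbin = int(np.floor(lengths.max() / bin_width)) + 1
    edges = np.arange(nbin + 1) * bin_width
    idx = np.floor(lengths / bin_width).astype(int)
    counts = np.bincount(idx, minlength=nbin)
    return LengthSummary(
        n_total=len(lengths),
        n_fully_contained=None,
        total_length_um=float(lengths.sum()) / 1000.0,
        mean_length_nm=float(lengths.mean()),
        hist_edges_nm=edges,
        hist_counts=counts,
    )


def spatial_length_map(scene: SpindleScene, bin_nm: float = 500.0):
    """Length class per filament + 3D occupancy of filament midpoints.

    Each filament is assigned the deterministic class
    ``floor(length / bin_nm)``; occupancy counts midpoints (arclength
    midpoint of each polyline) in a grid of ``bin_nm`` cells covering the
    slab.  Returns ``(classes: Series, occupancy: ndarray, edges: 3 arrays)``.
    """
    if bin_nm <= 0:
        raise ValueError("bin_nm must be > 0")
    lo, hi = scene.slab.bounds_min, scene.slab.bounds_max
    nbins = np.maximum(1, np.ceil((hi - lo) / bin_nm).astype(int))
    edges = [lo[k] + np.arange(nbins[k] + 1) * bin_nm for k in range(3)]
    occupancy = np.zeros(tuple(nbins), dtype=int)
    classes = {}
    for f in scene.filaments:
        classes[f.id] = int(np.floor(f.length / bin_nm))
        mid = f.point_at(f.length / 2.0)
        idx = np.floor((mid - lo) / bin_nm).astype(int)
        idx = np.clip(idx, 0, nbins - 1)
        occupancy[tuple(idx)] += 1
    return pd.Series(classes, name="length_class"), occupancy, edges
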