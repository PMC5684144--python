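"""Domain types for anaphase-spindle reconstructions.

All geometry is held in nanometres, the native scale of the tomographic
traces (pixel size ~2.3 nm).  Distances that cross the reporting boundary
to live-imaging conventions (inter-centroid separations) are converted to
micrometres only at output time.

The central container is :class:`SpindleScene`: a reconstructed slab, the
chromosome-segregation axis, exactly two segregated chromosome masses
(polar-body proximal and pronucleus proximal), and the set of traced
microtubule centerlines (:class:`Filament`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage, optimize

__all__ = [
    "ValidationError",
    "Filament",
    "Ellipsoid",
    "VoxelMask",
    "ChromosomeMass",
    "ReconstructionSlab",
    "SpindleScene",
    "SegregationTrace",
    "IntensityRecord",
    "PB_PROXIMAL",
    "PN_PROXIMAL",
    "MASS_LABELS",
    "resample_filament",
]

PB_PROXIMAL = "PB_proximal"
PN_PROXIMAL = "PN_proximal"
MASS_LABELS = (PB_PROXIMAL, PN_PROXIMAL)


class ValidationError(ValueError):
    """A domain object violates one of its structural invariants."""


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValidationError(f"expected an (n, 3) point array, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ValidationError("points contain non-finite coordinates")
    return pts


@dataclass
class Filament:
    """An ordered 3D polyline (nm) tracing one microtubule centerline.

    Parameters
    ----------
    id : str or int
        Identifier, unique within a scene.
    points : (n, 3) array_like
        Ordered vertices in nm; at least two, consecutive vertices distinct.
    metadata : dict, optional
        Free-form annotations (e.g. tracing provenance).
    """

    id: object
    points: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.points = _as_points(self.points)
        if len(self.points) < 2:
            raise ValidationError(f"filament {self.id!r}: needs >= 2 points")
        seg = np.diff(self.points, axis=0)
        seglen = np.linalg.norm(seg, axis=1)
        if np.any(seglen == 0.0):
            raise ValidationError(f"filament {self.id!r}: consecutive duplicate points")

    @property
    def length(self) -> float:
        """Arclength in nm (sum of consecutive point distances)."""
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    @property
    def chord(self) -> np.ndarray:
        """End-to-end vector (nm)."""
        return self.points[-1] - self.points[0]

    @property
    def endpoints(self) -> np.ndarray:
        return self.points[[0, -1]]

    def arclengths(self) -> np.ndarray:
        """Cumulative arclength position of each vertex, starting at 0."""
        seglen = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seglen)])

    def reversed(self) -> "Filament":
        return Filament(self.id, self.points[::-1].copy(), dict(self.metadata))

    def point_at(self, s: float) -> np.ndarray:
        """Point at arclength position ``s`` (clipped to [0, length])."""
        cum = self.arclengths()
        s = float(np.clip(s, 0.0, cum[-1]))
        out = np.array(
            [np.interp(s, cum, self.points[:, k]) for k in range(3)]
        )
        return out


def resample_filament(f: Filament, step: float) -> Filament:
    """Resample a filament at (at most) ``step`` nm equal spacing.

    The number of intervals is ``ceil(L / step)`` so spacing is ``L / n``,
    never exceeding ``step``.  Endpoints are preserved exactly; intermediate
    vertices are linearly interpolated along arclength, so the resampled
    arclength can only shrink (chordal shortcutting), by < 0.1 % for
    ``step`` well below the local radius of curvature.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    cum = f.arclengths()
    total = cum[-1]
    n = max(1, int(np.ceil(total / step)))
    s = np.linspace(0.0, total, n + 1)
    new = np.column_stack([np.interp(s, cum, f.points[:, k]) for k in range(3)])
    new[0] = f.points[0]
    new[-1] = f.points[-1]
    return Filament(f.id, new, dict(f.metadata))


# --------------------------------------------------------------------------
# chromosome-mass geometry


@dataclass
class Ellipsoid:
    """Ellipsoid in nm: center, semi-axes, and a rotation matrix whose
    columns are the principal directions (identity = axis-aligned)."""

    center: np.ndarray
    semi_axes: np.ndarray
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        self.semi_axes = np.asarray(self.semi_axes, dtype=float).reshape(3)
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        if np.any(self.semi_axes <= 0):
            raise ValidationError("ellipsoid semi-axes must be positive")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ValidationError("ellipsoid rotation must be orthonormal")

    def _to_frame(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.center) @ self.rotation

    def contains(self, points) -> np.ndarray:
        """True where the point lies inside or on the surface."""
        q = self._to_frame(np.asarray(points, dtype=float)) / self.semi_axes
        return np.einsum("ij,ij->i", q, q) <= 1.0 + 1e-12

    def signed_distance(self, point) -> float:
        """Euclidean distance to the surface; negative inside.

        Solved exactly from the stationarity condition of the closest
        surface point, ``x_i = a_i^2 p_i / (t + a_i^2)`` with
        ``sum (x_i / a_i)^2 = 1``, by bracketing the unique root in ``t``.
        """
        p = self._to_frame(np.asarray(point, dtype=float))[0]
        a2 = self.semi_axes**2
        inside = float(np.sum(p**2 / a2)) <= 1.0

        pa = np.abs(p)
        # On-axis degeneracies are handled by nudging off exact zero.
        pa = np.maximum(pa, 1e-9)

        def g(t):
            return float(np.sum((self.semi_axes * pa / (t + a2)) ** 2) - 1.0)

        lo = -float(a2.min())
        # g decreases monotonically on (lo, inf) from +inf to -1
        hi = float(np.linalg.norm(pa) * self.semi_axes.max() + a2.max())
        while g(hi) > 0:
            hi *= 2.0
        eps = 1e-9 * max(1.0, float(a2.min()))
        t = optimize.brentq(g, lo + eps, hi, xtol=1e-9, rtol=1e-12)
        x = a2 * pa / (t + a2)
        d = float(np.linalg.norm(pa - x))
        return -d if inside else d

    @property
    def centroid(self) -> np.ndarray:
        return self.center.copy()

    def support(self, direction: np.ndarray) -> float:
        """Support function: max extent of the surface along ``direction``."""
        d = np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
        return float(np.linalg.norm(self.semi_axes * (self.rotation.T @ d)))

    def axial_extent(self, axis: np.ndarray) -> tuple[float, float]:
        """(min, max) coordinate of the mass along ``axis``."""
        c = float(self.center @ axis)
        h = self.support(axis)
        return c - h, c + h

    def surface_point(self, direction: np.ndarray) -> np.ndarray:
        """Point on the surface in the (world-frame) ``direction`` from center."""
        d = np.asarray(direction, dtype=float)
        q = self.rotation.T @ (d / np.linalg.norm(d))
        # scale q onto the surface: s such that sum((s q_i / a_i)^2) = 1
        s = 1.0 / np.sqrt(np.sum((q / self.semi_axes) ** 2))
        return self.center + self.rotation @ (s * q)


@dataclass
class VoxelMask:
    """Binary voxel mask for one chromosome mass.

    ``mask`` is indexed (z, y, x); ``voxel_size`` and ``origin`` are nm.
    World position of voxel (k, j, i) center =
    origin + voxel_size * (i, j, k) (x, y, z order).
    """

    mask: np.ndarray
    voxel_size: np.ndarray
    origin: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ValidationError("voxel mask must be 3-D (z, y, x)")
        if not self.mask.any():
            raise ValidationError("voxel mask is empty")
        self.voxel_size = np.broadcast_to(
            np.asarray(self.voxel_size, dtype=float), (3,)
        ).copy()
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if np.any(self.voxel_size <= 0):
            raise ValidationError("voxel size must be positive")
        self._edt = None

    def _to_index(self, points: np.ndarray) -> np.ndarray:
        # world (x, y, z) -> fractional index (z, y, x)
        rel = (np.atleast_2d(points) - self.origin) / self.voxel_size
        return rel[:, ::-1]

    def contains(self, points) -> np.ndarray:
        idx = np.rint(self._to_index(np.asarray(points, dtype=float))).astype(int)
        ok = np.all((idx >= 0) & (idx < self.mask.shape), axis=1)
        out = np.zeros(len(idx), dtype=bool)
        out[ok] = self.mask[tuple(idx[ok].T)]
        return out

    def distance(self, point) -> float:
        """Distance (nm) from a point to the nearest mask voxel center;
        0 inside the mask.  Uses a cached Euclidean distance transform."""
        if self._edt is None:
            self._edt = ndimage.distance_transform_edt(
                ~self.mask, sampling=self.voxel_size[::-1]
            )
        idx = self._to_index(np.asarray(point, dtype=float))[0]
        clipped = np.clip(idx, 0, np.array(self.mask.shape) - 1)
        base = float(
            ndimage.map_coordinates(self._edt, clipped[:, None], order=1, mode="nearest")[0]
        )
        # add the out-of-grid offset if the point fell outside the mask volume
        off = (idx - clipped) * self.voxel_size[::-1]
        return float(np.hypot(base, np.linalg.norm(off)))

    def signed_distance(self, point) -> float:
        if self.contains([point])[0]:
            return -0.0
        return self.distance(point)

    @property
    def centroid(self) -> np.ndarray:
        zyx = np.argwhere(self.mask).mean(axis=0)
        return self.origin + zyx[::-1] * self.voxel_size

    def axial_extent(self, axis: np.ndarray) -> tuple[float, float]:
        zyx = np.argwhere(self.mask)
        world = self.origin + zyx[:, ::-1] * self.voxel_size
        proj = world @ np.asarray(axis, dtype=float)
        h = 0.5 * float(np.max(self.voxel_size))
        return float(proj.min()) - h, float(proj.max()) + h


@dataclass
class ChromosomeMass:
    """One of the two segregating chromosome masses.

    ``label`` is ``"PB_proximal"`` (destined for the polar body) or
    ``"PN_proximal"`` (retained, forms the maternal pronucleus).
    ``geometry`` is an :class:`Ellipsoid` or a :class:`VoxelMask`.
    """

    label: str
    geometry: object

    def __post_init__(self):
        if self.label not in MASS_LABELS:
            raise ValidationError(f"mass label must be one of {MASS_LABELS}")
        if not isinstance(self.geometry, (Ellipsoid, VoxelMask)):
            raise ValidationError("mass geometry must be an Ellipsoid or VoxelMask")

    @property
    def centroid(self) -> np.ndarray:
        return self.geometry.centroid

    def contains(self, points) -> np.ndarray:
        return self.geometry.contains(points)

    def signed_distance(self, point) -> float:
        return self.geometry.signed_distance(point)

    def axial_extent(self, axis) -> tuple[float, float]:
        return self.geometry.axial_extent(axis)


@dataclass
class ReconstructionSlab:
    """Axis-aligned reconstructed volume (nm) with optional recorded tilt
    of the spindle axis relative to the reconstruction Y and Z axes."""

    bounds_min: np.ndarray
    bounds_max: np.ndarray
    tilt: tuple[float, float] | None = None  # (tilt_Y, tilt_Z) degrees

    def __post_init__(self):
        self.bounds_min = np.asarray(self.bounds_min, dtype=float).reshape(3)
        self.bounds_max = np.asarray(self.bounds_max, dtype=float).reshape(3)
        if np.any(self.bounds_max <= self.bounds_min):
            raise ValidationError("slab extents must be positive")
        if self.tilt is not None:
            ty, tz = self.tilt
            if not (-90 < ty < 90 and -90 < tz < 90):
                raise ValidationError("tilt angles must lie in (-90, 90) degrees")
            self.tilt = (float(ty), float(tz))

    def contains_strict(self, points) -> np.ndarray:
        """Strictly-interior test; boundary points are *outside* (an
        endpoint on the section surface marks a truncated filament)."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        return np.all((p > self.bounds_min) & (p < self.bounds_max), axis=1)

    @property
    def extents(self) -> np.ndarray:
        return self.bounds_max - self.bounds_min


def _check_masses_disjoint(a: ChromosomeMass, b: ChromosomeMass) -> None:
    # cheap necessary checks: neither centroid inside the other, and for
    # ellipsoid pairs a sampled-surface containment test
    if a.contains([b.centroid])[0] or b.contains([a.centroid])[0]:
        raise ValidationError("chromosome masses intersect")
    if isinstance(a.geometry, Ellipsoid) and isinstance(b.geometry, Ellipsoid):
        for u, v in ((a, b), (b, a)):
            g: Ellipsoid = u.geometry
            th = np.linspace(0, 2 * np.pi, 16, endpoint=False)
            ph = np.linspace(0.3, np.pi - 0.3, 8)
            tt, pp = np.meshgrid(th, ph)
            unit = np.column_stack(
                [
                    (np.sin(pp) * np.cos(tt)).ravel(),
                    (np.sin(pp) * np.sin(tt)).ravel(),
                    np.cos(pp).ravel(),
                ]
            )
            surf = g.center + (unit * g.semi_axes) @ g.rotation.T
            inside = v.contains(surf)
            # strictly inside (not merely touching)
            if np.any(inside):
                d = [v.signed_distance(s) for s in surf[inside]]
                if min(d) < -1e-6:
                    raise ValidationError("chromosome masses intersect")


@dataclass
class SpindleScene:
    """One reconstructed spindle: slab, segregation axis (unit vector,
    oriented PB-proximal -> PN-proximal), two chromosome masses, and the
    traced filaments."""

    slab: ReconstructionSlab
    axis: np.ndarray
    masses: Sequence[ChromosomeMass]
    filaments: list[Filament]
    stage_tag: str = ""

    def __post_init__(self):
        self.axis = np.asarray(self.axis, dtype=float).reshape(3)
        if not np.isclose(np.linalg.norm(self.axis), 1.0, atol=1e-6):
            raise ValidationError("segregation axis must be a unit vector")
        self.masses = list(self.masses)
        if len(self.masses) != 2:
            raise ValidationError("a scene holds exactly two chromosome masses")
        labels = {m.label for m in self.masses}
        if labels != set(MASS_LABELS):
            raise ValidationError(f"mass labels must be exactly {MASS_LABELS}")
        _check_masses_disjoint(*self.masses)
        self.filaments = list(self.filaments)
        ids = [f.id for f in self.filaments]
        if len(set(ids)) != len(ids):
            raise ValidationError("filament ids must be unique")

    def mass(self, label: str) -> ChromosomeMass:
        for m in self.masses:
            if m.label == label:
                return m
        raise KeyError(label)

    @property
    def filament_ids(self) -> list:
        return [f.id for f in self.filaments]

    def filament(self, fid) -> Filament:
        for f in self.filaments:
            if f.id == fid:
                return f
        raise KeyError(fid)

    @property
    def midpoint_axial(self) -> float:
        """Axial coordinate of the spindle midpoint (mean of the two mass
        centroids projected on the axis)."""
        c = 0.5 * (self.masses[0].centroid + self.masses[1].centroid)
        return float(c @ self.axis)


@dataclass
class SegregationTrace:
    """Time course of the two chromosome-mass centroids.

    ``time_s`` strictly increasing; centroids in µm; ``distance_um`` is the
    Euclidean inter-centroid separation.
    """

    time_s: np.ndarray
    centroid_a: np.ndarray  # (n, 3) µm
    centroid_b: np.ndarray  # (n, 3) µm

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float).reshape(-1)
        self.centroid_a = _as_points(self.centroid_a)
        self.centroid_b = _as_points(self.centroid_b)
        n = len(self.time_s)
        if len(self.centroid_a) != n or len(self.centroid_b) != n:
            raise ValidationError("centroid arrays must match the time axis")
        if n < 2:
            raise ValidationError("a trace needs at least two frames")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValidationError("time must be strictly increasing")

    @property
    def distance_um(self) -> np.ndarray:
        return np.linalg.norm(self.centroid_b - self.centroid_a, axis=1)


@dataclass
class IntensityRecord:
    """One time point of ROI-integrated fluorescence bookkeeping."""

    time_s: float
    int_den_spin: float  # summed intensity in the spindle ROI (a.u.)
    mean_bck: float = np.nan  # mean background intensity (a.u.)
    int_den_bck: float = np.nan  # summed background intensity (a.u.)

    def __post_init__(self):
        for name in ("int_den_spin", "mean_bck", "int_den_bck"):
            v = getattr(self, name)
            if np.isfinite(v) and v < 0:
                raise ValidationError(f"{name} must be >= 0")
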