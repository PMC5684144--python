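"""Population and array assignment of traced microtubules.

Anaphase oocyte spindles hold two populations: the *central spindle*
(microtubules lying between the two segregating chromosome masses, aligned
with the segregation axis) and the *spindle-pole remnants* (randomly
oriented, disassembling microtubules on the poleward faces of the masses).

Central-spindle filaments are further split by chromosome contact into the
*chromosomal arrays* (at least one end in direct contact with one mass —
PB-proximal or PN-proximal — or with both) and the *central array* (no
chromosome contact; a tiled bridging network).

The population decision is geometric and deterministic:

1. A filament whose arclength midpoint lies axially between the two
   chromosome region planes is central-spindle.
2. A filament contacting a mass is central-spindle when its non-contacting
   portion extends toward the spindle midpoint, pole otherwise (pole
   remnants sit on the poleward faces of the chromosomes).
3. Everything else is pole.

Region planes default to the *inner faces* of the masses (their extreme
axial extent toward the spindle midpoint); centroid planes are available
but would misclassify intra-mass portions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .core import ChromosomeMass, Filament, SpindleScene, PB_PROXIMAL, PN_PROXIMAL

__all__ = [
    "Population",
    "ArrayLabel",
    "ContactParams",
    "end_contacts",
    "region_planes",
    "assign_population",
    "assign_array",
    "classify_scene",
    "class_counts",
    "per_array_length_stats",
    "chain_count",
]


class Population(str, Enum):
    POLE = "pole"
    CENTRAL_SPINDLE = "central_spindle"


class ArrayLabel(str, Enum):
    CHROMOSOMAL_PB = "chromosomal_PB"
    CHROMOSOMAL_PN = "chromosomal_PN"
    BOTH_CONTACT = "both_contact"
    CENTRAL_ARRAY = "central_array"
    NOT_APPLICABLE = "not_applicable"


@dataclass
class ContactParams:
    """Parameters of the end-contact test.

    ``contact_tolerance`` (nm): a filament end within this distance of a
    mass surface counts as touching; 0 = inside or on the surface.
    ``region_mode``: 'inner_faces' places the central-region planes at each
    mass's inner axial extreme; 'centroids' at the mass centroids.
    """

    contact_tolerance: float = 0.0
    region_mode: str = "inner_faces"

    def __post_init__(self):
        if self.contact_tolerance < 0:
            raise ValueError("contact_tolerance must be >= 0")
        if self.region_mode not in ("inner_faces", "centroids"):
            raise ValueError("region_mode must be 'inner_faces' or 'centroids'")


def _end_touches(point: np.ndarray, mass: ChromosomeMass, tol: float) -> bool:
    if mass.contains([point])[0]:
        return True
    if tol <= 0:
        return False
    return mass.signed_distance(point) <= tol


def end_contacts(
    f: Filament, masses, params: ContactParams | None = None
) -> tuple[set, set]:
    """Mass labels touched by each filament end (start, end)."""
    params = params or ContactParams()
    out = []
    for point in (f.points[0], f.points[-1]):
        touched = {
            m.label for m in masses if _end_touches(point, m, params.contact_tolerance)
        }
        out.append(touched)
    return out[0], out[1]


def region_planes(scene: SpindleScene, params: ContactParams | None = None):
    """Axial coordinates (lo, hi) bounding the inter-chromosomal region."""
    params = params or ContactParams()
    mid = scene.midpoint_axial
    planes = []
    for m in scene.masses:
        if params.region_mode == "centroids":
            planes.append(float(m.centroid @ scene.axis))
        else:
            lo, hi = m.axial_extent(scene.axis)
            c = float(m.centroid @ scene.axis)
            # inner face: the extreme toward the spindle midpoint
            planes.append(hi if c < mid else lo)
    return min(planes), max(planes)


def _contact_mask(f: Filament, mass: ChromosomeMass, tol: float) -> np.ndarray:
    inside = mass.contains(f.points)
    if tol > 0:
        extra = np.array(
            [
                False if inside[k] else mass.signed_distance(p) <= tol
                for k, p in enumerate(f.points)
            ]
        )
        inside = inside | extra
    return inside


def assign_population(
    scene: SpindleScene, params: ContactParams | None = None
) -> pd.Series:
    """Population label per filament (exhaustive, exclusive, deterministic)."""
    params = params or ContactParams()
    lo, hi = region_planes(scene, params)
    mid = scene.midpoint_axial
    labels = {}
    for f in scene.filaments:
        sa, sb = end_contacts(f, scene.masses, params)
        contacted = sa | sb
        if contacted:
            # decide by where the non-contacting portion sits axially
            touch = np.zeros(len(f.points), dtype=bool)
            for m in scene.masses:
                if m.label in contacted:
                    touch |= _contact_mask(f, m, params.contact_tolerance)
            free = f.points[~touch]
            probe = free if len(free) else f.points
            ax_mean = float(np.mean(probe @ scene.axis))
            # the contacted mass's side: compare against its inner-face plane
            inward = lo < ax_mean < hi
            labels[f.id] = (
                Population.CENTRAL_SPINDLE.value if inward else Population.POLE.value
            )
            continue
        mid_ax = float(f.point_at(f.length / 2.0) @ scene.axis)
        labels[f.id] = (
            Population.CENTRAL_SPINDLE.value
            if lo < mid_ax < hi
            else Population.POLE.value
        )
    return pd.Series(labels, name="population")


def assign_array(
    scene: SpindleScene,
    population: pd.Series | None = None,
    params: ContactParams | None = None,
) -> pd.Series:
    """Array sub-label per filament.

    Central-spindle filaments get one of {chromosomal_PB, chromosomal_PN,
    both_contact, central_array}; pole filaments get not_applicable.  The
    four central classes partition the central-spindle set.
    """
    params = params or ContactParams()
    if population is None:
        population = assign_population(scene, params)
    labels = {}
    for f in scene.filaments:
        if population[f.id] != Population.CENTRAL_SPINDLE.value:
            labels[f.id] = ArrayLabel.NOT_APPLICABLE.value
            continue
        sa, sb = end_contacts(f, scene.masses, params)
        touched = sa | sb
        if PB_PROXIMAL in touched and PN_PROXIMAL in touched:
            labels[f.id] = ArrayLabel.BOTH_CONTACT.value
        elif PB_PROXIMAL in touched:
            labels[f.id] = ArrayLabel.CHROMOSOMAL_PB.value
        elif PN_PROXIMAL in touched:
            labels[f.id] = ArrayLabel.CHROMOSOMAL_PN.value
        else:
            labels[f.id] = ArrayLabel.CENTRAL_ARRAY.value
    return pd.Series(labels, name="array")


def classify_scene(
    scene: SpindleScene, params: ContactParams | None = None
) -> pd.DataFrame:
    """Per-filament DataFrame with 'population' and 'array' columns."""
    params = params or ContactParams()
    pop = assign_population(scene, params)
    arr = assign_array(scene, pop, params)
    return pd.DataFrame({"population": pop, "array": arr})


def class_counts(labels: pd.DataFrame) -> dict:
    """Population / array counts as a plain dict (JSON-friendly)."""
    return {
        "population": labels["population"].value_counts().to_dict(),
        "array": labels[labels["population"] == Population.CENTRAL_SPINDLE.value][
            "array"
        ]
        .value_counts()
        .to_dict(),
    }


def per_array_length_stats(
    scene: SpindleScene,
    labels: pd.DataFrame,
    fully_contained: pd.Series | None = None,
) -> pd.DataFrame:
    """Length statistics (nm) per array class, over fully-contained members.

    Truncated filaments only bound their true length from below, so means
    follow the fully-contained restriction; pass ``fully_contained=None``
    to compute containment on the fly.  Empty classes are absent from the
    result rather than reported as zero.
    """
    if fully_contained is None:
        from .geometry import containment

        fully_contained, _ = containment(scene)
    rows = []
    by_id = {f.id: f for f in scene.filaments}
    for label, grp in labels.groupby("array"):
        if label == ArrayLabel.NOT_APPLICABLE.value:
            continue
        ids = [i for i in grp.index if fully_contained[i]]
        if not ids:
            continue
        lens = np.array([by_id[i].length for i in ids])
        rows.append(
            {
                "array": label,
                "n": len(grp),
                "n_fully_contained": len(ids),
                "mean_nm": float(lens.mean()),
                "median_nm": float(np.median(lens)),
                "p25_nm": float(np.percentile(lens, 25)),
                "p75_nm": float(np.percentile(lens, 75)),
            }
        )
    return pd.DataFrame(rows).set_index("array") if rows else pd.DataFrame()


def chain_count(D: float, L_mean: float, overlap_mean: float) -> int:
    """Minimum number of end-to-end overlapping microtubules bridging an
    inter-chromosomal distance ``D``.

    A chain of ``n`` microtubules of mean length ``L_mean`` whose
    consecutive members share ``overlap_mean`` of their length spans
    ``L_mean + (n - 1)(L_mean - overlap_mean)``; the smallest ``n``
    reaching ``D`` is returned (1 when a single microtubule suffices).
    """
    if D <= 0:
        raise ValueError("D must be > 0")
    if not (L_mean > overlap_mean >= 0):
        raise ValueError("need L_mean > overlap_mean >= 0")
    if L_mean >= D:
        return 1
    return 1 + math.ceil((D - L_mean) / (L_mean - overlap_mean))
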