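"""Readers and writers for scenes, traces, masks and tracking tables.

File layout for a persisted scene:

* ``scene.json`` — descriptor: slab bounds, segregation axis, stage tag,
  and for each chromosome mass either ellipsoid parameters or a pointer to
  a labeled mask TIFF (with voxel size and origin in nm).
* ``traces.csv`` — long-format polylines with columns
  ``filament_id, point_order, x_nm, y_nm, z_nm`` (point_order 0-based).
* ``mask.tif`` — optional multi-page TIFF, voxel values 0 = background,
  1 = PB-proximal, 2 = PN-proximal.

Tracking tables are CSV with either centroid columns
``time_s, ax, ay, az, bx, by, bz`` (µm) or a precomputed
``time_s, distance_um`` pair.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import (
    MASS_LABELS,
    ChromosomeMass,
    Ellipsoid,
    Filament,
    ReconstructionSlab,
    SegregationTrace,
    SpindleScene,
    ValidationError,
    VoxelMask,
)

TRACE_COLUMNS = ["filament_id", "point_order", "x_nm", "y_nm", "z_nm"]
_MASK_VALUE = {MASS_LABELS[0]: 1, MASS_LABELS[1]: 2}


class FormatError(ValueError):
    """An input file does not match the expected schema."""


# -- filament traces -------------------------------------------------------


def read_traces(path) -> list[Filament]:
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"traces file {path}: missing columns {missing}")
    filaments = []
    for fid, grp in df.groupby("filament_id", sort=False):
        grp = grp.sort_values("point_order")
        pts = grp[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
        if len(pts) < 2:
            raise ValidationError(f"filament {fid!r} has fewer than 2 points")
        filaments.append(Filament(fid, pts))
    return filaments


def write_traces(filaments, path) -> None:
    rows = []
    for f in filaments:
        for k, p in enumerate(f.points):
            rows.append((f.id, k, p[0], p[1], p[2]))
    df = pd.DataFrame(rows, columns=TRACE_COLUMNS)
    # fixed 6 decimal places: round-trips nm coordinates to <= 5e-7 nm
    df.to_csv(path, index=False, float_format="%.6f")


# -- scene descriptor ------------------------------------------------------


def _mass_to_json(mass: ChromosomeMass, out_dir: Path | None):
    g = mass.geometry
    if isinstance(g, Ellipsoid):
        return {
            "label": mass.label,
            "ellipsoid": {
                "center_nm": g.center.tolist(),
                "semi_axes_nm": g.semi_axes.tolist(),
                "rotation": g.rotation.tolist(),
            },
        }
    return {
        "label": mass.label,
        "mask": {
            "path": "mask.tif",
            "voxel_size_nm": g.voxel_size.tolist(),
            "origin_nm": g.origin.tolist(),
            "value": _MASK_VALUE[mass.label],
        },
    }


def _mass_from_json(entry: dict, base: Path) -> ChromosomeMass:
    label = entry.get("label")
    if "ellipsoid" in entry:
        e = entry["ellipsoid"]
        geom = Ellipsoid(
            np.array(e["center_nm"]),
            np.array(e["semi_axes_nm"]),
            np.array(e.get("rotation", np.eye(3).tolist())),
        )
    elif "mask" in entry:
        m = entry["mask"]
        stack = tifffile.imread(base / m["path"])
        geom = VoxelMask(
            stack == int(m.get("value", _MASK_VALUE[label])),
            np.array(m["voxel_size_nm"]),
            np.array(m["origin_nm"]),
        )
    else:
        raise FormatError(f"mass entry for {label!r}: no ellipsoid or mask geometry")
    return ChromosomeMass(label, geom)


def load_scene(descriptor_path, traces_path=None) -> SpindleScene:
    """Load a scene from its JSON descriptor (+ traces CSV, + mask TIFF).

    ``traces_path`` defaults to the ``traces`` entry of the descriptor,
    resolved next to it.
    """
    descriptor_path = Path(descriptor_path)
    base = descriptor_path.parent
    try:
        desc = json.loads(descriptor_path.read_text())
    except json.JSONDecodeError as e:
        raise FormatError(f"descriptor {descriptor_path}: {e}") from e
    for key in ("slab", "axis", "masses"):
        if key not in desc:
            raise FormatError(f"descriptor missing required key {key!r}")
    slab = ReconstructionSlab(
        np.array(desc["slab"]["bounds_min_nm"]),
        np.array(desc["slab"]["bounds_max_nm"]),
        tuple(desc["slab"]["tilt_deg"]) if desc["slab"].get("tilt_deg") else None,
    )
    masses = [_mass_from_json(m, base) for m in desc["masses"]]
    if traces_path is None:
        traces_path = base / desc.get("traces", "traces.csv")
    filaments = read_traces(traces_path)
    return SpindleScene(
        slab=slab,
        axis=np.array(desc["axis"], dtype=float),
        masses=masses,
        filaments=filaments,
        stage_tag=desc.get("stage_tag", ""),
    )


def save_scene(scene: SpindleScene, out_dir) -> dict:
    """Persist a scene; returns the mapping of written file paths.

    ``load_scene(save_scene(s))`` reproduces the scene with coordinate
    deviations below 1e-6 nm.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {"descriptor": out_dir / "scene.json", "traces": out_dir / "traces.csv"}
    masks = [m for m in scene.masses if isinstance(m.geometry, VoxelMask)]
    if masks:
        grids = [m.geometry for m in masks]
        g0 = grids[0]
        if len(grids) == 2 and (
            grids[1].mask.shape != g0.mask.shape
            or not np.allclose(grids[1].voxel_size, g0.voxel_size)
            or not np.allclose(grids[1].origin, g0.origin)
        ):
            raise ValidationError("voxel masks must share one grid to be saved")
        stack = np.zeros(g0.mask.shape, dtype=np.uint8)
        for m in masks:
            stack[m.geometry.mask] = _MASK_VALUE[m.label]
        paths["mask"] = out_dir / "mask.tif"
        tifffile.imwrite(paths["mask"], stack)
    desc = {
        "stage_tag": scene.stage_tag,
        "axis": scene.axis.tolist(),
        "slab": {
            "bounds_min_nm": scene.slab.bounds_min.tolist(),
            "bounds_max_nm": scene.slab.bounds_max.tolist(),
            "tilt_deg": list(scene.slab.tilt) if scene.slab.tilt else None,
        },
        "traces": "traces.csv",
        "masses": [_mass_to_json(m, out_dir) for m in scene.masses],
    }
    paths["descriptor"].write_text(json.dumps(desc, indent=1))
    write_traces(scene.filaments, paths["traces"])
    return paths


# -- tracking tables -------------------------------------------------------


def read_centroid_table(path) -> SegregationTrace:
    df = pd.read_csv(path)
    need = ["time_s", "ax", "ay", "az", "bx", "by", "bz"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise FormatError(f"centroid table {path}: missing columns {missing}")
    return SegregationTrace(
        df["time_s"].to_numpy(),
        df[["ax", "ay", "az"]].to_numpy(dtype=float),
        df[["bx", "by", "bz"]].to_numpy(dtype=float),
    )


def write_centroid_table(trace: SegregationTrace, path) -> None:
    df = pd.DataFrame(
        np.column_stack([trace.time_s, trace.centroid_a, trace.centroid_b]),
        columns=["time_s", "ax", "ay", "az", "bx", "by", "bz"],
    )
    df.to_csv(path, index=False, float_format="%.6f")
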