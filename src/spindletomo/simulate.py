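"""Ground-truth synthetic spindles, segregation traces, and image stacks.

The generator emulates the statistical structure of an anaphase oocyte
spindle reconstruction: two ellipsoidal chromosome masses separated along
the segregation axis (+X), a central-spindle array between their inner
faces — split into chromosomal filaments (one end planted just inside a
mass) and a tiled central array (no chromosome contact) — a handful of
both-contact filaments spanning the full inter-chromosomal gap, and
randomly oriented short pole-remnant filaments on the poleward faces.
Filament lengths are gamma-distributed (strictly positive, right-skewed,
matching the observed sub-500-nm histogram peak), directions are drawn
uniformly within a spherical cap around the axis (pole class: uniform on
the hemisphere).  Constructed overlap pairs — parallel filaments at a
fixed sub-cutoff offset sharing a stated stretch — give the overlap
detector a known answer.

Everything is driven by one integer seed through
``numpy.random.default_rng``; identical seeds give identical scenes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import (
    ChromosomeMass,
    Ellipsoid,
    Filament,
    PB_PROXIMAL,
    PN_PROXIMAL,
    ReconstructionSlab,
    SpindleScene,
)
from .classify import ArrayLabel, Population
from .geometry import _rot_y, _rot_z, rotate_scene

__all__ = [
    "ClassSpec",
    "SceneSpec",
    "TraceSpec",
    "SceneTruth",
    "generate_scene",
    "generate_trace",
    "generate_stack",
    "MID_ANAPHASE",
    "LATE_ANAPHASE",
    "PRESETS",
]


@dataclass
class ClassSpec:
    """Count and sampling distributions for one filament class."""

    n: int = 0
    mean_length_nm: float = 600.0
    sd_length_nm: float = 300.0
    cone_half_angle_deg: float = 25.0  # ignored for the isotropic pole class

    def __post_init__(self):
        if self.n < 0:
            raise ValueError("class count must be >= 0")
        if self.mean_length_nm <= 0 or self.sd_length_nm <= 0:
            raise ValueError("length mean and sd must be > 0")
        if not (0 < self.cone_half_angle_deg <= 90):
            raise ValueError("cone half-angle must lie in (0, 90] degrees")


@dataclass
class SceneSpec:
    """Full parameterization of one synthetic spindle scene.

    Defaults reproduce a mid-anaphase-like spindle at reduced filament
    counts: 2.54 µm centroid separation, chromosomal-array mean length
    508 nm, central-array mean 665 nm, isotropic pole remnants.
    """

    seed: int = 0
    separation_um: float = 2.54
    mass_semi_axes_nm: tuple = (500.0, 900.0, 700.0)
    chromosomal_pb: ClassSpec = field(
        default_factory=lambda: ClassSpec(n=40, mean_length_nm=508.0, sd_length_nm=254.0)
    )
    chromosomal_pn: ClassSpec = field(
        default_factory=lambda: ClassSpec(n=40, mean_length_nm=508.0, sd_length_nm=254.0)
    )
    both_contact: ClassSpec = field(default_factory=lambda: ClassSpec(n=6))
    central: ClassSpec = field(
        default_factory=lambda: ClassSpec(n=60, mean_length_nm=665.0, sd_length_nm=330.0)
    )
    pole: ClassSpec = field(
        default_factory=lambda: ClassSpec(n=40, mean_length_nm=450.0, sd_length_nm=220.0)
    )
    n_overlap_pairs: int = 0
    overlap_offset_nm: float = 40.0
    overlap_length_nm: float = 300.0
    slab_margin_nm: float = 1200.0
    slab_half_thickness_nm: float = 750.0  # Z half-extent of the reconstructed slab
    spindle_radius_nm: float = 550.0  # lateral extent of filament placement
    region_margin_nm: float = 30.0  # keeps midpoints off the region planes
    tilt_deg: tuple | None = None  # optional (tilt_Y, tilt_Z) applied rigidly
    points_per_filament: int = 5
    stage_tag: str = "synthetic"

    def __post_init__(self):
        if self.separation_um <= 0:
            raise ValueError("separation must be > 0")
        if self.n_overlap_pairs < 0:
            raise ValueError("n_overlap_pairs must be >= 0")
        if not (0 < self.overlap_offset_nm < 45.0):
            raise ValueError("constructed overlap offset must lie in (0, 45) nm")
        if self.tilt_deg is not None:
            ty, tz = self.tilt_deg
            if not (-90 < ty < 90 and -90 < tz < 90):
                raise ValueError("tilt angles must lie in (-90, 90)")


@dataclass
class SceneTruth:
    """Ground truth accompanying a generated scene."""

    labels: pd.DataFrame  # per-filament population / array
    overlap_pairs: list  # [(id_a, id_b, overlap_length_nm), ...]


def _cap_direction(rng: np.random.Generator, axis: np.ndarray, half_angle_deg: float):
    """Uniform direction within a spherical cap of the given half-angle."""
    cos_max = np.cos(np.radians(half_angle_deg))
    c = rng.uniform(cos_max, 1.0)
    s = np.sqrt(1.0 - c * c)
    az = rng.uniform(0.0, 2 * np.pi)
    # local frame around the axis
    a = np.asarray(axis, dtype=float)
    ref = np.array([0.0, 0.0, 1.0]) if abs(a[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(a, ref)
    u /= np.linalg.norm(u)
    v = np.cross(a, u)
    return c * a + s * (np.cos(az) * u + np.sin(az) * v)


def _hemisphere_direction(rng: np.random.Generator):
    """Uniform direction on the full sphere (orientation sign is moot)."""
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _gamma_length(rng: np.random.Generator, spec: ClassSpec) -> float:
    shape = (spec.mean_length_nm / spec.sd_length_nm) ** 2
    scale = spec.sd_length_nm**2 / spec.mean_length_nm
    return float(max(rng.gamma(shape, scale), 50.0))


def _polyline(p0: np.ndarray, direction: np.ndarray, length: float, k: int):
    s = np.linspace(0.0, length, max(2, k))
    return p0[None, :] + s[:, None] * direction[None, :]


def _clip_lateral(p0, direction, length, radius, z_cap):
    """Shrink a straight filament so it stays within the lateral envelope."""
    p1 = p0 + direction * length
    for dim, cap in ((1, radius), (2, min(radius, z_cap))):
        for p in (p1,):
            if abs(p[dim]) > cap:
                # scale the length so the end lands on the envelope
                t = (np.sign(p[dim]) * cap - p0[dim]) / (direction[dim] * length)
                length = max(100.0, length * min(1.0, float(t)))
                p1 = p0 + direction * length
    return length


def generate_scene(spec: SceneSpec) -> tuple[SpindleScene, SceneTruth]:
    """Build a scene plus exact ground-truth labels and overlap pairs.

    Raises ``ValueError`` for infeasible specs (e.g. chromosomal mean
    length exceeding the inter-chromosomal gap, or filaments that cannot
    fit the slab).
    """
    rng = np.random.default_rng(spec.seed)
    D = spec.separation_um * 1000.0
    ax_semi = spec.mass_semi_axes_nm[0]
    half = D / 2.0
    gap_lo, gap_hi = -(half - ax_semi), half - ax_semi  # inner-face planes
    gap = gap_hi - gap_lo
    if gap <= 2 * spec.region_margin_nm + 100.0:
        raise ValueError("chromosome masses leave no inter-chromosomal gap")

    masses = [
        ChromosomeMass(PB_PROXIMAL, Ellipsoid([-half, 0, 0], spec.mass_semi_axes_nm)),
        ChromosomeMass(PN_PROXIMAL, Ellipsoid([+half, 0, 0], spec.mass_semi_axes_nm)),
    ]
    x_extent = half + ax_semi + spec.pole.mean_length_nm * 3 + spec.slab_margin_nm
    lateral = max(spec.mass_semi_axes_nm[1:]) + spec.slab_margin_nm
    slab = ReconstructionSlab(
        [-x_extent, -lateral, -spec.slab_half_thickness_nm - spec.slab_margin_nm],
        [x_extent, lateral, spec.slab_half_thickness_nm + spec.slab_margin_nm],
    )
    axis = np.array([1.0, 0.0, 0.0])

    filaments: list[Filament] = []
    labels = {}
    counter = [0]

    def add(points, population, array):
        fid = f"mt{counter[0]:05d}"
        counter[0] += 1
        filaments.append(Filament(fid, points))
        labels[fid] = (population.value, array.value)
        return fid

    z_cap = spec.slab_half_thickness_nm - 50.0
    margin = spec.region_margin_nm

    # chromosomal arrays: one end planted just inside a mass's inner face,
    # body extending inward within the orientation cone
    for mass, inward, array in (
        (masses[0], +1.0, ArrayLabel.CHROMOSOMAL_PB),
        (masses[1], -1.0, ArrayLabel.CHROMOSOMAL_PN),
    ):
        cspec = spec.chromosomal_pb if inward > 0 else spec.chromosomal_pn
        for _ in range(cspec.n):
            d = _cap_direction(rng, np.array([inward, 0.0, 0.0]), cspec.cone_half_angle_deg)
            # surface point on the inner face, biased toward the axis
            u = _cap_direction(rng, np.array([inward, 0.0, 0.0]), 50.0)
            p_surf = mass.geometry.surface_point(u)
            p0 = p_surf - inward * 20.0 * np.array([1.0, 0.0, 0.0])  # 20 nm inside
            L = _gamma_length(rng, cspec)
            # keep the free end clear of the opposite mass's inner plane
            plane = gap_lo if inward > 0 else gap_hi
            reach = (gap_hi if inward > 0 else -gap_lo) - margin - p0[0] * inward
            max_len = reach / max(abs(d[0]), 1e-6)
            # off-axis surface points sit behind the inner-face plane; force
            # enough length that the free portion clearly extends inward
            # (keeps generated labels unambiguous)
            depth = max(0.0, (plane - p0[0]) * inward)
            min_len = (2.0 * depth + 250.0) / max(abs(d[0]), 0.5)
            L = _clip_lateral(p0, d, L, spec.spindle_radius_nm, z_cap)
            # the inward-reach floor outranks the lateral envelope: labels
            # must stay unambiguous even for off-axis anchor points
            L = min(max(L, min_len), max(min_len, max_len))
            add(_polyline(p0, d, L, spec.points_per_filament), Population.CENTRAL_SPINDLE, array)

    # both-contact filaments: span the gap, endpoints planted 20 nm inside
    # each mass's inner surface at the sampled lateral position
    a_x, b_y, c_z = spec.mass_semi_axes_nm

    def inner_x(y, z, mass_sign):
        # x of the inner surface at (y, z); mass_sign -1 for PB, +1 for PN
        root = np.sqrt(max(0.0, 1.0 - (y / b_y) ** 2 - (z / c_z) ** 2))
        return mass_sign * half - mass_sign * a_x * root

    for _ in range(spec.both_contact.n):
        y0, z0 = rng.uniform(-0.4, 0.4, 2) * np.array([b_y, c_z])
        y1 = y0 + rng.normal(0, 30.0)
        z1 = z0 + rng.normal(0, 30.0)
        p0 = np.array([inner_x(y0, z0, -1) - 20.0, y0, z0])
        p1 = np.array([inner_x(y1, z1, +1) + 20.0, y1, z1])
        pts = np.linspace(p0, p1, max(2, spec.points_per_filament))
        add(pts, Population.CENTRAL_SPINDLE, ArrayLabel.BOTH_CONTACT)

    # central array: midpoint strictly between the region planes, both ends
    # clear of the masses
    def central_filament(length=None, direction=None, midpoint=None):
        for _ in range(200):
            d = direction if direction is not None else _cap_direction(
                rng, axis, spec.central.cone_half_angle_deg
            )
            L = length if length is not None else _gamma_length(rng, spec.central)
            span_x = abs(d[0]) * L
            lo = gap_lo + margin + span_x / 2.0
            hi = gap_hi - margin - span_x / 2.0
            if lo >= hi:
                if length is not None:
                    raise ValueError("central filament too long for the gap")
                continue
            if midpoint is None:
                m = np.array(
                    [
                        rng.uniform(lo, hi),
                        rng.uniform(-spec.spindle_radius_nm, spec.spindle_radius_nm),
                        rng.uniform(-min(spec.spindle_radius_nm, z_cap), min(spec.spindle_radius_nm, z_cap)),
                    ]
                )
            else:
                m = midpoint
            p0 = m - d * (L / 2.0)
            return p0, d, L
        raise ValueError("could not place a central filament; spec infeasible")

    for _ in range(spec.central.n):
        p0, d, L = central_filament()
        add(_polyline(p0, d, L, spec.points_per_filament), Population.CENTRAL_SPINDLE, ArrayLabel.CENTRAL_ARRAY)

    # constructed overlap pairs: two parallel central filaments sharing a
    # stretch of overlap_length_nm at a fixed sub-cutoff offset
    overlap_pairs = []
    ov = spec.overlap_length_nm
    for _ in range(spec.n_overlap_pairs):
        La = max(ov + 150.0, _gamma_length(rng, spec.central))
        Lb = max(ov + 150.0, _gamma_length(rng, spec.central))
        need_x = (La + Lb - ov) + 2 * margin
        d = _cap_direction(rng, axis, 10.0)
        if need_x * abs(d[0]) > gap - 2 * margin:
            scale = (gap - 2 * margin) / (need_x * abs(d[0]))
            La = max(ov + 120.0, La * scale)
            Lb = max(ov + 120.0, Lb * scale)
        # perpendicular offset direction
        perp = np.cross(d, _hemisphere_direction(rng))
        while np.linalg.norm(perp) < 1e-3:
            perp = np.cross(d, _hemisphere_direction(rng))
        perp /= np.linalg.norm(perp)
        total_span = La + Lb - ov
        lo = gap_lo + margin
        hi = gap_hi - margin - total_span * abs(d[0])
        if hi <= lo:
            raise ValueError("overlap pair does not fit the inter-chromosomal gap")
        x0 = rng.uniform(lo, hi)
        y0 = rng.uniform(-spec.spindle_radius_nm * 0.7, spec.spindle_radius_nm * 0.7)
        z0 = rng.uniform(-z_cap * 0.6, z_cap * 0.6)
        p0 = np.array([x0, y0, z0])
        a_id = add(
            _polyline(p0, d, La, spec.points_per_filament),
            Population.CENTRAL_SPINDLE,
            ArrayLabel.CENTRAL_ARRAY,
        )
        b_start = p0 + d * (La - ov) + perp * spec.overlap_offset_nm
        b_id = add(
            _polyline(b_start, d, Lb, spec.points_per_filament),
            Population.CENTRAL_SPINDLE,
            ArrayLabel.CENTRAL_ARRAY,
        )
        overlap_pairs.append((a_id, b_id, ov))

    # pole remnants: isotropic, placed beyond the outer faces of the masses
    outer_pb, outer_pn = -(half + ax_semi), half + ax_semi
    for _ in range(spec.pole.n):
        side = 1.0 if rng.uniform() < 0.5 else -1.0
        L = _gamma_length(rng, spec.pole)
        base_x = outer_pn + margin if side > 0 else outer_pb - margin
        # center of the filament sits in the pole region
        center = np.array(
            [
                base_x + side * rng.uniform(50.0, spec.pole.mean_length_nm * 1.5),
                rng.uniform(-spec.spindle_radius_nm, spec.spindle_radius_nm),
                rng.uniform(-z_cap * 0.8, z_cap * 0.8),
            ]
        )
        d = _hemisphere_direction(rng)
        # keep the whole filament on the poleward side of the outer face
        for _try in range(100):
            p0 = center - d * (L / 2.0)
            p1 = center + d * (L / 2.0)
            xs = np.array([p0[0], p1[0]])
            if side > 0 and xs.min() > outer_pn + 5.0:
                break
            if side < 0 and xs.max() < outer_pb - 5.0:
                break
            d = _hemisphere_direction(rng)
            center[0] = base_x + side * rng.uniform(
                L / 2.0 + 20.0, L / 2.0 + spec.pole.mean_length_nm * 1.5
            )
        add(_polyline(center - d * (L / 2.0), d, L, spec.points_per_filament), Population.POLE, ArrayLabel.NOT_APPLICABLE)

    scene = SpindleScene(
        slab=slab, axis=axis, masses=masses, filaments=filaments, stage_tag=spec.stage_tag
    )
    if spec.tilt_deg is not None:
        # tilt_Y tips the axis toward +Z (X-Z-plane angle), tilt_Z toward +Y
        ty, tz = spec.tilt_deg
        R = _rot_z(tz) @ _rot_y(-ty)
        scene = rotate_scene(scene, R)

    truth = SceneTruth(
        labels=pd.DataFrame(
            [(fid, pop, arr) for fid, (pop, arr) in labels.items()],
            columns=["filament_id", "population", "array"],
        ).set_index("filament_id"),
        overlap_pairs=overlap_pairs,
    )
    return scene, truth


# -- segregation traces ----------------------------------------------------


@dataclass
class TraceSpec:
    """Biphasic (anaphase A then B) centroid-separation time course.

    Rates in µm/min; the switch occurs when the true distance reaches
    ``switch_distance_um``.  Gaussian noise (sd in µm) is applied to each
    centroid coordinate independently.
    """

    seed: int = 0
    rate_a_um_min: float = 0.55
    rate_b_um_min: float = 1.1
    switch_distance_um: float = 2.54
    start_distance_um: float = 1.0
    frame_interval_s: float = 10.0
    n_frames: int = 40
    noise_sd_um: float = 0.0

    def __post_init__(self):
        if self.rate_a_um_min <= 0 or self.rate_b_um_min <= 0:
            raise ValueError("rates must be > 0")
        if self.noise_sd_um < 0:
            raise ValueError("noise sd must be >= 0")
        if self.switch_distance_um <= self.start_distance_um:
            raise ValueError("switch distance must exceed the start distance")


def generate_trace(spec: TraceSpec):
    """Centroid table (+ truth) for a biphasic separation time course.

    Returns ``(df, truth)`` where ``df`` has columns
    ``time_s, ax..bz`` (µm) and ``truth`` is a dict with the true switch
    time, the first frame index at/after the switch, and both rates.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.n_frames) * spec.frame_interval_s
    ra = spec.rate_a_um_min / 60.0
    rb = spec.rate_b_um_min / 60.0
    t_switch = (spec.switch_distance_um - spec.start_distance_um) / ra
    d = np.where(
        t < t_switch,
        spec.start_distance_um + ra * t,
        spec.switch_distance_um + rb * (t - t_switch),
    )
    a = np.column_stack([-d / 2.0, np.zeros_like(d), np.zeros_like(d)])
    b = np.column_stack([+d / 2.0, np.zeros_like(d), np.zeros_like(d)])
    if spec.noise_sd_um > 0:
        a = a + rng.normal(0.0, spec.noise_sd_um, a.shape)
        b = b + rng.normal(0.0, spec.noise_sd_um, b.shape)
    df = pd.DataFrame(
        np.column_stack([t, a, b]),
        columns=["time_s", "ax", "ay", "az", "bx", "by", "bz"],
    )
    truth = {
        "t_switch_s": float(t_switch),
        "switch_frame": int(np.searchsorted(t, t_switch)),
        "rate_a_um_min": spec.rate_a_um_min,
        "rate_b_um_min": spec.rate_b_um_min,
    }
    return df, truth


# -- fluorescence stacks ---------------------------------------------------


def generate_stack(
    shape: tuple,
    spots=(),
    background: float = 10.0,
    poisson: bool = False,
    seed: int = 0,
):
    """Synthetic fluorescence stack: Gaussian emitters on a flat background.

    ``shape`` is (T, Y, X); ``spots`` is a sequence of dicts with keys
    ``x, y, sigma, amplitude`` (static) and optionally ``vx, vy`` (pixel
    drift per frame).  With ``poisson=True`` each pixel is replaced by a
    Poisson draw of its expected value.  Returns ``(stack, truth)`` where
    truth lists per-spot integrated intensities (amplitude * 2 pi sigma^2).
    """
    rng = np.random.default_rng(seed)
    T, H, W = shape
    yy, xx = np.mgrid[0:H, 0:W]
    stack = np.full(shape, float(background))
    truth = []
    for s in spots:
        amp, sig = float(s["amplitude"]), float(s["sigma"])
        vx, vy = float(s.get("vx", 0.0)), float(s.get("vy", 0.0))
        positions = []
        for t in range(T):
            cx, cy = s["x"] + vx * t, s["y"] + vy * t
            stack[t] += amp * np.exp(
                -((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * sig**2)
            )
            positions.append((cx, cy))
        truth.append(
            {
                "positions": positions,
                "integrated": amp * 2.0 * np.pi * sig**2,
                "sigma": sig,
                "amplitude": amp,
            }
        )
    if poisson:
        stack = rng.poisson(stack).astype(float)
    return stack, truth


# -- presets anchored to the two reconstructed stages ----------------------

# Published totals: mid-anaphase 2880 microtubules (1655 central spindle of
# which 12 contact both masses; 1225 pole remnants), late anaphase 1310
# (1229 central spindle, 6 both-contact; 81 pole).  The chromosomal /
# central sub-array split is not printed, so presets divide the remainder
# evenly.  Length means: chromosomal 508 / 848 nm, central 665 / 956 nm
# (mid / late); sd is a free parameter, set to mean / 2.

def _preset(separation, n_chrom, n_both, n_central, n_pole, chrom_mean, central_mean, tag):
    half_chrom = n_chrom // 2
    # a 35-degree orientation cone leaves ~85-90% of directions within the
    # +-30-degree planar window, as observed for the central spindle at
    # both stages
    cone = 35.0
    return SceneSpec(
        separation_um=separation,
        chromosomal_pb=ClassSpec(n=half_chrom, mean_length_nm=chrom_mean, sd_length_nm=chrom_mean / 2, cone_half_angle_deg=cone),
        chromosomal_pn=ClassSpec(n=n_chrom - half_chrom, mean_length_nm=chrom_mean, sd_length_nm=chrom_mean / 2, cone_half_angle_deg=cone),
        both_contact=ClassSpec(n=n_both),
        central=ClassSpec(n=n_central, mean_length_nm=central_mean, sd_length_nm=central_mean / 2, cone_half_angle_deg=cone),
        pole=ClassSpec(n=n_pole, mean_length_nm=450.0, sd_length_nm=225.0),
        stage_tag=tag,
    )


MID_ANAPHASE = _preset(2.54, 822, 12, 821, 1225, 508.0, 665.0, "mid-anaphase")
LATE_ANAPHASE = _preset(3.51, 612, 6, 611, 81, 848.0, 956.0, "late-anaphase")
PRESETS = {"mid-anaphase": MID_ANAPHASE, "late-anaphase": LATE_ANAPHASE}


def scaled_preset(preset: SceneSpec, factor: float, seed: int = 0) -> SceneSpec:
    """Copy of a preset with all class counts scaled down by ``factor``."""
    if not (0 < factor <= 1):
        raise ValueError("factor must lie in (0, 1]")

    def scale(cs: ClassSpec) -> ClassSpec:
        return replace(cs, n=max(1, int(round(cs.n * factor))))

    return replace(
        preset,
        seed=seed,
        chromosomal_pb=scale(preset.chromosomal_pb),
        chromosomal_pn=scale(preset.chromosomal_pn),
        both_contact=scale(preset.both_contact),
        central=scale(preset.central),
        pole=scale(preset.pole),
    )
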