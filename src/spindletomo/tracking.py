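"""Live-imaging metrics: segregation traces, pole-focusing, intensities.

Chromosome segregation is followed as the Euclidean distance between the
centroids of the two segregating chromosome masses over time (µm).  The
trace is split into anaphase A (chromosome-to-pole movement) and anaphase
B (spindle elongation) by a distance threshold (default 2.54 µm): a frame
is anaphase A while the distance stays below the threshold; the first
crossing latches anaphase B for the remainder of the trace.

Spindle-pole focusing is scored from three linescans drawn perpendicular
to the two poles and to the spindle center: the mean pole width divided by
the center width, widths taken as the full width at half maximum (FWHM) of
the background-subtracted profile.  Focused poles give a lower score.

Two background corrections for ROI-integrated fluorescence are provided:
``IntDen(spin) / Mean(bck)`` followed by min-max normalization to [0, 1]
(tubulin-style), and ``(IntDen(spin) - IntDen(bck)) / IntDen(bck)``
(dynein-style).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .core import IntensityRecord, SegregationTrace, ValidationError

__all__ = [
    "ANAPHASE_A",
    "ANAPHASE_B",
    "PhaseSegmentation",
    "Linescan",
    "segregation_trace",
    "fwhm",
    "pole_focusing_score",
    "corrected_tubulin_intensity",
    "corrected_dynein_intensity",
    "roi_integrate",
    "RectangleROI",
    "CircleROI",
    "stack_centroids",
]

ANAPHASE_A = "anaphase_A"
ANAPHASE_B = "anaphase_B"
DEFAULT_TRANSITION_UM = 2.54


@dataclass
class PhaseSegmentation:
    """Per-frame anaphase phase with the latching distance threshold."""

    transition_distance_um: float
    phase: np.ndarray  # array of ANAPHASE_A / ANAPHASE_B

    @property
    def transition_index(self) -> int | None:
        """Index of the first anaphase-B frame, or None if never reached."""
        hits = np.flatnonzero(self.phase == ANAPHASE_B)
        return int(hits[0]) if len(hits) else None


@dataclass
class Linescan:
    """Intensity profile along a (3-pixel-wide, averaged) scan line."""

    positions: np.ndarray
    profile: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1)
        self.profile = np.asarray(self.profile, dtype=float).reshape(-1)
        if len(self.positions) != len(self.profile):
            raise ValidationError("positions and profile must have equal length")
        if np.any(self.profile < 0):
            raise ValidationError("linescan intensities must be non-negative")


def segregation_trace(
    trace: SegregationTrace | pd.DataFrame,
    transition_distance_um: float = DEFAULT_TRANSITION_UM,
    project_2d: bool = False,
) -> tuple[pd.DataFrame, PhaseSegmentation]:
    """Distance-over-time table + anaphase A/B segmentation.

    Accepts a :class:`SegregationTrace` or a centroid DataFrame with
    columns ``time_s, ax..bz`` (µm).  ``project_2d`` drops the axial (z)
    component before measuring distances, mimicking measurements on
    maximal projections; default is the full 3D distance.
    """
    if isinstance(trace, pd.DataFrame):
        trace = SegregationTrace(
            trace["time_s"].to_numpy(),
            trace[["ax", "ay", "az"]].to_numpy(dtype=float),
            trace[["bx", "by", "bz"]].to_numpy(dtype=float),
        )
    delta = trace.centroid_b - trace.centroid_a
    if project_2d:
        delta = delta[:, :2]
    dist = np.linalg.norm(delta, axis=1)
    crossed = np.maximum.accumulate(dist >= transition_distance_um)
    phase = np.where(crossed, ANAPHASE_B, ANAPHASE_A)
    df = pd.DataFrame(
        {"time_s": trace.time_s, "distance_um": dist, "phase": phase}
    )
    return df, PhaseSegmentation(transition_distance_um, phase)


def fwhm(scan: Linescan) -> float:
    """Full width at half maximum of the background-subtracted profile.

    Background is the profile minimum; half-max crossings on either side
    of the peak are located by linear interpolation.  A flat profile has
    no width and raises ``ValueError``.
    """
    y = scan.profile - scan.profile.min()
    peak = float(y.max())
    if peak <= 0:
        raise ValueError("flat linescan profile: width undefined")
    half = peak / 2.0
    x = scan.positions
    k = int(np.argmax(y))

    def cross(step):
        i = k
        while 0 <= i + step < len(y) and y[i + step] >= half:
            i += step
        j = i + step
        if j < 0 or j >= len(y):
            return x[i]  # profile never falls below half-max on this side
        # interpolate between samples i (>= half) and j (< half)
        f = (y[i] - half) / (y[i] - y[j])
        return x[i] + f * (x[j] - x[i])

    left = cross(-1)
    right = cross(+1)
    return float(abs(right - left))


def pole_focusing_score(
    pole_scan_1: Linescan, pole_scan_2: Linescan, center_scan: Linescan
) -> float:
    """Mean pole width divided by center width (widths = FWHM).

    Scores below/above 1 indicate poles narrower/wider than the spindle
    center; focused poles score low.
    """
    w1, w2 = fwhm(pole_scan_1), fwhm(pole_scan_2)
    wc = fwhm(center_scan)
    if wc == 0:
        raise ValueError("center linescan has zero width")
    return 0.5 * (w1 + w2) / wc


def corrected_tubulin_intensity(records) -> np.ndarray:
    """Background-corrected, min-max-normalized tubulin intensity series.

    Per frame: ``IntDen(spin) / Mean(bck)``; the ratio series is then
    scaled so its minimum is 0 and maximum 1.  Invariant to multiplying
    the whole image by a constant.
    """
    records = list(records)
    if len(records) < 2:
        raise ValueError("need at least two records to normalize")
    ratios = []
    for r in records:
        if not np.isfinite(r.mean_bck) or r.mean_bck <= 0:
            raise ValueError("Mean(bck) must be > 0 for the tubulin correction")
        ratios.append(r.int_den_spin / r.mean_bck)
    ratios = np.asarray(ratios)
    lo, hi = ratios.min(), ratios.max()
    if hi == lo:
        raise ValueError("constant intensity series cannot be min-max normalized")
    return (ratios - lo) / (hi - lo)


def corrected_dynein_intensity(record: IntensityRecord) -> float:
    """Background-corrected dynein intensity:
    ``(IntDen(spin) - IntDen(bck)) / IntDen(bck)``."""
    if not np.isfinite(record.int_den_bck) or record.int_den_bck <= 0:
        raise ValueError("IntDen(bck) must be > 0 for the dynein correction")
    return (record.int_den_spin - record.int_den_bck) / record.int_den_bck


# -- ROI integration over image stacks -------------------------------------


@dataclass
class RectangleROI:
    """Axis-aligned pixel rectangle [x0, x0+width) x [y0, y0+height)."""

    x0: int
    y0: int
    width: int
    height: int

    def mask(self, shape) -> np.ndarray:
        h, w = shape
        if (
            self.x0 < 0
            or self.y0 < 0
            or self.x0 + self.width > w
            or self.y0 + self.height > h
            or self.width <= 0
            or self.height <= 0
        ):
            raise ValueError("rectangle ROI out of image bounds")
        m = np.zeros(shape, dtype=bool)
        m[self.y0 : self.y0 + self.height, self.x0 : self.x0 + self.width] = True
        return m


@dataclass
class CircleROI:
    """Pixel-center-inclusion circle of radius ``r`` around (cx, cy)."""

    cx: float
    cy: float
    r: float

    def mask(self, shape) -> np.ndarray:
        h, w = shape
        if not (0 <= self.cx < w and 0 <= self.cy < h) or self.r <= 0:
            raise ValueError("circle ROI out of image bounds")
        yy, xx = np.mgrid[0:h, 0:w]
        return (xx - self.cx) ** 2 + (yy - self.cy) ** 2 <= self.r**2


def roi_integrate(
    stack: np.ndarray,
    roi,
    projection: str = "sum",
    times: np.ndarray | None = None,
) -> pd.DataFrame:
    """Integrated and mean ROI intensity per frame.

    ``stack`` is (T, Y, X) or (T, Z, Y, X); 4-D stacks are first projected
    along Z (``projection``: 'sum' or 'max').  Returns a DataFrame with
    columns ``time_s, int_den, mean`` — feed a spindle ROI and a background
    ROI through this to build :class:`~spindletomo.core.IntensityRecord`
    series for the correction formulas.
    """
    stack = np.asarray(stack)
    if stack.ndim == 4:
        if projection == "sum":
            stack = stack.sum(axis=1)
        elif projection == "max":
            stack = stack.max(axis=1)
        else:
            raise ValueError("projection must be 'sum' or 'max'")
    if stack.ndim != 3:
        raise ValueError("stack must be (T, Y, X) or (T, Z, Y, X)")
    m = roi.mask(stack.shape[1:])
    npix = int(m.sum())
    int_den = stack[:, m].sum(axis=1).astype(float)
    if times is None:
        times = np.arange(stack.shape[0], dtype=float)
    return pd.DataFrame(
        {"time_s": np.asarray(times, dtype=float), "int_den": int_den, "mean": int_den / npix}
    )


def stack_centroids(stack: np.ndarray, axis_coord: int = 1) -> pd.DataFrame:
    """Intensity-weighted centroids of the two brightest blobs per frame.

    Helper for synthetic chromosome (mCherry-like) stacks: each (Y, X)
    frame is thresholded with Otsu's method and split along the image
    column (or row) midline into the two separating masses; the
    intensity-weighted center of mass of each side is returned in pixel
    units with columns ``time, ax, ay, bx, by``.  Real tracking tables are
    expected to come from dedicated tracking tools; this exists to close
    the loop on generated stacks.
    """
    stack = np.asarray(stack, dtype=float)
    rows = []
    for t, frame in enumerate(stack):
        th = threshold_otsu(frame)
        mask = frame > th
        yy, xx = np.nonzero(mask)
        if len(xx) == 0:
            raise ValueError(f"frame {t}: nothing above the Otsu threshold")
        coord = xx if axis_coord == 1 else yy
        split = coord.mean()
        out = {}
        for tag, sel in (("a", coord <= split), ("b", coord > split)):
            if not sel.any():
                raise ValueError(f"frame {t}: could not split the two masses")
            w = frame[yy[sel], xx[sel]]
            out[tag] = (
                float(np.average(xx[sel], weights=w)),
                float(np.average(yy[sel], weights=w)),
            )
        rows.append((t, out["a"][0], out["a"][1], out["b"][0], out["b"][1]))
    return pd.DataFrame(rows, columns=["time", "ax", "ay", "bx", "by"])
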