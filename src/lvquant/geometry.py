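"""Geometric computation of the 11 LV indices and cardiac phase from label masks.

Given a 3-class short-axis label mask (0 background, 1 LV cavity,
2 LV myocardium), this module measures, fully deterministically:

* the two areas (cavity, myocardium) by pixel counting,
* the three cavity dimensions by casting a line through the cavity centroid
  in the IS-AL, I-A and IL-AS directions and measuring the distance between
  the two endocardial crossings,
* the six regional wall thicknesses (IS, I, IL, AL, A, AS) by casting a ray
  per segment bisector and measuring the myocardial chord on it,
* the binary cardiac phase from the cavity-area series over the cycle
  (end-diastole = maximal area, end-systole = minimal area).

All continuous indices are normalized: areas by H*W, lengths by H (square
images are assumed and checked).  Physical units are recovered with the
pixel spacing: lengths * H * spacing (mm), areas * H * W * spacing**2 (mm^2).

Angular convention (shared with the phantom generator): angle 0 points to
image-right (+col), angles increase counter-clockwise on the displayed image
(i.e. -row with +sin).  Segment bisectors sit 60 degrees apart with the
anterior (A) segment at the top (90 degrees).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BACKGROUND", "CAVITY", "MYOCARDIUM", "SEGMENT_NAMES", "SEGMENT_ANGLES",
    "DIM_ANGLES", "DEFAULT_SPACING", "INDEX_NAMES",
    "DegenerateMaskError", "UndefinedPhaseError", "LabelMask", "IndexVector",
    "cavity_centroid", "areas_from_mask", "ray_crossings",
    "cavity_dimensions", "regional_wall_thickness", "phase_from_areas",
    "indices_from_mask",
]

BACKGROUND, CAVITY, MYOCARDIUM = 0, 1, 2

DEFAULT_SPACING = 1.5625  # mm / pixel, the modal spacing of mid-cavity SAX cine

#: segment order used everywhere: inferoseptal, inferior, inferolateral,
#: anterolateral, anterior, anteroseptal
SEGMENT_NAMES = ("IS", "I", "IL", "AL", "A", "AS")

#: bisector angle of each segment, radians (A at the top = 90 deg, 60 deg apart)
SEGMENT_ANGLES = {
    "IS": np.deg2rad(210.0),
    "I": np.deg2rad(270.0),
    "IL": np.deg2rad(330.0),
    "AL": np.deg2rad(30.0),
    "A": np.deg2rad(90.0),
    "AS": np.deg2rad(150.0),
}

#: the three paired cavity-dimension directions: IS-AL, I-A, IL-AS
DIM_ANGLES = (SEGMENT_ANGLES["IS"], SEGMENT_ANGLES["I"], SEGMENT_ANGLES["IL"])

INDEX_NAMES = ("area_cav", "area_myo", "dim1", "dim2", "dim3",
               "rwt_is", "rwt_i", "rwt_il", "rwt_al", "rwt_a", "rwt_as")

#: phase codes
DIASTOLE, SYSTOLE = 0, 1


class DegenerateMaskError(ValueError):
    """The mask lacks the structure (cavity / ring) an index needs."""


class UndefinedPhaseError(ValueError):
    """The cavity-area series is constant; ED/ES cannot be located."""


@dataclass
class LabelMask:
    """A 3-class per-pixel label field with optional physical spacing."""

    classes: np.ndarray
    spacing: float = DEFAULT_SPACING

    def __post_init__(self):
        self.classes = np.asarray(self.classes)
        if not np.isin(self.classes, (BACKGROUND, CAVITY, MYOCARDIUM)).all():
            raise ValueError("mask may only contain class codes {0, 1, 2}")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")


@dataclass
class IndexVector:
    """The 11 normalized LV quantification targets plus the binary phase."""

    area_cav: float
    area_myo: float
    dims: np.ndarray          # (3,) IS-AL, I-A, IL-AS
    rwt: np.ndarray           # (6,) IS, I, IL, AL, A, AS
    phase: int = DIASTOLE

    def to_array(self) -> np.ndarray:
        """The 11 continuous entries in canonical order (no phase)."""
        return np.concatenate(([self.area_cav, self.area_myo],
                               np.asarray(self.dims, dtype=float),
                               np.asarray(self.rwt, dtype=float)))

    @classmethod
    def from_array(cls, values, phase: int = DIASTOLE) -> "IndexVector":
        values = np.asarray(values, dtype=float)
        if values.shape != (11,):
            raise ValueError("expected 11 index values")
        return cls(float(values[0]), float(values[1]),
                   values[2:5].copy(), values[5:11].copy(), int(phase))


def _as_classes(mask) -> np.ndarray:
    arr = mask.classes if isinstance(mask, LabelMask) else np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError("expected a single 2D mask")
    if arr.shape[0] != arr.shape[1]:
        raise ValueError("square masks are assumed (normalization by H)")
    return arr


def direction(angle: float) -> tuple[float, float]:
    """(d_row, d_col) unit vector for an angle measured CCW from +col."""
    return (-np.sin(angle), np.cos(angle))


def cavity_centroid(mask) -> tuple[float, float]:
    """Arithmetic mean of cavity pixel-center coordinates, (row, col)."""
    m = _as_classes(mask)
    rows, cols = np.nonzero(m == CAVITY)
    if rows.size == 0:
        raise DegenerateMaskError("mask has no cavity pixels")
    return (float(rows.mean()), float(cols.mean()))


def areas_from_mask(mask) -> tuple[float, float]:
    """Normalized (cavity, myocardium) areas: pixel counts / (H*W)."""
    m = _as_classes(mask)
    hw = m.size
    return (float((m == CAVITY).sum()) / hw, float((m == MYOCARDIUM).sum()) / hw)


def ray_crossings(mask, origin: tuple[float, float], angle: float,
                  step: float = 0.1) -> list[tuple[int, int, float]]:
    """Class transitions along a ray from `origin`, sub-pixel marched.

    Samples the mask by nearest pixel every `step` pixels; each class change
    is reported as (from_class, to_class, distance) with the distance taken
    at the midpoint of the two straddling samples.  Marching stops when the
    nearest pixel leaves the image.
    """
    m = _as_classes(mask)
    h, w = m.shape
    r0, c0 = origin
    if not (-0.5 <= r0 <= h - 0.5 and -0.5 <= c0 <= w - 0.5):
        raise ValueError("ray origin lies outside the image")
    if step <= 0:
        raise ValueError("step must be positive")
    dr, dc = direction(angle)
    # bound on the ray length: image diagonal
    n_steps = int(np.ceil(np.hypot(h, w) / step)) + 2
    t = np.arange(n_steps + 1) * step
    rr = np.rint(r0 + t * dr).astype(int)
    cc = np.rint(c0 + t * dc).astype(int)
    inside = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
    stop = np.argmin(inside) if not inside.all() else inside.size
    if stop <= 1:
        return []
    cls = m[rr[:stop], cc[:stop]]
    change = np.nonzero(cls[1:] != cls[:-1])[0]
    return [(int(cls[i]), int(cls[i + 1]), float((t[i] + t[i + 1]) / 2.0))
            for i in change]


def _first_crossing(crossings, frm: int, to: int, after: float = -np.inf):
    for f, t, d in crossings:
        if f == frm and t == to and d > after:
            return d
    return None


def cavity_dimensions(mask, step: float = 0.1) -> np.ndarray:
    """Normalized cavity dimensions along IS-AL, I-A, IL-AS through the centroid."""
    m = _as_classes(mask)
    origin = cavity_centroid(m)
    h = m.shape[0]
    dims = np.empty(3)
    for i, ang in enumerate(DIM_ANGLES):
        total = 0.0
        for a in (ang, ang + np.pi):
            d = _first_crossing(ray_crossings(m, origin, a, step), CAVITY, MYOCARDIUM)
            if d is None:
                raise DegenerateMaskError(
                    f"no endocardial crossing on the {SEGMENT_NAMES[i]} dimension ray")
            total += d
        dims[i] = total / h
    return dims


def regional_wall_thickness(mask, step: float = 0.1) -> np.ndarray:
    """Normalized wall thickness at the six segment bisectors (IS..AS order)."""
    m = _as_classes(mask)
    origin = cavity_centroid(m)
    h = m.shape[0]
    rwt = np.empty(6)
    for k, name in enumerate(SEGMENT_NAMES):
        crossings = ray_crossings(m, origin, SEGMENT_ANGLES[name], step)
        d_endo = _first_crossing(crossings, CAVITY, MYOCARDIUM)
        if d_endo is None:
            raise DegenerateMaskError(f"segment {name}: ray leaves cavity without "
                                      "entering myocardium (broken ring?)")
        d_epi = _first_crossing(crossings, MYOCARDIUM, BACKGROUND, after=d_endo)
        if d_epi is None:
            raise DegenerateMaskError(f"segment {name}: no epicardial crossing")
        rwt[k] = (d_epi - d_endo) / h
    return rwt


def phase_from_areas(area_series) -> np.ndarray:
    """Binary per-frame phase from the cavity-area series.

    ED is the argmax, ES the argmin of the series.  Frames strictly after ED
    up to and including ES (cyclically) are systole (1); all others diastole
    (0).
    """
    areas = np.asarray(area_series, dtype=float)
    if areas.ndim != 1 or areas.size < 3:
        raise ValueError("need a 1D series of at least 3 frames")
    if np.ptp(areas) == 0:
        raise UndefinedPhaseError("constant cavity-area series: phase undefined")
    n = areas.size
    ed = int(np.argmax(areas))
    es = int(np.argmin(areas))
    off = (np.arange(n) - ed) % n
    es_off = (es - ed) % n
    return ((off >= 1) & (off <= es_off)).astype(int)


def indices_from_mask(masks, spacing: float = DEFAULT_SPACING,
                      step: float = 0.1) -> list[IndexVector]:
    """Per-frame IndexVectors for a (T, H, W) stack of 3-class masks.

    This is the direct morphological "calculation" model: every index is
    measured from the segmentation alone; the phase comes from the
    cavity-area series across frames.
    """
    stack = np.asarray(masks)
    if stack.ndim != 3:
        raise ValueError("expected a (frames, H, W) mask stack")
    out = []
    for t in range(stack.shape[0]):
        try:
            a_cav, a_myo = areas_from_mask(stack[t])
            dims = cavity_dimensions(stack[t], step)
            rwt = regional_wall_thickness(stack[t], step)
        except (DegenerateMaskError, ValueError) as e:
            raise DegenerateMaskError(f"frame {t}: {e}") from e
        out.append(IndexVector(a_cav, a_myo, dims, rwt))
    phases = phase_from_areas([iv.area_cav for iv in out])
    for iv, p in zip(out, phases):
        iv.phase = int(p)
    return out
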