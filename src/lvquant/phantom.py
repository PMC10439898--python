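"""Synthetic beating-LV phantom: cine frames, 3-class masks, exact indices.

The phantom is a continuous geometric model of a mid-cavity short-axis slice:
an endocardial boundary r_endo(t, theta) and an epicardial boundary
r_epi = r_endo + wall(t, theta) around a fixed center.

* Contraction: the base endocardial radius follows a raised-cosine profile
  between its end-diastolic value (frame 0) and its end-systolic value
  (frame ``es_frame``), cyclic over the ``n_frames`` cycle, so the cavity
  area series has exactly one minimum.
* Wall: six nodal thicknesses (one per anatomical segment, at the segment
  bisector angles shared with :mod:`lvquant.geometry`) interpolated over
  angle by trigonometric (Fourier) interpolation, so the thickness at each
  bisector is exactly the nodal value; walls thicken toward end-systole.
* Shape: low-order angular Fourier perturbations (orders >= 2, so the
  centroid stays at the center to first order) break circularity.
* Appearance: three class mean grey levels (bright blood pool), an optional
  multiplicative low-frequency bias field and additive Gaussian noise.

Because the model is continuous, every index (areas by quadrature of
r^2 / 2, dimensions and wall thicknesses in closed form at the ray angles)
is known exactly, independent of rasterization — the masks are rendered by
pixel-center classification and the true indices come from the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import (DEFAULT_SPACING, INDEX_NAMES, SEGMENT_ANGLES,
                       SEGMENT_NAMES, DIM_ANGLES, IndexVector,
                       phase_from_areas)

__all__ = ["PhantomSpec", "PhantomSubject", "sample_spec", "boundary_radius",
           "render_subject", "analytic_indices", "analytic_index_table",
           "generate_dataset", "CSV_COLUMNS"]

CSV_COLUMNS = ("frame",) + INDEX_NAMES + ("phase",)

#: angles of the six wall-thickness nodes in FFT order (equally spaced,
#: starting at AL = 30 deg): AL, A, AS, IS, I, IL
_NODE_ORDER = ("AL", "A", "AS", "IS", "I", "IL")
_NODE_START = SEGMENT_ANGLES["AL"]
#: index of each canonical segment (IS..AS) in the FFT node order
_SEG_TO_NODE = tuple(_NODE_ORDER.index(s) for s in SEGMENT_NAMES)


@dataclass
class PhantomSpec:
    """Parametric description of one synthetic beating LV."""

    image_size: int = 80
    n_frames: int = 20
    center: tuple[float, float] = (39.5, 39.5)
    r_endo_ed: float = 18.0
    r_endo_es: float = 12.0
    wall_ed: np.ndarray = field(default_factory=lambda: np.full(6, 7.0))
    wall_es: np.ndarray = field(default_factory=lambda: np.full(6, 9.5))
    shape_fourier: np.ndarray = field(default_factory=lambda: np.zeros(2))
    shape_phase: np.ndarray = field(default_factory=lambda: np.zeros(2))
    es_frame: int = 9
    intensity: tuple[float, float, float] = (0.2, 0.45, 0.8)  # bg, myo, cavity
    noise_sigma: float = 0.0
    bias_amp: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.wall_ed = np.asarray(self.wall_ed, dtype=float)
        self.wall_es = np.asarray(self.wall_es, dtype=float)
        self.shape_fourier = np.asarray(self.shape_fourier, dtype=float)
        self.shape_phase = np.asarray(self.shape_phase, dtype=float)
        if self.wall_ed.shape != (6,) or self.wall_es.shape != (6,):
            raise ValueError("wall_ed / wall_es must have 6 segment values")
        if not self.r_endo_es < self.r_endo_ed:
            raise ValueError("endocardial radius must shrink toward end-systole")
        if not (self.wall_es >= self.wall_ed).all():
            raise ValueError("wall must thicken (or hold) toward end-systole")
        if not 0 < self.es_frame < self.n_frames:
            raise ValueError("es_frame must lie strictly inside the cycle")
        if np.abs(self.shape_fourier).sum() > 0.25:
            raise ValueError("shape perturbation too large")
        # fits-in-frame: dense angular/temporal check of the epicardial radius
        ang = np.linspace(0.0, 2 * np.pi, 360, endpoint=False)
        for t in range(self.n_frames):
            r_epi = boundary_radius(self, t, ang, "epi")
            if r_epi.max() + 1.0 >= self.image_size / 2.0:
                raise ValueError("phantom does not fit in the frame")


@dataclass
class PhantomSubject:
    spec: PhantomSpec
    images: np.ndarray          # (n_frames, H, W) float
    masks: np.ndarray           # (n_frames, H, W) int, classes {0,1,2}
    truth: list                 # n_frames IndexVector records
    subject_id: str = "subject"


def _contraction_fraction(spec: PhantomSpec, frame: int | np.ndarray) -> np.ndarray:
    """Raised-cosine fraction: 0 at frame 0 (ED), 1 at es_frame (ES), cyclic."""
    t = np.asarray(frame, dtype=float) % spec.n_frames
    es, n = float(spec.es_frame), float(spec.n_frames)
    down = 0.5 * (1.0 - np.cos(np.pi * t / es))             # t in [0, es]
    up = 0.5 * (1.0 + np.cos(np.pi * (t - es) / (n - es)))  # t in [es, n]
    return np.where(t <= es, down, up)


def _trig_interp_coeffs(values: np.ndarray) -> np.ndarray:
    """FFT coefficients for trigonometric interpolation through 6 nodes."""
    return np.fft.fft(np.asarray(values, dtype=float)) / 6.0


def _trig_interp_eval(coeffs: np.ndarray, theta) -> np.ndarray:
    """Evaluate the 6-node trigonometric interpolant at angle(s) theta."""
    u = np.asarray(theta, dtype=float) - _NODE_START
    out = np.full_like(u, coeffs[0].real)
    for m in (1, 2):
        out = out + 2.0 * (coeffs[m].real * np.cos(m * u)
                           - coeffs[m].imag * np.sin(m * u))
    out = out + coeffs[3].real * np.cos(3.0 * u)
    return out


def _wall_thickness(spec: PhantomSpec, frame: int, theta) -> np.ndarray:
    alpha = float(_contraction_fraction(spec, frame))
    nodal = spec.wall_ed + alpha * (spec.wall_es - spec.wall_ed)   # IS..AS order
    node_vals = nodal[list(_SEG_TO_NODE)]                          # FFT order
    return _trig_interp_eval(_trig_interp_coeffs(node_vals), theta)


def _shape_factor(spec: PhantomSpec, theta) -> np.ndarray:
    th = np.asarray(theta, dtype=float)
    f = np.ones_like(th)
    for i, (amp, ph) in enumerate(zip(spec.shape_fourier, spec.shape_phase)):
        m = i + 2   # orders start at 2: no first-order centroid shift
        f = f + amp * np.cos(m * th + ph)
    return f


def boundary_radius(spec: PhantomSpec, frame: int, angle, surface: str):
    """Radius of the endo- or epicardial boundary at (frame, angle), pixels."""
    if not 0 <= frame < spec.n_frames:
        raise ValueError(f"frame {frame} out of range [0, {spec.n_frames})")
    alpha = float(_contraction_fraction(spec, frame))
    base = spec.r_endo_ed + alpha * (spec.r_endo_es - spec.r_endo_ed)
    r_endo = base * _shape_factor(spec, angle)
    if surface == "endo":
        return r_endo
    if surface == "epi":
        return r_endo + _wall_thickness(spec, frame, angle)
    raise ValueError("surface must be 'endo' or 'epi'")


def sample_spec(rng: np.random.Generator, difficulty: str = "realistic") -> PhantomSpec:
    """Draw a valid phantom spec.

    ``easy``: concentric circles (zero shape perturbation), uniform wall,
    no noise, no bias.  ``realistic``: per-segment wall asymmetry, angular
    shape perturbation, noise, bias field and an off-center LV.
    """
    if difficulty not in ("easy", "realistic"):
        raise ValueError("difficulty must be 'easy' or 'realistic'")
    for _ in range(100):
        seed = int(rng.integers(0, 2**31 - 1))
        if difficulty == "easy":
            r_ed = float(rng.uniform(14.0, 22.0))
            r_es = r_ed * float(rng.uniform(0.55, 0.75))
        else:
            r_ed = float(rng.uniform(11.0, 21.0))
            r_es = r_ed * float(rng.uniform(0.5, 0.78))
        es_frame = int(rng.integers(8, 13))
        if difficulty == "easy":
            wall_ed = np.full(6, float(rng.uniform(5.0, 9.0)))
            wall_es = wall_ed + float(rng.uniform(1.5, 3.5))
            kwargs = dict(center=(39.5, 39.5), shape_fourier=np.zeros(2),
                          shape_phase=np.zeros(2), noise_sigma=0.0, bias_amp=0.0)
        else:
            # wall population spans the clinical range (thin dilated walls to
            # hypertrophic segments) with proportional systolic thickening
            base = float(rng.uniform(3.5, 11.5))
            wall_ed = np.clip(base + rng.uniform(-2.2, 2.2, 6), 2.8, 13.5)
            wall_es = wall_ed * rng.uniform(1.1, 1.6, 6)
            kwargs = dict(
                center=(39.5 + float(rng.uniform(-3, 3)),
                        39.5 + float(rng.uniform(-3, 3))),
                shape_fourier=rng.uniform(0.0, 0.06, 2),
                shape_phase=rng.uniform(0.0, 2 * np.pi, 2),
                noise_sigma=float(rng.uniform(0.02, 0.06)),
                bias_amp=float(rng.uniform(0.05, 0.2)),
            )
        try:
            return PhantomSpec(r_endo_ed=r_ed, r_endo_es=r_es, wall_ed=wall_ed,
                               wall_es=wall_es, es_frame=es_frame, seed=seed,
                               **kwargs)
        except ValueError:
            continue   # resample until the phantom fits in the frame
    raise RuntimeError("could not sample a valid phantom spec")


def _quadrature_angles(n: int = 2048) -> np.ndarray:
    return np.linspace(0.0, 2 * np.pi, n, endpoint=False)


def analytic_index_table(spec: PhantomSpec) -> list[IndexVector]:
    """Exact IndexVectors for every frame, from the continuous model.

    Areas are 0.5 * integral(r^2 dtheta), computed by periodic trapezoid
    quadrature (spectrally accurate for these smooth boundaries); dimensions
    and wall thicknesses are closed-form evaluations at the ray angles.
    """
    ang = _quadrature_angles()
    dtheta = 2 * np.pi / ang.size
    h = float(spec.image_size)
    out = []
    for t in range(spec.n_frames):
        r_endo = boundary_radius(spec, t, ang, "endo")
        r_epi = boundary_radius(spec, t, ang, "epi")
        a_cav = 0.5 * np.sum(r_endo ** 2) * dtheta / (h * h)
        a_myo = 0.5 * np.sum(r_epi ** 2 - r_endo ** 2) * dtheta / (h * h)
        dims = np.array([
            (boundary_radius(spec, t, a, "endo")
             + boundary_radius(spec, t, a + np.pi, "endo")) / h
            for a in DIM_ANGLES])
        rwt = np.array([
            (boundary_radius(spec, t, SEGMENT_ANGLES[s], "epi")
             - boundary_radius(spec, t, SEGMENT_ANGLES[s], "endo")) / h
            for s in SEGMENT_NAMES])
        out.append(IndexVector(float(a_cav), float(a_myo), dims, rwt))
    phases = phase_from_areas([iv.area_cav for iv in out])
    for iv, p in zip(out, phases):
        iv.phase = int(p)
    return out


def analytic_indices(spec: PhantomSpec, frame: int) -> IndexVector:
    """Exact IndexVector of one frame (phase from the whole-cycle area series)."""
    if not 0 <= frame < spec.n_frames:
        raise ValueError(f"frame {frame} out of range [0, {spec.n_frames})")
    return analytic_index_table(spec)[frame]


def render_subject(spec: PhantomSpec, subject_id: str = "subject") -> PhantomSubject:
    """Rasterize masks by pixel-center classification and synthesize images."""
    h = spec.image_size
    rows, cols = np.mgrid[0:h, 0:h].astype(float)
    dr, dc = rows - spec.center[0], cols - spec.center[1]
    rad = np.hypot(dr, dc)
    # geometry.direction: d_row = -sin(theta), d_col = cos(theta)
    theta = np.arctan2(-dr, dc)
    rng = np.random.default_rng(spec.seed)
    # one fixed bias field per subject
    ph_r, ph_c = rng.uniform(0, 2 * np.pi, 2)
    bias = 1.0 + spec.bias_amp * np.cos(2 * np.pi * rows / h + ph_r) \
        * np.cos(2 * np.pi * cols / h + ph_c)
    bg, myo, cav = spec.intensity
    masks = np.empty((spec.n_frames, h, h), dtype=np.uint8)
    images = np.empty((spec.n_frames, h, h), dtype=np.float32)
    for t in range(spec.n_frames):
        r_endo = boundary_radius(spec, t, theta, "endo")
        r_epi = boundary_radius(spec, t, theta, "epi")
        m = np.zeros((h, h), dtype=np.uint8)
        m[rad < r_epi] = 2
        m[rad < r_endo] = 1
        masks[t] = m
        img = np.where(m == 1, cav, np.where(m == 2, myo, bg))
        img = img * bias
        if spec.noise_sigma > 0:
            img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
        images[t] = np.clip(img, 0.0, 1.0).astype(np.float32)
    truth = analytic_index_table(spec)
    return PhantomSubject(spec, images, masks, truth, subject_id)


def truth_frame(iv: IndexVector, frame: int) -> dict:
    row = {"frame": frame}
    row.update(dict(zip(INDEX_NAMES, iv.to_array())))
    row["phase"] = iv.phase
    return row


def generate_dataset(n_subjects: int, rng: np.random.Generator,
                     difficulty: str = "realistic",
                     out_dir: str | Path | None = None) -> list[PhantomSubject]:
    """Generate subjects and (optionally) write the on-disk dataset layout.

    Layout: one directory per subject with ``images.npz`` (keys ``images``
    float (20, H, W) and ``masks`` integer (20, H, W)) and ``indices.csv``
    with columns frame, the 11 indices, and phase.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    subjects = []
    for i in range(n_subjects):
        sid = f"subject_{i:03d}"
        spec = sample_spec(rng, difficulty)
        subjects.append(render_subject(spec, sid))
    if out_dir is not None:
        out_dir = Path(out_dir)
        for subj in subjects:
            d = out_dir / subj.subject_id
            d.mkdir(parents=True, exist_ok=True)
            np.savez(d / "images.npz", images=subj.images, masks=subj.masks)
            rows = [truth_frame(iv, t) for t, iv in enumerate(subj.truth)]
            df = pd.DataFrame(rows, columns=list(CSV_COLUMNS))
            df.to_csv(d / "indices.csv", index=False, float_format="%.10g")
    return subjects
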