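"""Evaluation metrics and report assembly.

Segmentation quality: per-class Dice overlap and symmetric Hausdorff
distance between boundary pixels.  Quantification quality: per-index mean
absolute error (normalized and in physical units), Pearson correlation
pooled across every evaluated frame, and the cardiac-phase error rate
(fraction of misclassified frames).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .geometry import (BACKGROUND, CAVITY, DEFAULT_SPACING, INDEX_NAMES,
                       MYOCARDIUM, DegenerateMaskError)

__all__ = ["MetricReport", "dice_coef", "boundary_points", "hausdorff",
           "mae", "pcc", "phase_error_rate", "evaluate"]

CLASS_NAMES = {BACKGROUND: "background", CAVITY: "cavity", MYOCARDIUM: "myocardium"}
# indices 0-1 are areas, 2-10 lengths (3 dims + 6 RWT)
_AREA_INDICES = ("area_cav", "area_myo")


@dataclass
class MetricReport:
    """Evaluation summary; all values are plain floats for serialization."""

    dice: dict = field(default_factory=dict)            # class name -> value
    hausdorff_px: dict = field(default_factory=dict)    # class name -> pixels
    hausdorff_mm: dict = field(default_factory=dict)    # class name -> mm
    mae_norm: dict = field(default_factory=dict)        # index name -> normalized
    mae_phys: dict = field(default_factory=dict)        # index name -> mm or mm^2
    pcc: dict = field(default_factory=dict)             # index name -> value
    phase_error_rate: float = 0.0
    n_frames: int = 0
    spacing: float = DEFAULT_SPACING

    def __post_init__(self):
        for v in self.dice.values():
            if not 0.0 <= v <= 1.0 + 1e-12:
                raise ValueError(f"dice out of [0, 1]: {v}")
        for v in self.hausdorff_px.values():
            if v < 0:
                raise ValueError("hausdorff must be non-negative")
        for v in self.pcc.values():
            if not -1.0 - 1e-12 <= v <= 1.0 + 1e-12:
                raise ValueError(f"pcc out of [-1, 1]: {v}")
        if not 0.0 <= self.phase_error_rate <= 1.0:
            raise ValueError("phase error rate must be a fraction")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "dice": dict(self.dice),
            "hausdorff_px": dict(self.hausdorff_px),
            "hausdorff_mm": dict(self.hausdorff_mm),
            "mae_norm": dict(self.mae_norm),
            "mae_phys": dict(self.mae_phys),
            "pcc": dict(self.pcc),
            "phase_error_rate": float(self.phase_error_rate),
            "n_frames": int(self.n_frames),
            "spacing": float(self.spacing),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MetricReport":
        return cls(dice=dict(d["dice"]), hausdorff_px=dict(d["hausdorff_px"]),
                   hausdorff_mm=dict(d["hausdorff_mm"]),
                   mae_norm=dict(d["mae_norm"]), mae_phys=dict(d["mae_phys"]),
                   pcc=dict(d["pcc"]),
                   phase_error_rate=float(d["phase_error_rate"]),
                   n_frames=int(d["n_frames"]), spacing=float(d["spacing"]))

    def save_json(self, path):
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load_json(cls, path) -> "MetricReport":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_frame(self) -> pd.DataFrame:
        """Long-form table: one row per (group, name, value)."""
        rows = []
        for group in ("dice", "hausdorff_px", "hausdorff_mm",
                      "mae_norm", "mae_phys", "pcc"):
            for name, value in getattr(self, group).items():
                rows.append({"group": group, "name": name, "value": value})
        rows.append({"group": "phase", "name": "error_rate",
                     "value": self.phase_error_rate})
        rows.append({"group": "meta", "name": "n_frames", "value": self.n_frames})
        rows.append({"group": "meta", "name": "spacing", "value": self.spacing})
        return pd.DataFrame(rows, columns=["group", "name", "value"])

    def save_csv(self, path):
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def load_csv(cls, path) -> "MetricReport":
        df = pd.read_csv(path)
        kw = {g: {} for g in ("dice", "hausdorff_px", "hausdorff_mm",
                              "mae_norm", "mae_phys", "pcc")}
        meta = {}
        for _, row in df.iterrows():
            if row["group"] in kw:
                kw[row["group"]][row["name"]] = float(row["value"])
            elif row["group"] == "phase":
                meta["phase_error_rate"] = float(row["value"])
            elif row["group"] == "meta":
                meta[row["name"]] = float(row["value"])
        return cls(phase_error_rate=meta.get("phase_error_rate", 0.0),
                   n_frames=int(meta.get("n_frames", 0)),
                   spacing=meta.get("spacing", DEFAULT_SPACING), **kw)

    def summary(self) -> str:
        lines = [f"frames evaluated: {self.n_frames}  (spacing {self.spacing} mm)"]
        if self.dice:
            lines.append("Dice:        " + "  ".join(
                f"{k}={v:.4f}" for k, v in self.dice.items()))
        if self.hausdorff_px:
            lines.append("Hausdorff:   " + "  ".join(
                f"{k}={v:.2f}px" for k, v in self.hausdorff_px.items()))
        if self.mae_norm:
            lines.append("MAE (norm):  " + "  ".join(
                f"{k}={v:.4f}" for k, v in self.mae_norm.items()))
        if self.pcc:
            lines.append("PCC:         " + "  ".join(
                f"{k}={v:.3f}" for k, v in self.pcc.items()))
        lines.append(f"phase error rate: {self.phase_error_rate:.3f}")
        return "\n".join(lines)


# -- individual metrics ----------------------------------------------------

def dice_coef(a, b) -> float:
    """2|A∩B| / (|A|+|B|) for boolean regions; empty vs empty -> 1."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("regions must share one grid")
    sa, sb = int(a.sum()), int(b.sum())
    if sa == 0 and sb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (sa + sb)


def boundary_points(region) -> np.ndarray:
    """Pixels of a boolean region with at least one differing 4-neighbor.

    Pixels on the image border count as boundary (the outside differs).
    Returns an (n, 2) array of (row, col) coordinates.
    """
    r = np.asarray(region, dtype=bool)
    if r.ndim != 2:
        raise ValueError("expected a 2D region")
    padded = np.pad(r, 1, constant_values=False)
    interior = (padded[:-2, 1:-1] & padded[2:, 1:-1]
                & padded[1:-1, :-2] & padded[1:-1, 2:])
    return np.argwhere(r & ~interior)


def hausdorff(a_points, b_points) -> float:
    """Symmetric Hausdorff distance between two point sets (Euclidean)."""
    a = np.asarray(a_points, dtype=float)
    b = np.asarray(b_points, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DegenerateMaskError("hausdorff needs two non-empty point sets")
    a = a.reshape(len(a), -1)
    b = b.reshape(len(b), -1)
    d = cdist(a, b)
    return float(max(d.min(axis=1).max(), d.min(axis=0).max()))


def mae(pred, target) -> float:
    """Mean absolute difference between two equal-length series."""
    p = np.asarray(pred, dtype=float)
    t = np.asarray(target, dtype=float)
    if p.shape != t.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {t.shape}")
    if p.size == 0:
        raise ValueError("empty series")
    return float(np.mean(np.abs(p - t)))


def pcc(pred, target) -> float:
    """Pearson correlation between two series (each centered by its own mean)."""
    p = np.asarray(pred, dtype=float).ravel()
    t = np.asarray(target, dtype=float).ravel()
    if p.shape != t.shape:
        raise ValueError("length mismatch")
    if p.size < 2:
        raise ValueError("correlation needs at least 2 points")
    dp, dt = p - p.mean(), t - t.mean()
    denom = np.sqrt((dp * dp).sum() * (dt * dt).sum())
    if denom == 0:
        raise ValueError("undefined correlation: constant series")
    return float((dp * dt).sum() / denom)


def phase_error_rate(pred_labels, target_labels) -> float:
    """Fraction of frames whose binary phase label is misclassified."""
    p = np.asarray(pred_labels)
    t = np.asarray(target_labels)
    if p.shape != t.shape:
        raise ValueError("length mismatch")
    if p.size == 0:
        raise ValueError("empty label series")
    return float(np.mean(p != t))


# -- report assembly -------------------------------------------------------

def _physical_factor(index_name: str, h: int, w: int, spacing: float) -> float:
    if index_name in _AREA_INDICES:
        return h * w * spacing * spacing      # normalized area -> mm^2
    return h * spacing                        # normalized length -> mm


def evaluate(pred_masks, true_masks, pred_indices, true_indices,
             pred_phase, true_phase, spacing: float = DEFAULT_SPACING,
             skip_degenerate_hausdorff: bool = False) -> MetricReport:
    """Assemble a MetricReport from aligned per-frame predictions and truth.

    `*_masks` are (n, H, W) 3-class fields (or None to skip segmentation
    metrics); `*_indices` are (n, 11) arrays in canonical order (or None);
    `*_phase` are (n,) binary labels (or None).  Dice and Hausdorff pool
    over frames by the mean; MAE and PCC pool per index over all frames.
    """
    report = MetricReport(spacing=spacing)
    n_frames = 0
    if pred_masks is not None:
        pm = np.asarray(pred_masks)
        tm = np.asarray(true_masks)
        if pm.shape != tm.shape or pm.ndim != 3:
            raise ValueError("mask stacks must be (n, H, W) and aligned")
        n_frames = pm.shape[0]
        h, w = pm.shape[1:]
        for cls, name in CLASS_NAMES.items():
            if cls == BACKGROUND:
                continue
            dices, hds = [], []
            for k in range(n_frames):
                a, b = pm[k] == cls, tm[k] == cls
                dices.append(dice_coef(a, b))
                try:
                    hds.append(hausdorff(boundary_points(a), boundary_points(b)))
                except DegenerateMaskError:
                    if not skip_degenerate_hausdorff:
                        raise
            report.dice[name] = float(np.mean(dices))
            if hds:
                report.hausdorff_px[name] = float(np.mean(hds))
                report.hausdorff_mm[name] = float(np.mean(hds) * spacing)
    if pred_indices is not None:
        pi = np.asarray(pred_indices, dtype=float)
        ti = np.asarray(true_indices, dtype=float)
        if pi.shape != ti.shape or pi.ndim != 2 or pi.shape[1] != len(INDEX_NAMES):
            raise ValueError("index tables must be aligned (n, 11) arrays")
        n_frames = max(n_frames, pi.shape[0])
        if pred_masks is not None:
            h, w = np.asarray(pred_masks).shape[1:]
        else:
            h = w = 80
        for j, name in enumerate(INDEX_NAMES):
            report.mae_norm[name] = mae(pi[:, j], ti[:, j])
            report.mae_phys[name] = report.mae_norm[name] * \
                _physical_factor(name, h, w, spacing)
            report.pcc[name] = pcc(pi[:, j], ti[:, j])
    if pred_phase is not None:
        report.phase_error_rate = phase_error_rate(pred_phase, true_phase)
        n_frames = max(n_frames, np.asarray(pred_phase).size)
    report.n_frames = n_frames
    return report
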