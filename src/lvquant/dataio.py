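"""File I/O: subject datasets, NIfTI/PNG interchange, run configuration.

On-disk subject layout (one directory per subject)::

    subject_000/
        images.npz    keys: images (n, H, W) float, masks (n, H, W) int
        indices.csv   columns: frame, the 11 indices, phase

Interchange formats: NIfTI for volumetric stacks, single-channel PNG label
maps with class codes {0, 1, 2}, CSV index tables, YAML run configuration.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .geometry import (BACKGROUND, CAVITY, DEFAULT_SPACING, INDEX_NAMES,
                       MYOCARDIUM, IndexVector)
from .losses import LossWeights
from .phantom import CSV_COLUMNS
from .reg_path import RegConfig
from .seg_path import SegConfig
from .trainer import TrainConfig

__all__ = ["SchemaError", "SubjectData", "load_subject", "save_subject",
           "indices_to_frame", "frame_to_indices", "save_indices_csv",
           "load_indices_csv", "export_nifti", "import_nifti",
           "save_mask_png", "load_mask_png", "RunConfig"]


class SchemaError(ValueError):
    """A dataset file violates the documented layout."""


@dataclass
class SubjectData:
    """One subject as loaded from disk (the training duck type)."""

    subject_id: str
    images: np.ndarray          # (n, H, W) float
    masks: np.ndarray           # (n, H, W) int classes {0,1,2}
    truth: list                 # n IndexVector records


# -- index tables ------------------------------------------------------------

def indices_to_frame(truth: list) -> pd.DataFrame:
    """IndexVector records -> the canonical indices.csv table."""
    rows = []
    for t, iv in enumerate(truth):
        row = {"frame": t}
        row.update(dict(zip(INDEX_NAMES, iv.to_array())))
        row["phase"] = iv.phase
        rows.append(row)
    return pd.DataFrame(rows, columns=list(CSV_COLUMNS))


def frame_to_indices(df: pd.DataFrame) -> list:
    """The canonical indices table -> IndexVector records (frame order)."""
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"indices table missing column(s): {', '.join(missing)}")
    df = df.sort_values("frame").reset_index(drop=True)
    frames = df["frame"].to_numpy()
    if not np.array_equal(frames, np.arange(len(df))):
        raise SchemaError("column 'frame' must enumerate 0..n-1 exactly once")
    out = []
    for _, row in df.iterrows():
        values = np.array([row[name] for name in INDEX_NAMES], dtype=float)
        phase = int(row["phase"])
        if phase not in (0, 1):
            raise SchemaError(f"column 'phase' must be binary, got {row['phase']}")
        out.append(IndexVector.from_array(values, phase=phase))
    return out


def save_indices_csv(truth: list, path):
    indices_to_frame(truth).to_csv(path, index=False, float_format="%.10g")


def load_indices_csv(path) -> list:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"missing indices file: {path}")
    return frame_to_indices(pd.read_csv(path))


# -- subject directories -----------------------------------------------------

def load_subject(path, expected_frames: int = 20) -> SubjectData:
    """Read one subject directory, validating the documented layout."""
    path = Path(path)
    npz_path = path / "images.npz"
    if not npz_path.exists():
        raise SchemaError(f"missing file: {npz_path}")
    with np.load(npz_path) as z:
        for key in ("images", "masks"):
            if key not in z:
                raise SchemaError(f"{npz_path}: missing array '{key}'")
        images = np.asarray(z["images"], dtype=np.float32)
        masks = np.asarray(z["masks"])
    if images.ndim != 3:
        raise SchemaError(f"array 'images': expected (frames, H, W), got {images.shape}")
    if expected_frames and images.shape[0] != expected_frames:
        raise SchemaError(f"array 'images': expected {expected_frames} frames, "
                          f"got {images.shape[0]}")
    if images.shape[1] != images.shape[2]:
        raise SchemaError(f"array 'images': frames must be square, got {images.shape}")
    if masks.shape != images.shape:
        raise SchemaError(f"array 'masks': shape {masks.shape} does not match "
                          f"images {images.shape}")
    if not np.isin(masks, (BACKGROUND, CAVITY, MYOCARDIUM)).all():
        raise SchemaError("array 'masks': class codes must be in {0, 1, 2}")
    truth = load_indices_csv(path / "indices.csv")
    if len(truth) != images.shape[0]:
        raise SchemaError(f"indices.csv: {len(truth)} rows for "
                          f"{images.shape[0]} frames")
    return SubjectData(path.name, images, masks.astype(np.uint8), truth)


def save_subject(subject, out_dir) -> Path:
    """Write one subject in the canonical directory layout."""
    d = Path(out_dir) / subject.subject_id
    d.mkdir(parents=True, exist_ok=True)
    np.savez(d / "images.npz", images=np.asarray(subject.images),
             masks=np.asarray(subject.masks))
    save_indices_csv(subject.truth, d / "indices.csv")
    return d


def load_dataset(root, expected_frames: int = 20) -> list:
    """All subject directories under `root`, sorted by name."""
    root = Path(root)
    if not root.is_dir():
        raise SchemaError(f"dataset directory not found: {root}")
    dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not dirs:
        raise SchemaError(f"no subject directories under {root}")
    return [load_subject(p, expected_frames) for p in dirs]


# -- volumetric / image interchange ------------------------------------------

def export_nifti(stack: np.ndarray, path, spacing: float = DEFAULT_SPACING):
    """(n, H, W) stack -> NIfTI with in-plane spacing in mm (frames on axis 2)."""
    arr = np.asarray(stack)
    if arr.ndim != 3:
        raise ValueError("expected an (n, H, W) stack")
    vol = np.ascontiguousarray(arr.transpose(1, 2, 0))
    affine = np.diag([spacing, spacing, 1.0, 1.0])
    img = nib.Nifti1Image(vol.astype(np.float64), affine)
    nib.save(img, str(path))


def import_nifti(path) -> np.ndarray:
    """NIfTI written by `export_nifti` -> the original (n, H, W) stack."""
    img = nib.load(str(path))
    vol = np.asarray(img.dataobj)
    return np.ascontiguousarray(vol.transpose(2, 0, 1))


def save_mask_png(mask: np.ndarray, path):
    """Single-channel PNG with raw class codes {0, 1, 2}."""
    m = np.asarray(mask)
    if not np.isin(m, (BACKGROUND, CAVITY, MYOCARDIUM)).all():
        raise ValueError("mask may only contain class codes {0, 1, 2}")
    iio.imwrite(str(path), m.astype(np.uint8))


def load_mask_png(path) -> np.ndarray:
    m = np.asarray(iio.imread(str(path)))
    if m.ndim != 2:
        raise SchemaError(f"{path}: expected a single-channel label map")
    if not np.isin(m, (BACKGROUND, CAVITY, MYOCARDIUM)).all():
        raise SchemaError(f"{path}: pixel values must be class codes {{0, 1, 2}}")
    return m.astype(np.uint8)


# -- run configuration -------------------------------------------------------

@dataclass
class RunConfig:
    """One YAML-configurable run: data source, module settings, outputs."""

    seed: int = 0
    out_dir: str = "runs/out"
    data_dir: str | None = None      # existing dataset; None = simulate
    n_subjects: int = 20             # phantom generation parameters
    difficulty: str = "realistic"
    spacing: float = DEFAULT_SPACING
    small: bool = True               # desk-scale module configs as the base
    seg: dict = field(default_factory=dict)     # SegConfig overrides
    reg: dict = field(default_factory=dict)     # RegConfig overrides
    train: dict = field(default_factory=dict)   # TrainConfig overrides
    loss: dict = field(default_factory=dict)    # LossWeights overrides
    apply_clahe: bool = True
    verbosity: int = 1

    def __post_init__(self):
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        if self.difficulty not in ("easy", "realistic"):
            raise ValueError("difficulty must be 'easy' or 'realistic'")
        if self.data_dir is not None and not Path(self.data_dir).is_dir():
            raise SchemaError(f"data_dir does not exist: {self.data_dir}")

    # typed module configs --------------------------------------------------

    def seg_config(self) -> SegConfig:
        base = SegConfig.small() if self.small else SegConfig()
        return replace(base, **self.seg)

    def reg_config(self) -> RegConfig:
        base = RegConfig.small() if self.small else RegConfig()
        return replace(base, **self.reg)

    def train_config(self) -> TrainConfig:
        base = TrainConfig.small() if self.small else TrainConfig()
        overrides = dict(self.train)
        loss = LossWeights(**self.loss) if self.loss else base.loss_weights
        return replace(base, seed=self.seed, loss_weights=loss, **overrides)

    # YAML roundtrip ---------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def save_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise SchemaError(f"{path}: expected a mapping at the top level")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"{path}: unknown key(s): {', '.join(sorted(unknown))}")
        return cls(**raw)
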