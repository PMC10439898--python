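"""Joint training of the two-path quantification network.

The unified model couples the segmentation path (logits + multi-scale
decoder features) with the regression path (11 indices + phase), trained
end to end on the joint objective.  Two optimizers run simultaneously on
disjoint parameter groups: a rectified-Adam optimizer on the segmentation
path (exponential learning-rate decay per epoch) and momentum SGD on the
regression path, whose SE-fusion blocks live inside the regression group.

Cross-validation splits at the subject level, so no subject appears in
both the training and test side of a fold.
"""

from __future__ import annotations

import pickle
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .autodiff import Tensor, no_grad, softmax
from . import geometry
from .geometry import DEFAULT_SPACING, DegenerateMaskError, UndefinedPhaseError
from .losses import (LossWeights, phase_probability, reg_loss, seg_loss,
                     unified_loss)
from .metrics import MetricReport, evaluate
from .preprocess import (AugmentConfig, InputWindow, augment,
                         preprocess_subject_images, temporal_window)
from .reg_path import RegConfig, RegPath
from .seg_path import SegConfig, SegPath

__all__ = ["TrainConfig", "UnifiedModel", "build_training_windows",
           "make_folds", "train", "predict_subject", "decode_cyclic_phase",
           "cross_validate",
           "save_checkpoint", "load_checkpoint"]


@dataclass
class TrainConfig:
    """Optimization settings; the defaults mirror the reference protocol."""

    epochs: int = 500
    batch_size: int = 20
    folds: int = 5
    seed: int = 0
    # segmentation-path optimizer (rectified Adam)
    seg_lr: float = 5e-4
    seg_betas: tuple = (0.9, 0.999)
    seg_weight_decay: float = 1e-4
    seg_lr_decay: float = 0.99          # multiplicative, per epoch
    # regression-path optimizer (momentum SGD)
    reg_lr: float = 5e-4
    reg_momentum: float = 0.06
    reg_weight_decay: float = 5e-3
    # schedule / plumbing
    steps_per_epoch: int | None = None  # None = one full pass over windows
    seg_warmup_epochs: int = 0          # joint from the start by default
    stop_gradient: bool = False         # detach fused features if True
    augment: bool = False
    augment_config: AugmentConfig = field(default_factory=AugmentConfig)
    standardize_targets: bool = True    # affine index-target normalization
    loss_weights: LossWeights = field(default_factory=LossWeights)

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1 or self.folds < 2:
            raise ValueError("epochs/batch >= 1 and folds >= 2 required")
        if min(self.seg_lr, self.reg_lr) <= 0:
            raise ValueError("learning rates must be positive")
        if not 0 < self.seg_lr_decay <= 1:
            raise ValueError("lr decay must lie in (0, 1]")

    @classmethod
    def small(cls, epochs: int = 15, steps_per_epoch: int | None = 26) -> "TrainConfig":
        """Desk-scale CPU profile: small batches (more optimizer updates per
        sample on one CPU), faster learning rates."""
        return cls(epochs=epochs, batch_size=4, folds=2,
                   seg_lr=3e-3, reg_lr=0.05, reg_momentum=0.9,
                   reg_weight_decay=1e-4,
                   steps_per_epoch=steps_per_epoch)


class UnifiedModel(nn.Module):
    """Segmentation path + regression path with feature fusion."""

    def __init__(self, seg_config: SegConfig | None = None,
                 reg_config: RegConfig | None = None,
                 init_rng=None, stop_gradient: bool = False):
        super().__init__()
        if init_rng is not None:
            nn.set_init_rng(init_rng)
        self.seg_config = seg_config or SegConfig()
        self.reg_config = reg_config or RegConfig()
        self.stop_gradient = stop_gradient
        size = self.seg_config.image_size
        d0, d1, d2, d3 = self.seg_config.decoder_channels
        feature_channels = {size // 2: d2, size // 4: d1}
        self.seg = SegPath(self.seg_config)
        self.reg = RegPath(self.reg_config, feature_channels)
        # affine target normalization learned from the training pool; the
        # regression head works in standardized space, predictions are
        # mapped back, so reported indices stay in normalized units
        self.index_mean = np.zeros(self.reg_config.n_indices)
        self.index_std = np.ones(self.reg_config.n_indices)
        self._buffers = ("index_mean", "index_std")

    def set_index_norm(self, mean, std):
        mean = np.asarray(mean, dtype=float)
        std = np.asarray(std, dtype=float)
        if mean.shape != self.index_mean.shape or std.shape != mean.shape:
            raise ValueError("normalization stats must have one value per index")
        if (std <= 0).any():
            raise ValueError("standard deviations must be positive")
        self.index_mean, self.index_std = mean, std

    def standardize_targets(self, y_idx: np.ndarray) -> np.ndarray:
        return (np.asarray(y_idx, dtype=float) - self.index_mean) / self.index_std

    def destandardize_indices(self, y_std: np.ndarray) -> np.ndarray:
        return np.asarray(y_std, dtype=float) * self.index_std + self.index_mean

    def forward(self, window: Tensor):
        """(seg logits, indices, phase logits) for a (B, 1, 5, H, W) batch."""
        logits, feats = self.seg(window)
        if self.stop_gradient:
            feats = {k: Tensor(v.data) for k, v in feats.items()}
        indices, phase_logits = self.reg(window, feats)
        return logits, indices, phase_logits

    def seg_parameters(self):
        return self.seg.parameters()

    def reg_parameters(self):
        return self.reg.parameters()

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


# -- data plumbing ----------------------------------------------------------

def build_training_windows(subject, apply_clahe: bool = True) -> list[InputWindow]:
    """All cyclic 5-frame windows of one subject, preprocessed, with targets.

    `subject` provides ``images`` (n, H, W), ``masks`` (n, H, W) and
    ``truth`` (n IndexVector records) — the phantom subject layout.
    """
    images = preprocess_subject_images(subject.images, apply_clahe=apply_clahe)
    masks = np.asarray(subject.masks)
    return [temporal_window(images, t, masks=masks, indices=subject.truth)
            for t in range(images.shape[0])]


def _one_hot(masks: np.ndarray, n_classes: int = 3) -> np.ndarray:
    return (masks[:, None] == np.arange(n_classes).reshape(1, -1, 1, 1, 1)) \
        .astype(nn.DTYPE)


def _batch_arrays(windows: list[InputWindow]):
    x = np.stack([w.frames for w in windows])[:, None].astype(nn.DTYPE)
    masks = np.stack([w.masks for w in windows])
    y_seg = _one_hot(masks)
    y_idx = np.stack([w.target.to_array() for w in windows]).astype(np.float64)
    y_phase = np.array([w.target.phase for w in windows], dtype=np.float64)
    return x, y_seg, y_idx, y_phase


def make_folds(n_subjects: int, folds: int, rng: np.random.Generator):
    """Subject-level folds: shuffled indices split into `folds` test groups."""
    if not 2 <= folds <= n_subjects:
        raise ValueError("need 2 <= folds <= n_subjects")
    order = rng.permutation(n_subjects)
    parts = np.array_split(order, folds)
    out = []
    for k in range(folds):
        test = np.sort(parts[k])
        train = np.sort(np.concatenate([parts[j] for j in range(folds) if j != k]))
        out.append((train, test))
    return out


# -- training loop ----------------------------------------------------------

def _make_optimizers(model: UnifiedModel, cfg: TrainConfig):
    opt_seg = nn.RAdam(model.seg_parameters(), lr=cfg.seg_lr,
                       betas=cfg.seg_betas, weight_decay=cfg.seg_weight_decay)
    opt_reg = nn.SGD(model.reg_parameters(), lr=cfg.reg_lr,
                     momentum=cfg.reg_momentum,
                     weight_decay=cfg.reg_weight_decay)
    return opt_seg, opt_reg


def train_step(model: UnifiedModel, batch, weights: LossWeights,
               joint: bool = True):
    """One forward/backward pass; returns the per-term loss values."""
    x, y_seg, y_idx, y_phase = batch
    logits, indices, phase_logits = model(Tensor(x))
    probs = softmax(logits, axis=1)
    l_seg = seg_loss(probs, Tensor(y_seg), weights)
    l_reg = reg_loss(indices, Tensor(model.standardize_targets(y_idx)),
                     phase_probability(phase_logits), Tensor(y_phase))
    loss = unified_loss(l_seg, l_reg, weights) if joint \
        else weights.lambda3 * l_seg
    loss.backward()
    vals = {"loss": float(loss.data), "seg": float(l_seg.data),
            "reg": float(l_reg.data)}
    if not np.isfinite(vals["loss"]):
        raise FloatingPointError(f"non-finite training loss: {vals}")
    return vals


def train(model: UnifiedModel, windows: list[InputWindow],
          config: TrainConfig | None = None, log=None,
          optimizers=None, start_epoch: int = 0, rng=None):
    """Train on a pool of windows; returns the per-epoch loss history.

    `optimizers` and `start_epoch` allow resuming from a checkpoint; a
    fresh run derives everything from `config.seed`.
    """
    cfg = config or TrainConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    model.train()
    model.seed_stochastic(rng)
    if optimizers is None and cfg.standardize_targets:
        targets = np.stack([w.target.to_array() for w in windows])
        model.set_index_norm(targets.mean(axis=0),
                             np.maximum(targets.std(axis=0), 1e-3))
    opt_seg, opt_reg = optimizers if optimizers is not None \
        else _make_optimizers(model, cfg)
    history = []
    for epoch in range(start_epoch, cfg.epochs):
        order = rng.permutation(len(windows))
        if cfg.steps_per_epoch is not None:
            order = order[:cfg.steps_per_epoch * cfg.batch_size]
        sums, steps = {"loss": 0.0, "seg": 0.0, "reg": 0.0}, 0
        joint = epoch >= cfg.seg_warmup_epochs
        for lo in range(0, len(order), cfg.batch_size):
            sel = order[lo:lo + cfg.batch_size]
            if len(sel) == 0:
                continue
            batch_windows = [windows[i] for i in sel]
            if cfg.augment:
                batch_windows = [augment(w, rng, cfg.augment_config)
                                 for w in batch_windows]
            vals = train_step(model, _batch_arrays(batch_windows),
                              cfg.loss_weights, joint=joint)
            opt_seg.step()
            opt_reg.step()
            model.zero_grad()
            for k in sums:
                sums[k] += vals[k]
            steps += 1
        opt_seg.lr *= cfg.seg_lr_decay
        entry = {"epoch": epoch,
                 **{k: sums[k] / max(steps, 1) for k in sums}}
        history.append(entry)
        if log is not None:
            log(entry)
    return history, (opt_seg, opt_reg)


# -- inference --------------------------------------------------------------

def decode_cyclic_phase(probs: np.ndarray) -> np.ndarray:
    """Most likely physiologic phase sequence given per-frame P(systole).

    A cardiac cycle contains exactly one contiguous (cyclic) systolic run —
    the frames after end-diastole up to end-systole.  This picks the run
    whose implied labeling maximizes the summed Bernoulli log-likelihood of
    the per-frame probabilities.
    """
    p = np.clip(np.asarray(probs, dtype=np.float64), 1e-7, 1.0 - 1e-7)
    n = p.size
    if n < 3:
        raise ValueError("phase decoding needs at least 3 frames")
    gain = np.log(p) - np.log1p(-p)   # gain of labeling a frame systole
    best_score, best_sel = -np.inf, None
    for start in range(n):            # first systolic frame
        for length in range(1, n):    # systole never covers the whole cycle
            sel = np.arange(start, start + length) % n
            score = gain[sel].sum()
            if score > best_score:
                best_score, best_sel = score, sel
    labels = np.zeros(n, dtype=int)
    labels[best_sel] = 1
    return labels


def predict_subject(model: UnifiedModel, images: np.ndarray,
                    apply_clahe: bool = True, batch_size: int = 10,
                    smooth_phase: bool = False, readout: str = "head"):
    """Per-frame predictions for one subject's full cine stack.

    Returns (masks (n, H, W) uint8 from the center-slice argmax,
    indices (n, 11), phase labels (n,)).

    ``readout`` selects how the final quantification is produced:

    * ``"head"`` (default) — the 11 indices and the phase come from the
      regression path: de-standardized index head outputs and per-frame
      phase argmax.
    * ``"unified"`` — each frame's indices are measured geometrically from
      the predicted segmentation (the same estimator used for ground-truth
      masks); frames whose predicted mask is degenerate fall back to the
      regression head.  The phase comes from the resulting cavity-area
      series (one cyclic systolic run), falling back to the decoded phase
      head if the series is degenerate.  This is what the evaluation
      pipeline and the CLI use.

    With ``smooth_phase``, head-derived phase labels are the physiologic
    decoding of the per-frame probabilities (one cyclic systolic run per
    cycle) instead of the frame-wise argmax.
    """
    if readout not in ("unified", "head"):
        raise ValueError("readout must be 'unified' or 'head'")
    model.eval()
    pre = preprocess_subject_images(np.asarray(images), apply_clahe=apply_clahe)
    n = pre.shape[0]
    windows = [temporal_window(pre, t) for t in range(n)]
    masks, idx, probs = [], [], []
    with no_grad():
        for lo in range(0, n, batch_size):
            chunk = windows[lo:lo + batch_size]
            x = np.stack([w.frames for w in chunk])[:, None].astype(nn.DTYPE)
            logits, indices, phase_logits = model(Tensor(x))
            center = logits.data[:, :, logits.data.shape[2] // 2]
            masks.append(np.argmax(center, axis=1).astype(np.uint8))
            idx.append(model.destandardize_indices(indices.data))
            d = phase_logits.data.astype(np.float64)
            probs.append(1.0 / (1.0 + np.exp(np.clip(d[:, 0] - d[:, 1],
                                                     -60.0, 60.0))))
    masks = np.concatenate(masks)
    idx = np.concatenate(idx)
    probs = np.concatenate(probs)
    if readout == "unified":
        for t in range(n):
            try:
                a_cav, a_myo = geometry.areas_from_mask(masks[t])
                dims = geometry.cavity_dimensions(masks[t])
                rwt = geometry.regional_wall_thickness(masks[t])
                idx[t] = np.concatenate(([a_cav, a_myo], dims, rwt))
            except (DegenerateMaskError, ValueError):
                pass            # keep the regression head's frame
        try:
            return masks, idx, geometry.phase_from_areas(idx[:, 0])
        except (UndefinedPhaseError, ValueError):
            smooth_phase = True     # fall through to the decoded phase head
    if smooth_phase and n >= 3:
        phase = decode_cyclic_phase(probs)
    else:
        phase = (probs > 0.5).astype(int)
    return masks, idx, phase


def evaluate_subjects(model: UnifiedModel, subjects,
                      spacing: float = DEFAULT_SPACING,
                      apply_clahe: bool = True,
                      readout: str = "unified") -> MetricReport:
    """Pooled evaluation of a model over held-out subjects.

    The evaluation pipeline defaults to the unified readout (geometric
    indices from the predicted segmentation with regression-head fallback);
    pass ``readout="head"`` to score the regression path alone.
    """
    pm, tm, pi, ti, pp, tp = [], [], [], [], [], []
    for s in subjects:
        masks, indices, phase = predict_subject(model, s.images,
                                                apply_clahe=apply_clahe,
                                                readout=readout)
        pm.append(masks)
        tm.append(np.asarray(s.masks))
        pi.append(indices)
        ti.append(np.stack([iv.to_array() for iv in s.truth]))
        pp.append(phase)
        tp.append(np.array([iv.phase for iv in s.truth]))
    return evaluate(np.concatenate(pm), np.concatenate(tm),
                    np.concatenate(pi), np.concatenate(ti),
                    np.concatenate(pp), np.concatenate(tp),
                    spacing=spacing, skip_degenerate_hausdorff=True)


def cross_validate(subjects, config: TrainConfig | None = None,
                   seg_config: SegConfig | None = None,
                   reg_config: RegConfig | None = None,
                   spacing: float = DEFAULT_SPACING, log=None):
    """Subject-level k-fold cross-validation; returns per-fold results."""
    cfg = config or TrainConfig()
    rng = np.random.default_rng(cfg.seed)
    folds = make_folds(len(subjects), cfg.folds, rng)
    results = []
    for k, (train_idx, test_idx) in enumerate(folds):
        model = UnifiedModel(seg_config, reg_config,
                             init_rng=np.random.default_rng(cfg.seed + 1000 + k),
                             stop_gradient=cfg.stop_gradient)
        windows = []
        for i in train_idx:
            windows.extend(build_training_windows(subjects[i]))
        fold_log = (lambda e: log({"fold": k, **e})) if log is not None else None
        history, _ = train(model, windows, cfg, log=fold_log,
                           rng=np.random.default_rng(cfg.seed + 2000 + k))
        report = evaluate_subjects(model, [subjects[i] for i in test_idx],
                                   spacing=spacing)
        results.append({"fold": k, "train_subjects": train_idx.tolist(),
                        "test_subjects": test_idx.tolist(),
                        "history": history, "report": report})
    return results


# -- checkpointing ----------------------------------------------------------

def save_checkpoint(path, model: UnifiedModel, optimizers, epoch: int,
                    rng: np.random.Generator, config: TrainConfig,
                    history=None):
    """Serialize everything needed to resume training bit-for-bit."""
    opt_seg, opt_reg = optimizers
    state = {
        "model": model.state_dict(),
        "opt_seg": opt_seg.state_dict(),
        "opt_reg": opt_reg.state_dict(),
        "epoch": int(epoch),
        "rng_state": rng.bit_generator.state,
        "config": asdict(config),
        "history": history or [],
    }
    with open(path, "wb") as f:
        pickle.dump(state, f)


def load_checkpoint(path, model: UnifiedModel, config: TrainConfig | None = None):
    """Restore model/optimizer/rng state; returns (optimizers, epoch, rng, history)."""
    with open(Path(path), "rb") as f:
        state = pickle.load(f)
    model.load_state_dict(state["model"])
    cfg = config or TrainConfig()
    opt_seg, opt_reg = _make_optimizers(model, cfg)
    opt_seg.load_state_dict(state["opt_seg"])
    opt_reg.load_state_dict(state["opt_reg"])
    rng = np.random.default_rng()
    rng.bit_generator.state = state["rng_state"]
    return (opt_seg, opt_reg), state["epoch"], rng, state["history"]
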