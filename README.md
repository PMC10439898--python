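# lvquant

Joint left-ventricle (LV) segmentation and quantification for short-axis cine
MRI, built around a task-unified network: a 3D hybrid CNN–transformer
segmentation path and a spatio-temporal regression path that share features
and train end to end on one objective. Because clinical cine data cannot be
bundled, the package ships a parametric beating-LV phantom generator with
closed-form ground truth and an analytic geometric baseline, so every stage —
simulation, preprocessing, training, inference, evaluation — is reproducible
and testable on a single CPU.

## What it computes

For every frame of a cine sequence the pipeline produces:

- a 3-class segmentation (background / LV cavity / myocardium),
- 11 quantitative indices: cavity area, myocardium area, 3 cavity
  dimensions, and 6 regional wall thicknesses (IS, I, IL, AL, A, AS), all
  normalized by the image size (physical conversion via pixel spacing),
- the binary cardiac phase (systole / diastole).

Evaluation reports Dice, Hausdorff distance, per-index MAE (normalized and
physical), Pearson correlation, and the phase error rate.

## Quick start (CLI)

```bash
# 1. simulate a 20-subject synthetic cohort
lvquant simulate --subjects 20 --seed 7 --difficulty realistic --out data/

# 2. geometric baseline: indices measured directly from a subject's masks
lvquant indices --subject data/subject_000 --out baseline.csv

# 3. train the unified model on the cohort (desk-scale config)
lvquant train --data data/ --seed 7 --out runs/demo

# 4. segment + quantify one subject with the trained model
lvquant segment --run-dir runs/demo --subject data/subject_000 --out pred/

# 5. score predicted indices against the ground truth
lvquant evaluate --pred pred/indices.csv \
                 --truth data/subject_000/indices.csv --out report.csv
```

Every run directory receives a resolved `config.yaml` and a `run.log` with
the command, seed and library versions. Training is configurable through a
YAML file (`lvquant train --config run.yaml`) covering data paths, model
sizes, optimizer settings and loss weights; see `lvquant.dataio.RunConfig`.

## Quick start (Python)

```python
import numpy as np
from lvquant import phantom, trainer

rng = np.random.default_rng(7)
subjects = [phantom.render_subject(phantom.sample_spec(rng, "realistic"))
            for _ in range(20)]

results = trainer.cross_validate(subjects, trainer.TrainConfig.small())
for r in results:
    print(r["fold"], r["report"].summary())
```

## Model

- **Segmentation path** — residual 3D conv stem (three 1×2×2 pooled stages),
  patch embedding to a 5×5×5 grid whose 125 tokens feed a transformer
  encoder, then a transposed-conv decoder with skip connections emitting
  3-class logits for a 5-frame, 80×80 window.
- **Regression path** — recurrent-residual attention blocks alternating with
  spatio-temporal blocks that collapse the 5 frames to the center frame
  (5 → 3 → 1); squeeze-and-excitation fusion injects the segmentation
  decoder's multi-scale features; two heads emit the 11 indices and the
  phase.
- **Loss** — 4 · (CE + 1.5 · soft Dice) + 1 · (MSE + BCE).
- **Optimization** — RAdam on the segmentation path (per-epoch lr decay),
  momentum SGD on the regression path, simultaneously; subject-level k-fold
  cross-validation; deterministic under a fixed seed, with bit-exact
  checkpoint resume.
- **Inference readouts** — `predict_subject` returns the regression path's
  indices and phase by default; the evaluation pipeline and the CLI use the
  unified readout (`readout="unified"`), which measures indices
  geometrically from the predicted segmentation (regression head as
  per-frame fallback for degenerate masks) and derives the phase from the
  cavity-area series.

The reference-scale configuration (stem 32/64/128, hidden 256, depth 4,
500 epochs, 5 folds) is the default; `SegConfig.small()` /
`RegConfig.small()` / `TrainConfig.small()` define a desk profile that
trains in minutes on one CPU. See `docs/methods.md` for conventions,
population model, numerical decisions and limitations.

## Testing and acceptance

```bash
python -m pytest -q                       # unit + acceptance tests
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script regenerates everything from scratch (phantom cohorts,
training runs, evaluations) and writes the computed quantities — geometry
closure errors, loss algebra values, architecture shape numbers, overfit and
cross-validation metrics, determinism deltas — to JSON.

## Repository layout

```
src/lvquant/
  autodiff.py     numpy reverse-mode autodiff engine (tensors, conv3d, no_grad)
  nn.py           layers (conv, norms, attention, SE, RReLU) and optimizers
  geometry.py     index definitions and the mask-based geometric estimator
  phantom.py      parametric beating-LV simulator with analytic ground truth
  preprocess.py   CLAHE, z-scoring, cyclic 5-frame windows, augmentation
  losses.py       joint multi-task objective
  seg_path.py     hybrid CNN-transformer segmentation path
  reg_path.py     spatio-temporal regression path
  metrics.py      Dice / Hausdorff / MAE / PCC / phase error, reports
  trainer.py      unified model, dual optimizers, CV, checkpointing
  dataio.py       dataset layout, NIfTI/PNG/CSV/YAML interchange
  cli.py          command-line interface
tests/            unit tests + tests/test_acceptance.py (one per criterion)
scripts/          acceptance.py
docs/methods.md   modeling and numerical documentation
```
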