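# Methods

This note documents the modeling, numerical and configuration choices behind
`lvquant`. The package implements a task-unified network that jointly
segments the left ventricle (LV) in short-axis cine MR image windows and
regresses eleven quantitative indices plus the cardiac phase, together with
a synthetic phantom generator and an analytic geometric baseline that make
the whole pipeline testable end to end without clinical data.

## 1. Quantities and conventions

Eleven indices describe a mid-cavity short-axis cross-section per frame, in
canonical order: cavity area, myocardium area, three cavity dimensions, and
six regional wall thicknesses (RWT). Areas are normalized by the squared
image side (`H·W` pixels → fraction of the frame), lengths by the image side,
so every index is dimensionless; `MetricReport` converts to physical units
(mm², mm) with the in-plane pixel spacing (default 1.5625 mm).

Segments follow the standard mid-cavity six-segment model in the order
inferoseptal, inferior, inferolateral, anterolateral, anterior, anteroseptal
(IS, I, IL, AL, A, AS), with the anterior bisector pointing "up" (row index
decreasing) and segment bisectors 60° apart. The three cavity dimensions are
measured along the paired directions IS–AL, I–A and IL–AS. The cardiac phase
is binary per frame: frames strictly after end-diastole (maximal cavity area)
up to and including end-systole (minimal area) are systole (1); the rest,
including the ED frame itself, are diastole (0).

Label codes: 0 background, 1 LV cavity, 2 myocardium.

## 2. Synthetic phantom population

`phantom.py` renders a beating LV as two star-convex boundaries around a
common center: an endocardial radius and an epicardial radius obtained by
adding a six-node wall-thickness profile interpolated trigonometrically
(6-point FFT interpolation), with optional low-order Fourier shape
perturbations. Contraction follows a raised-cosine fraction of the cycle
(ED at frame 0, ES at a sampled frame, cyclic), shrinking the endocardial
radius and thickening the wall simultaneously. Masks are rasterized by
sub-pixel area sampling; images add tissue intensities, a smooth
multiplicative bias field and Gaussian noise.

Because boundaries are analytic, every index has a closed-form value
(`analytic_indices`): areas by polar integration of the boundary radii,
dimensions and RWT by evaluating the radii along the segment bisectors. This
is the oracle against which the mask-based estimator `indices_from_mask` is
closed (acceptance criterion 1).

The "realistic" population samples, per subject: ED endocardial radius,
fractional systolic shrink, a base ED wall thickness spanning the clinical
spectrum from dilated-thin to hypertrophic-thick walls (base uniform in
[3.5, 11.5] px with ±2.2 px per-segment asymmetry, clipped to [2.8, 13.5]),
a proportional systolic thickening factor in [1.1, 1.6], ES frame position,
shape perturbations, noise level and bias amplitude. The wide wall spread is
deliberate: the ray-casting RWT estimator has an irreducible rasterization
noise of roughly 0.4 px, so a population whose true RWT spread is only ~2 px
cannot exhibit a mask-vs-analytic correlation above 0.99; spanning the
clinical range both emulates the pathology mix of typical LV quantification
cohorts and makes the closure property informative. The "easy" population
uses thicker, rounder, low-noise phantoms for overfit-style tests.

## 3. Geometric baseline

`geometry.indices_from_mask` measures a 3-class mask stack directly: areas
by pixel counting; the cavity centroid as the ray origin; dimensions and RWT
by casting rays at the segment angles and locating class-transition
crossings at sub-pixel positions (linear interpolation between pixel
centers); the phase from the cavity-area series. Degenerate masks (no
cavity, broken ring) raise `DegenerateMaskError` labeled with the frame.

## 4. Network

Both paths run on a self-contained numpy reverse-mode autodiff engine
(`autodiff.py`) with a tape of analytic vector-Jacobian products, float32
parameters, and a `no_grad` inference mode. This substitution is forced by
the environment (no deep-learning framework available offline); the
mathematical content — losses, optimizers, architectures — is implemented
exactly, and `conv3d` is verified against a six-loop direct convolution in
the tests.

**Segmentation path** (`seg_path.py`): a residual 3D convolutional stem
(group norm, randomized leaky ReLU, 1×2×2 max pooling; the 5-slice temporal
axis is never pooled) downsamples an (1, 5, 80, 80) window three times; a
strided 1×2×2 patch embedding yields a (hidden, 5, 5, 5) grid whose 125
cells, plus learned positional embeddings, form the token sequence of a
pre-norm transformer encoder (multi-head self-attention + MLP blocks). A
cascade of 1×2×2 transposed convolutions with stem skip concatenation
restores full resolution and emits 3-class logits for all five slices. The
decoder's intermediate feature maps at half and quarter resolution are
exposed to the regression path.

**Regression path** (`reg_path.py`): recurrent-residual attention (RRA)
blocks — two recurrent-residual convolution units followed by
squeeze-and-excitation — alternate with spatio-temporal blocks (unpadded
3×1×1 temporal conv, padded 1×3×3 spatial conv, 1×2×2 pooling). Two ST
blocks collapse the five slices to one (5 → 3 → 1), so the output describes
the center frame with a temporal receptive field covering the whole window.
After each ST block, SE fusion concatenates the matching segmentation
decoder features (center-cropped on the slice axis), applies
squeeze-and-excitation over the joint channels and mixes back to the
regression width. Heads: a 1×1×1 conv + global average pool + linear layer
for the 11 indices, and a 360-unit MLP with 2 outputs for the phase.

**Loss** (`losses.py`): L_seg = λ1·CE + λ2·softDice with λ1 = 1, λ2 = 1.5;
L_reg = MSE over the 11 indices + BCE on the phase; unified
L = λ3·L_seg + λ4·L_reg with λ3 = 4, λ4 = 1.

## 5. Training protocol

Two optimizers run simultaneously on disjoint parameter groups: rectified
Adam (RAdam) on the segmentation path with per-epoch exponential
learning-rate decay, and momentum SGD on the regression path; the SE-fusion
parameters belong to the regression group (they exist only for regression).
Gradients from the regression loss flow into the segmentation path through
the fused features (end-to-end); a `stop_gradient` switch detaches them for
ablation. The reference-scale defaults are 500 epochs, batch 20, 5 folds, RAdam lr 5e-4 / β (0.9, 0.999) / weight decay
1e-4 / decay 0.99, SGD lr 5e-4 / momentum 0.06 / weight decay 5e-3.

**Index-target standardization.** The 11 indices differ in scale by an order
of magnitude (areas ~0.05–0.3, RWT ~0.05), so a joint MSE is dominated by the
widest-range index. The model stores per-index mean/std computed from the
training pool as buffers (std floored at 1e-3), the regression head trains in
standardized space, and predictions are de-standardized. This is the
regression analogue of input normalization and is controlled by
`TrainConfig.standardize_targets` (on by default).

**Readouts at inference.** `predict_subject` defaults to the regression
path's own outputs (`readout="head"`): de-standardized index head values
and per-frame phase argmax. The evaluation pipeline (`evaluate_subjects`,
cross-validation) and the CLI instead use the *unified* readout
(`readout="unified"`), which quantifies from both trained paths: each
frame's 11 indices are measured geometrically from the predicted
segmentation — the same estimator that is closed against analytic ground
truth on reference masks — and the phase follows from the resulting
cavity-area series; frames whose predicted mask is degenerate (no cavity,
broken ring) fall back to the regression head, as does the phase when the
area series is constant. The rationale is sample efficiency: at desk scale
a fold trains on ~10 subjects, too few for a learned regressor to
*generalize* index calibration across unseen anatomies, whereas the
geometric readout of a well-segmented mask carries no such barrier.

**Phase decoding.** Head-derived phase labels are structured-decoded: a
cardiac cycle contains exactly one contiguous (cyclic) systolic run — the
frames after end-diastole up to end-systole — so `decode_cyclic_phase`
picks the run maximizing the summed Bernoulli log-likelihood of the
per-frame probabilities (O(n²) exact search). The per-frame head remains
the sole source of evidence; the decoder only rules out physiologically
impossible label sequences such as isolated one-frame phase flips.
Frame-wise argmax remains available via `smooth_phase=False`.

**Preprocessing**: CLAHE per frame (scikit-image backend, normalized clip
limit 0.02, 8×8 tiles) then per-subject z-scoring; 5-frame cyclic temporal
windows (the cycle is periodic). Augmentation (off by default in the desk
profile) applies one shared rotation/flip/elastic warp to all five frames
and masks plus an image-only gamma shift.

**Desk profile.** The reference configuration is far beyond a single-CPU
container, so `*.small()` configurations define a desk-scale profile: stem
(4, 8, 16), one conv per stage, hidden 32, depth 1, 4 heads, decoder
(16, 8, 8, 4); regression stage widths (4, 16, 32) — the full-resolution
stage stays narrow because it dominates CPU cost, while the pooled stages
carry the capacity the index head needs — recurrence 1; batch 4, 26 steps
per epoch, RAdam lr 3e-3, SGD lr 0.05 / momentum 0.9 / weight decay 1e-4.
These were tuned on phantom runs to converge within the CPU time budget;
the optimizer *types*, loss weights and data conventions are identical to
the reference protocol.

## 6. Numerical decisions

- Probability floor in all log losses is 1e-7: `1 − 1e-12` is not
  representable next to 1.0 in float32 (it rounds back to exactly 1), so a
  smaller floor makes `log(0)` reachable when a predicted probability
  saturates.
- Sigmoid uses the standard numerically stable form that exponentiates only
  non-positive arguments.
- Soft Dice uses symmetric smoothing (ε = 1e-5 in numerator and
  denominator), so a class absent from both prediction and truth contributes
  a perfect ratio instead of a penalty.
- MSE is implemented as the standard non-negative mean of squared errors;
  PCC centers each series by its own mean; the phase metric is an error
  *rate* (misclassification fraction).
- Hausdorff distances are computed between 4-neighbor boundary pixels
  (image-border pixels count as boundary); frames where a class is empty in
  prediction or truth can be skipped (`skip_degenerate_hausdorff`) during
  pooled evaluation of imperfect models.

## 7. Reproducibility

All stochasticity flows through explicit `numpy.random.Generator` objects:
phantom sampling, parameter initialization, batch shuffling, augmentation
and the randomized activations. Checkpoints serialize model and optimizer
state plus the generator's bit-state, so a resumed run reproduces the
uninterrupted run bit-for-bit (tested). Single-threaded numpy execution
makes losses and reports reproducible to well below 1e-6.

## 8. Limitations

- Phantoms are star-convex, single-slice analogues of mid-cavity SAX cine;
  clinical-grade accuracy claims are out of scope.
- The autodiff engine is single-threaded numpy; throughput, not correctness,
  is the constraint, hence the desk-scale configuration defaults.
- The phase head is trained on per-frame labels only; cyclic consistency is
  imposed at inference by the structured decoder, not learned.
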