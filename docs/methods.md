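# Methods

## The distillation model

`irmkd` trains a compact student CNN under a teacher that stays frozen
throughout (inference mode, no gradients, checksum-verified unchanged).
Four kinds of knowledge are transferred, all defined through Euclidean
distances between *canonical vectors* of intermediate feature maps:

1. **Instance relations** (`L_IRM`). For each sample, the m×m matrix of
   pairwise distances between its m tap-layer vectors; stacked over the
   batch this is the n×m×m instance relation matrix. The loss is the mean
   squared teacher–student difference over all n·m² cells. The matrix is
   symmetric with a zero diagonal by construction, and because canonical
   vectors lie on the unit sphere every distance is in [0, 2].
2. **Feature-space transformation / knowledge flow** (`L_IRM-t`). At each
   tap layer j, D_j is the n×n matrix of inter-sample distances. The flow
   from layer g to layer h is D_g − D_h; the loss is the mean squared
   difference between teacher flow and student flow, averaged over the
   configured layer pairs (default: consecutive pairs (1,2), (2,3), …).
3. **Responses** (`L_logits`), the mean squared distance between teacher
   and student logit vectors, and classic softened-softmax distillation
   (`L_KD = T²·CE(p̃ᵗ, p̃ˢ)`) for the `kd` training variant.
4. **Supervision** (`L_GT`), cross-entropy against hard labels.

The combined objective is
`L_MTK = α·L_IRM-t + (1−α)·L_IRM + β·L_logits + γ·L_GT`.

Two printed forms of the source formulas are not implementable as written
and are corrected here as deliberate design choices: the IRM discrepancy
is computed between teacher and student matrices (a same-matrix
difference would be identically zero), and the response-distillation term
is the cross-entropy of the student's softened probabilities under the
teacher's soft targets (a teacher-only entropy would carry no student
gradient). Both corrections restore the standard forms these losses are
known by.

### Canonicalization

Teacher and student maps at corresponding taps differ in channel count
and spatial size (the method is explicitly architecture-heterogeneous),
so distances need a common space. Each C×H×W map is reduced by

- channel aggregation — mean of raw activations by default (`abs_mean`
  and `sq_mean` are config options; the default is the plainest reading
  of "the feature map as a spatial object"),
- bilinear resize of the H×W result to S_c×S_c, expressed as a constant
  interpolation matrix (hence exactly the identity when sizes already
  match, and trivially differentiable),
- flattening and L2 normalisation; an all-zero map (a dead-ReLU batch)
  stays exactly zero rather than producing NaNs, and distances to it
  remain defined.

`canonical_size` S_c defaults to the smallest tap grid among the selected
layers so that no distance is dominated by upsampling artefacts. Taps are
the post-activation block outputs; pre-activation maps would be an
equally defensible choice, but one convention had to be fixed and
post-ReLU maps are what the downstream classifier actually consumes.

### Numerical choices

- All squared-norm losses are normalised by element count (means, not
  sums) so magnitudes are batch-size- and m-invariant and α/β/γ transfer
  across configurations.
- Softmax is max-stabilised; rows sum to 1 to ~1e-12.
- Pairwise distances use an exact `sqrt` forward with a guarded backward
  (`0.5/√(x+1e-12)`): the diagonal of a distance matrix is exactly zero,
  where the true derivative diverges; the guard keeps gradients finite
  without perturbing forward values.
- Everything is float64. The toy networks are small enough that the cost
  is irrelevant, and the finite-difference gradient checks benefit.
- Argmax predictions break ties toward the lowest class index.
- A non-finite loss component aborts training with an error naming the
  component and epoch (degenerate batches are the expected failure mode
  of relational losses, and silent NaN propagation would be worse).

## Networks and training

Models are stacks of conv(3×3, stride 2) → batch-norm → ReLU blocks with
global average pooling and a linear head, built on the package's own
reverse-mode autodiff engine (a numpy Tensor with hand-written
vector–Jacobian products; convolution is an im2col gather plus matmul so
its gradient follows from the primitives). Checkpoints are
self-describing (architecture descriptor + parameters + batch-norm
running statistics).

Optimisation is SGD with momentum 0.9 and weight decay 1e-4 at initial
learning rate 0.1 — the reference recipe — with a step decay (×0.1 at 50%
and 75% of epochs; a constant schedule is available since the original
schedule is not documented). Weight decay applies to all parameters,
batch-norm included; at these scales the distinction is immaterial.
`batch_size` clamps to the training-split size with a warning. The
train/validation split is stratified 80/20, derived deterministically
from the config seed. Data augmentation (flips, random crops, rotations,
shifts) is applied at training time only.

Variants: `baseline` (γ·L_GT, teacher never evaluated — bit-identical to
plain supervised training at γ=1 and the same seed), `kd`
(kd_alpha·L_cls + (1−kd_alpha)·L_KD; `kd_alpha` is deliberately a
separate knob from the relational α, since the two mixes are logically
distinct), `irm` (L_IRM + γ·L_GT), and `mtk` (the full objective). Every
epoch record stores the four component values and the effective (α, β, γ)
under which the logged total decomposes exactly, so logs are auditable.

Default hyperparameters: T=4 (from the conventional 3–5 range), α=0.5,
β=0.1, γ=1.0. β and γ have no documented reference values; they were
chosen once so that supervision dominates early training while the
relational terms act as regularisers, and are exposed in the config.

## Synthetic data

The generator emulates the structure of leaf-disease photo corpora at
desk scale: an elliptical leaf (~60% of the frame) over a clean (uniform
grey + slight noise) or cluttered (multi-octave value noise) background,
with class identity carried by lesion spots — anti-aliased filled circles
whose colour, count and radius range are per-class parameters drawn from
a fixed palette of disease-like colours. Every image is a pure function
of (spec, class, index), so datasets are bit-reproducible, and classes
are validated to be pairwise distinct in lesion parameters.

What it does *not* emulate: photographic texture, lighting, leaf venation
and 3-D pose, intra-class disease-stage variation, label noise, class
imbalance. Passing tests therefore demonstrate that the machinery —
losses, gradients, training dynamics, variant ordering — behaves
correctly on a learnable image task; they are not evidence about accuracy
on real plant photographs.

## Desk-scale study conditions

The end-to-end comparison runs at: 4 classes × 30 images at 32 px with a
cluttered background (generator seed 7), teacher widths (16, 32, 64)
(24 068 parameters), student widths (3, 6, 12) (1 006 parameters, ~24×
compression — comparable to the teacher/student size gap the method
targets), 30 epochs, batch 32, seeds {2, 3, 4}. The student capacity was
chosen so the supervised baseline sits below ceiling: a wider student
solves this synthetic task perfectly on its own, which would make any
comparison of training objectives uninformative. Under these conditions
the teacher reaches 100% validation accuracy, the baseline student a
median of 91.7%, and the relationally distilled student 100%.

## Known limitations

- The engine is single-threaded CPU numpy; it is meant for method study
  at toy scale, not for training production classifiers.
- Architecture is fixed in shape (stride-2 conv blocks); only widths,
  depth and tap selection are configurable. Teacher and student must
  expose the same number of taps.
- Batch-norm running statistics make training-mode loss values depend on
  batch composition; reproducibility is guaranteed per seed, and
  documented to 1e-4 across repeated identical runs.
- The bilinear canonical grid treats feature maps as spatial attention
  patterns; methods that match channel statistics or learned projections
  are out of scope.
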