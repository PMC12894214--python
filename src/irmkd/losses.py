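"""Instance-relation-matrix (IRM) distillation losses.

The method transfers four kinds of knowledge from a trained teacher to a
compact student, all expressed through Euclidean distances between
canonicalized feature maps:

* **L_IRM** — instance relations: for each sample, the m x m matrix of
  pairwise distances between its m tap-layer maps.  Stacked over a batch
  this is the n x m x m *instance relation matrix*; the loss is the mean
  squared difference between the teacher's and the student's IRM.
* **L_IRM-t** — feature-space transformation ("knowledge flow"): for a
  layer pair (g, h), the change D_g - D_h of the n x n inter-sample
  distance matrix between the two layers; the loss penalises the
  difference between teacher flow and student flow.
* **L_logits** — mean squared distance between teacher and student logit
  vectors.
* **L_GT** — ordinary cross-entropy of the student against the hard
  labels.

These combine into the multi-type-knowledge objective

    L_MTK = alpha * L_IRM-t + (1 - alpha) * L_IRM + beta * L_logits + gamma * L_GT.

Classic response-based distillation (temperature-softened softmax,
L = alpha * L_cls + (1 - alpha) * L_KD) is provided alongside for the
``kd`` training variant.

All squared-norm losses are normalised by element count (means, not sums),
so their magnitudes are invariant to batch size and tap count and the
alpha/beta/gamma weights transfer across configurations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, as_tensor
from .features import FeatureTapSet

__all__ = [
    "LossWeights",
    "IRMTensor",
    "SampleDistanceMatrix",
    "MTKBreakdown",
    "soft_softmax",
    "log_soft_softmax",
    "build_irm",
    "irm_loss",
    "sample_distance_matrix",
    "irm_t_loss",
    "irm_t_loss_pairs",
    "logits_loss",
    "kd_loss",
    "cls_loss",
    "combined_kd",
    "mtk_loss",
]


@dataclass(frozen=True)
class LossWeights:
    """Hyperparameters of the combined objective.

    ``alpha`` mixes the two relational terms (IRM-t vs IRM), ``beta`` and
    ``gamma`` weight the logits and ground-truth terms, ``temperature``
    softens the softmax for the classic-KD variant, and ``flow_pairs``
    lists the 0-based tap-index pairs (g, h), g < h, whose knowledge flow
    enters L_IRM-t (default: consecutive pairs, averaged).
    """

    alpha: float = 0.5
    beta: float = 0.1
    gamma: float = 1.0
    temperature: float = 4.0
    flow_pairs: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self):
        if not 0 <= self.alpha <= 1:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.beta < 0 or self.gamma < 0:
            raise ValueError(f"beta and gamma must be >= 0, got {self.beta}, {self.gamma}")
        if self.temperature <= 1:
            raise ValueError(f"temperature must be > 1, got {self.temperature}")
        if self.flow_pairs is not None:
            pairs = tuple(tuple(p) for p in self.flow_pairs)
            for g, h in pairs:
                if not g < h:
                    raise ValueError(f"flow pair ({g}, {h}) must satisfy g < h")
            object.__setattr__(self, "flow_pairs", pairs)

    def resolve_flow_pairs(self, m: int) -> tuple[tuple[int, int], ...]:
        if self.flow_pairs is not None:
            for g, h in self.flow_pairs:
                if h >= m:
                    raise ValueError(f"flow pair ({g}, {h}) out of range for m={m} taps")
            return self.flow_pairs
        return tuple((i, i + 1) for i in range(m - 1))


@dataclass
class IRMTensor:
    """The n x m x m instance relation matrix of a batch.

    Entry [k, g, h] is the Euclidean distance between the canonical unit
    vectors of tap layers g and h for sample k — symmetric in (g, h), zero
    on the diagonal, bounded by 2.
    """

    values: Tensor

    def __post_init__(self):
        v = self.values
        if v.ndim != 3 or v.shape[1] != v.shape[2]:
            raise ValueError(f"IRM must have shape (n, m, m), got {v.shape}")
        if not np.all(np.isfinite(v.data)):
            raise FloatingPointError("IRM contains non-finite entries")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]


@dataclass
class SampleDistanceMatrix:
    """The n x n inter-sample distance matrix at one tap layer."""

    values: Tensor
    layer: int = 0

    def __post_init__(self):
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"sample distance matrix must be (n, n), got {v.shape}")
        if not np.all(np.isfinite(v.data)):
            raise FloatingPointError("distance matrix contains non-finite entries")


# --------------------------------------------------------------------------
# softened softmax and response-based KD


def soft_softmax(logits, temperature: float) -> Tensor:
    """Temperature-softened softmax, row-wise, max-stabilised.

    ``temperature`` > 1 softens the distribution, exposing the teacher's
    inter-class similarity structure; temperature 1 recovers plain softmax.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be > 0, got {temperature}")
    z = as_tensor(logits)
    if not np.all(np.isfinite(z.data)):
        raise FloatingPointError("logits contain non-finite values")
    z = z * (1.0 / temperature)
    z = z - z.max_const(axis=-1, keepdims=True)
    e = z.exp()
    return e / e.sum(axis=-1, keepdims=True)


def log_soft_softmax(logits, temperature: float) -> Tensor:
    if temperature <= 0:
        raise ValueError(f"temperature must be > 0, got {temperature}")
    z = as_tensor(logits) * (1.0 / temperature)
    z = z - z.max_const(axis=-1, keepdims=True)
    return z - z.exp().sum(axis=-1, keepdims=True).log()


def kd_loss(teacher_logits, student_logits, temperature: float) -> Tensor:
    """Response distillation: T^2 * CE(teacher soft targets, student soft probs).

    The T^2 factor keeps gradient magnitudes comparable across temperatures.
    Mean over samples.  The teacher's probabilities are treated as
    constants (no gradient flows into the teacher).
    """
    t = as_tensor(teacher_logits)
    s = as_tensor(student_logits)
    if t.shape != s.shape:
        raise ValueError(f"logit shape mismatch: teacher {t.shape} vs student {s.shape}")
    p_t = soft_softmax(t.detach(), temperature)
    logp_s = log_soft_softmax(s, temperature)
    ce = -(p_t * logp_s).sum(axis=-1).mean()
    return ce * (temperature**2)


def cls_loss(student_logits, labels) -> Tensor:
    """Standard cross-entropy (temperature 1) against hard labels, mean over samples."""
    s = as_tensor(student_logits)
    labels = np.asarray(labels, dtype=int)
    if labels.shape != (s.shape[0],):
        raise ValueError(f"labels shape {labels.shape} does not match logits {s.shape}")
    onehot = np.zeros(s.shape)
    onehot[np.arange(len(labels)), labels] = 1.0
    return -(Tensor(onehot) * log_soft_softmax(s, 1.0)).sum(axis=-1).mean()


def combined_kd(cls_term, kd_term, alpha: float) -> Tensor:
    """Classic distillation objective: alpha * L_cls + (1 - alpha) * L_KD."""
    if not 0 <= alpha <= 1:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    return as_tensor(cls_term) * alpha + as_tensor(kd_term) * (1.0 - alpha)


# --------------------------------------------------------------------------
# relational losses


def build_irm(taps: FeatureTapSet) -> IRMTensor:
    """Pairwise cross-layer distances per sample: the n x m x m relation matrix."""
    if taps.m < 2:
        raise ValueError(f"building an IRM requires m >= 2 tap layers, got m={taps.m}")
    n, m, d = taps.vectors.shape
    a = taps.vectors.reshape(n, m, 1, d)
    b = taps.vectors.reshape(n, 1, m, d)
    sq = ((a - b) ** 2).sum(axis=3)  # (n, m, m); exact zeros on the diagonal
    return IRMTensor(sq.sqrt_safe())


def irm_loss(irm_teacher: IRMTensor, irm_student: IRMTensor) -> Tensor:
    """Mean squared difference of the two relation matrices over all n*m*m cells."""
    ht, hs = irm_teacher.values, irm_student.values
    if ht.shape != hs.shape:
        raise ValueError(f"IRM shape mismatch: {ht.shape} vs {hs.shape}")
    return ((ht - hs) ** 2).mean()


def sample_distance_matrix(taps: FeatureTapSet, layer: int) -> SampleDistanceMatrix:
    """Pairwise inter-sample distances of one layer's canonical vectors."""
    if taps.n < 2:
        raise ValueError(f"inter-sample distances need n >= 2 samples, got n={taps.n}")
    v = taps.layer(layer)  # raises IndexError for a bad layer
    n, d = v.shape
    a = v.reshape(n, 1, d)
    b = v.reshape(1, n, d)
    sq = ((a - b) ** 2).sum(axis=2)
    return SampleDistanceMatrix(sq.sqrt_safe(), layer=layer)


def irm_t_loss(d_teacher_g, d_teacher_h, d_student_g, d_student_h) -> Tensor:
    """Knowledge-flow loss for one layer pair (g, h).

    D_g - D_h is the change of the inter-sample distance matrix from layer
    g to layer h (the "knowledge flow"); the loss is the mean squared
    difference between teacher flow and student flow over the n x n grid.
    """
    mats = []
    for d in (d_teacher_g, d_teacher_h, d_student_g, d_student_h):
        mats.append(d.values if isinstance(d, SampleDistanceMatrix) else as_tensor(d))
    shapes = {t.shape for t in mats}
    if len(shapes) != 1:
        raise ValueError(f"distance-matrix shape mismatch: {sorted(shapes)}")
    tg, th, sg, sh = mats
    return (((tg - th) - (sg - sh)) ** 2).mean()


def irm_t_loss_pairs(
    taps_teacher: FeatureTapSet, taps_student: FeatureTapSet, weights: LossWeights
) -> Tensor:
    """L_IRM-t averaged over the configured flow pairs."""
    if taps_teacher.m != taps_student.m:
        raise ValueError(
            f"teacher has m={taps_teacher.m} taps but student has m={taps_student.m}"
        )
    pairs = weights.resolve_flow_pairs(taps_teacher.m)
    total = None
    for g, h in pairs:
        term = irm_t_loss(
            sample_distance_matrix(taps_teacher, g),
            sample_distance_matrix(taps_teacher, h),
            sample_distance_matrix(taps_student, g),
            sample_distance_matrix(taps_student, h),
        )
        total = term if total is None else total + term
    return total * (1.0 / len(pairs))


def logits_loss(teacher_logits, student_logits) -> Tensor:
    """Mean over samples of the squared Euclidean distance between logit rows."""
    t = as_tensor(teacher_logits)
    s = as_tensor(student_logits)
    if t.shape != s.shape:
        raise ValueError(f"logit shape mismatch: {t.shape} vs {s.shape}")
    return ((t.detach() - s) ** 2).sum(axis=-1).mean()


# --------------------------------------------------------------------------
# combined objective


@dataclass
class MTKBreakdown:
    """The four component values entering one L_MTK evaluation (for logging)."""

    irm_t: float
    irm: float
    logits: float
    gt: float
    total: float

    def as_dict(self) -> dict[str, float]:
        return {
            "irm_t": self.irm_t,
            "irm": self.irm,
            "logits": self.logits,
            "gt": self.gt,
            "total": self.total,
        }


def mtk_loss(irm_t_term, irm_term, logits_term, gt_term, weights: LossWeights) -> tuple[Tensor, MTKBreakdown]:
    """The combined multi-type-knowledge objective.

    Returns the differentiable scalar and a float breakdown of the four
    components for logging.  Non-finite components abort with an error
    naming the offending term.
    """
    terms = {
        "irm_t": as_tensor(irm_t_term),
        "irm": as_tensor(irm_term),
        "logits": as_tensor(logits_term),
        "gt": as_tensor(gt_term),
    }
    for name, t in terms.items():
        if not np.all(np.isfinite(t.data)):
            raise FloatingPointError(f"loss component '{name}' is non-finite")
    total = (
        terms["irm_t"] * weights.alpha
        + terms["irm"] * (1.0 - weights.alpha)
        + terms["logits"] * weights.beta
        + terms["gt"] * weights.gamma
    )
    breakdown = MTKBreakdown(
        irm_t=terms["irm_t"].item(),
        irm=terms["irm"].item(),
        logits=terms["logits"].item(),
        gt=terms["gt"].item(),
        total=total.item(),
    )
    return total, breakdown
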