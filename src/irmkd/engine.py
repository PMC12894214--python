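"""Training orchestration: teacher training and student distillation.

The engine owns batching, SGD optimisation, the loss-variant dispatch
(``baseline`` / ``kd`` / ``irm`` / ``mtk``), per-epoch logging and
checkpointing.  Four training variants mirror the usual ablation grid:

* ``baseline`` — plain supervised training of the student (gamma * L_GT);
  the teacher is never evaluated, so at gamma = 1 this is bit-identical
  to ordinary training at the same seed.
* ``kd`` — classic response distillation,
  kd_alpha * L_cls + (1 - kd_alpha) * L_KD at the configured temperature.
* ``irm`` — instance-relation loss plus supervised loss
  (L_IRM + gamma * L_GT).
* ``mtk`` — the full combined objective
  alpha * L_IRM-t + (1 - alpha) * L_IRM + beta * L_logits + gamma * L_GT.

Whatever the variant, every epoch record stores the four component values
and the *effective* (alpha, beta, gamma) weights under which the logged
total decomposes exactly, so the decomposition can be audited offline.

Defaults follow the reference training recipe (batch 512, initial lr 0.1,
momentum 0.9, weight decay 1e-4, seed 2, 128 x 128 inputs, 200 epochs);
desk-scale runs override epochs/batch/image size.  The learning-rate
schedule is a step decay (x0.1 at 50% and 75% of the epochs) unless
``lr_schedule="constant"``.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .autograd import Tensor
from .features import build_tap_set
from .losses import (
    LossWeights,
    MTKBreakdown,
    build_irm,
    cls_loss,
    combined_kd,
    irm_loss,
    irm_t_loss_pairs,
    kd_loss,
    logits_loss,
    mtk_loss,
)
from .nn import (
    SGD,
    ConfigurationError,
    ToyCNN,
    load_checkpoint,
    parameter_checksum,
    save_checkpoint,
)
from .synthetic import AugmentationPlan, LabeledImageBatch, augment, read_image_folder

__all__ = [
    "VARIANTS",
    "DistillationConfig",
    "EpochRecord",
    "TrainingLog",
    "stratified_split",
    "train_teacher",
    "train_supervised",
    "distill",
]

VARIANTS = ("baseline", "kd", "irm", "mtk")

LOG_COLUMNS = ["epoch", "total", "irm_t", "irm", "logits", "gt", "train_acc", "val_acc", "seconds"]


@dataclass(frozen=True)
class DistillationConfig:
    """Everything one training/distillation run needs.

    ``teacher_widths``/``student_widths`` are the conv-block channel counts
    of the two architectures; taps default to all block outputs.
    """

    data_dir: str | None = None
    teacher_ckpt: str | None = None
    teacher_widths: tuple[int, ...] = (16, 32, 64)
    student_widths: tuple[int, ...] = (3, 6, 12)
    n_classes: int = 4
    epochs: int = 200
    batch_size: int = 512
    lr: float = 0.1
    momentum: float = 0.9
    weight_decay: float = 1e-4
    seed: int = 2
    image_size: int = 128
    variant: str = "mtk"
    weights: LossWeights = field(default_factory=LossWeights)
    kd_alpha: float = 0.7
    canonical_size: int | None = None
    channel_agg: str = "mean"
    lr_schedule: str = "step"
    val_fraction: float = 0.2
    augmentation: AugmentationPlan | None = None

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError(f"lr must be > 0, got {self.lr}")
        if not 0 <= self.momentum < 1:
            raise ValueError(f"momentum must be in [0, 1), got {self.momentum}")
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")
        if self.batch_size < 2:
            raise ValueError(
                f"batch_size must be >= 2 (relational losses need sample pairs), got {self.batch_size}"
            )
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if not 0 <= self.kd_alpha <= 1:
            raise ValueError(f"kd_alpha must be in [0, 1], got {self.kd_alpha}")
        if self.lr_schedule not in ("step", "constant"):
            raise ValueError(f"lr_schedule must be 'step' or 'constant', got {self.lr_schedule!r}")
        if not 0 < self.val_fraction < 1:
            raise ValueError(f"val_fraction must be in (0, 1), got {self.val_fraction}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "DistillationConfig":
        """Load a config file; keyword overrides win over file values."""
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        loss_keys = raw.pop("loss", {})
        if loss_keys:
            fp = loss_keys.get("flow_pairs")
            raw["weights"] = LossWeights(
                alpha=loss_keys.get("alpha", 0.5),
                beta=loss_keys.get("beta", 0.1),
                gamma=loss_keys.get("gamma", 1.0),
                temperature=loss_keys.get("temperature", 4.0),
                flow_pairs=tuple(tuple(p) for p in fp) if fp else None,
            )
            if "variant" in loss_keys:
                raw["variant"] = loss_keys["variant"]
        kd_keys = raw.pop("kd", {})
        if "alpha" in kd_keys:
            raw["kd_alpha"] = kd_keys["alpha"]
        taps = raw.pop("taps", None)  # tap names default to all blocks; reserved key
        for k in ("teacher_widths", "student_widths"):
            if k in raw:
                raw[k] = tuple(raw[k])
        raw.update(overrides)
        return cls(**raw)


@dataclass
class EpochRecord:
    epoch: int
    total: float
    irm_t: float
    irm: float
    logits: float
    gt: float
    train_acc: float
    val_acc: float
    seconds: float


@dataclass
class TrainingLog:
    """Per-epoch training history plus the effective decomposition weights."""

    records: list[EpochRecord] = field(default_factory=list)
    effective_alpha: float = 0.0
    effective_beta: float = 0.0
    effective_gamma: float = 1.0

    def append(self, rec: EpochRecord) -> None:
        self.records.append(rec)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records], columns=LOG_COLUMNS)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @property
    def final_val_acc(self) -> float:
        return self.records[-1].val_acc

    def total_recomposed(self, epoch_index: int) -> float:
        """Re-derive the logged total from its components (audit helper)."""
        r = self.records[epoch_index]
        return (
            self.effective_alpha * r.irm_t
            + (1.0 - self.effective_alpha) * r.irm
            + self.effective_beta * r.logits
            + self.effective_gamma * r.gt
        )


def stratified_split(
    labels: np.ndarray, val_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class shuffled train/validation index split (at least 1 val per class)."""
    rng = np.random.default_rng([seed, 17])
    train_idx, val_idx = [], []
    for k in np.unique(labels):
        idx = np.flatnonzero(labels == k)
        rng.shuffle(idx)
        n_val = max(1, int(round(val_fraction * len(idx))))
        val_idx.append(idx[:n_val])
        train_idx.append(idx[n_val:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(val_idx))


def _accuracy(model: ToyCNN, images: np.ndarray, labels: np.ndarray) -> float:
    return float(np.mean(model.predict(images) == labels))


def _load_dataset(config: DistillationConfig, dataset: LabeledImageBatch | None) -> LabeledImageBatch:
    if dataset is not None:
        return dataset
    if config.data_dir is None:
        raise IOError("no dataset given and config.data_dir is unset")
    batch, _ = read_image_folder(config.data_dir, image_size=config.image_size)
    return batch


def _fit(
    model: ToyCNN,
    dataset: LabeledImageBatch,
    config: DistillationConfig,
    loss_fn,
    effective: tuple[float, float, float],
) -> TrainingLog:
    """Shared SGD loop.  ``loss_fn(images, labels) -> (Tensor, MTKBreakdown)``."""
    train_idx, val_idx = stratified_split(dataset.labels, config.val_fraction, config.seed)
    x_train, y_train = dataset.images[train_idx], dataset.labels[train_idx]
    x_val, y_val = dataset.images[val_idx], dataset.labels[val_idx]

    batch_size = config.batch_size
    if batch_size > len(x_train):
        warnings.warn(
            f"batch_size {batch_size} exceeds the {len(x_train)}-sample training split; "
            "clamping to the dataset size"
        )
        batch_size = len(x_train)

    opt = SGD(model.parameters(), config.lr, config.momentum, config.weight_decay)
    shuffle_rng = np.random.default_rng([config.seed, 23])
    milestones = {int(config.epochs * 0.5), int(config.epochs * 0.75)} if config.lr_schedule == "step" else set()

    log = TrainingLog(
        effective_alpha=effective[0], effective_beta=effective[1], effective_gamma=effective[2]
    )
    for epoch in range(1, config.epochs + 1):
        t0 = time.perf_counter()
        if epoch in milestones:
            opt.lr *= 0.1
        model.train()
        order = shuffle_rng.permutation(len(x_train))
        if config.augmentation is not None:
            plan = config.augmentation.with_seed(config.augmentation.seed * 100003 + epoch)
            epoch_batch = augment(LabeledImageBatch(x_train, y_train), plan)
            x_epoch, y_epoch = epoch_batch.images, epoch_batch.labels
        else:
            x_epoch, y_epoch = x_train, y_train
        sums = {"total": 0.0, "irm_t": 0.0, "irm": 0.0, "logits": 0.0, "gt": 0.0}
        n_seen = 0
        for start in range(0, len(order), batch_size):
            idx = order[start : start + batch_size]
            if len(idx) < 2:
                continue  # relational terms are undefined on singleton batches
            total, comps = loss_fn(x_epoch[idx], y_epoch[idx])
            if not np.isfinite(comps.total):
                bad = [k for k, v in comps.as_dict().items() if not np.isfinite(v)]
                raise FloatingPointError(
                    f"non-finite loss component(s) {bad} at epoch {epoch}"
                )
            opt.zero_grad()
            total.backward()
            opt.step()
            for key in sums:
                sums[key] += getattr(comps, key) * len(idx)
            n_seen += len(idx)
        means = {k: v / n_seen for k, v in sums.items()}
        model.eval()
        rec = EpochRecord(
            epoch=epoch,
            total=means["total"],
            irm_t=means["irm_t"],
            irm=means["irm"],
            logits=means["logits"],
            gt=means["gt"],
            train_acc=_accuracy(model, x_train, y_train),
            val_acc=_accuracy(model, x_val, y_val),
            seconds=time.perf_counter() - t0,
        )
        log.append(rec)
    model.eval()
    return log


# --------------------------------------------------------------------------
# public entry points


def train_supervised(
    model: ToyCNN, config: DistillationConfig, dataset: LabeledImageBatch | None = None
) -> TrainingLog:
    """Plain cross-entropy training of ``model`` (no teacher involved)."""
    data = _load_dataset(config, dataset)

    def loss_fn(x, y):
        gt = cls_loss_from_images(model, x, y)
        zero = MTKBreakdown(0.0, 0.0, 0.0, gt.item(), gt.item())
        return gt, zero

    return _fit(model, data, config, loss_fn, effective=(0.0, 0.0, 1.0))


def cls_loss_from_images(model: ToyCNN, images, labels) -> Tensor:
    logits, _ = model.forward(images)
    return cls_loss(logits, labels)


def train_teacher(
    config: DistillationConfig,
    dataset: LabeledImageBatch | None = None,
    out_path=None,
) -> tuple[ToyCNN, TrainingLog]:
    """Train the teacher architecture with supervised cross-entropy.

    Returns the trained model (in eval mode) and its log; writes a
    checkpoint when ``out_path`` is given.
    """
    data = _load_dataset(config, dataset)
    model = ToyCNN(list(config.teacher_widths), config.n_classes, seed=config.seed)
    log = train_supervised(model, config, data)
    if out_path is not None:
        save_checkpoint(model, out_path)
    return model, log


def _make_distill_loss(student: ToyCNN, teacher: ToyCNN | None, config: DistillationConfig):
    """Build (loss_fn, effective_weights) for the configured variant."""
    w = config.weights
    variant = config.variant

    if variant == "baseline":

        def loss_fn(x, y):
            gt = cls_loss_from_images(student, x, y)
            total = gt * w.gamma
            comps = MTKBreakdown(0.0, 0.0, 0.0, gt.item(), total.item())
            return total, comps

        return loss_fn, (0.0, 0.0, w.gamma)

    if teacher is None:
        raise IOError(f"variant {variant!r} requires a teacher model/checkpoint")

    if variant == "kd":

        def loss_fn(x, y):
            t_logits, _ = teacher.forward(x)
            s_logits, _ = student.forward(x)
            ce = cls_loss(s_logits, y)
            kd = kd_loss(t_logits.detach(), s_logits, w.temperature)
            total = combined_kd(ce, kd, config.kd_alpha)
            comps = MTKBreakdown(0.0, 0.0, kd.item(), ce.item(), total.item())
            return total, comps

        # decomposition: total = (1-kd_alpha) * "logits"(=L_KD) + kd_alpha * gt
        return loss_fn, (0.0, 1.0 - config.kd_alpha, config.kd_alpha)

    def relational_loss(x, y, use_full_mtk: bool):
        s_c = config.canonical_size
        if s_c is None:
            # common default: the smaller of the two models' final tap grids
            s_c = min(
                x.shape[-1] // 2 ** len(teacher.widths),
                x.shape[-1] // 2 ** len(student.widths),
            )
            s_c = max(s_c, 1)
        taps_t, t_logits = build_tap_set(teacher, x, s_c, config.channel_agg)
        taps_s, s_logits = build_tap_set(student, x, s_c, config.channel_agg)
        irm_term = irm_loss(build_irm(taps_t), build_irm(taps_s))
        gt_term = cls_loss(s_logits, y)
        if use_full_mtk:
            irm_t_term = irm_t_loss_pairs(taps_t, taps_s, w)
            logit_term = logits_loss(t_logits, s_logits)
            return mtk_loss(irm_t_term, irm_term, logit_term, gt_term, w)
        total = irm_term + gt_term * w.gamma
        comps = MTKBreakdown(0.0, irm_term.item(), 0.0, gt_term.item(), total.item())
        return total, comps

    if variant == "irm":
        return (lambda x, y: relational_loss(x, y, False)), (0.0, 0.0, w.gamma)
    # mtk
    return (lambda x, y: relational_loss(x, y, True)), (w.alpha, w.beta, w.gamma)


def distill(
    config: DistillationConfig,
    teacher: ToyCNN | None = None,
    dataset: LabeledImageBatch | None = None,
    out_path=None,
) -> tuple[ToyCNN, TrainingLog]:
    """Train a student under the configured loss variant.

    The teacher comes from ``teacher`` or ``config.teacher_ckpt``; it runs
    in eval mode, its parameters receive no gradients, and a checksum
    guards that they are unchanged after the run.
    """
    data = _load_dataset(config, dataset)
    if teacher is None and config.teacher_ckpt is not None:
        if not Path(config.teacher_ckpt).exists():
            raise IOError(f"teacher checkpoint not found: {config.teacher_ckpt}")
        teacher = load_checkpoint(config.teacher_ckpt)

    student = ToyCNN(list(config.student_widths), config.n_classes, seed=config.seed)
    if teacher is not None:
        if teacher.tap_spec.m != student.tap_spec.m:
            raise ConfigurationError(
                f"teacher has m={teacher.tap_spec.m} taps but student has "
                f"m={student.tap_spec.m}; the relation matrices must match"
            )
        if teacher.n_classes != config.n_classes:
            raise ValueError(
                f"teacher was trained for {teacher.n_classes} classes, config says {config.n_classes}"
            )
        teacher.eval()
        for p in teacher.parameters():
            p.requires_grad = False
        checksum_before = parameter_checksum(teacher)

    loss_fn, effective = _make_distill_loss(student, teacher, config)
    log = _fit(student, data, config, loss_fn, effective)

    if teacher is not None and parameter_checksum(teacher) != checksum_before:
        raise RuntimeError("teacher parameters changed during distillation")
    if out_path is not None:
        save_checkpoint(student, out_path)
    return student, log
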