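"""Checkpoint evaluation and the variant-comparison harness.

``evaluate`` scores a classifier on a labelled dataset (accuracy, per-class
precision/recall, confusion matrix) and attaches the size accounting used
in compression comparisons.  Latency is measured but explicitly
informational: it depends on the host machine and is never an acceptance
metric.

``compare_variants`` runs the full distillation grid — one row per loss
variant, aggregated over seeds — which is the desk-scale analogue of the
usual baseline / KD / IRM / MTK ablation table.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support

from .engine import DistillationConfig, TrainingLog, distill
from .nn import ConfigurationError, ToyCNN, load_checkpoint, parameter_count, size_bytes
from .synthetic import LabeledImageBatch, read_image_folder

__all__ = ["EvalReport", "evaluate", "compare_variants", "plot_training_log"]


@dataclass
class EvalReport:
    """Classification quality plus model-size accounting for one checkpoint."""

    accuracy: float
    per_class_precision: np.ndarray
    per_class_recall: np.ndarray
    confusion: np.ndarray  # (K, K) counts, rows = true class
    n_samples: int
    parameter_count: int
    size_bytes: int
    mean_latency_ms: float  # hardware-dependent - not an acceptance metric

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "per_class_precision": self.per_class_precision.tolist(),
            "per_class_recall": self.per_class_recall.tolist(),
            "confusion": self.confusion.tolist(),
            "n_samples": self.n_samples,
            "parameter_count": self.parameter_count,
            "size_bytes": self.size_bytes,
            "mean_latency_ms": self.mean_latency_ms,
        }


def _measure_latency(model: ToyCNN, image: np.ndarray, n_warmup: int = 10, n_runs: int = 100) -> float:
    """Median single-image forward time in ms (informational only)."""
    x = image[None]
    model.eval()
    for _ in range(n_warmup):
        model.forward(x)
    times = []
    for _ in range(n_runs):
        t0 = time.perf_counter()
        model.forward(x)
        times.append((time.perf_counter() - t0) * 1e3)
    return float(np.median(times))


def evaluate(
    model_or_ckpt,
    data,
    measure_latency: bool = False,
) -> EvalReport:
    """Score a model (or checkpoint path) on a dataset (batch or directory).

    Deterministic on fixed data: predictions are argmax with ties broken to
    the lowest class index.  Raises a configuration error when the model's
    class count does not match the dataset's.
    """
    model = model_or_ckpt if isinstance(model_or_ckpt, ToyCNN) else load_checkpoint(model_or_ckpt)
    if isinstance(data, LabeledImageBatch):
        batch = data
    else:
        batch, _ = read_image_folder(data)
    k_data = int(batch.labels.max()) + 1
    if k_data > model.n_classes:
        raise ConfigurationError(
            f"dataset has {k_data} classes but the checkpoint predicts {model.n_classes}"
        )
    preds = model.predict(batch.images)
    labels = np.arange(model.n_classes)
    conf = _sk_confusion(batch.labels, preds, labels=labels)
    prec, rec, _, _ = precision_recall_fscore_support(
        batch.labels, preds, labels=labels, zero_division=0
    )
    latency = _measure_latency(model, batch.images[0]) if measure_latency else float("nan")
    return EvalReport(
        accuracy=float(np.trace(conf) / conf.sum()),
        per_class_precision=prec,
        per_class_recall=rec,
        confusion=conf,
        n_samples=batch.n,
        parameter_count=parameter_count(model),
        size_bytes=size_bytes(model),
        mean_latency_ms=latency,
    )


def compare_variants(
    config: DistillationConfig,
    variants: list[str],
    seeds: list[int],
    teacher: ToyCNN | None = None,
    dataset: LabeledImageBatch | None = None,
    out_dir=None,
) -> pd.DataFrame:
    """Distill every (variant, seed) pair and tabulate validation accuracy.

    Returns a DataFrame with one row per variant: mean and standard
    deviation of final validation accuracy over the seeds, plus parameter
    count and size of the student.  When ``out_dir`` is given, each run's
    log (CSV) and checkpoint are persisted there.
    """
    if not variants:
        raise ValueError("need at least one variant")
    if not seeds:
        raise ValueError("need at least one seed")
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for variant in variants:
        accs = []
        student = None
        for seed in seeds:
            cfg = replace(config, variant=variant, seed=int(seed))
            ckpt = out_dir / f"student_{variant}_s{seed}.ckpt" if out_dir else None
            student, log = distill(cfg, teacher=teacher, dataset=dataset, out_path=ckpt)
            if out_dir is not None:
                log.to_csv(out_dir / f"log_{variant}_s{seed}.csv")
            accs.append(log.final_val_acc)
        rows.append(
            {
                "variant": variant,
                "accuracy_mean": float(np.mean(accs)),
                "accuracy_sd": float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
                "params": parameter_count(student),
                "size_bytes": size_bytes(student),
            }
        )
    return pd.DataFrame(rows)


def plot_training_log(log: TrainingLog, path) -> None:
    """Loss and accuracy curves of one run, written as a PNG/PDF figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = log.to_dataframe()
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    ax1.plot(df["epoch"], df["total"], label="total")
    for comp in ("irm_t", "irm", "logits", "gt"):
        if df[comp].abs().max() > 0:
            ax1.plot(df["epoch"], df[comp], label=comp, alpha=0.7)
    ax1.set_xlabel("epoch")
    ax1.set_ylabel("loss")
    ax1.legend()
    ax2.plot(df["epoch"], df["train_acc"], label="train")
    ax2.plot(df["epoch"], df["val_acc"], label="validation")
    ax2.set_xlabel("epoch")
    ax2.set_ylabel("accuracy")
    ax2.set_ylim(0, 1.02)
    ax2.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
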