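"""Training protocol for the Lite variants.

A fixed optimization regime shared by every variant: Adam (learning rate
1e-3), class-weighted softmax cross-entropy, batch size 32, at most 25
epochs. Model selection is driven by validation macro-F1 computed at the end
of every epoch: the checkpoint is (re)saved whenever the metric improves by
more than a small tolerance (1e-4), and training stops early after six
consecutive epochs without improvement. The returned model always carries the
best-checkpoint weights, never the final-epoch ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from . import litecnn as _litecnn
from . import metrics as _metrics
from .datapipe import AugmentConfig, ClassWeightTable, augment_batch, balanced_class_weights
from .litecnn import LiteModel, VariantConfig, build_model, builtin_variants
from .pairstats import StabilitySummary, stability_summary
from .synthgen import ConfigurationError, LabeledImageSet

__all__ = [
    "TrainConfig",
    "EpochRecord",
    "RunLog",
    "EvalResult",
    "weighted_cross_entropy",
    "select_best_epoch",
    "train_variant",
    "evaluate_model",
    "run_stability",
    "compare_variants",
]

_EPS = 1e-12  # probability clamp inside the log


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 25
    patience: int = 6
    improvement_tolerance: float = 1e-4
    seed: int = 42
    use_class_weights: bool = True
    reduce_lr_on_plateau: bool = False
    reduce_lr_factor: float = 0.1
    reduce_lr_patience: int = 3

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.max_epochs, self.patience) <= 0:
            raise ConfigurationError("learning_rate, batch_size, max_epochs, patience must be positive")
        if self.improvement_tolerance < 0:
            raise ConfigurationError("improvement_tolerance must be >= 0")
        if self.patience >= self.max_epochs:
            raise ConfigurationError(
                f"patience ({self.patience}) must be smaller than max_epochs ({self.max_epochs})"
            )


@dataclass(frozen=True)
class EpochRecord:
    epoch: int  # 1-based
    train_loss: float
    train_accuracy: float
    val_loss: float
    val_accuracy: float
    val_macro_f1: float


@dataclass
class RunLog:
    """Per-run reproducibility record: config, per-epoch history, best epoch."""

    variant: str
    config: TrainConfig
    records: list[EpochRecord]
    best_epoch: int
    best_val_macro_f1: float
    checkpoint_path: str
    stopped_early: bool
    environment: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "config": asdict(self.config),
            "records": [asdict(r) for r in self.records],
            "best_epoch": self.best_epoch,
            "best_val_macro_f1": self.best_val_macro_f1,
            "checkpoint_path": self.checkpoint_path,
            "stopped_early": self.stopped_early,
            "environment": self.environment,
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    def history(self, metric: str) -> list[float]:
        return [getattr(r, metric) for r in self.records]


def weighted_cross_entropy(
    probabilities: np.ndarray,
    labels: Sequence[int],
    weights: ClassWeightTable | None = None,
) -> float:
    """Mean over samples of w_y * (-ln p_y); natural log, probabilities
    clamped at 1e-12. Unit weights when no table is given."""
    p = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(labels)
    if p.ndim != 2 or len(p) != len(y):
        raise ValueError("probabilities must be (N, C) aligned with labels")
    row_sums = p.sum(axis=1)
    if np.any(np.abs(row_sums - 1.0) > 1e-6):
        raise ValueError("probability rows must sum to 1 (within 1e-6)")
    p_true = np.clip(p[np.arange(len(y)), y], _EPS, None)
    nll = -np.log(p_true)
    if weights is not None:
        nll = nll * weights.as_array(p.shape[1])[y]
    return float(nll.mean())


def select_best_epoch(
    history: Sequence[float], patience: int = 6, tolerance: float = 1e-4
) -> tuple[int, int]:
    """Replay the epoch-end selection rule on a metric history.

    An epoch improves iff its value exceeds the best so far by more than
    ``tolerance`` (the first epoch always improves); improvement resets the
    no-improvement counter and re-saves the checkpoint. Returns 1-based
    ``(best_epoch, stop_epoch)`` where ``stop_epoch`` is the epoch at which
    the counter reaches ``patience``, or the final epoch if it never does.
    """
    if len(history) == 0:
        raise ValueError("history is empty")
    best_value = -np.inf
    best_epoch = 0
    counter = 0
    for epoch, value in enumerate(history, start=1):
        if value > best_value + tolerance or best_epoch == 0:
            best_value = value
            best_epoch = epoch
            counter = 0
        else:
            counter += 1
            if counter >= patience:
                return best_epoch, epoch
    return best_epoch, len(history)


class _Adam:
    """Adam with bias correction (beta1 0.9, beta2 0.999, eps 1e-7)."""

    def __init__(self, lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-7
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self, params: list[tuple[str, object, str]]) -> None:
        self.t += 1
        b1c = 1 - self.beta1**self.t
        b2c = 1 - self.beta2**self.t
        for tag, layer, name in params:
            key = f"{tag}/{name}"
            grad = layer.grads[name].astype(np.float32)
            if key not in self.m:
                self.m[key] = np.zeros_like(grad)
                self.v[key] = np.zeros_like(grad)
            self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * grad
            self.v[key] = self.beta2 * self.v[key] + (1 - self.beta2) * grad**2
            update = self.lr * (self.m[key] / b1c) / (np.sqrt(self.v[key] / b2c) + self.eps)
            arr = layer.params[name]
            arr -= update.astype(arr.dtype)


@dataclass(frozen=True)
class EvalResult:
    loss: float
    accuracy: float
    macro_f1: float
    predictions: np.ndarray
    confusion: _metrics.ConfusionMatrix
    report: _metrics.ClassReport


def evaluate_model(
    model: LiteModel, image_set: LabeledImageSet, batch_size: int = 64
) -> EvalResult:
    """Deterministic, unaugmented evaluation over a full split."""
    probs = model.predict(image_set.images, batch_size=batch_size)
    preds = probs.argmax(axis=1)
    cm = _metrics.confusion_matrix(
        image_set.labels, preds, image_set.n_classes, image_set.class_names
    )
    report = _metrics.classification_report(cm)
    return EvalResult(
        loss=weighted_cross_entropy(probs, image_set.labels),
        accuracy=cm.accuracy(),
        macro_f1=report.macro_f1,
        predictions=preds,
        confusion=cm,
        report=report,
    )


def train_variant(
    model: LiteModel,
    train_set: LabeledImageSet,
    val_set: LabeledImageSet,
    cfg: TrainConfig = TrainConfig(),
    augment: AugmentConfig | None = AugmentConfig(),
    checkpoint_path: str | Path | None = None,
    on_epoch_end: Callable[[EpochRecord], None] | None = None,
) -> RunLog:
    """Train one variant under the fixed protocol and return its RunLog.

    The model is left holding the best-checkpoint weights (highest validation
    macro-F1, strict improvement by more than the tolerance, patience-driven
    early stop). ``augment=None`` disables train-time augmentation.
    """
    if len(val_set) == 0:
        raise ConfigurationError("validation set is empty; macro-F1 undefined")
    if len(train_set) == 0:
        raise ConfigurationError("training set is empty")

    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(1,)))
    model.set_dropout_rng(
        np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(2,)))
    )
    weight_table = balanced_class_weights(train_set.labels) if cfg.use_class_weights else None
    weight_arr = (
        weight_table.as_array(train_set.n_classes) if weight_table is not None else None
    )
    optimizer = _Adam(cfg.learning_rate)
    params = model.parameters()
    n = len(train_set)

    records: list[EpochRecord] = []
    best_f1 = -np.inf
    best_epoch = 0
    best_weights: dict[str, np.ndarray] | None = None
    counter = 0
    lr_counter = 0
    stopped_early = False

    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        epoch_correct = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb = train_set.images[idx]
            yb = train_set.labels[idx]
            if augment is not None and augment.enabled:
                xb = augment_batch(xb, augment, rng)
            probs = model.forward(xb, training=True)
            p_true = np.clip(probs[np.arange(len(yb)), yb], _EPS, None)
            sample_w = weight_arr[yb] if weight_arr is not None else np.ones(len(yb))
            epoch_loss += float((sample_w * -np.log(p_true)).sum())
            epoch_correct += int((probs.argmax(axis=1) == yb).sum())
            # d(mean_i w_i * CE_i)/d(logits): w_i * (p - onehot) / batch
            dlogits = probs.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits *= (sample_w / len(yb))[:, None]
            model.backward(dlogits.astype(np.float32))
            optimizer.step(params)

        val_eval = evaluate_model(model, val_set, batch_size=max(cfg.batch_size, 64))
        record = EpochRecord(
            epoch=epoch,
            train_loss=epoch_loss / n,
            train_accuracy=epoch_correct / n,
            val_loss=val_eval.loss,
            val_accuracy=val_eval.accuracy,
            val_macro_f1=val_eval.macro_f1,
        )
        records.append(record)
        if on_epoch_end is not None:
            on_epoch_end(record)

        if record.val_macro_f1 > best_f1 + cfg.improvement_tolerance or best_epoch == 0:
            best_f1 = record.val_macro_f1
            best_epoch = epoch
            counter = 0
            lr_counter = 0
            best_weights = model.get_weights()
            if checkpoint_path is not None:
                model.save_checkpoint(checkpoint_path)
        else:
            counter += 1
            lr_counter += 1
            if cfg.reduce_lr_on_plateau and lr_counter >= cfg.reduce_lr_patience:
                optimizer.lr *= cfg.reduce_lr_factor
                lr_counter = 0
            if counter >= cfg.patience:
                stopped_early = True
                break

    if best_weights is not None:
        model.set_weights(best_weights)

    return RunLog(
        variant=model.config.name,
        config=cfg,
        records=records,
        best_epoch=best_epoch,
        best_val_macro_f1=float(best_f1),
        checkpoint_path=str(checkpoint_path) if checkpoint_path else "",
        stopped_early=stopped_early,
        environment={
            "seed": cfg.seed,
            "class_names": list(train_set.class_names),
            "split_sizes": {"train": len(train_set), "val": len(val_set)},
            "class_weights": weight_table.weights if weight_table else None,
            "bn_momentum": _litecnn.BN_MOMENTUM,
            "bn_epsilon": _litecnn.BN_EPSILON,
            "optimizer": "adam",
            "input_size": model.config.input_size,
        },
    )


def run_stability(
    variant: VariantConfig,
    data: tuple[LabeledImageSet, LabeledImageSet, LabeledImageSet],
    cfg: TrainConfig,
    seeds: Sequence[int],
    augment: AugmentConfig | None = AugmentConfig(),
) -> tuple[StabilitySummary, list[RunLog]]:
    """Train the same variant once per seed (all else fixed) and summarise
    validation/test accuracy and macro-F1 as mean ± sample sd."""
    if len(seeds) < 2:
        raise ValueError("stability analysis needs at least 2 seeds")
    train_set, val_set, test_set = data
    logs: list[RunLog] = []
    val_acc, val_f1, test_acc, test_f1 = [], [], [], []
    for seed in seeds:
        run_cfg = TrainConfig(**{**asdict(cfg), "seed": int(seed)})
        _, model = build_model(variant, seed=int(seed))
        log = train_variant(model, train_set, val_set, run_cfg, augment=augment)
        logs.append(log)
        best = log.records[log.best_epoch - 1]
        val_acc.append(best.val_accuracy)
        val_f1.append(best.val_macro_f1)
        test_eval = evaluate_model(model, test_set)
        test_acc.append(test_eval.accuracy)
        test_f1.append(test_eval.macro_f1)
    summary = stability_summary(
        {
            "val_accuracy": val_acc,
            "val_macro_f1": val_f1,
            "test_accuracy": test_acc,
            "test_macro_f1": test_f1,
        }
    )
    return summary, logs


def compare_variants(
    variants: Mapping[str, VariantConfig],
    data: tuple[LabeledImageSet, LabeledImageSet, LabeledImageSet],
    cfg: TrainConfig,
    augment: AugmentConfig | None = AugmentConfig(),
) -> dict:
    """Train every variant under the identical pipeline, rank by best
    validation macro-F1 (ties go to the smaller model), and evaluate the
    winner's checkpoint exactly once on the held-out test set."""
    if len(variants) < 2:
        raise ValueError("need at least 2 variants to compare")
    train_set, val_set, test_set = data
    logs: dict[str, RunLog] = {}
    models: dict[str, LiteModel] = {}
    for name, vcfg in variants.items():
        _, model = build_model(vcfg, seed=cfg.seed)
        logs[name] = train_variant(model, train_set, val_set, cfg, augment=augment)
        models[name] = model
    ranking = sorted(
        variants,
        key=lambda name: (-logs[name].best_val_macro_f1, models[name].spec.parameter_count),
    )
    winner = ranking[0]
    test_eval = evaluate_model(models[winner], test_set)
    return {
        "ranking": ranking,
        "winner": winner,
        "logs": logs,
        "models": models,
        "test_eval": test_eval,
    }
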