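"""Training protocol for the encoder + BiLSTM + CRF stack.

Optimization follows the standard fine-tuning recipe for this architecture:
AdamW (decoupled weight decay) with two parameter groups — the contextual
encoder at a base learning rate and the BiLSTM/CRF head at five times that
rate — a linear-warmup + cosine-decay schedule, per-step gradient-norm
clipping, per-epoch validation macro-F1 checkpoint selection, early stopping
on a patience counter, and five-fold cross-validation.

Defaults mirror the fine-tuning setting (encoder rate 3e-5, batch 16,
50 epochs, warmup fraction 0.1, weight decay 0.01, dropout 0.1, patience
10).  Training a tiny encoder from random initialisation needs larger rates;
see the package docs for the from-scratch configuration used on synthetic
corpora.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .autodiff import Tensor
from .corpus_io import SplitSpec, TaggedSequence, split_dataset
from .evaluation import (
    mentions_from_tags,
    metrics_report,
    token_accuracy,
)
from .labels import DEFAULT_SCHEME
from .model import ModelConfig, NerTagger


class TrainingError(RuntimeError):
    pass


@dataclass
class TrainConfig:
    encoder_lr: float = 3e-5
    head_lr_multiplier: float = 5.0        # head lr = multiplier * encoder lr
    weight_decay: float = 0.01
    batch_size: int = 16
    max_epochs: int = 50
    warmup_fraction: float = 0.1
    patience: int = 10
    clip_norm: float = 1.0
    seed: int = 0
    folds: int = 5

    @property
    def head_lr(self) -> float:
        return self.head_lr_multiplier * self.encoder_lr

    def validate(self) -> None:
        if self.encoder_lr <= 0 or self.head_lr_multiplier <= 0:
            raise TrainingError("learning rates must be positive")
        if not (0.0 < self.warmup_fraction < 1.0):
            raise TrainingError("warmup fraction must lie in (0, 1)")
        if self.patience > self.max_epochs:
            raise TrainingError("patience cannot exceed max_epochs")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_macro_f1: list[float] = field(default_factory=list)
    val_per_category_f1: list[dict[str, float]] = field(default_factory=list)
    lr_trace: list[float] = field(default_factory=list)  # schedule multiplier/step
    best_epoch: int = -1


def build_schedule(total_steps: int, warmup_fraction: float
                   ) -> Callable[[int], float]:
    """Learning-rate multiplier: linear ramp 0 -> 1 over the warmup steps,
    then cosine decay 1 -> 0 over the remainder (0 at ``total_steps``)."""
    if total_steps <= 0:
        raise TrainingError("total_steps must be positive")
    if not (0.0 < warmup_fraction < 1.0):
        raise TrainingError("warmup fraction must lie in (0, 1)")
    warmup = max(1, int(round(total_steps * warmup_fraction)))

    def multiplier(step: int) -> float:
        if step < warmup:
            return step / warmup
        progress = (step - warmup) / max(1, total_steps - warmup)
        return 0.5 * (1.0 + math.cos(math.pi * min(progress, 1.0)))

    return multiplier


class AdamW:
    """Decoupled-weight-decay Adam over named parameter groups.

    Weight decay applies to weight matrices only (ndim >= 2), never to
    biases or normalization gains.
    """

    def __init__(self, groups: Sequence[tuple[dict[str, Tensor], float]],
                 weight_decay: float = 0.01, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.groups = [(dict(params), lr) for params, lr in groups]
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {name: np.zeros_like(p.data)
                  for params, _ in self.groups for name, p in params.items()}
        self.v = {name: np.zeros_like(p.data)
                  for params, _ in self.groups for name, p in params.items()}

    def zero_grad(self) -> None:
        for params, _ in self.groups:
            for p in params.values():
                p.zero_grad()

    def clip_gradients(self, max_norm: float) -> float:
        """Global-norm gradient clipping across all groups; returns the norm."""
        sq = 0.0
        for params, _ in self.groups:
            for p in params.values():
                if p.grad is not None:
                    sq += float((p.grad ** 2).sum())
        norm = math.sqrt(sq)
        if max_norm > 0 and norm > max_norm:
            scale = max_norm / (norm + 1e-12)
            for params, _ in self.groups:
                for p in params.values():
                    if p.grad is not None:
                        p.grad *= scale
        return norm

    def step(self, lr_multiplier: float = 1.0) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for params, lr in self.groups:
            eff_lr = lr * lr_multiplier
            for name, p in params.items():
                g = p.grad
                if g is None:
                    continue
                m = self.m[name] = self.b1 * self.m[name] + (1 - self.b1) * g
                v = self.v[name] = self.b2 * self.v[name] + (1 - self.b2) * g * g
                update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
                if self.weight_decay > 0 and p.data.ndim >= 2:
                    p.data -= eff_lr * self.weight_decay * p.data
                p.data -= eff_lr * update


def evaluate_tagger(model: NerTagger, sequences: Sequence[TaggedSequence]):
    """Entity-level metrics report (with token accuracy) on gold slices."""
    pred_tags = model.predict_tags(list(sequences))
    gold = mentions_from_tags(sequences, [s.tags for s in sequences], model.scheme)
    pred = mentions_from_tags(sequences, pred_tags, model.scheme)
    acc = token_accuracy([s.tags for s in sequences], pred_tags)
    return metrics_report(gold, pred, categories=model.scheme.categories,
                          accuracy=acc)


def train(model: NerTagger, train_set: Sequence[TaggedSequence],
          val_set: Sequence[TaggedSequence], config: TrainConfig,
          val_metric_fn: Callable[[NerTagger], tuple[float, dict[str, float]]] | None = None,
          verbose: bool = False,
          log_fn: Callable[[dict], None] | None = None
          ) -> tuple[dict[str, np.ndarray], TrainingHistory]:
    """Run the optimization protocol; returns (best state dict, history).

    The model is left holding the best checkpoint's parameters.  An epoch
    "improves" only if validation macro-F1 strictly exceeds the best seen;
    after ``patience`` consecutive non-improving epochs training stops.
    """
    config.validate()
    if not train_set or not val_set:
        raise TrainingError("train and validation sets must be non-empty")
    rng = np.random.default_rng(config.seed)
    drop_rng = np.random.default_rng(config.seed + 1)
    optimizer = AdamW(
        [(model.encoder_parameters(), config.encoder_lr),
         (model.head_parameters(), config.head_lr)],
        weight_decay=config.weight_decay)
    steps_per_epoch = math.ceil(len(train_set) / config.batch_size)
    schedule = build_schedule(config.max_epochs * steps_per_epoch,
                              config.warmup_fraction)
    history = TrainingHistory()
    best_f1 = -math.inf
    best_state: dict[str, np.ndarray] = model.state_dict()
    stale = 0
    step = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(train_set))
        epoch_losses: list[float] = []
        for lo in range(0, len(order), config.batch_size):
            batch = [train_set[i] for i in order[lo:lo + config.batch_size]]
            optimizer.zero_grad()
            loss = model.loss(batch, train=True, rng=drop_rng)
            value = float(loss.data)
            if not math.isfinite(value):
                raise TrainingError(
                    f"divergent loss ({value}) at epoch {epoch}, step {step}")
            loss.backward()
            optimizer.clip_gradients(config.clip_norm)
            mult = schedule(step)
            optimizer.step(mult)
            history.lr_trace.append(mult)
            epoch_losses.append(value)
            step += 1
        if val_metric_fn is not None:
            macro_f1, per_cat = val_metric_fn(model)
        else:
            report = evaluate_tagger(model, val_set)
            macro_f1 = report.macro["f1"]
            per_cat = {c: m["f1"] for c, m in report.per_category.items()}
        history.train_loss.append(float(np.mean(epoch_losses)))
        history.val_macro_f1.append(macro_f1)
        history.val_per_category_f1.append(per_cat)
        record = {"epoch": epoch, "loss": history.train_loss[-1],
                  "val_macro_f1": macro_f1, "lr_multiplier": schedule(step - 1),
                  **{f"f1_{c}": v for c, v in per_cat.items()}}
        if log_fn is not None:
            log_fn(record)
        if verbose:
            print(f"epoch {epoch}: loss={record['loss']:.4f} "
                  f"val_macro_f1={macro_f1:.4f}")
        if macro_f1 > best_f1:
            best_f1 = macro_f1
            best_state = model.state_dict()
            history.best_epoch = epoch
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    model.load_state_dict(best_state)
    return best_state, history


@dataclass
class FoldResult:
    fold: int
    macro_f1: float
    per_category_f1: dict[str, float]
    accuracy: float


def cross_validate(slices: Sequence[TaggedSequence], config: TrainConfig,
                   model_factory: Callable[[int], NerTagger],
                   verbose: bool = False) -> tuple[list[FoldResult], float]:
    """K-fold cross-validation: each fold held out once for testing, the
    remainder split train:val 5:1; reports per-fold and mean macro F1."""
    k = config.folds
    if len(slices) < k:
        raise TrainingError(f"need at least {k} sequences for {k}-fold CV")
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(slices))
    folds = np.array_split(order, k)
    results: list[FoldResult] = []
    for fi, fold_idx in enumerate(folds):
        held = set(fold_idx.tolist())
        test = [slices[i] for i in fold_idx]
        rest = [slices[i] for i in order if i not in held]
        train_part, val_part, _ = split_dataset(
            rest, SplitSpec(test_count=0, seed=config.seed + fi))
        model = model_factory(config.seed + fi)
        train(model, train_part, val_part, replace(config, seed=config.seed + fi),
              verbose=verbose)
        report = evaluate_tagger(model, test)
        results.append(FoldResult(
            fold=fi, macro_f1=report.macro["f1"],
            per_category_f1={c: m["f1"] for c, m in report.per_category.items()},
            accuracy=report.accuracy))
    mean_f1 = float(np.mean([r.macro_f1 for r in results]))
    return results, mean_f1
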