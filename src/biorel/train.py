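"""Training protocol: Adam, mini-batches of 8, early stopping on
validation micro-F1, and best-of-N random-initialisation selection.

Training minimises multiclass cross-entropy.  After every epoch the
model is scored on the validation split (micro precision/recall/F1 over
the positive categories); training stops once the F1 has not improved
for ``patience`` consecutive epochs, and the best epoch's weights are
restored.  Because small corpora make single runs unstable, the full
protocol trains the same architecture under several random seeds and
keeps the seed whose validation F1 is highest, reporting the
min/max/mean/SD across seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .encoding import EncodedInstance
from .model import ModelConfig, RelationModel
from .nn.autograd import Tensor


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 8
    max_epochs: int = 20
    patience: int = 3
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


class Adam:
    """Adaptive moment estimation over a fixed parameter list."""

    def __init__(self, params: Sequence[Tensor], cfg: TrainConfig):
        self.params = list(params)
        self.lr = cfg.learning_rate
        self.b1, self.b2, self.eps = cfg.adam_beta1, cfg.adam_beta2, cfg.adam_eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def instance_micro_prf(
    gold_labels: Sequence[str], pred_labels: Sequence[str]
) -> tuple[float, float, float]:
    """Micro P/R/F1 pooled over the positive categories ('none' excluded)."""
    tp = fp = fn = 0
    for g, p in zip(gold_labels, pred_labels):
        if p != "none" and p == g:
            tp += 1
        else:
            if p != "none":
                fp += 1
            if g != "none":
                fn += 1
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return prec, rec, f1


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    val_precision: float
    val_recall: float
    val_f1: float


@dataclass
class TrainedModel:
    model: RelationModel
    seed: int
    history: list[EpochRecord] = field(default_factory=list)
    selected_epoch: int = 0

    @property
    def val_f1(self) -> float:
        return self.history[self.selected_epoch].val_f1


def train_one(
    train_set: Sequence[EncodedInstance],
    val_set: Sequence[EncodedInstance],
    space,
    categories: Sequence[str],
    model_config: Optional[ModelConfig] = None,
    train_config: Optional[TrainConfig] = None,
    seed: int = 0,
) -> TrainedModel:
    """Train one random initialisation to early-stopping convergence."""
    if not train_set or not val_set:
        raise ValueError("both splits must be non-empty")
    if not any(e.label != "none" for e in val_set):
        raise ValueError("validation set has no positive instance; F1 is degenerate")
    tc = train_config or TrainConfig()
    model = RelationModel(space, categories, model_config, seed=seed)
    opt = Adam(model.parameters(), tc)
    order_rng = np.random.default_rng(seed + 1)
    gold_val = [e.label for e in val_set]

    history: list[EpochRecord] = []
    best_f1 = -1.0
    best_state = model.state_copy()
    best_epoch = 0
    stale = 0
    idx = np.arange(len(train_set))
    for epoch in range(tc.max_epochs):
        order_rng.shuffle(idx)
        losses = []
        for start in range(0, len(idx), tc.batch_size):
            batch = [train_set[i] for i in idx[start : start + tc.batch_size]]
            model.zero_grad()
            loss = model.loss(batch, train=True)
            loss.backward()
            model.freeze_pad_rows()
            opt.step()
            losses.append(float(loss.data))
        p, r, f1 = instance_micro_prf(gold_val, model.predict_labels(val_set))
        history.append(EpochRecord(epoch, float(np.mean(losses)), p, r, f1))
        if f1 > best_f1:
            best_f1 = f1
            best_state = model.state_copy()
            best_epoch = epoch
            stale = 0
        else:
            stale += 1
            if stale >= tc.patience:
                break
    model.load_state(best_state)
    return TrainedModel(model=model, seed=seed, history=history, selected_epoch=best_epoch)


@dataclass
class SeedSummary:
    per_seed_f1: list[float]
    minimum: float
    maximum: float
    mean: float
    sd: float


def summarize_f1(per_seed_f1: Sequence[float]) -> SeedSummary:
    a = np.asarray(per_seed_f1, dtype=float)
    sd = float(a.std(ddof=1)) if a.size > 1 else 0.0
    return SeedSummary(
        per_seed_f1=list(map(float, a)),
        minimum=float(a.min()),
        maximum=float(a.max()),
        mean=float(a.mean()),
        sd=sd,
    )


def multi_seed_select(
    train_set,
    val_set,
    space,
    categories,
    model_config: Optional[ModelConfig] = None,
    train_config: Optional[TrainConfig] = None,
    seeds: Sequence[int] = tuple(range(10)),
) -> tuple[TrainedModel, SeedSummary]:
    """Train one model per seed; keep the best validation F1.

    Mirrors the protocol of evaluating several random initialisations
    and selecting the final model on the validation split; the summary
    carries the min/max/mean/SD of the per-seed F1s.
    """
    if not seeds:
        raise ValueError("need at least one seed")
    runs = [
        train_one(train_set, val_set, space, categories, model_config,
                  train_config, seed=s)
        for s in seeds
    ]
    f1s = [r.val_f1 for r in runs]
    best = runs[int(np.argmax(f1s))]
    return best, summarize_f1(f1s)
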