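"""Training loop, data splitting and k-fold cross-validation.

BCE-optimised Adam training with a reduce-on-plateau learning-rate
schedule.  Defaults follow the segmentation setup this package implements:
learning rate 1e-3, batch size 8, 100 epochs, Adam, binary cross-entropy.
Plateau settings (patience 5, factor 0.5, floor 1e-5, improvement threshold
1e-4 on validation loss) are the framework-conventional defaults for the
named callback.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .augment import AugmentSpec, augment_pair
from .graph import ModelConfig
from .metrics import (MetricReport, aggregate_folds, basic_metrics, bce_loss,
                      confusion, roc_auc)
from .network import AttentionGatedMultiResUNet, build_network
from .nn import Adam
from .nn.layers import DTYPE, sigmoid
from .phantom import Sample

__all__ = [
    "Hyperparams",
    "FoldPlan",
    "TrainHistory",
    "split_dataset",
    "make_folds",
    "ReduceOnPlateau",
    "fit",
    "evaluate",
    "cross_validate",
    "BINARIZE_THRESHOLD",
]

log = logging.getLogger("ultraseg.train")

# sigmoid maps >= threshold to foreground (ties included)
BINARIZE_THRESHOLD = 0.5


@dataclass(frozen=True)
class Hyperparams:
    learning_rate: float = 1e-3
    batch_size: int = 8
    epochs: int = 100
    plateau_patience: int = 5
    plateau_factor: float = 0.5
    min_lr: float = 1e-5
    plateau_threshold: float = 1e-4
    val_fraction: float = 0.1
    seed: int = 0
    augment: AugmentSpec | None = None

    def __post_init__(self):
        if min(self.learning_rate, self.batch_size, self.epochs,
               self.plateau_patience, self.plateau_factor,
               self.min_lr) < 0:
            raise ValueError("hyperparameters must be positive")
        if not (0.0 < self.plateau_factor < 1.0):
            raise ValueError("plateau_factor must lie in (0, 1)")

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "learning_rate", "batch_size", "epochs", "plateau_patience",
            "plateau_factor", "min_lr", "plateau_threshold", "val_fraction",
            "seed")}
        d["augment"] = self.augment.to_dict() if self.augment else None
        return d


@dataclass(frozen=True)
class FoldPlan:
    k: int
    assignment: np.ndarray  # sample index -> fold id

    def test_indices(self, fold: int) -> np.ndarray:
        return np.nonzero(self.assignment == fold)[0]

    def train_indices(self, fold: int) -> np.ndarray:
        return np.nonzero(self.assignment != fold)[0]


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_dice: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)

    def to_rows(self) -> list[dict]:
        return [{"epoch": i + 1, "train_loss": tl, "val_loss": vl,
                 "val_dice": vd, "lr": lr}
                for i, (tl, vl, vd, lr) in enumerate(
                    zip(self.train_loss, self.val_loss, self.val_dice,
                        self.lr))]


def split_dataset(n: int, train_fraction: float, seed: int
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Shuffled disjoint train/eval split; train size is
    floor(train_fraction * n)."""
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie in (0, 1)")
    perm = np.random.default_rng(seed).permutation(n)
    n_train = int(np.floor(train_fraction * n))
    return perm[:n_train], perm[n_train:]


def make_folds(n: int, k: int, seed: int,
               labels: list | np.ndarray | None = None) -> FoldPlan:
    """k near-equal disjoint folds (sizes differ by at most one),
    stratified by class label when labels are given."""
    if k < 2:
        raise ValueError("k must be at least 2")
    if n < k:
        raise ValueError(f"cannot make {k} folds from {n} samples")
    assignment = np.empty(n, dtype=int)
    if labels is not None:
        splitter = StratifiedKFold(n_splits=k, shuffle=True,
                                   random_state=seed)
        split_iter = splitter.split(np.zeros(n), np.asarray(labels))
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        split_iter = splitter.split(np.zeros(n))
    for fold, (_, test_idx) in enumerate(split_iter):
        assignment[test_idx] = fold
    return FoldPlan(k=k, assignment=assignment)


class ReduceOnPlateau:
    """Halve (by ``plateau_factor``) the learning rate when validation loss
    stops improving by more than ``plateau_threshold`` for
    ``plateau_patience`` consecutive epochs; never below ``min_lr``."""

    def __init__(self, hp: Hyperparams):
        self.hp = hp
        self.best = np.inf
        self.wait = 0
        self.lr = hp.learning_rate

    def step(self, val_loss: float) -> float:
        if val_loss < self.best - self.hp.plateau_threshold:
            self.best = val_loss
            self.wait = 0
        else:
            self.wait += 1
            if self.wait >= self.hp.plateau_patience:
                self.lr = max(self.lr * self.hp.plateau_factor,
                              self.hp.min_lr)
                self.wait = 0
        return self.lr


def _stack(samples: list[Sample]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([s.image for s in samples]).astype(DTYPE)[:, None]
    y = np.stack([s.mask for s in samples]).astype(DTYPE)[:, None]
    return x, y


def _predict_probs(net: AttentionGatedMultiResUNet, samples: list[Sample],
                   batch: int = 8) -> np.ndarray:
    out = []
    for i in range(0, len(samples), batch):
        x, _ = _stack(samples[i:i + batch])
        out.append(sigmoid(net.forward(x, train=False)))
    return np.concatenate(out)[:, 0]


def fit(net: AttentionGatedMultiResUNet, train_samples: list[Sample],
        val_samples: list[Sample], hp: Hyperparams
        ) -> tuple[AttentionGatedMultiResUNet, TrainHistory]:
    """Adam/BCE training with per-epoch validation and plateau scheduling.

    Deterministic given ``hp.seed`` and the network's initialisation seed.
    Returns the trained network and the per-epoch history (train loss,
    validation loss, validation Dice, learning rate).
    """
    if not train_samples:
        raise ValueError("empty training set")
    if not val_samples:
        raise ValueError("empty validation set")
    rng = np.random.default_rng(hp.seed)
    opt = Adam(net.params(), lr=hp.learning_rate)
    sched = ReduceOnPlateau(hp)
    history = TrainHistory()
    yv = np.stack([s.mask for s in val_samples])

    for epoch in range(hp.epochs):
        order = rng.permutation(len(train_samples))
        losses = []
        for start in range(0, len(order), hp.batch_size):
            batch = [train_samples[i] for i in order[start:start +
                                                     hp.batch_size]]
            if hp.augment is not None:
                aug = [augment_pair(s.image, s.mask, hp.augment, rng=rng)
                       for s in batch]
                batch = [Sample(image=img, mask=msk, label=s.label,
                                seed=s.seed)
                         for (img, msk), s in zip(aug, batch)]
            x, y = _stack(batch)
            logits = net.forward(x, train=True)
            p = sigmoid(logits)
            losses.append(bce_loss(y.astype(np.uint8), p))
            if opt.lr > 0:
                dlogits = (p - y) / np.float32(p.size)
                net.zero_grad()
                net.backward(dlogits)
                opt.step()
        probs_v = _predict_probs(net, val_samples, hp.batch_size)
        val_loss = bce_loss(yv.astype(np.uint8), probs_v)
        pred_v = (probs_v >= BINARIZE_THRESHOLD).astype(np.uint8)
        c = confusion(pred_v, yv.astype(np.uint8))
        val_dice = basic_metrics(c).dice
        history.train_loss.append(float(np.mean(losses)))
        history.val_loss.append(float(val_loss))
        history.val_dice.append(float(val_dice))
        history.lr.append(opt.lr)
        opt.lr = sched.step(val_loss)
        log.info("epoch %d/%d train_loss=%.4f val_loss=%.4f val_dice=%.4f "
                 "lr=%.2e", epoch + 1, hp.epochs, history.train_loss[-1],
                 val_loss, val_dice, history.lr[-1])
    return net, history


def evaluate(net: AttentionGatedMultiResUNet, samples: list[Sample],
             batch: int = 8) -> MetricReport:
    """Pool pixel-wise confusion counts over all samples, then derive the
    metric suite; ROC-AUC over the pooled probabilities (NaN if the pooled
    truth is single-class)."""
    probs = _predict_probs(net, samples, batch)
    truth = np.stack([s.mask for s in samples]).astype(np.uint8)
    pred = (probs >= BINARIZE_THRESHOLD).astype(np.uint8)
    report = basic_metrics(confusion(pred, truth))
    try:
        report.auc = roc_auc(probs, truth)
    except ValueError:
        pass
    return report


def cross_validate(samples: list[Sample], k: int, hp: Hyperparams,
                   config: ModelConfig
                   ) -> tuple[MetricReport, FoldPlan]:
    """Train k models, each evaluated on its held-out fold, and aggregate.

    Folds are stratified by class label.  Within each fold's training
    portion a small validation slice (``hp.val_fraction``) drives the
    plateau callback only; the held-out fold never touches training.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    labels = [s.label for s in samples]
    stratify = labels if len(set(labels)) > 1 else None
    plan = make_folds(len(samples), k, hp.seed, labels=stratify)
    reports = []
    for fold in range(k):
        train_idx = plan.train_indices(fold)
        test_idx = plan.test_indices(fold)
        inner_rng = np.random.default_rng(hp.seed + 1000 + fold)
        perm = inner_rng.permutation(train_idx)
        n_val = max(1, int(round(hp.val_fraction * len(perm))))
        val_set = [samples[i] for i in perm[:n_val]]
        train_set = [samples[i] for i in perm[n_val:]]
        net = build_network(replace(config, seed=config.seed + fold))
        net, _ = fit(net, train_set, val_set, hp)
        reports.append(evaluate(net, [samples[i] for i in test_idx],
                                hp.batch_size))
        log.info("fold %d/%d dice=%.4f", fold + 1, k, reports[-1].dice)
    return aggregate_folds(reports), plan
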