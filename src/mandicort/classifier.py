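"""Stage 1 — axial slice classification.

A residual network (first convolution re-fitted for single-channel input:
1 -> 64 channels, 7x7, stride 2, padding 3, no bias; head Linear(features,
512) / ReLU / Dropout(0.2) / Linear(512, 2) / softmax) scores every axial
slice with the probability that it is the "correct" slice — the one on
which both mental foramina are visible. The slice with the highest
probability is selected for the later stages. Training uses plain SGD on
the cross-entropy of the softmax output.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .phantom import PhantomTruth
from .volume import CTVolume, normalize_volume

logger = logging.getLogger(__name__)

POSITIVE_CLASS = 1


@dataclass(frozen=True)
class ClassifierConfig:
    backbone_depth: str = "small"      # "small" or "full_101"
    lr: float = 0.001
    epochs: int = 50
    batch_size: int = 16
    dropout: float = 0.2
    seed: int = 0
    pretrained_backbone: bool = False
    pretrained_weights_path: str | None = None
    #: oversample the minority class to even odds during training; only a
    #: few slices per volume are positives, and plain SGD at a fixed small
    #: learning rate otherwise settles on the majority class
    balance_classes: bool = True
    #: restore the weights of the epoch with the highest validation
    #: accuracy (training accuracy peaks at some epoch, not the last)
    keep_best: bool = True

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError(f"learning rate must be positive, got {self.lr}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


@dataclass(frozen=True)
class SliceScore:
    slice_index: int
    probability: float


@dataclass
class ClassifierMetrics:
    accuracy: float = float("nan")
    precision: float = float("nan")
    recall: float = float("nan")
    train_loss: list = field(default_factory=list)
    train_accuracy: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_accuracy: list = field(default_factory=list)


def build_slice_classifier(cfg: ClassifierConfig) -> nn.Network:
    """Construct the two-class slice classifier (untrained)."""
    model = nn.build_network(cfg.backbone_depth, 2, softmax=True,
                             dropout=cfg.dropout, seed=cfg.seed,
                             meta={"stage": "slice_classifier"})
    if cfg.pretrained_backbone:
        if not cfg.pretrained_weights_path:
            raise ValueError(
                "pretrained_backbone=True requires pretrained_weights_path; "
                "no pretrained weight file is bundled with the package")
        model.load(cfg.pretrained_weights_path)
    return model


def _as_batches(pairs: list, batch_size: int, order: np.ndarray):
    for start in range(0, len(order), batch_size):
        idx = order[start:start + batch_size]
        x = np.stack([pairs[i][0] for i in idx])[:, None]
        y = np.array([pairs[i][1] for i in idx], dtype=np.int64)
        yield x, y


def _eval_epoch(model: nn.Network, pairs: list, batch_size: int) -> tuple[float, float]:
    losses, correct = [], 0
    order = np.arange(len(pairs))
    for x, y in _as_batches(pairs, batch_size, order):
        probs = model.forward(x, train=False)
        loss, _ = nn.nll_from_probs(probs, y)
        losses.append(loss * len(y))
        correct += int((probs.argmax(axis=1) == y).sum())
    return float(np.sum(losses) / len(pairs)), correct / len(pairs)


def train_classifier(model: nn.Network, train: list, val: list,
                     cfg: ClassifierConfig) -> tuple[nn.Network, ClassifierMetrics]:
    """SGD / cross-entropy training on (slice_image, binary_label) pairs.

    Labels: 1 for slices inside the valid band, 0 otherwise. Returns the
    trained model and per-epoch loss/accuracy histories for both sets.
    """
    if not train:
        raise ValueError("training set is empty")
    opt = nn.SGD(model.params(), lr=cfg.lr)
    shuffle_rng = np.random.default_rng(cfg.seed + 1)
    metrics = ClassifierMetrics()
    labels = np.array([y for _, y in train])
    pos_idx = np.nonzero(labels == 1)[0]
    neg_idx = np.nonzero(labels == 0)[0]
    balance = cfg.balance_classes and 0 < len(pos_idx) < len(neg_idx)
    for _epoch in range(cfg.epochs):
        if balance:
            # even odds per epoch: all positives + a fresh negative subsample
            neg_draw = shuffle_rng.choice(neg_idx, size=len(pos_idx), replace=False)
            base_idx = np.concatenate([pos_idx, neg_draw])
        else:
            base_idx = np.arange(len(train))
        order = base_idx[shuffle_rng.permutation(len(base_idx))]
        epoch_loss, correct = 0.0, 0
        for x, y in _as_batches(train, cfg.batch_size, order):
            probs = model.forward(x, train=True)
            loss, dprobs = nn.nll_from_probs(probs, y)
            model.zero_grad()
            model.backward(dprobs)
            opt.step()
            epoch_loss += loss * len(y)
            correct += int((probs.argmax(axis=1) == y).sum())
        metrics.train_loss.append(epoch_loss / len(order))
        metrics.train_accuracy.append(correct / len(order))
        if val:
            vl, va = _eval_epoch(model, val, cfg.batch_size)
            metrics.val_loss.append(vl)
            metrics.val_accuracy.append(va)
            if cfg.keep_best and va >= max(metrics.val_accuracy):
                best_state = ([p.value.copy() for p in model.params()],
                              [b.copy() for b in model.buffers()])
    if val and cfg.keep_best:
        params, buffers = best_state
        for p, v in zip(model.params(), params):
            p.value[...] = v
        for b, v in zip(model.buffers(), buffers):
            b[...] = v
    if val:
        preds, labels = predict_labels(model, val, cfg.batch_size)
        final = evaluate_classifier(preds, labels)
        metrics.accuracy = final.accuracy
        metrics.precision = final.precision
        metrics.recall = final.recall
    return model, metrics


def predict_labels(model: nn.Network, pairs: list, batch_size: int = 64
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Hard class predictions and true labels for (image, label) pairs."""
    order = np.arange(len(pairs))
    preds, labels = [], []
    for x, y in _as_batches(pairs, batch_size, order):
        probs = model.forward(x, train=False)
        preds.append(probs.argmax(axis=1))
        labels.append(y)
    return np.concatenate(preds), np.concatenate(labels)


def score_slices(model: nn.Network, vol: CTVolume, batch_size: int = 64) -> list[SliceScore]:
    """Probability of "correct slice" for every axial slice, in order."""
    if not vol.normalized:
        warnings.warn("volume is not normalized; normalizing before scoring",
                      stacklevel=2)
        vol = normalize_volume(vol)
    scores = []
    for start in range(0, vol.n_slices, batch_size):
        x = vol.data[start:start + batch_size][:, None]
        probs = model.forward(x, train=False)
        for j, p in enumerate(probs[:, POSITIVE_CLASS]):
            scores.append(SliceScore(slice_index=start + j, probability=float(p)))
    return scores


def select_optimal_slice(scores: list[SliceScore]) -> int:
    """Index of the highest-probability slice; ties go to the lowest index."""
    if not scores:
        raise ValueError("no slice scores given")
    probs = np.array([s.probability for s in scores])
    return int(scores[int(np.argmax(probs))].slice_index)


def evaluate_classifier(predictions, truth) -> ClassifierMetrics:
    """Binary accuracy / precision / recall; 0 on empty denominators."""
    pred = np.asarray(predictions, dtype=np.int64)
    true = np.asarray(truth, dtype=np.int64)
    if pred.shape != true.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {true.shape}")
    tp = int(((pred == 1) & (true == 1)).sum())
    fp = int(((pred == 1) & (true == 0)).sum())
    fn = int(((pred == 0) & (true == 1)).sum())
    accuracy = float((pred == true).mean())
    if tp + fp == 0:
        logger.info("no positive predictions; precision defined as 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        logger.info("no positive labels; recall defined as 0")
        recall = 0.0
    else:
        recall = tp / (tp + fn)
    return ClassifierMetrics(accuracy=accuracy, precision=precision, recall=recall)


# -- dataset helpers ------------------------------------------------------

def slices_from_phantoms(items: list[tuple[CTVolume, PhantomTruth]]) -> list:
    """Per-slice (image, label) pairs from normalized phantom volumes.

    Every axial slice of every volume becomes one example; the label is 1
    iff the slice lies in the truth valid band.
    """
    pairs = []
    for vol, truth in items:
        nv = vol if vol.normalized else normalize_volume(vol)
        band = set(truth.valid_slices)
        for z in range(nv.n_slices):
            pairs.append((nv.data[z], 1 if z in band else 0))
    return pairs


def slice_hit_accuracy(model: nn.Network, items: list[tuple[CTVolume, PhantomTruth]]) -> float:
    """Fraction of volumes whose selected slice falls in the truth band."""
    hits = 0
    for vol, truth in items:
        nv = vol if vol.normalized else normalize_volume(vol)
        chosen = select_optimal_slice(score_slices(model, nv))
        hits += int(chosen in truth.valid_slices)
    return hits / len(items)
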