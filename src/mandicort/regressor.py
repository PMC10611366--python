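"""Stage 2 — seven-landmark regression on the selected axial slice.

The network shares the Stage-1 backbone surgery (single-channel 7x7 stem)
but its head ends in Linear(512, 14) with no softmax: the 14 outputs are
the flattened (x, y) pixel coordinates of 5 bone-line points and 2 canal
points. Training minimizes the mean absolute coordinate error (L1, in
pixels) with Adam, which is also the reported evaluation metric; at 0.3 mm
per pixel an L1 of 1 px corresponds to 0.3 mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .landmarks import N_COORDS, LandmarkSet
from .phantom import PhantomTruth
from .volume import CTVolume, normalize_volume

MM_PER_PX = 0.3


@dataclass(frozen=True)
class RegressorConfig:
    backbone_depth: str = "small"
    lr: float = 0.001
    epochs: int = 60
    batch_size: int = 16
    dropout: float = 0.2
    seed: int = 0
    normalize_targets: bool = False  # regress coords scaled to [0, 1] instead of px
    keep_best: bool = True           # restore the weights of the min-val-L1 epoch

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError(f"learning rate must be positive, got {self.lr}")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


@dataclass
class RegressorHistory:
    train_l1: list = field(default_factory=list)  # px
    val_l1: list = field(default_factory=list)    # px


def build_keypoint_regressor(cfg: RegressorConfig) -> nn.Network:
    """Construct the 14-output landmark regressor (untrained)."""
    return nn.build_network(cfg.backbone_depth, N_COORDS, softmax=False,
                            dropout=cfg.dropout, seed=cfg.seed,
                            meta={"stage": "keypoint_regressor"})


def _target_scale(cfg: RegressorConfig, image_shape: tuple[int, int]) -> np.ndarray:
    if not cfg.normalize_targets:
        return np.ones(N_COORDS)
    h, w = image_shape
    return np.tile([w - 1.0, h - 1.0], N_COORDS // 2)


def _as_batches(pairs: list, batch_size: int, order: np.ndarray, scale: np.ndarray):
    for start in range(0, len(order), batch_size):
        idx = order[start:start + batch_size]
        x = np.stack([pairs[i][0] for i in idx])[:, None]
        t = np.stack([pairs[i][1].to_vector() / scale for i in idx])
        yield x, t


def _eval_l1_px(model, pairs, batch_size, scale) -> float:
    total = 0.0
    order = np.arange(len(pairs))
    for x, t in _as_batches(pairs, batch_size, order, scale):
        out = model.forward(x, train=False)
        total += float(np.abs((out - t) * scale).mean()) * len(x)
    return total / len(pairs)


def train_regressor(model: nn.Network, train: list, val: list,
                    cfg: RegressorConfig) -> tuple[nn.Network, RegressorHistory]:
    """Adam / L1 training on (slice_image, LandmarkSet) pairs.

    Histories are reported in pixels regardless of target scaling.
    """
    if not train:
        raise ValueError("training set is empty")
    opt = nn.Adam(model.params(), lr=cfg.lr)
    shuffle_rng = np.random.default_rng(cfg.seed + 1)
    scale = _target_scale(cfg, train[0][0].shape)
    hist = RegressorHistory()
    for _epoch in range(cfg.epochs):
        order = shuffle_rng.permutation(len(train))
        epoch_l1 = 0.0
        for x, t in _as_batches(train, cfg.batch_size, order, scale):
            out = model.forward(x, train=True)
            loss, dout = nn.l1_loss(out, t)
            model.zero_grad()
            model.backward(dout)
            opt.step()
            epoch_l1 += float(np.abs((out - t) * scale).mean()) * len(x)
        hist.train_l1.append(epoch_l1 / len(train))
        if val:
            hist.val_l1.append(_eval_l1_px(model, val, cfg.batch_size, scale))
            if cfg.keep_best and hist.val_l1[-1] <= min(hist.val_l1):
                best_state = ([p.value.copy() for p in model.params()],
                              [b.copy() for b in model.buffers()])
    if val and cfg.keep_best:
        params, buffers = best_state
        for p, v in zip(model.params(), params):
            p.value[...] = v
        for b, v in zip(model.buffers(), buffers):
            b[...] = v
    model.meta["normalize_targets"] = cfg.normalize_targets
    return model, hist


def predict_keypoints(model: nn.Network, slice_img: np.ndarray,
                      clip: bool = False) -> LandmarkSet:
    """Predict the 7 landmarks on one 2D slice.

    Predicted coordinates may fall outside the image; pass ``clip=True`` to
    clamp them to the bounds (the clip is logged via the returned values
    only — the raw prediction is otherwise untouched).
    """
    slice_img = np.asarray(slice_img, dtype=np.float64)
    if slice_img.ndim != 2:
        raise ValueError(f"expected a single 2D slice, got shape {slice_img.shape}")
    out = model.forward(slice_img[None, None], train=False)[0]
    if model.meta.get("normalize_targets"):
        h, w = slice_img.shape
        out = out * np.tile([w - 1.0, h - 1.0], N_COORDS // 2)
    lms = LandmarkSet.from_vector(out)
    if clip:
        h, w = slice_img.shape
        lms = lms.clipped(w, h)
    return lms


def evaluate_regressor(pred: list[LandmarkSet], truth: list[LandmarkSet],
                       mm_per_px: float = MM_PER_PX) -> dict:
    """L1 summary: per-coordinate MAE in px and mm, per-point Euclidean mean."""
    if len(pred) != len(truth):
        raise ValueError(f"length mismatch: {len(pred)} vs {len(truth)}")
    if not pred:
        raise ValueError("no landmark sets to evaluate")
    pv = np.stack([p.to_vector() for p in pred])
    tv = np.stack([t.to_vector() for t in truth])
    mae_px = float(np.abs(pv - tv).mean())
    diffs = (pv - tv).reshape(len(pred), -1, 2)
    euclid = float(np.linalg.norm(diffs, axis=2).mean())
    return {
        "mae_px": mae_px,
        "mae_mm": mae_px * mm_per_px,
        "mean_point_euclidean_px": euclid,
        "n": len(pred),
    }


def keypoint_pairs_from_phantoms(items: list[tuple[CTVolume, PhantomTruth]]) -> list:
    """(correct-slice image, truth LandmarkSet) training pairs."""
    pairs = []
    for vol, truth in items:
        nv = vol if vol.normalized else normalize_volume(vol)
        pairs.append((nv.data[truth.correct_slice], truth.landmarks))
    return pairs
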