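"""Residual-network builders and weight serialization.

Two backbone depths are provided behind one switch:

* ``full_101`` — the 101-layer bottleneck network (stage layout 3-4-23-3,
  2048 features after global average pooling), with the first convolution
  replaced to accept a single grayscale channel: 1 -> 64 channels, 7x7
  kernel, stride 2, padding 3, no bias.
* ``small`` — the same stem surgery followed by one basic residual block,
  64 features. Intended for desk-scale experiments on small phantom slices
  where 101 layers buy nothing.

Heads: classification = Linear(features, 512) / ReLU / Dropout(0.2) /
Linear(512, 2) / softmax; regression = same trunk but Linear(512, 14) and
no softmax (14 = 7 landmark coordinate pairs).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .blocks import BasicBlock, Bottleneck
from .layers import (BatchNorm2d, Conv2d, Dropout, GlobalAvgPool, GlobalMaxPool,
                     Linear, MaxPool2d, Module, ReLU, Sequential, Softmax)

BACKBONE_FEATURES = {"full_101": 2048, "small": 64}


class Network(Module):
    """A backbone + head pair that consumes (n, 1, h, w) image batches."""

    def __init__(self, backbone: Sequential, head: Sequential, feature_dim: int,
                 meta: dict | None = None):
        self.backbone = backbone
        self.head = head
        self.feature_dim = feature_dim
        self.meta = dict(meta or {})

    def params(self):
        return self.backbone.params() + self.head.params()

    def buffers(self):
        return self.backbone.buffers() + self.head.buffers()

    def forward(self, x, train=False):
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 2:
            x = x[None, None]
        elif x.ndim == 3:
            x = x[:, None]
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError(
                f"expected single-channel input (n, 1, h, w), got shape {x.shape}")
        feats = self.backbone.forward(x, train=train)
        return self.head.forward(feats, train=train)

    def backward(self, grad):
        return self.backbone.backward(self.head.backward(grad))

    # -- persistence ------------------------------------------------------

    def save(self, path: str | Path) -> Path:
        """Write weights (npz) plus a JSON manifest next to it."""
        path = Path(path)
        arrays = {f"p{i}": p.value for i, p in enumerate(self.params())}
        arrays.update({f"b{i}": b for i, b in enumerate(self.buffers())})
        np.savez(path, **arrays)
        if path.suffix != ".npz":
            path = path.with_suffix(path.suffix + ".npz")
        manifest = path.with_suffix(".json")
        manifest.write_text(json.dumps(self.meta, indent=2, sort_keys=True))
        return path

    def load(self, path: str | Path) -> None:
        with np.load(Path(path)) as data:
            for i, p in enumerate(self.params()):
                p.value[...] = data[f"p{i}"]
            for i, b in enumerate(self.buffers()):
                b[...] = data[f"b{i}"]


def load_network(path: str | Path) -> Network:
    """Rebuild a network from a weights file and its JSON manifest."""
    path = Path(path)
    manifest = path.with_suffix(".json")
    if not path.exists() or not manifest.exists():
        raise FileNotFoundError(f"missing weights or manifest for {path}")
    meta = json.loads(manifest.read_text())
    net = build_network(meta["depth"], meta["n_outputs"], softmax=meta["softmax"],
                        dropout=meta.get("dropout", 0.2), seed=meta.get("seed", 0),
                        meta=meta)
    net.load(path)
    return net


def _stem(rng: np.random.Generator) -> list[Module]:
    return [
        Conv2d(1, 64, 7, stride=2, padding=3, bias=False, rng=rng),
        BatchNorm2d(64),
        ReLU(),
        MaxPool2d(3, 2, 1),
    ]


def build_backbone(depth: str, rng: np.random.Generator) -> tuple[Sequential, int]:
    if depth == "small":
        # global MAX pooling: the discriminative structures (canal voids,
        # thin cortical edges) are small and local, and average pooling
        # over the 8x8 map dilutes them below what plain SGD recovers
        mods = _stem(rng) + [BasicBlock(64, 64, stride=2, rng=rng), GlobalMaxPool()]
        return Sequential(*mods), BACKBONE_FEATURES["small"]
    if depth == "full_101":
        mods = _stem(rng)
        in_ch = 64
        for mid, n_blocks, stride in ((64, 3, 1), (128, 4, 2), (256, 23, 2), (512, 3, 2)):
            for b in range(n_blocks):
                mods.append(Bottleneck(in_ch, mid, stride=stride if b == 0 else 1, rng=rng))
                in_ch = mid * Bottleneck.expansion
        mods.append(GlobalAvgPool())
        return Sequential(*mods), BACKBONE_FEATURES["full_101"]
    raise ValueError(f"unknown backbone depth {depth!r}; choose from {sorted(BACKBONE_FEATURES)}")


def build_network(depth: str, n_outputs: int, *, softmax: bool, dropout: float = 0.2,
                  seed: int = 0, meta: dict | None = None) -> Network:
    rng = np.random.default_rng(seed)
    backbone, feat = build_backbone(depth, rng)
    head_mods: list[Module] = [
        Linear(feat, 512, rng=rng),
        ReLU(),
        Dropout(dropout, rng=np.random.default_rng(rng.integers(2 ** 31))),
        Linear(512, n_outputs, rng=rng),
    ]
    if softmax:
        head_mods.append(Softmax())
    meta = dict(meta or {})
    meta.update({"depth": depth, "n_outputs": n_outputs, "softmax": softmax,
                 "dropout": dropout, "seed": seed})
    return Network(backbone, Sequential(*head_mods), feat, meta)
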