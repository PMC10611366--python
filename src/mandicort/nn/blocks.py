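"""Residual blocks (basic and bottleneck variants)."""

from __future__ import annotations

import numpy as np

from .layers import BatchNorm2d, Conv2d, Module, ReLU, Sequential


class _Residual(Module):
    """Shared add-and-rectify plumbing for residual blocks.

    Subclasses provide ``self.main`` (the residual branch) and optionally
    ``self.shortcut`` (projection when shape changes; identity otherwise).
    """

    main: Sequential
    shortcut: Sequential | None

    def params(self):
        ps = self.main.params()
        if self.shortcut is not None:
            ps = ps + self.shortcut.params()
        return ps

    def buffers(self):
        bs = self.main.buffers()
        if self.shortcut is not None:
            bs = bs + self.shortcut.buffers()
        return bs

    def forward(self, x, train=False):
        branch = self.main.forward(x, train=train)
        skip = self.shortcut.forward(x, train=train) if self.shortcut is not None else x
        out = branch + skip
        mask = out > 0
        if train:
            self._mask = mask
        return out * mask

    def backward(self, grad):
        grad = grad * self._mask
        dx_branch = self.main.backward(grad)
        dx_skip = self.shortcut.backward(grad) if self.shortcut is not None else grad
        return dx_branch + dx_skip


class BasicBlock(_Residual):
    """Two 3x3 convolutions with identity (or 1x1-projected) skip."""

    def __init__(self, in_ch: int, out_ch: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        self.main = Sequential(
            Conv2d(in_ch, out_ch, 3, stride=stride, padding=1, bias=False, rng=rng),
            BatchNorm2d(out_ch),
            ReLU(),
            Conv2d(out_ch, out_ch, 3, stride=1, padding=1, bias=False, rng=rng),
            BatchNorm2d(out_ch),
        )
        if stride != 1 or in_ch != out_ch:
            self.shortcut = Sequential(
                Conv2d(in_ch, out_ch, 1, stride=stride, bias=False, rng=rng),
                BatchNorm2d(out_ch),
            )
        else:
            self.shortcut = None


class Bottleneck(_Residual):
    """1x1 reduce, 3x3, 1x1 expand — the building block of the 101-layer net."""

    expansion = 4

    def __init__(self, in_ch: int, mid_ch: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        out_ch = mid_ch * self.expansion
        self.main = Sequential(
            Conv2d(in_ch, mid_ch, 1, bias=False, rng=rng),
            BatchNorm2d(mid_ch),
            ReLU(),
            Conv2d(mid_ch, mid_ch, 3, stride=stride, padding=1, bias=False, rng=rng),
            BatchNorm2d(mid_ch),
            ReLU(),
            Conv2d(mid_ch, out_ch, 1, bias=False, rng=rng),
            BatchNorm2d(out_ch),
        )
        if stride != 1 or in_ch != out_ch:
            self.shortcut = Sequential(
                Conv2d(in_ch, out_ch, 1, stride=stride, bias=False, rng=rng),
                BatchNorm2d(out_ch),
            )
        else:
            self.shortcut = None
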