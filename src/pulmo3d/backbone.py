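"""Residual 3D backbone shared between the rotation-pretext classifier and
the feature-pyramid detector.

The backbone is a ResNet-18-style bottom-up network: a full-resolution stem
(C1) followed by four stride-2 stages (C2..C5), each a strided conv plus
``blocks_per_stage`` basic residual blocks. Channel widths are configurable
so the same topology runs at reference scale and at the slim desk scale that
trains on a single CPU core. Because pretext model and detector build their
backbones from the same config, parameter shapes match and weights transfer
verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn


@dataclass(frozen=True)
class BackboneConfig:
    widths: tuple[int, int, int, int, int] = (8, 16, 32, 32, 32)
    blocks_per_stage: int = 0

    @staticmethod
    def reference() -> "BackboneConfig":
        return BackboneConfig(widths=(64, 64, 128, 256, 512), blocks_per_stage=2)

    @staticmethod
    def tiny() -> "BackboneConfig":
        return BackboneConfig(widths=(4, 8, 16, 16, 16), blocks_per_stage=0)


class BasicBlock(nn.Module):
    """conv-BN-ReLU-conv-BN with an identity skip, ReLU after the sum."""

    def __init__(self, ch: int, rng: np.random.Generator):
        super().__init__()
        self.body = nn.Sequential(
            nn.Conv3d(ch, ch, 3, padding=1, rng=rng), nn.BatchNorm(ch),
            nn.ReLU(),
            nn.Conv3d(ch, ch, 3, padding=1, rng=rng), nn.BatchNorm(ch))
        self._mask = None

    def forward(self, x, train: bool = True):
        y = self.body.forward(x, train=train) + x
        if train:
            self._mask = y > 0
        return np.maximum(y, 0.0)

    def backward(self, grad):
        mask, self._mask = self._mask, None
        g = grad * mask
        return self.body.backward(g) + g


class Backbone(nn.Module):
    """Returns the five stage outputs C1..C5 (C1 full resolution)."""

    def __init__(self, cfg: BackboneConfig, rng: np.random.Generator,
                 in_ch: int = 1):
        super().__init__()
        w = cfg.widths
        self.stem = nn.Sequential(
            nn.Conv3d(in_ch, w[0], 3, padding=1, rng=rng),
            nn.BatchNorm(w[0]), nn.ReLU())
        self.n_stages = 4
        for i in range(self.n_stages):
            layers = [nn.Conv3d(w[i], w[i + 1], 3, stride=2, padding=1, rng=rng),
                      nn.BatchNorm(w[i + 1]), nn.ReLU()]
            layers += [BasicBlock(w[i + 1], rng)
                       for _ in range(cfg.blocks_per_stage)]
            setattr(self, f"stage{i + 2}", nn.Sequential(*layers))

    def _stages(self):
        return [getattr(self, f"stage{i + 2}") for i in range(self.n_stages)]

    def forward(self, x, train: bool = True):
        c = self.stem.forward(x, train=train)
        outs = [c]
        for stage in self._stages():
            c = stage.forward(c, train=train)
            outs.append(c)
        return outs

    def backward(self, grads):
        """``grads`` aligns with [C1..C5]; entries may be None."""
        stages = self._stages()
        g = grads[-1]
        for i in range(self.n_stages - 1, -1, -1):
            g = stages[i].backward(g)
            if grads[i] is not None:
                g = g + grads[i]
        return self.stem.backward(g)
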