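"""Heatmap-regression U-Net for initial landmark localization.

Encoder-decoder with skip connections: each level applies two convolution
blocks (3x3 convolution, batch normalization, leaky rectifier with slope
0.1, dropout 0.3); levels are joined by 2x2 average pooling on the way
down and fixed bilinear upsampling on the way up, with skip concatenation
so the first decoder convolution of a level sees twice the base width.
The final convolution maps to one full-resolution heatmap per landmark.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .nn import (
    Conv2d, ConvBlock, Module, Tensor, avg_pool2, concat, upsample_bilinear2x,
)


@dataclass
class UNetConfig:
    levels: int = 4
    width: int = 128
    kernel: int = 3
    slope: float = 0.1
    dropout: float = 0.3
    n_landmarks: int = 37
    seed: int = 0


class UNet(Module):
    def __init__(self, cfg: UNetConfig = UNetConfig()):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        w, k = cfg.width, cfg.kernel
        blk = lambda cin: [ConvBlock(cin, w, k, rng, cfg.slope, cfg.dropout),
                           ConvBlock(w, w, k, rng, cfg.slope, cfg.dropout)]
        self.enc = [blk(1 if lvl == 0 else w) for lvl in range(cfg.levels)]
        self.dec = [blk(2 * w) for _ in range(cfg.levels)]
        self.head = Conv2d(w, cfg.n_landmarks, k, rng)

    def forward(self, x: Tensor) -> Tensor:
        cfg = self.cfg
        n, c, h, wd = x.data.shape
        d = 2 ** cfg.levels
        if h % d or wd % d:
            raise ValueError(f"frame {(h, wd)} not divisible by {d}")
        skips = []
        for blocks in self.enc:
            for b in blocks:
                x = b(x)
            skips.append(x)
            x = avg_pool2(x)
        for blocks, skip in zip(self.dec, reversed(skips)):
            x = upsample_bilinear2x(x)
            x = concat([x, skip], axis=1)
            for b in blocks:
                x = b(x)
        return self.head(x)


def heatmap_loss(pred: Tensor, target: np.ndarray, visible: np.ndarray) -> Tensor:
    """MSE over the pixels of visible-landmark channels only.

    pred: (N, L, H, W) tensor; target: matching array; visible: (N, L) bool.
    Invisible channels contribute neither to the loss nor to the gradient.
    """
    mask = np.asarray(visible, dtype=np.float32)
    n_vis = float(mask.sum())
    if n_vis == 0:
        warnings.warn("all landmarks invisible in batch; loss is zero")
        return Tensor(np.zeros(()))
    h, w = pred.data.shape[2:]
    diff = (pred - Tensor(np.asarray(target, dtype=np.float32))) * Tensor(
        mask[:, :, None, None]
    )
    return (diff * diff).sum() * (1.0 / (n_vis * h * w))


def predict_heatmaps(
    model: UNet, images: np.ndarray, batch: int = 8, normalize: bool = True
) -> np.ndarray:
    """Eval-mode forward over (N, H, W) images; returns (N, L, H, W).

    Inputs are min-max normalized to [-1, 1] per image by default, matching
    the training-time intensity preprocessing.
    """
    from .augment import normalize_intensity

    model.eval()
    outs = []
    for k in range(0, len(images), batch):
        chunk = np.asarray(images[k: k + batch], dtype=np.float32)
        if normalize:
            chunk = np.stack([normalize_intensity(im) for im in chunk])
        x = Tensor(chunk[:, None].astype(np.float32))
        outs.append(model(x).data)
    return np.concatenate(outs, axis=0)
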