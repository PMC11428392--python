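"""SpatialConfiguration-Net refinement head (implicit anatomical prior).

The local-appearance heatmaps are reduced to a coarse working resolution,
passed through a few successive large-kernel convolutions (no further
internal downsampling, batch normalization before each activation), and
the resulting spatial-filter heatmaps are upsampled back and multiplied
elementwise (Hadamard product) with the local heatmaps. The product is the
model output: a spurious local peak survives only where the coarse spatial
filter also responds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (
    BatchNorm2d, Conv2d, Module, Parameter, Tensor, avg_pool2, interp_matrix,
    resize2d,
)


@dataclass
class ScnConfig:
    n_layers: int = 3
    kernel: int = 7
    maps: int = 128
    down_factor: int = 4
    slope: float = 0.1
    n_landmarks: int = 37
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel % 2 == 0 or self.maps <= 0:
            raise ValueError("kernel must be odd and maps positive")


class SpatialConfigurationHead(Module):
    """Coarse spatial-filter component; call with the local heatmap stack."""

    def __init__(self, cfg: ScnConfig = ScnConfig()):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        L = cfg.n_landmarks
        chans = [L] + [cfg.maps] * (cfg.n_layers - 1) + [L]
        self.convs = [Conv2d(cin, cout, cfg.kernel, rng)
                      for cin, cout in zip(chans[:-1], chans[1:])]
        self.bns = [BatchNorm2d(cout) for cout in chans[1:]]

    def spatial_filter(self, local: Tensor) -> Tensor:
        """Downsample (average pooling), convolve, upsample (bilinear)."""
        cfg = self.cfg
        x = local
        f = cfg.down_factor
        while f > 1:
            x = avg_pool2(x)
            f //= 2
        for i, (conv, bn) in enumerate(zip(self.convs, self.bns)):
            x = bn(conv(x))
            if i < len(self.convs) - 1:
                x = x.leaky_relu(cfg.slope)
        h, w = local.data.shape[-2:]
        hw = x.data.shape[-2:]
        return resize2d(x, interp_matrix(hw[0], h, "bilinear"),
                        interp_matrix(hw[1], w, "bilinear"))

    def forward(self, local: Tensor) -> Tensor:
        return local * self.spatial_filter(local)


def scn_forward(local_heatmaps: np.ndarray, head: SpatialConfigurationHead) -> np.ndarray:
    """Numpy convenience wrapper around the head."""
    return head(Tensor(np.asarray(local_heatmaps, dtype=np.float32))).data.astype(float)
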