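"""Target-heatmap rendering and coordinate decoding.

A landmark's regression target is an image-sized grid that is zero except
for a Gaussian (or Laplacian) blob whose peak sits on the annotated
position, scaled by a factor gamma for numerical stability of the MSE loss.
Decoding goes either through the non-differentiable argmax or through the
differentiable soft-argmax (DSNT): rectify, normalize to a distribution,
and take the expectation of the pixel-coordinate grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landmarks import LandmarkSet

#: beta of the Softplus rectifier shared with the energy-domain refiner.
SOFTPLUS_BETA = 5.0


@dataclass(frozen=True)
class BlobConfig:
    """Blob shape for target heatmaps: peak ``gamma`` at the landmark,
    falling off as exp(-d^2/(2 sigma^2)) (gaussian) or exp(-d/sigma)
    (laplacian) with d the Euclidean pixel distance."""

    sigma: float = 3.0
    gamma: float = 1000.0
    family: str = "gaussian"

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.gamma <= 0:
            raise ValueError("sigma and gamma must be positive")
        if self.family not in ("gaussian", "laplacian"):
            raise ValueError(f"unknown blob family {self.family!r}")


@dataclass
class HeatmapStack:
    """L heatmap channels sharing one (H, W) frame; convention (u, v) =
    (column, row), 0-based."""

    grids: np.ndarray  # (L, H, W)

    def __post_init__(self) -> None:
        self.grids = np.asarray(self.grids, dtype=float)
        if self.grids.ndim != 3:
            raise ValueError("grids must be (L, H, W)")

    @property
    def frame(self) -> tuple[int, int]:
        return self.grids.shape[1], self.grids.shape[2]

    def __len__(self) -> int:
        return self.grids.shape[0]


def render_target(
    landmark: np.ndarray | tuple[float, float],
    frame: tuple[int, int],
    cfg: BlobConfig = BlobConfig(),
) -> np.ndarray:
    """Render one blob heatmap of shape ``frame`` = (H, W).

    The blob is evaluated over the whole frame (no truncation radius); a
    landmark far outside the frame therefore yields a numerically all-zero
    map through the exponential tail.
    """
    h, w = frame
    if h <= 0 or w <= 0:
        raise ValueError("frame must be positive")
    u0, v0 = float(landmark[0]), float(landmark[1])
    uu = np.arange(w, dtype=float)[None, :] - u0
    vv = np.arange(h, dtype=float)[:, None] - v0
    d2 = uu**2 + vv**2
    if cfg.family == "gaussian":
        out = cfg.gamma * np.exp(-d2 / (2.0 * cfg.sigma**2))
    else:
        out = cfg.gamma * np.exp(-np.sqrt(d2) / cfg.sigma)
    return out


def render_stack(
    landmarks: LandmarkSet, frame: tuple[int, int], cfg: BlobConfig = BlobConfig()
) -> HeatmapStack:
    """One target channel per landmark; invisible landmarks get all-zero maps."""
    grids = np.zeros((len(landmarks), *frame), dtype=float)
    for i, (xy, vis) in enumerate(zip(landmarks.coords, landmarks.visible)):
        if vis:
            grids[i] = render_target(xy, frame, cfg)
    return HeatmapStack(grids)


def save_stack(stack: HeatmapStack, path) -> None:
    """Serialize as 32-bit float NPZ with one array per channel."""
    np.savez_compressed(path, **{
        f"ch{i}": g.astype(np.float32) for i, g in enumerate(stack.grids)
    })


def load_stack(path) -> HeatmapStack:
    with np.load(path) as npz:
        grids = [npz[f"ch{i}"] for i in range(len(npz.files))]
    return HeatmapStack(np.stack(grids))


def export_png(heatmap: np.ndarray, path) -> None:
    """Min-max scaled 8-bit PNG export of one heatmap, for visualization."""
    from PIL import Image

    h = np.asarray(heatmap, dtype=float)
    lo, hi = h.min(), h.max()
    scaled = np.zeros_like(h) if hi - lo <= 0 else (h - lo) / (hi - lo)
    Image.fromarray((scaled * 255).astype(np.uint8)).save(path)


def decode_argmax(heatmap: np.ndarray) -> tuple[int, int]:
    """(u, v) of the maximum pixel; ties break to the first in row-major order."""
    heatmap = np.asarray(heatmap)
    if heatmap.size == 0:
        raise ValueError("empty heatmap")
    flat = int(np.argmax(heatmap))
    v, u = np.unravel_index(flat, heatmap.shape)
    return int(u), int(v)


def softplus(x: np.ndarray | float, beta: float = SOFTPLUS_BETA) -> np.ndarray:
    """Numerically stable (1/beta) * log(1 + exp(beta x))."""
    bx = beta * np.asarray(x, dtype=float)
    return (np.maximum(bx, 0.0) + np.log1p(np.exp(-np.abs(bx)))) / beta


def _rectify(h: np.ndarray, rectifier: str, beta: float) -> np.ndarray:
    if rectifier == "relu":
        return np.maximum(h, 0.0)
    if rectifier == "softplus":
        return softplus(h, beta)
    if rectifier == "softmax":
        return np.exp(beta * (h - h.max()))
    raise ValueError(f"unknown rectifier {rectifier!r}")


def soft_argmax_dsnt(
    heatmap: np.ndarray, rectifier: str = "relu", beta: float = SOFTPLUS_BETA
) -> tuple[float, float]:
    """Differentiable expected-coordinate decoding of a heatmap.

    The map is rectified to non-negative values, normalized to unit sum,
    and the expectation of the (u, v) pixel grid under that distribution is
    returned. A uniform map decodes to the frame centre ((W-1)/2, (H-1)/2);
    concentrating all mass on one pixel decodes to that pixel.

    Rectifiers: ``relu`` (default; identity on non-negative maps, so the
    decoded point is the exact heatmap centroid), ``softplus`` (strictly
    positive everywhere, useful when a gradient is needed on negative
    pixels), ``softmax`` (exp(beta x) weighting; sharp, suited to
    log-energy maps whose background is negative).
    """
    h = np.asarray(heatmap, dtype=float)
    p = _rectify(h, rectifier, beta)
    total = p.sum()
    if not np.isfinite(total) or total <= 0.0:
        raise ValueError("heatmap rectifies to a degenerate distribution")
    p = p / total
    us = np.arange(h.shape[1], dtype=float)
    vs = np.arange(h.shape[0], dtype=float)
    return float(p.sum(axis=0) @ us), float(p.sum(axis=1) @ vs)
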