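"""On-the-fly training augmentation: spatial, intensity, and occlusion boxes.

The spatial transform composes a rigid part (uniform translation and
rotation about the frame centre) with an elastic deformation defined by a
5x5 control grid of random displacements interpolated with cubic splines.
Images are resampled with a backward warp (linear interpolation); landmark
coordinates are pushed through the exact forward map, with the elastic
backward field inverted by fixed-point iteration so image and annotation
stay consistent. Landmarks mapped outside the frame are flagged invisible
so the training loss can mask them.

Occlusion boxes erase a randomly placed rectangle (1-15% of the pixels,
identical location for every image of a batch) and fill it with random
intensities; annotations are never modified, which forces the model to
infer occluded landmarks from global structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RectBivariateSpline
from scipy.ndimage import map_coordinates
from skimage.transform import resize as _resize

from .landmarks import LandmarkSet


@dataclass
class AugmentConfig:
    resize_to: tuple[int, int] = (256, 256)
    translate_px: tuple[float, float] = (-10.0, 10.0)
    rotate_rad: tuple[float, float] = (-0.2, 0.2)
    elastic_grid: tuple[int, int] = (5, 5)
    elastic_amp_px: float = 20.0
    spline_order: int = 3
    intensity_shift: tuple[float, float] = (-0.15, 0.15)
    intensity_scale_v: tuple[float, float] = (-0.15, 0.15)
    shift_per_pixel: bool = False
    occlusion_area_frac: tuple[float, float] = (0.01, 0.15)
    occlusion_aspect: tuple[float, float] = (0.5, 2.0)
    occlusion_enabled: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.translate_px, self.rotate_rad, self.intensity_shift,
                       self.intensity_scale_v, self.occlusion_area_frac):
            if lo > hi:
                raise ValueError(f"interval [{lo}, {hi}] is not well-ordered")
        if not (0 < self.occlusion_area_frac[0] <= self.occlusion_area_frac[1] < 1):
            raise ValueError("occlusion area fractions must lie in (0, 1)")

    def rng_for(self, epoch: int, batch_index: int) -> np.random.Generator:
        """One independent stream per (seed, epoch, batch)."""
        return np.random.default_rng((self.seed, epoch, batch_index))


def scaled_default_augment(
    frame: tuple[int, int], seed: int = 0, occlusion: bool = False
) -> AugmentConfig:
    """Default augmentation with spatial ranges scaled from the 256-frame
    convention (translation ±10 px, elastic ±20 px at 256)."""
    f = min(frame) / 256.0
    return AugmentConfig(
        resize_to=frame,
        translate_px=(-10.0 * f, 10.0 * f),
        elastic_amp_px=20.0 * f,
        occlusion_enabled=occlusion,
        seed=seed,
    )


def resize_with_landmarks(
    image: np.ndarray, landmarks: LandmarkSet, to: tuple[int, int]
) -> tuple[np.ndarray, LandmarkSet]:
    """Resize image to (H, W) and rescale coordinates accordingly."""
    h0, w0 = image.shape
    h1, w1 = to
    out = _resize(image, to, order=1, anti_aliasing=(h1 < h0), preserve_range=True)
    coords = landmarks.coords * np.array([w1 / w0, h1 / h0])
    return out.astype(float), LandmarkSet(coords, landmarks.visible.copy(), landmarks.image_id)


class _ElasticField:
    """Cubic-spline interpolation of a control grid of 2-D displacements."""

    def __init__(self, dgrid_u: np.ndarray, dgrid_v: np.ndarray,
                 frame: tuple[int, int], order: int) -> None:
        h, w = frame
        gv = np.linspace(0, h - 1, dgrid_u.shape[0])
        gu = np.linspace(0, w - 1, dgrid_u.shape[1])
        kx = ky = min(order, dgrid_u.shape[0] - 1)
        self._su = RectBivariateSpline(gv, gu, dgrid_u, kx=kx, ky=ky)
        self._sv = RectBivariateSpline(gv, gu, dgrid_v, kx=kx, ky=ky)

    def __call__(self, u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return self._su(v, u, grid=False), self._sv(v, u, grid=False)


def _sample_spatial_params(cfg: AugmentConfig, rng: np.random.Generator):
    t = rng.uniform(*cfg.translate_px, size=2)
    theta = rng.uniform(*cfg.rotate_rad)
    gh, gw = cfg.elastic_grid
    amp = cfg.elastic_amp_px
    du = rng.uniform(-amp, amp, size=(gh, gw)) if amp > 0 else np.zeros((gh, gw))
    dv = rng.uniform(-amp, amp, size=(gh, gw)) if amp > 0 else np.zeros((gh, gw))
    return t, theta, du, dv


def spatial_transform(
    image: np.ndarray,
    landmarks: LandmarkSet,
    cfg: AugmentConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, LandmarkSet]:
    """Apply one sampled translation+rotation+elastic warp to both image and
    landmarks. The image must already be at ``cfg.resize_to`` resolution."""
    h, w = image.shape
    t, theta, du, dv = _sample_spatial_params(cfg, rng)
    field = _ElasticField(du, dv, (h, w), cfg.spline_order)
    c = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])

    # forward map for landmarks: rigid, then elastic x -> x + E(x)
    p = (landmarks.coords - c) @ rot.T + c + t
    eu, ev = field(p[:, 0], p[:, 1])
    p_out = p + np.stack([eu, ev], axis=1)

    # backward map for the image: invert the elastic part by fixed point,
    # then the rigid part analytically
    vv, uu = np.mgrid[0:h, 0:w].astype(float)
    qu, qv = uu.ravel(), vv.ravel()
    xu, xv = qu.copy(), qv.copy()
    for _ in range(4):
        eu, ev = field(xu, xv)
        xu, xv = qu - eu, qv - ev
    xy = np.stack([xu, xv], axis=1)
    src = (xy - c - t) @ rot + c  # rot is orthogonal: R^-1 = R^T
    warped = map_coordinates(
        image, [src[:, 1].reshape(h, w), src[:, 0].reshape(h, w)],
        order=1, mode="constant", cval=0.0,
    )

    inside = (
        (p_out[:, 0] >= 0) & (p_out[:, 0] <= w - 1)
        & (p_out[:, 1] >= 0) & (p_out[:, 1] <= h - 1)
    )
    out_lms = LandmarkSet(p_out, landmarks.visible & inside, landmarks.image_id)
    return warped, out_lms


def normalize_intensity(image: np.ndarray) -> np.ndarray:
    """Min-max normalize to [-1, 1]; a constant image maps to all zeros."""
    lo, hi = float(image.min()), float(image.max())
    if hi - lo <= 0:
        return np.zeros_like(image, dtype=float)
    return 2.0 * (image - lo) / (hi - lo) - 1.0


def intensity_transform(
    image: np.ndarray, cfg: AugmentConfig, rng: np.random.Generator
) -> np.ndarray:
    """Normalize to [-1, 1], add a random shift, then scale v_new = v_old(1+v).

    The shift is drawn once per image by default; ``cfg.shift_per_pixel``
    switches to an independent draw per pixel.
    """
    out = normalize_intensity(image)
    if cfg.shift_per_pixel:
        out = out + rng.uniform(*cfg.intensity_shift, size=out.shape)
    else:
        out = out + rng.uniform(*cfg.intensity_shift)
    v = rng.uniform(*cfg.intensity_scale_v)
    return out * (1.0 + v)


def occlusion_boxes(
    batch: np.ndarray, cfg: AugmentConfig, rng: np.random.Generator
) -> np.ndarray:
    """Erase one random rectangle at the same location in every batch image.

    The box covers a fraction of the pixels drawn from
    ``cfg.occlusion_area_frac`` with aspect ratio in ``cfg.occlusion_aspect``
    and is filled with i.i.d. uniform noise spanning each image's intensity
    range. Returns a new array; target landmarks are the caller's business
    and remain untouched.
    """
    if not cfg.occlusion_enabled:
        return batch
    n, h, w = batch.shape
    frac = rng.uniform(*cfg.occlusion_area_frac)
    aspect = rng.uniform(*cfg.occlusion_aspect)  # width / height
    area = frac * h * w
    bw = int(np.clip(round(np.sqrt(area * aspect)), 1, w))
    bh = int(np.clip(round(area / bw), 1, h))
    v0 = int(rng.integers(0, h - bh + 1))
    u0 = int(rng.integers(0, w - bw + 1))
    noise = rng.uniform(0.0, 1.0, size=(bh, bw))
    out = batch.copy()
    for k in range(n):
        lo, hi = float(out[k].min()), float(out[k].max())
        out[k, v0:v0 + bh, u0:u0 + bw] = lo + (hi - lo) * noise
    return out
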