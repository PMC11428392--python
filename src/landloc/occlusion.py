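"""Occlusion test setting: finger sampling, circle-chain erasure, averaged
multi-run evaluation.

Each finger is independently selected with a small probability; within a
selected finger a contiguous distal run of joint pairs is occluded by a
chain of filled circles along each segment — simulating a partially or
fully missing finger — with near-zero noisy intensities. Annotations are
never modified and every landmark (occluded or not) counts equally in the
evaluation, so the protocol measures whether a model can place invisible
joints from the global hand structure. Because the occlusions are random,
metrics are averaged over repeated sampled test runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .landmarks import LandmarkSet
from .metrics import (
    DEFAULT_OUTLIER_RADII_MM, MetricsSummary, errors_for_image,
    normalization_constant, summarize,
)
from .topology import FINGER_CHAINS


@dataclass(frozen=True)
class FingerGrouping:
    """Five ordered landmark chains, MCP joint to fingertip; the thumb has
    four joints, the rest five (24 occludable landmarks in total)."""

    chains: tuple[tuple[int, ...], ...] = FINGER_CHAINS

    def __post_init__(self) -> None:
        flat = [i for c in self.chains for i in c]
        if len(flat) != len(set(flat)):
            raise ValueError("finger chains must be disjoint")

    @property
    def occludable(self) -> frozenset[int]:
        return frozenset(i for c in self.chains for i in c)


@dataclass
class OcclusionTestConfig:
    finger_select_prob: float = 0.2
    circle_radius_px: float = 10.0  # for a 256-frame; scaled proportionally
    noise_sd: float = 0.02
    runs_per_fold: int = 30
    pair_mode: str = "distal_suffix"  # or "uniform_pair"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.finger_select_prob <= 1):
            raise ValueError("finger_select_prob must lie in [0, 1]")
        if self.circle_radius_px <= 0:
            raise ValueError("circle radius must be positive")


def radius_for_frame(cfg: OcclusionTestConfig, frame: tuple[int, int]) -> float:
    return cfg.circle_radius_px * min(frame) / 256.0


def sample_occlusion_plan(
    landmarks: LandmarkSet,
    grouping: FingerGrouping,
    cfg: OcclusionTestConfig,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Joint pairs (l_i, l_{i+1}) to occlude for one image.

    Each finger enters with probability ``finger_select_prob``; a selected
    finger contributes a uniformly chosen contiguous distal suffix of its
    joint pairs — possibly empty, so a selected finger may stay intact.
    The ``uniform_pair`` mode instead draws one uniformly chosen pair (or
    none) per selected finger.
    """
    plan: list[tuple[int, int]] = []
    for chain in grouping.chains:
        if rng.random() >= cfg.finger_select_prob:
            continue
        pairs = list(zip(chain[:-1], chain[1:]))
        if cfg.pair_mode == "distal_suffix":
            m = int(rng.integers(0, len(pairs) + 1))  # 0 = no occlusion
            plan.extend(pairs[len(pairs) - m:])
        elif cfg.pair_mode == "uniform_pair":
            k = int(rng.integers(-1, len(pairs)))
            if k >= 0:
                plan.append(pairs[k])
        else:
            raise ValueError(f"unknown pair_mode {cfg.pair_mode!r}")
    return plan


def occlude_segment(
    image: np.ndarray,
    l_i: Sequence[float],
    l_ip1: Sequence[float],
    r: float,
    rng: np.random.Generator,
    noise_sd: float = 0.02,
) -> np.ndarray:
    """Erase the segment between two joints with a chain of filled circles.

    With v = l_i - l_{i+1} and c = floor(||v|| / r), circles of radius r are
    centred at l_{i+1} + k * v/c for k = 0..c (both joints covered), filled
    with zero intensity plus Gaussian noise, clipped to the frame. If the
    joints are closer than r (c = 0) a single circle at the midpoint is
    drawn. Only pixels within r of some centre change.
    """
    if r <= 0:
        raise ValueError("radius must be positive")
    a = np.asarray(l_i, dtype=float)
    b = np.asarray(l_ip1, dtype=float)
    v = a - b
    norm = float(np.linalg.norm(v))
    c = int(np.floor(norm / r))
    if c == 0:
        centres = [(a + b) / 2.0]
    else:
        t = v / c
        centres = [b + k * t for k in range(c + 1)]
    h, w = image.shape
    out = image.copy()
    for ctr in centres:
        u0 = int(np.floor(ctr[0] - r)); u1 = int(np.ceil(ctr[0] + r)) + 1
        v0 = int(np.floor(ctr[1] - r)); v1 = int(np.ceil(ctr[1] + r)) + 1
        u0, u1 = max(u0, 0), min(u1, w)
        v0, v1 = max(v0, 0), min(v1, h)
        if u0 >= u1 or v0 >= v1:
            continue
        vv, uu = np.mgrid[v0:v1, u0:u1]
        mask = (uu - ctr[0]) ** 2 + (vv - ctr[1]) ** 2 <= r**2
        patch = out[v0:v1, u0:u1]
        patch[mask] = rng.normal(0.0, noise_sd, size=int(mask.sum()))
    return out


def occlude_image(
    image: np.ndarray,
    landmarks: LandmarkSet,
    grouping: FingerGrouping,
    cfg: OcclusionTestConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Sample a plan and apply it; annotations are left untouched."""
    plan = sample_occlusion_plan(landmarks, grouping, cfg, rng)
    r = radius_for_frame(cfg, image.shape)
    out = image
    for i, j in plan:
        out = occlude_segment(out, landmarks.get(i), landmarks.get(j), r, rng,
                              cfg.noise_sd)
    return out, plan


def run_occlusion_eval(
    predictor: Callable[[np.ndarray], np.ndarray],
    images: list[np.ndarray],
    landmarks: list[LandmarkSet],
    grouping: FingerGrouping = FingerGrouping(),
    cfg: OcclusionTestConfig = OcclusionTestConfig(),
    radii_mm: Sequence[float] = DEFAULT_OUTLIER_RADII_MM,
) -> MetricsSummary:
    """Averaged occlusion-setting metrics over ``runs_per_fold`` sampled runs.

    ``predictor`` maps an (N, H, W) image array to (N, L, 2) coordinates.
    Per run, the test images are freshly occluded and all landmark
    predictions enter the metrics (targets unchanged). Outlier counts are
    averaged across runs and percentages computed from the averaged counts;
    median/mean/SD are averaged. Deterministic under ``cfg.seed``.
    """
    per_run: list[MetricsSummary] = []
    for run in range(cfg.runs_per_fold):
        rng = np.random.default_rng((cfg.seed, run))
        occluded = np.stack([
            occlude_image(img, lms, grouping, cfg, rng)[0]
            for img, lms in zip(images, landmarks)
        ])
        preds = np.asarray(predictor(occluded))
        errs = []
        for p, lms in zip(preds, landmarks):
            s = normalization_constant(lms)
            errs.extend(errors_for_image(LandmarkSet(p, image_id=lms.image_id),
                                         lms, s))
        per_run.append(summarize(errs, radii_mm))
    n = per_run[0].n_predictions
    counts = {
        r: float(np.mean([s.outlier_counts[r] for s in per_run]))
        for r in per_run[0].outlier_counts
    }
    return MetricsSummary(
        median_mm=float(np.mean([s.median_mm for s in per_run])),
        mean_mm=float(np.mean([s.mean_mm for s in per_run])),
        sd_mm=float(np.mean([s.sd_mm for s in per_run])),
        outlier_counts=counts,
        outlier_pct={r: 100.0 * c / n for r, c in counts.items()},
        n_predictions=n,
    )
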