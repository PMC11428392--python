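"""Conditional displacement priors p(i|j) from annotated training coordinates.

For an ordered landmark pair (i, j), each training annotation contributes
the position of landmark i after the translation that moves landmark j to
the centre of a frame of twice the image resolution (doubling guarantees
every possible displacement stays on the grid). A Gaussian mixture with
1..10 components is fitted to these samples; the component count minimizing
the mean of AIC and BIC is kept, and the selected density is rasterized at
pixel centres onto the doubled grid. The grids are treated as energies
downstream, so no normalization to unit sum is applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
from sklearn.mixture import GaussianMixture

from .augment import AugmentConfig, spatial_transform
from .landmarks import LandmarkSet
from .topology import Topology


@dataclass(frozen=True)
class GmmFitConfig:
    max_components: int = 10
    samples_per_image: int = 3
    covariance: str = "full"
    reg_covar: float = 1e-3  # ridge floor (px^2) against degenerate clusters
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_components < 1:
            raise ValueError("max_components must be >= 1")


@dataclass
class ConditionalPrior:
    """Rasterized displacement density for the ordered pair (i, j), on a grid
    of exactly twice the localization frame."""

    pair: tuple[int, int]
    grid: np.ndarray  # (2H, 2W)
    n_components: int
    frame: tuple[int, int]

    def __post_init__(self) -> None:
        h, w = self.frame
        if self.grid.shape != (2 * h, 2 * w):
            raise ValueError(
                f"prior grid must be {(2 * h, 2 * w)}, got {self.grid.shape}"
            )


def doubled_centre(frame: tuple[int, int]) -> np.ndarray:
    """Centre pixel of the doubled frame: (W, H) for a frame (H, W)."""
    h, w = frame
    return np.array([float(w), float(h)])


def displacement_sample(
    l_i: np.ndarray, l_j: np.ndarray, frame: tuple[int, int]
) -> np.ndarray:
    """Position of landmark i in the doubled frame after translating
    landmark j to the doubled-frame centre: centre + (l_i - l_j)."""
    return doubled_centre(frame) + (np.asarray(l_i, float) - np.asarray(l_j, float))


class InsufficientSamplesError(ValueError):
    pass


def fit_gmm_mean_ic(
    samples: np.ndarray, cfg: GmmFitConfig
) -> GaussianMixture:
    """Fit 1..max_components mixtures; keep the count minimizing (AIC+BIC)/2,
    ties broken toward fewer components."""
    samples = np.asarray(samples, dtype=float)
    if len(samples) < 2:
        raise InsufficientSamplesError("need at least 2 displacement samples")
    max_k = min(cfg.max_components, len(samples) // 2)
    best, best_score = None, np.inf
    for k in range(1, max_k + 1):
        gm = GaussianMixture(
            n_components=k,
            covariance_type=cfg.covariance,
            reg_covar=cfg.reg_covar,
            init_params="kmeans",
            random_state=cfg.seed,
            n_init=1,
        ).fit(samples)
        score = 0.5 * (gm.aic(samples) + gm.bic(samples))
        if score < best_score - 1e-9:  # strict improvement: ties keep fewer
            best, best_score = gm, score
    assert best is not None
    return best


def rasterize_mixture(
    gm: GaussianMixture, frame: tuple[int, int]
) -> np.ndarray:
    """Evaluate the mixture density at pixel centres of the doubled grid."""
    h, w = frame
    vv, uu = np.mgrid[0: 2 * h, 0: 2 * w].astype(float)
    pts = np.stack([uu.ravel(), vv.ravel()], axis=1)
    dens = np.exp(gm.score_samples(pts)).reshape(2 * h, 2 * w)
    return dens


def fit_conditional(
    samples: np.ndarray,
    frame: tuple[int, int],
    cfg: GmmFitConfig = GmmFitConfig(),
    pair: tuple[int, int] = (0, 0),
) -> ConditionalPrior:
    """GMM fit + rasterization for one ordered pair; see module docstring."""
    gm = fit_gmm_mean_ic(np.asarray(samples, float), cfg)
    return ConditionalPrior(
        pair=pair,
        grid=rasterize_mixture(gm, frame),
        n_components=int(gm.n_components),
        frame=frame,
    )


class MissingPriorError(KeyError):
    pass


def collect_displacement_samples(
    landmark_sets: list[LandmarkSet],
    topology: Topology,
    frame: tuple[int, int],
    augment: AugmentConfig | None = None,
    samples_per_image: int = 3,
    seed: int = 0,
) -> dict[tuple[int, int], np.ndarray]:
    """Displacement samples for every ordered (i, j in N_i) pair.

    Each training annotation is sampled ``samples_per_image`` times under
    spatial augmentation only (translation/rotation/elastic); intensity and
    occlusion perturbations do not move coordinates and are skipped. Pass
    ``augment=None`` to sample the raw annotations once.
    """
    rng = np.random.default_rng(seed)
    pairs = topology.message_pairs()
    buckets: dict[tuple[int, int], list[np.ndarray]] = {p: [] for p in pairs}
    dummy = np.zeros((4, 4))
    for lms in landmark_sets:
        draws = []
        if augment is None:
            draws.append(lms)
        else:
            spatial_only = replace(augment, occlusion_enabled=False)
            h, w = frame
            for _ in range(samples_per_image):
                # only coordinates matter here; warp a dummy image
                _, lm_aug = spatial_transform(
                    np.zeros((h, w)), lms, spatial_only, rng
                )
                draws.append(lm_aug)
        for lm in draws:
            for i, j in pairs:
                if lm.visible[i - 1] and lm.visible[j - 1]:
                    buckets[(i, j)].append(
                        displacement_sample(lm.get(i), lm.get(j), frame)
                    )
    out: dict[tuple[int, int], np.ndarray] = {}
    for p, vals in buckets.items():
        if not vals:
            raise MissingPriorError(
                f"no visible training samples for landmark pair {p}"
            )
        out[p] = np.asarray(vals)
    return out


def build_prior_bank(
    landmark_sets: list[LandmarkSet],
    topology: Topology,
    frame: tuple[int, int],
    cfg: GmmFitConfig = GmmFitConfig(),
    augment: AugmentConfig | None = None,
) -> dict[tuple[int, int], ConditionalPrior]:
    """Fit a ConditionalPrior for every ordered pair required by the topology."""
    samples = collect_displacement_samples(
        landmark_sets, topology, frame,
        augment=augment, samples_per_image=cfg.samples_per_image, seed=cfg.seed,
    )
    return {
        p: fit_conditional(vals, frame, cfg, pair=p) for p, vals in samples.items()
    }


def save_prior_bank(
    bank: Mapping[tuple[int, int], ConditionalPrior], path: str | Path
) -> None:
    """Single NPZ keyed "p_{i}|{j}" plus a JSON metadata sidecar."""
    path = Path(path)
    arrays = {f"p_{i}|{j}": prior.grid for (i, j), prior in bank.items()}
    np.savez_compressed(path, **arrays)
    meta = {
        f"{i}|{j}": {"n_components": prior.n_components, "frame": list(prior.frame)}
        for (i, j), prior in bank.items()
    }
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))


def load_prior_bank(path: str | Path) -> dict[tuple[int, int], ConditionalPrior]:
    path = Path(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    with np.load(path) as npz:
        bank = {}
        for key, arr in npz.items():
            i, j = key[2:].split("|")
            m = meta[f"{i}|{j}"]
            bank[(int(i), int(j))] = ConditionalPrior(
                pair=(int(i), int(j)),
                grid=arr,
                n_components=int(m["n_components"]),
                frame=tuple(m["frame"]),
            )
    return bank
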