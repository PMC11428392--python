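"""End-to-end training loop: augmentation pipeline, loss balancing, Adam.

One training run follows a fixed-epoch schedule without early stopping.
Each batch is augmented on the fly (spatial, intensity, then batch-wide
occlusion boxes), targets are rendered from the transformed coordinates
(equivalent to warping the target heatmaps with the same spatial
transform), and landmarks that left the frame are masked out of both loss
terms. When a refinement head is attached the total loss is
``heatmap MSE + lambda * coordinate MSE`` with lambda set once from the
first batch so both terms start at the same magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .augment import AugmentConfig, intensity_transform, occlusion_boxes, spatial_transform
from .gaffa import GaffaRefiner, coordinate_loss
from .heatmaps import BlobConfig, render_stack
from .landmarks import LandmarkSet
from .nn import Adam, Tensor
from .unet import UNet, heatmap_loss


@dataclass
class TrainConfig:
    epochs: int = 800
    batch: int = 8
    lr: float = 1e-3
    loss_balance: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch) < 1 or self.lr <= 0:
            raise ValueError("hyperparameters must be positive")


def augment_batch(
    images: list[np.ndarray],
    landmarks: list[LandmarkSet],
    aug: AugmentConfig,
    blob: BlobConfig,
    rng: np.random.Generator,
):
    """Augmented (x, targets, coords, visible) arrays for one batch."""
    frame = images[0].shape
    xs, tgts, coords, vis = [], [], [], []
    lms_aug = []
    for img, lms in zip(images, landmarks):
        img_t, lms_t = spatial_transform(img, lms, aug, rng)
        img_t = intensity_transform(img_t, aug, rng)
        xs.append(img_t)
        lms_aug.append(lms_t)
    batch = np.stack(xs)
    batch = occlusion_boxes(batch, aug, rng)
    for lms_t in lms_aug:
        tgts.append(render_stack(lms_t, frame, blob).grids)
        coords.append(lms_t.coords)
        vis.append(lms_t.visible)
    return (
        batch[:, None].astype(np.float32),
        np.stack(tgts).astype(np.float32),
        np.stack(coords).astype(np.float32),
        np.stack(vis),
    )


class DivergenceError(RuntimeError):
    pass


def train(
    model: UNet,
    images: list[np.ndarray],
    landmarks: list[LandmarkSet],
    cfg: TrainConfig,
    aug: AugmentConfig,
    blob: BlobConfig = BlobConfig(),
    refiner: GaffaRefiner | None = None,
    scn_head=None,
) -> dict:
    """Train the localizer, optionally jointly with an attached refinement
    head: either the sum-product ``refiner`` (adds the balanced coordinate
    loss) or an ``scn_head`` whose Hadamard-product output replaces the
    localizer heatmaps in the MSE (the loss only sees the final heatmap).

    Returns a history dict with per-epoch mean losses and the frozen
    loss-balance factor ``lambda``.
    """
    if refiner is not None and scn_head is not None:
        raise ValueError("attach either the sum-product refiner or the "
                         "spatial-configuration head, not both")
    params = model.parameters() + (refiner.parameters() if refiner else [])
    if scn_head is not None:
        params += scn_head.parameters()
    opt = Adam(params, lr=cfg.lr)
    order_rng = np.random.default_rng(cfg.seed)
    n = len(images)
    lam: float | None = None
    history: dict = {"heatmap_loss": [], "coord_loss": [], "total_loss": []}
    model.train()
    if refiner is not None:
        refiner.train()
    if scn_head is not None:
        scn_head.train()
    for epoch in range(cfg.epochs):
        perm = order_rng.permutation(n)
        ep_h, ep_c, ep_t, nb = 0.0, 0.0, 0.0, 0
        for bi, k in enumerate(range(0, n, cfg.batch)):
            idx = perm[k: k + cfg.batch]
            rng = aug.rng_for(epoch, bi)
            x, tgt, coords, vis = augment_batch(
                [images[i] for i in idx], [landmarks[i] for i in idx], aug, blob, rng
            )
            opt.zero_grad()
            pred = model(Tensor(x))
            if scn_head is not None:
                pred = scn_head(pred)
            loss_h = heatmap_loss(pred, tgt, vis)
            if refiner is not None:
                _, pred_coords = refiner(pred)
                loss_c = coordinate_loss(pred_coords, coords, vis)
                if lam is None:
                    lam = (loss_h.item() / max(loss_c.item(), 1e-12)
                           if cfg.loss_balance else 1.0)
                loss = loss_h + float(lam) * loss_c
                ep_c += loss_c.item()
            else:
                loss = loss_h
            if not np.isfinite(loss.item()):
                raise DivergenceError(
                    f"non-finite loss at epoch {epoch}, batch {bi}: "
                    f"heatmap={loss_h.item()}"
                )
            loss.backward()
            opt.step()
            ep_h += loss_h.item()
            ep_t += loss.item()
            nb += 1
        history["heatmap_loss"].append(ep_h / nb)
        history["coord_loss"].append(ep_c / nb if refiner else 0.0)
        history["total_loss"].append(ep_t / nb)
    history["lambda"] = lam
    return history
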