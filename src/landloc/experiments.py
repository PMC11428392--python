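"""Scaled-down end-to-end experiments on synthetic hands.

The benchmark mirrors the full training protocol at a desk scale: generate
a synthetic hand dataset, train the heatmap-regression localizer, estimate
conditional priors from the training annotations, attach the sum-product
refiner and fine-tune end-to-end, then evaluate the clean test error and
the occlusion setting comparing the localizer alone against the refined
output. Problem sizes (image resolution, network width, epoch counts) are
deliberately small so a full run completes in minutes on one CPU core;
see docs/methods.md for the choices.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .augment import scaled_default_augment as _aug_for_frame
from .gaffa import GaffaConfig, GaffaRefiner
from .heatmaps import BlobConfig, decode_argmax
from .landmarks import LandmarkSet
from .metrics import summarize
from .occlusion import FingerGrouping, OcclusionTestConfig, run_occlusion_eval
from .priors import GmmFitConfig, build_prior_bank
from .synthetic import SyntheticConfig, make_dataset
from .topology import default_hand_topology
from .training import TrainConfig, train
from .unet import UNet, UNetConfig, predict_heatmaps


@dataclass
class BenchmarkConfig:
    """Study conditions of the scaled end-to-end run."""

    n_images: int = 60
    frame: tuple[int, int] = (64, 64)
    seed: int = 0
    unet_levels: int = 3
    unet_width: int = 16
    unet_dropout: float = 0.1
    epochs_localizer: int = 60
    epochs_joint: int = 15
    batch: int = 8
    lr: float = 3e-3
    blob_sigma: float = 2.0
    blob_gamma: float = 100.0
    down_factor: int = 4
    gmm_max_components: int = 3
    occlusion_runs: int = 10
    finger_select_prob: float = 0.2
    outlier_radius_px: float = 10.0




def run_scaled_benchmark(seed: int = 0, cfg: BenchmarkConfig | None = None) -> dict:
    """Full pipeline on fold 0 of a synthetic dataset; returns a flat dict
    of the quantities the run computes (pixel units)."""
    cfg = cfg or BenchmarkConfig(seed=seed)
    cfg.seed = seed
    t0 = time.time()
    topo = default_hand_topology()

    ds = make_dataset(SyntheticConfig(
        n_images=cfg.n_images, frame=cfg.frame, seed=seed))
    train_idx, test_idx = ds.folds[0]
    tr_imgs = [ds.images[i] for i in train_idx]
    tr_lms = [ds.landmarks[i] for i in train_idx]
    te_imgs = [ds.images[i] for i in test_idx]
    te_lms = [ds.landmarks[i] for i in test_idx]

    aug = _aug_for_frame(cfg.frame, seed)
    blob = BlobConfig(sigma=cfg.blob_sigma, gamma=cfg.blob_gamma)
    model = UNet(UNetConfig(levels=cfg.unet_levels, width=cfg.unet_width,
                            dropout=cfg.unet_dropout, seed=seed))

    # stage 1: localizer alone
    tc = TrainConfig(epochs=cfg.epochs_localizer, batch=cfg.batch, lr=cfg.lr,
                     seed=seed)
    hist1 = train(model, tr_imgs, tr_lms, tc, aug, blob)

    # conditional priors from the (augmented) training annotations
    bank = build_prior_bank(
        tr_lms, topo, cfg.frame,
        GmmFitConfig(max_components=cfg.gmm_max_components, seed=seed),
        augment=aug,
    )
    refiner = GaffaRefiner(bank, topo, cfg.frame,
                           GaffaConfig(down_factor=cfg.down_factor))

    # stage 2: joint end-to-end fine-tuning with the refiner attached
    tc2 = TrainConfig(epochs=cfg.epochs_joint, batch=cfg.batch, lr=cfg.lr,
                      seed=(seed + 1) % 2**31)
    hist2 = train(model, tr_imgs, tr_lms, tc2, aug, blob, refiner=refiner)

    # predictors -----------------------------------------------------------
    def predict_unet(images: np.ndarray) -> np.ndarray:
        hm = predict_heatmaps(model, images, batch=cfg.batch)
        return np.array([[decode_argmax(ch) for ch in im] for im in hm], float)

    def predict_gaffa(images: np.ndarray) -> np.ndarray:
        hm = predict_heatmaps(model, images, batch=cfg.batch)
        refiner.eval()
        coords = []
        for k in range(0, len(hm), cfg.batch):
            _, c = refiner.refine_numpy(hm[k: k + cfg.batch])
            coords.append(c)
        return np.concatenate(coords, axis=0)

    # clean test error in pixels (scale = 1)
    te_arr = np.stack(te_imgs)
    pred_g = predict_gaffa(te_arr)
    pred_u = predict_unet(te_arr)
    radii = (2.0, 4.0, cfg.outlier_radius_px)

    def _pe(preds):
        errs = np.concatenate([
            np.linalg.norm(p - lms.coords, axis=1)[lms.visible]
            for p, lms in zip(preds, te_lms)
        ])
        return summarize(errs, radii)

    clean_g, clean_u = _pe(pred_g), _pe(pred_u)

    # occlusion setting: localizer alone vs refined output, identical seeds
    occ_cfg = OcclusionTestConfig(
        finger_select_prob=cfg.finger_select_prob,
        runs_per_fold=cfg.occlusion_runs,
        seed=seed,
    )
    grouping = FingerGrouping()

    from .occlusion import occlude_image

    def eval_occ(predictor):
        per_run = []
        for run in range(occ_cfg.runs_per_fold):
            rng = np.random.default_rng((occ_cfg.seed, run))
            occl = np.stack([
                occlude_image(img, lms, grouping, occ_cfg, rng)[0]
                for img, lms in zip(te_imgs, te_lms)
            ])
            preds = predictor(occl)
            errs = np.concatenate([
                np.linalg.norm(p - lms.coords, axis=1)[lms.visible]
                for p, lms in zip(preds, te_lms)
            ])
            per_run.append(summarize(errs, radii))
        counts = {r: float(np.mean([s.outlier_counts[r] for s in per_run]))
                  for r in radii}
        return {
            "mean_px": float(np.mean([s.mean_mm for s in per_run])),
            "outliers": counts,
            "n": per_run[0].n_predictions,
        }

    occ_u = eval_occ(predict_unet)
    occ_g = eval_occ(predict_gaffa)

    return {
        "clean_mean_pe_px_gaffa": clean_g.mean_mm,
        "clean_mean_pe_px_unet": clean_u.mean_mm,
        "clean_median_pe_px_gaffa": clean_g.median_mm,
        "occl_mean_pe_px_unet": occ_u["mean_px"],
        "occl_mean_pe_px_gaffa": occ_g["mean_px"],
        "occl_outliers_gt10px_unet": occ_u["outliers"][cfg.outlier_radius_px],
        "occl_outliers_gt10px_gaffa": occ_g["outliers"][cfg.outlier_radius_px],
        "n_test_predictions": occ_u["n"],
        "final_heatmap_loss": hist2["heatmap_loss"][-1],
        "final_coord_loss": hist2["coord_loss"][-1],
        "loss_lambda": hist2["lambda"],
        "runtime_s": time.time() - t0,
        "n_train": len(tr_imgs),
        "n_test": len(te_imgs),
    }
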