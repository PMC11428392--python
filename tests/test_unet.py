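"""Localizer architecture contract, loss masking, and a small training run."""

import numpy as np
import pytest

from landloc.nn import Parameter, Tensor
from landloc.unet import UNet, UNetConfig, heatmap_loss, predict_heatmaps


def _tiny(levels=2, width=4, n_landmarks=3, seed=0, dropout=0.0):
    return UNet(UNetConfig(levels=levels, width=width, n_landmarks=n_landmarks,
                           dropout=dropout, seed=seed))


class TestForward:
    def test_output_one_heatmap_per_landmark(self, rng):
        model = _tiny(levels=2, width=4, n_landmarks=5)
        out = model(Tensor(rng.normal(size=(2, 1, 32, 32)).astype(np.float32)))
        assert out.data.shape == (2, 5, 32, 32)
        assert np.isfinite(out.data).all()

    def test_frame_divisibility_enforced(self, rng):
        model = _tiny(levels=3)
        with pytest.raises(ValueError):
            model(Tensor(rng.normal(size=(1, 1, 20, 20)).astype(np.float32)))

    def test_parameter_count_matches_architecture_formula(self):
        """Closed-form parameter count from the config: conv weights+biases
        plus batch-norm affine pairs per block, plus the output head."""
        levels, w, k, L = 2, 4, 3, 3
        model = _tiny(levels=levels, width=w, n_landmarks=L)

        def conv_params(cin, cout):
            return cin * cout * k * k + cout

        expected = 0
        for lvl in range(levels):          # encoder: two blocks per level
            cin = 1 if lvl == 0 else w
            expected += conv_params(cin, w) + conv_params(w, w)
            expected += 2 * (2 * w)        # batch-norm gamma/beta per block
        for _ in range(levels):            # decoder: concat doubles input
            expected += conv_params(2 * w, w) + conv_params(w, w)
            expected += 2 * (2 * w)
        expected += conv_params(w, L)      # head
        got = sum(p.data.size for p in model.parameters())
        assert got == expected


class TestHeatmapLoss:
    def test_zero_when_equal(self, rng):
        t = rng.normal(size=(2, 3, 8, 8)).astype(np.float32)
        vis = np.ones((2, 3), bool)
        assert heatmap_loss(Tensor(t), t, vis).item() == 0.0

    def test_constant_offset_closed_form(self):
        pred = Tensor(np.full((1, 1, 8, 8), 2.0, dtype=np.float32))
        target = np.full((1, 1, 8, 8), 5.0, dtype=np.float32)
        loss = heatmap_loss(pred, target, np.ones((1, 1), bool))
        assert loss.item() == pytest.approx(9.0)

    def test_masking_removes_exact_channel_contribution(self, rng):
        pred = Tensor(rng.normal(size=(1, 2, 8, 8)).astype(np.float32))
        target = np.zeros((1, 2, 8, 8), dtype=np.float32)
        full = heatmap_loss(pred, target, np.array([[True, True]])).item()
        only0 = heatmap_loss(pred, target, np.array([[True, False]])).item()
        ch0 = float((pred.data[0, 0] ** 2).mean())
        ch1 = float((pred.data[0, 1] ** 2).mean())
        assert full == pytest.approx((ch0 + ch1) / 2, rel=1e-5)
        assert only0 == pytest.approx(ch0, rel=1e-5)

    def test_invisible_channels_get_zero_gradient(self, rng):
        p = Parameter(rng.normal(size=(1, 2, 4, 4)))
        target = np.zeros((1, 2, 4, 4), dtype=np.float32)
        loss = heatmap_loss(p, target, np.array([[True, False]]))
        loss.backward()
        assert np.abs(p.grad[0, 0]).max() > 0
        assert np.all(p.grad[0, 1] == 0)

    def test_all_invisible_warns_and_is_zero(self, rng):
        pred = Tensor(rng.normal(size=(1, 2, 4, 4)).astype(np.float32))
        with pytest.warns(UserWarning):
            loss = heatmap_loss(pred, np.zeros((1, 2, 4, 4), np.float32),
                                np.zeros((1, 2), bool))
        assert loss.item() == 0.0


def test_overfit_tiny_dataset():
    """Training without augmentation drives train-set localization below
    1 px mean error (sanity convergence)."""
    from landloc.augment import AugmentConfig
    from landloc.heatmaps import BlobConfig, decode_argmax
    from landloc.synthetic import SyntheticConfig, make_dataset
    from landloc.training import TrainConfig, train

    ds = make_dataset(SyntheticConfig(n_images=3, frame=(32, 32), seed=5))
    model = UNet(UNetConfig(levels=2, width=12, dropout=0.0, seed=5))
    aug = AugmentConfig(resize_to=(32, 32), translate_px=(0, 0),
                        rotate_rad=(0, 0), elastic_amp_px=0.0,
                        intensity_shift=(0, 0), intensity_scale_v=(0, 0),
                        occlusion_enabled=False, seed=0)
    hist = train(model, ds.images, ds.landmarks,
                 TrainConfig(epochs=150, batch=3, lr=1e-2, seed=5),
                 aug, BlobConfig(sigma=1.5, gamma=50.0))
    assert len(hist["heatmap_loss"]) == 150
    assert hist["heatmap_loss"][-1] < hist["heatmap_loss"][0] / 4
    hm = predict_heatmaps(model, np.stack(ds.images))
    errs = []
    for m, lms in zip(hm, ds.landmarks):
        pred = np.array([decode_argmax(ch) for ch in m], float)
        errs.extend(np.linalg.norm(pred - lms.coords, axis=1)[lms.visible])
    assert np.mean(errs) < 1.5
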