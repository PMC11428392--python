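"""Sum-product refinement layer: closed forms, convolution oracles,
refinement behaviour, differentiability."""

import numpy as np
import pytest

from landloc.gaffa import (
    GaffaConfig, GaffaRefiner, coordinate_loss, dsnt_coordinates, message,
    softplus_beta, unary_energy,
)
from landloc.heatmaps import render_target, BlobConfig
from landloc.nn import Parameter, Tensor
from landloc.priors import ConditionalPrior
from landloc.topology import Topology


def _mini_topology(n, edges, global_set=()):
    return Topology(n, frozenset(frozenset(e) for e in edges),
                    frozenset(global_set))


def _delta_prior(pair, frame, d, sigma=1.0):
    """Gaussian prior concentrated at displacement d from the centre."""
    h, w = frame
    grid = render_target((w + d[0], h + d[1]), (2 * h, 2 * w),
                         BlobConfig(sigma=sigma, gamma=1.0))
    return ConditionalPrior(pair=pair, grid=grid, n_components=1, frame=frame)


def _nested_loop_refine(heatmaps, priors, topology, beta=5.0, eps=1e-6):
    """Literal transcription of the marginal-energy update with explicit
    loops; biases fixed at their epsilon initialization."""
    L, H, W = heatmaps.shape
    out = np.zeros_like(heatmaps, dtype=float)
    for i in range(1, L + 1):
        me = np.log(softplus_beta(heatmaps[i - 1] + eps, beta))
        total = me.copy()
        for j in sorted(topology.neighbors(i)):
            k = softplus_beta(priors[(i, j)].grid, beta)
            p = softplus_beta(heatmaps[j - 1], beta)
            conv = np.zeros((H, W))
            for pv in range(H):
                for pu in range(W):
                    s = 0.0
                    for qv in range(H):
                        for qu in range(W):
                            s += k[H + pv - qv, W + pu - qu] * p[qv, qu]
                    conv[pv, pu] = s
            total += np.log(conv + softplus_beta(eps, beta) + eps)
        out[i - 1] = total
    return out


class TestClosedForms:
    def test_softplus_beta_values(self):
        assert softplus_beta(0.0, 5.0) == pytest.approx(np.log(2) / 5)
        assert softplus_beta(-100.0, 5.0) == pytest.approx(0.0, abs=1e-12)
        assert softplus_beta(10.0, 5.0) == pytest.approx(10.0, rel=1e-6)
        assert softplus_beta(1.0) > softplus_beta(0.0)

    def test_unary_energy_constant_zero_heatmap(self):
        me = unary_energy(np.zeros((4, 4)))
        expected = np.log(softplus_beta(1e-6, 5.0))
        assert np.allclose(me, expected)
        assert me[0, 0] == pytest.approx(np.log(np.log(2) / 5), rel=1e-4)

    def test_unary_energy_preserves_argmax(self, rng):
        p = rng.normal(size=(16, 16))
        assert unary_energy(p).argmax() == p.argmax()
        assert np.isfinite(unary_energy(p * 1000)).all()


class TestMessageOracle:
    def test_fourier_equals_nested_loops_8x8(self, rng):
        """Fourier-space message equals the brute-force spatial convolution."""
        p = rng.uniform(0, 2, size=(8, 8))
        prior = rng.uniform(0, 1, size=(16, 16))
        got = message(p, prior, bias_ij=0.0)
        k = softplus_beta(prior)
        sp = softplus_beta(p)
        conv = np.zeros((8, 8))
        for pv in range(8):
            for pu in range(8):
                for qv in range(8):
                    for qu in range(8):
                        conv[pv, pu] += k[8 + pv - qv, 8 + pu - qu] * sp[qv, qu]
        ref = np.log(conv + softplus_beta(0.0) + 1e-6)
        assert np.allclose(got, ref, rtol=1e-5, atol=1e-5)

    def test_delta_inputs_shift_property(self):
        p = np.zeros((8, 8))
        p[2, 3] = 50.0  # softplus ~ identity at large values
        prior = np.zeros((16, 16))
        prior[8 + 2, 8 + 1] = 50.0
        out = message(p, prior)
        assert np.unravel_index(out.argmax(), out.shape) == (4, 4)

    def test_constant_inputs_give_constant_finite_message(self):
        out = message(np.zeros((8, 8)), np.zeros((16, 16)))
        assert np.isfinite(out).all()
        interior = out[2:-2, 2:-2]
        assert np.ptp(interior) < 1e-5

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            message(np.zeros((8, 8)), np.zeros((8, 8)))


class TestRefiner:
    def _refiner(self, topology, priors, frame, **cfg_kw):
        cfg = GaffaConfig(down_factor=1, kernel_store_factor=1,
                          use_batchnorm=False, **cfg_kw)
        return GaffaRefiner(priors, topology, frame, cfg)

    def test_empty_neighborhood_returns_unary_energy(self):
        topo = _mini_topology(1, edges=[], global_set=())
        ref = self._refiner(topo, {}, (8, 8))
        hm = np.random.default_rng(0).uniform(0, 1, size=(1, 1, 8, 8))
        e, c = ref.refine_numpy(hm.astype(np.float32))
        assert np.allclose(e[0, 0], unary_energy(hm[0, 0]), atol=1e-5)

    def test_matches_nested_loop_oracle(self, rng):
        """Full refine on an 8x8 two-landmark chain equals the loop
        transcription within 1e-5."""
        topo = _mini_topology(2, edges=[(1, 2)])
        frame = (8, 8)
        priors = {
            (1, 2): ConditionalPrior((1, 2), rng.uniform(0, 1, (16, 16)), 1, frame),
            (2, 1): ConditionalPrior((2, 1), rng.uniform(0, 1, (16, 16)), 1, frame),
        }
        hm = rng.uniform(0, 2, size=(2, 8, 8)).astype(np.float32)
        ref = self._refiner(topo, priors, frame)
        e, _ = ref.refine_numpy(hm[None])
        oracle = _nested_loop_refine(hm.astype(float), priors, topo)
        assert np.allclose(e[0], oracle, rtol=1e-4, atol=1e-4)

    def test_spurious_peak_suppressed_by_prior(self):
        """Bimodal heatmap: the mode consistent with the neighbour's prior
        wins after refinement."""
        frame = (32, 32)
        topo = _mini_topology(2, edges=[(1, 2)])
        # landmark 2 confidently at (8, 8); landmark 1 truly at (18, 8)
        hm2 = render_target((8, 8), frame, BlobConfig(sigma=2, gamma=100))
        hm1 = (render_target((18, 8), frame, BlobConfig(sigma=2, gamma=60))
               + render_target((28, 24), frame, BlobConfig(sigma=2, gamma=100)))
        priors = {
            (1, 2): _delta_prior((1, 2), frame, (10, 0), sigma=2.0),
            (2, 1): _delta_prior((2, 1), frame, (-10, 0), sigma=2.0),
        }
        assert np.unravel_index(hm1.argmax(), frame) == (24, 28)  # spurious
        ref = self._refiner(topo, priors, frame)
        e, _ = ref.refine_numpy(np.stack([hm1, hm2])[None].astype(np.float32))
        v, u = np.unravel_index(e[0, 0].argmax(), frame)
        assert np.hypot(u - 18, v - 8) <= 2.0

    def test_output_resolution_matches_input(self, rng):
        topo = _mini_topology(2, edges=[(1, 2)])
        frame = (16, 16)
        priors = {
            (1, 2): _delta_prior((1, 2), frame, (3, 0)),
            (2, 1): _delta_prior((2, 1), frame, (-3, 0)),
        }
        cfg = GaffaConfig(down_factor=2, use_batchnorm=False)
        ref = GaffaRefiner(priors, topo, frame, cfg)
        e, c = ref.refine_numpy(rng.uniform(0, 1, (1, 2, 16, 16)))
        assert e.shape == (1, 2, 16, 16) and c.shape == (1, 2, 2)

    def test_missing_prior_pair_rejected(self):
        topo = _mini_topology(2, edges=[(1, 2)])
        with pytest.raises(KeyError):
            self._refiner(topo, {(1, 2): _delta_prior((1, 2), (8, 8), (1, 0))},
                          (8, 8))

    def test_prior_rescaling_leaves_argmax_unchanged(self, rng):
        """Energies tolerate prior scale: multiplying all prior grids by a
        constant does not move the refined argmax at initialization."""
        frame = (32, 32)
        topo = _mini_topology(2, edges=[(1, 2)])
        hm = np.stack([
            render_target((18, 16), frame, BlobConfig(sigma=2, gamma=80)),
            render_target((10, 16), frame, BlobConfig(sigma=2, gamma=80)),
        ])[None].astype(np.float32)
        argmaxes = []
        for scale in (1.0, 50.0, 0.02):
            priors = {
                (1, 2): _delta_prior((1, 2), frame, (8, 0), sigma=2.0),
                (2, 1): _delta_prior((2, 1), frame, (-8, 0), sigma=2.0),
            }
            for p in priors.values():
                p.grid *= scale
            ref = self._refiner(topo, priors, frame)
            e, _ = ref.refine_numpy(hm)
            argmaxes.append([np.unravel_index(ch.argmax(), ch.shape)
                             for ch in e[0]])
        assert argmaxes[0] == argmaxes[1] == argmaxes[2]

    def test_gradients_flow_to_heatmaps_priors_biases(self):
        rng = np.random.default_rng(1)
        frame = (8, 8)
        topo = _mini_topology(2, edges=[(1, 2)])
        priors = {
            (1, 2): ConditionalPrior((1, 2), rng.uniform(0, 1, (16, 16)), 1, frame),
            (2, 1): ConditionalPrior((2, 1), rng.uniform(0, 1, (16, 16)), 1, frame),
        }
        ref = self._refiner(topo, priors, frame)
        hm = Parameter(rng.uniform(0, 1, (1, 2, 8, 8)))
        _, coords = ref(hm)
        loss = coordinate_loss(coords, np.full((1, 2, 2), 4.0),
                               np.ones((1, 2), bool))
        loss.backward()
        for t in (hm, ref.kernels, ref.biases):
            assert t.grad is not None
            assert np.isfinite(t.grad).all()
            assert np.abs(t.grad).max() > 0

    def test_occluded_landmark_recovered_from_neighbor(self):
        """Zeroed heatmap channel: the message from the neighbour still
        places the landmark near the prior-consistent location."""
        frame = (32, 32)
        topo = _mini_topology(2, edges=[(1, 2)])
        hm2 = render_target((10, 16), frame, BlobConfig(sigma=2, gamma=100))
        hm1 = np.zeros(frame)  # occluded
        priors = {
            (1, 2): _delta_prior((1, 2), frame, (8, 0), sigma=2.0),
            (2, 1): _delta_prior((2, 1), frame, (-8, 0), sigma=2.0),
        }
        ref = self._refiner(topo, priors, frame)
        e, _ = ref.refine_numpy(np.stack([hm1, hm2])[None].astype(np.float32))
        v, u = np.unravel_index(e[0, 0].argmax(), frame)
        assert np.hypot(u - 18, v - 16) <= 3.0


class TestCoordinateLoss:
    def test_zero_at_exact_prediction(self):
        pred = Tensor(np.ones((1, 3, 2)))
        loss = coordinate_loss(pred, np.ones((1, 3, 2)), np.ones((1, 3), bool))
        assert loss.item() == 0.0

    def test_single_offset_closed_form(self):
        pred = Tensor(np.array([[[3.0, 4.0]]]))
        loss = coordinate_loss(pred, np.zeros((1, 1, 2)), np.ones((1, 1), bool))
        assert loss.item() == pytest.approx(12.5)

    def test_invisible_landmarks_excluded(self):
        pred = Tensor(np.array([[[3.0, 4.0], [100.0, 100.0]]]))
        target = np.zeros((1, 2, 2))
        vis = np.array([[True, False]])
        loss = coordinate_loss(pred, target, vis)
        assert loss.item() == pytest.approx(12.5)


def test_dsnt_on_energy_stack_matches_peak(rng):
    e = np.full((1, 1, 24, 24), -2.0, dtype=np.float32)
    e[0, 0, 5, 17] = 6.0
    c = dsnt_coordinates(Tensor(e), beta=5.0).data
    assert np.allclose(c[0, 0], (17, 5), atol=1e-2)
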