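"""Differentiable one-iteration sum-product landmark refinement (GAFFA).

The refiner treats every pixel as a landmark candidate and performs a
single sum-product iteration of the landmark MRF in log-energy space: the
marginal energy of landmark i is

    me_hat_i = me_i + sum_{j in N_i} log( SP(p_i|j) * SP(p_j) + SP(b_j->i) + eps )

with me_i = log SP(p_i + eps), SP the Softplus_beta rectifier, ``*`` true
convolution with the double-size conditional prior kernel p_i|j (origin at
its exact centre pixel), and b_j->i a learnable per-message bias grid. The
result stays in log space — the location of the maximum is unchanged — and
coordinates are decoded with a differentiable soft-argmax.

For computational feasibility the messages run at a bicubically
downsampled working resolution; the summed message energy is bicubically
upsampled back before the addition with the full-resolution me_i. Priors
are stored at the working resolution and upsampled by two to kernel size
each forward pass, and may be further trained (they initialize the
convolution kernels); the convolutions are evaluated in Fourier space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from . import nn
from .heatmaps import softplus as np_softplus
from .nn import (
    BatchNorm2d, Module, Parameter, Tensor, interp_matrix, matmul_first,
    message_conv, resize_bicubic,
)
from .priors import ConditionalPrior
from .topology import Topology


def softplus_beta(x, beta: float = 5.0):
    """(1/beta) log(1 + exp(beta x)); strictly positive, monotone."""
    return np_softplus(x, beta)


def unary_energy(p: np.ndarray, beta: float = 5.0, eps: float = 1e-6) -> np.ndarray:
    """me = log Softplus_beta(p + eps) at full heatmap resolution; stable
    for strongly negative inputs (asymptote beta*x - log beta)."""
    x = np.asarray(p, float) + eps
    bx = beta * x
    with np.errstate(divide="ignore"):
        return np.where(bx < -30.0, bx - np.log(beta),
                        np.log(softplus_beta(x, beta)))


def message(
    p_j_ds: np.ndarray,
    prior_ij_ds: np.ndarray,
    bias_ij: np.ndarray | float = 0.0,
    beta: float = 5.0,
    eps: float = 1e-6,
) -> np.ndarray:
    """Log-message grid for one ordered pair, all inputs at the (shared)
    downsampled resolution; the prior kernel spans twice the heatmap extent."""
    heat = Tensor(softplus_beta(p_j_ds, beta)[None, None])
    kern = Tensor(softplus_beta(prior_ij_ds, beta)[None])
    conv = message_conv(heat, kern).data[0, 0].astype(float)
    return np.log(conv + softplus_beta(bias_ij, beta) + eps)


@dataclass
class GaffaConfig:
    beta: float = 5.0
    epsilon: float = 1e-6
    down_factor: int = 4
    kernel_store_factor: int = 2  # priors kept this much below kernel size
    dsnt_beta: float = 5.0
    use_batchnorm: bool = True
    learn_priors: bool = True
    learn_biases: bool = True

    def __post_init__(self) -> None:
        if self.beta <= 0 or self.epsilon <= 0:
            raise ValueError("beta and epsilon must be positive")
        for f in (self.down_factor, self.kernel_store_factor):
            if f < 1 or (f & (f - 1)):
                raise ValueError("resolution factors must be powers of two")


class GaffaRefiner(Module):
    """One differentiable sum-product iteration over the landmark graph.

    Parameters: per-message prior kernels (initialized from the fitted
    conditional priors, bicubically downsampled to the working resolution)
    and per-message bias grids (initialized to epsilon everywhere), plus the
    optional batch normalization over the input heatmap channels.
    """

    def __init__(
        self,
        priors: Mapping[tuple[int, int], ConditionalPrior],
        topology: Topology,
        frame: tuple[int, int],
        cfg: GaffaConfig = GaffaConfig(),
    ):
        self.cfg = cfg
        self.topology = topology
        self.frame = frame
        self.pairs = topology.message_pairs()
        missing = [p for p in self.pairs if p not in priors]
        if missing:
            raise KeyError(f"prior bank is missing pairs {missing[:5]} ...")
        h, w = frame
        f = cfg.down_factor
        if h % f or w % f:
            raise ValueError("frame must be divisible by down_factor")
        self.work = (h // f, w // f)
        L = topology.n_landmarks
        M = len(self.pairs)

        # gather/scatter matrices: sender selection (M, L) and receiver sum (L, M)
        self._send = np.zeros((M, L), dtype=np.float32)
        self._recv = np.zeros((L, M), dtype=np.float32)
        for m, (i, j) in enumerate(self.pairs):
            self._send[m, j - 1] = 1.0
            self._recv[i - 1, m] = 1.0

        # prior kernels are stored kernel_store_factor below the conv kernel
        # extent (2h/f, 2w/f) and bicubically restored at forward time; with
        # store factor 1 and down factor 1 the stored kernel IS the prior grid
        ksf = cfg.kernel_store_factor
        self.kernel_size = (2 * self.work[0], 2 * self.work[1])
        store = (self.kernel_size[0] // ksf, self.kernel_size[1] // ksf)
        mat_h = interp_matrix(2 * h, store[0], "bicubic")
        mat_w = interp_matrix(2 * w, store[1], "bicubic")
        if M:
            stack = np.stack([
                mat_h @ priors[p].grid @ mat_w.T for p in self.pairs
            ])
        else:
            stack = np.zeros((0, *store))
        self.kernels = Parameter(stack) if cfg.learn_priors else Tensor(stack)
        bias = np.full((M, *self.work), cfg.epsilon, dtype=np.float32)
        self.biases = Parameter(bias) if cfg.learn_biases else Tensor(bias)
        self.bn = BatchNorm2d(L) if cfg.use_batchnorm else None

    # ------------------------------------------------------------------
    def energies(self, heatmaps: Tensor) -> Tensor:
        """Marginal energy stack me_hat at the input heatmap resolution."""
        cfg = self.cfg
        p = self.bn(heatmaps) if self.bn is not None else heatmaps
        me = (p + cfg.epsilon).log_softplus(cfg.beta)
        if not self.pairs:
            return me
        p_ds = resize_bicubic(p, self.work)
        senders = matmul_first(self._send, p_ds)  # (N, M, h', w')
        kernels = self.kernels
        if kernels.data.shape[-2:] != self.kernel_size:
            kernels = resize_bicubic(kernels, self.kernel_size)
        conv = message_conv(senders.softplus(cfg.beta), kernels.softplus(cfg.beta))
        msg = (conv + self.biases.softplus(cfg.beta) + cfg.epsilon).log()
        summed = matmul_first(self._recv, msg)  # (N, L, h', w')
        up = resize_bicubic(summed, self.frame)
        return me + up

    def forward(self, heatmaps: Tensor) -> tuple[Tensor, Tensor]:
        """Returns (marginal energies (N,L,H,W), coordinates (N,L,2))."""
        e = self.energies(heatmaps)
        return e, dsnt_coordinates(e, beta=self.cfg.dsnt_beta)

    def refine_numpy(self, heatmaps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Inference helper on a plain (N,L,H,W) array; returns energies and
        soft-argmax coordinates as numpy arrays."""
        e, c = self.forward(Tensor(heatmaps))
        return e.data.astype(float), c.data.astype(float)


def dsnt_coordinates(energies: Tensor, beta: float = 1.0) -> Tensor:
    """Differentiable soft-argmax over log-domain maps: exp(beta x) weights
    (softmax; the detached per-map maximum is subtracted for stability),
    normalized, then the expectation of the (u, v) grid. Output (N, L, 2)."""
    n, l, h, w = energies.data.shape
    mx = energies.data.max(axis=(2, 3), keepdims=True)
    wgt = ((energies - Tensor(mx)) * beta).exp()
    z = wgt.sum(axis=(2, 3), keepdims=True)
    p = wgt / z
    ugrid = Tensor(np.broadcast_to(np.arange(w, dtype=np.float32), (h, w)).copy())
    vgrid = Tensor(np.broadcast_to(np.arange(h, dtype=np.float32)[:, None], (h, w)).copy())
    u = (p * ugrid).sum(axis=(2, 3))
    v = (p * vgrid).sum(axis=(2, 3))
    return concat_coords(u, v)


def concat_coords(u: Tensor, v: Tensor) -> Tensor:
    return nn.concat([u.reshape(*u.shape, 1), v.reshape(*v.shape, 1)], axis=2)


def coordinate_loss(
    pred: Tensor, target: np.ndarray, visible: np.ndarray
) -> Tensor:
    """MSE over coordinate components of visible landmarks.

    pred: (N, L, 2) tensor; target: (N, L, 2) array; visible: (N, L) bool.
    The mean runs over the 2*n_visible coordinate components.
    """
    mask = np.asarray(visible, dtype=np.float32)[..., None]
    n_comp = max(float(mask.sum() * 2), 1.0)
    diff = (pred - Tensor(np.asarray(target, dtype=np.float32))) * Tensor(mask)
    return (diff * diff).sum() * (1.0 / n_comp)
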