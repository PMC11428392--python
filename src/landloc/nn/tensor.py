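"""Reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ndarray and records the operations applied to
it; :meth:`Tensor.backward` propagates gradients through the recorded graph
in reverse topological order. The op set is exactly what the localization
networks and the energy-domain refiner need: elementwise arithmetic,
exp/log/softplus/leaky-relu, reductions, shape ops, same-padded 2-D
convolution, 2x average pooling, fixed linear resampling, and an FFT-based
"message" convolution with a double-size kernel.

float32 is used throughout; gradient correctness is pinned down by
finite-difference tests rather than symbolic derivation.
"""

from __future__ import annotations

import numpy as np
from scipy.fft import next_fast_len

DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward op."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph plumbing ---------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.asarray(g, dtype=DTYPE).copy()
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient needs a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accum(grad)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
                node._parents = ()
                node._backward = None

    def zero_grad(self) -> None:
        self.grad = None

    # -- helpers ----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    # -- elementwise arithmetic -------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), bw)

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), bw)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = as_tensor(other)
        out_data = self.data / other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return Tensor._make(out_data, (self, other), bw)

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def bw(g):
            self._accum(g * exponent * self.data ** (exponent - 1))

        return Tensor._make(out_data, (self,), bw)

    # -- elementwise nonlinearities ---------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._accum(g * out_data)

        return Tensor._make(out_data, (self,), bw)

    def log(self):
        out_data = np.log(self.data)

        def bw(g):
            self._accum(g / self.data)

        return Tensor._make(out_data, (self,), bw)

    def softplus(self, beta: float = 5.0):
        """(1/beta) log(1 + exp(beta x)), numerically stable."""
        bx = beta * self.data.astype(np.float64)
        out_data = ((np.maximum(bx, 0.0) + np.log1p(np.exp(-np.abs(bx)))) / beta)
        sig = 1.0 / (1.0 + np.exp(-bx))

        def bw(g):
            self._accum(g * sig.astype(DTYPE))

        return Tensor._make(out_data.astype(DTYPE), (self,), bw)

    def log_softplus(self, beta: float = 5.0):
        """log(Softplus_beta(x)), stable for large-magnitude arguments:
        approaches beta*x - log(beta) as x -> -inf and log(x) as x -> inf."""
        bx = beta * self.data.astype(np.float64)
        sp = (np.maximum(bx, 0.0) + np.log1p(np.exp(-np.abs(bx)))) / beta
        with np.errstate(divide="ignore"):
            out_data = np.where(bx < -30.0, bx - np.log(beta), np.log(sp))
        sig = 1.0 / (1.0 + np.exp(-bx))
        with np.errstate(divide="ignore", invalid="ignore"):
            grad = np.where(bx < -30.0, beta, sig / np.maximum(sp, 1e-300))

        def bw(g):
            self._accum((g * grad).astype(DTYPE))

        return Tensor._make(out_data.astype(DTYPE), (self,), bw)

    def leaky_relu(self, slope: float = 0.1):
        mask = self.data > 0
        out_data = np.where(mask, self.data, slope * self.data)

        def bw(g):
            self._accum(g * np.where(mask, 1.0, slope).astype(DTYPE))

        return Tensor._make(out_data, (self,), bw)

    def relu(self):
        return self.leaky_relu(0.0)

    # -- reductions and shape ops -----------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        return Tensor._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        out_data = self.data.reshape(*shape)
        orig = self.data.shape

        def bw(g):
            self._accum(g.reshape(orig))

        return Tensor._make(out_data, (self,), bw)

    def transpose(self, axes):
        out_data = self.data.transpose(axes)
        inv = np.argsort(axes)

        def bw(g):
            self._accum(g.transpose(inv))

        return Tensor._make(out_data, (self,), bw)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def bw(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            self._accum(full)

        return Tensor._make(out_data, (self,), bw)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=DTYPE))


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), bw)


# -- structured linear ops ------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Same-padded stride-1 2-D convolution (cross-correlation orientation,
    as in deep-learning frameworks). x: (N,Ci,H,W), w: (Co,Ci,kh,kw) with
    odd kernel sizes, b: (Co,)."""
    n, ci, h, wd = x.data.shape
    co, ci2, kh, kw = w.data.shape
    assert ci == ci2 and kh % 2 == 1 and kw % 2 == 1
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    view = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    # (N, Ci, H, W, kh, kw) -> (N*H*W, Ci*kh*kw)
    cols = np.ascontiguousarray(view.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * h * wd, ci * kh * kw
    )
    wmat = w.data.reshape(co, ci * kh * kw)
    out = (cols @ wmat.T).reshape(n, h, wd, co).transpose(0, 3, 1, 2)
    if b is not None:
        out = out + b.data[None, :, None, None]

    def bw(g):
        g2 = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(n * h * wd, co)
        if w.requires_grad:
            w._accum((g2.T @ cols).reshape(co, ci, kh, kw))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gp = np.pad(g, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
            gview = np.lib.stride_tricks.sliding_window_view(gp, (kh, kw), axis=(2, 3))
            gcols = np.ascontiguousarray(gview.transpose(0, 2, 3, 1, 4, 5)).reshape(
                n * h * wd, co * kh * kw
            )
            wflip = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
            wmat2 = np.ascontiguousarray(wflip).reshape(ci, co * kh * kw)
            gx = (gcols @ wmat2.T).reshape(n, h, wd, ci).transpose(0, 3, 1, 2)
            x._accum(gx)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out, parents, bw)


def avg_pool2(x: Tensor) -> Tensor:
    """2x2 average pooling, stride 2."""
    n, c, h, w = x.data.shape
    assert h % 2 == 0 and w % 2 == 0
    out = x.data.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def bw(g):
        gx = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * 0.25
        x._accum(gx)

    return Tensor._make(out, (x,), bw)


def resize2d(x: Tensor, mat_h: np.ndarray, mat_w: np.ndarray) -> Tensor:
    """Fixed linear resampling along the last two axes:
    y[..., :, :] = mat_h @ x[..., :, :] @ mat_w.T."""
    a = np.asarray(mat_h, dtype=DTYPE)
    bm = np.asarray(mat_w, dtype=DTYPE)
    out = np.matmul(np.matmul(a, x.data), bm.T)

    def bw(g):
        x._accum(np.matmul(np.matmul(a.T, g), bm))

    return Tensor._make(out, (x,), bw)


def matmul_first(mat: np.ndarray, x: Tensor) -> Tensor:
    """y[n, l, ...] = sum_p mat[l, p] x[n, p, ...] for a constant matrix."""
    m = np.asarray(mat, dtype=DTYPE)
    n, p = x.data.shape[0], x.data.shape[1]
    rest = x.data.shape[2:]
    out = np.matmul(m, x.data.reshape(n, p, -1)).reshape(n, m.shape[0], *rest)

    def bw(g):
        gx = np.matmul(m.T, g.reshape(n, m.shape[0], -1)).reshape(x.data.shape)
        x._accum(gx)

    return Tensor._make(out, (x,), bw)


# -- FFT message convolution ----------------------------------------------

def _fftconv_full(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Linear (zero-padded) 2-D convolution over the last two axes, with
    broadcasting over leading axes."""
    ha, wa = a.shape[-2:]
    hb, wb = b.shape[-2:]
    sh, sw = ha + hb - 1, wa + wb - 1
    fh, fw = next_fast_len(sh), next_fast_len(sw)
    fa = np.fft.rfft2(a, s=(fh, fw))
    fb = np.fft.rfft2(b, s=(fh, fw))
    out = np.fft.irfft2(fa * fb, s=(fh, fw))[..., :sh, :sw]
    return out.astype(DTYPE)


def message_conv(heat: Tensor, kernel: Tensor) -> Tensor:
    """True convolution of a (..., h, w) heatmap with a (..., 2h, 2w) kernel
    whose origin is its exact centre pixel (h, w), cropped to the heatmap
    frame: out[p] = sum_q kernel[centre + p - q] * heat[q].

    A delta heatmap at x and a delta kernel at centre+d peak at x+d.
    Realized in Fourier space; leading axes broadcast (e.g. kernels shaped
    (M, 2h, 2w) against heatmaps (N, M, h, w))."""
    h, w = heat.data.shape[-2:]
    kh, kw = kernel.data.shape[-2:]
    if (kh, kw) != (2 * h, 2 * w):
        raise ValueError(
            f"kernel must be twice the heatmap extent: got {(kh, kw)} for {(h, w)}"
        )
    full = _fftconv_full(kernel.data, heat.data)
    out = full[..., h: 2 * h, w: 2 * w]  # crop at the kernel-centre offset

    def bw(g):
        if heat.requires_grad:
            kf = kernel.data[..., ::-1, ::-1]
            gh = _fftconv_full(g, kf)[..., h - 1: 2 * h - 1, w - 1: 2 * w - 1]
            heat._accum(_unbroadcast(gh, heat.data.shape))
        if kernel.requires_grad:
            hf = heat.data[..., ::-1, ::-1]
            gk_core = _fftconv_full(g, hf)  # (..., 2h-1, 2w-1)
            shape = np.broadcast_shapes(g.shape[:-2], hf.shape[:-2])
            gk = np.zeros(shape + (2 * h, 2 * w), dtype=DTYPE)
            gk[..., 1:, 1:] = gk_core
            kernel._accum(_unbroadcast(gk, kernel.data.shape))

    return Tensor._make(out, (heat, kernel), bw)
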