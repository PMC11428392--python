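"""Network building blocks on top of the autodiff tensor."""

from __future__ import annotations

import numpy as np

from .tensor import DTYPE, Tensor, avg_pool2, concat, conv2d, resize2d


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Minimal parameter container with train/eval mode."""

    training: bool = True

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()

        def collect(obj):
            if isinstance(obj, Parameter):
                if id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    collect(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    collect(v)
            elif isinstance(obj, dict):
                for v in obj.values():
                    collect(v)

        collect(self)
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]

        def collect(obj):
            if isinstance(obj, Module):
                mods.append(obj)
                for v in vars(obj).values():
                    collect(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    collect(v)
            elif isinstance(obj, dict):
                for v in obj.values():
                    collect(v)

        for v in vars(self).values():
            collect(v)
        return mods

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    def state_dict(self) -> dict[str, np.ndarray]:
        return {str(i): p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p.data[...] = state[str(i)]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    """Same-padded 3x3/odd-kernel convolution with Kaiming fan-in init."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        fan_in = cin * k * k
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, std, size=(cout, cin, k, k)))
        self.bias = Parameter(np.zeros(cout))

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias)


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics for eval."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Parameter(np.ones((1, channels, 1, 1)))
        self.beta = Parameter(np.zeros((1, channels, 1, 1)))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros((1, channels, 1, 1), dtype=DTYPE)
        self.running_var = np.ones((1, channels, 1, 1), dtype=DTYPE)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data
            self.running_var = (1 - m) * self.running_var + m * var.data
            return xc / ((var + self.eps) ** 0.5) * self.gamma + self.beta
        xc = x - Tensor(self.running_mean)
        denom = np.sqrt(self.running_var + self.eps)
        return xc / Tensor(denom) * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate <= 0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.data.shape) < keep).astype(DTYPE) / keep
        return x * Tensor(mask)


class ConvBlock(Module):
    """convolution -> batch norm -> leaky rectifier -> dropout."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 slope: float = 0.1, dropout: float = 0.3):
        self.conv = Conv2d(cin, cout, k, rng)
        self.bn = BatchNorm2d(cout)
        self.slope = slope
        self.drop = Dropout(dropout, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.drop(self.bn(self.conv(x)).leaky_relu(self.slope))


# -- fixed resampling operators -------------------------------------------

def _cubic_kernel(x: float, a: float = -0.75) -> float:
    ax = abs(x)
    if ax <= 1:
        return (a + 2) * ax**3 - (a + 3) * ax**2 + 1
    if ax < 2:
        return a * ax**3 - 5 * a * ax**2 + 8 * a * ax - 4 * a
    return 0.0


from functools import lru_cache


@lru_cache(maxsize=256)
def interp_matrix(n_in: int, n_out: int, kind: str = "bilinear") -> np.ndarray:
    """Row-stochastic 1-D resampling matrix (n_out, n_in) with half-pixel
    alignment and replicated edges; ``kind`` is bilinear or bicubic."""
    scale = n_in / n_out
    src = (np.arange(n_out) + 0.5) * scale - 0.5
    mat = np.zeros((n_out, n_in))
    if kind == "bilinear":
        taps, kernel = 1, None
    elif kind == "bicubic":
        taps, kernel = 2, _cubic_kernel
    else:
        raise ValueError(f"unknown interpolation {kind!r}")
    for o, s in enumerate(src):
        base = int(np.floor(s))
        for t in range(-taps + 1, taps + 1):
            idx = base + t
            if kernel is None:
                wgt = max(0.0, 1.0 - abs(s - idx))
            else:
                wgt = kernel(s - idx)
            mat[o, int(np.clip(idx, 0, n_in - 1))] += wgt
    mat /= mat.sum(axis=1, keepdims=True)
    return mat


def resize_bicubic(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    h, w = x.data.shape[-2:]
    return resize2d(x, interp_matrix(h, out_hw[0], "bicubic"),
                    interp_matrix(w, out_hw[1], "bicubic"))


def upsample_bilinear2x(x: Tensor) -> Tensor:
    h, w = x.data.shape[-2:]
    return resize2d(x, interp_matrix(h, 2 * h, "bilinear"),
                    interp_matrix(w, 2 * w, "bilinear"))


__all__ = [
    "Parameter", "Module", "Conv2d", "BatchNorm2d", "Dropout", "ConvBlock",
    "interp_matrix", "resize_bicubic", "upsample_bilinear2x",
    "Tensor", "avg_pool2", "concat",
]
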