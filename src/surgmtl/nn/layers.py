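"""Neural-network layers with hand-written forward and backward passes.

Convolutions run as kh*kw shifted BLAS matmuls accumulated in NCHW layout;
for the small kernels used here this beats an explicit im2col gather in
NumPy by a wide margin and keeps peak memory proportional to the
activations, not to ``C*kh*kw`` times the activations.
"""

from __future__ import annotations

import numpy as np

# module-level so numerical tests can swap in float64 for gradient checking
DTYPE = np.float32


def dtype():
    return DTYPE


class Parameter:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.ascontiguousarray(value, dtype=dtype())
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size

    def zero_grad(self) -> None:
        self.grad.fill(0.0)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Parameter({self.name}, shape={self.value.shape})"


class Layer:
    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x, *, train: bool = False, rng=None):
        raise NotImplementedError

    def backward(self, dout):
        raise NotImplementedError

    def __call__(self, x, **kwargs):
        return self.forward(x, **kwargs)


def _shift_slices(xp: np.ndarray, i: int, j: int, ho: int, wo: int) -> np.ndarray:
    """Contiguous (B, C, ho*wo) copy of the (i, j)-shifted window of xp."""
    b, c = xp.shape[:2]
    return xp[:, :, i : i + ho, j : j + wo].reshape(b, c, ho * wo)


class Conv2d(Layer):
    """Stride-1 2-D convolution (cross-correlation) with per-side padding.

    ``padding`` is (top, bottom, left, right); the asymmetric form is what the
    2x2 channel-halving "up-convolution" needs to preserve spatial size under
    an even kernel.
    """

    def __init__(self, in_ch, out_ch, kernel, padding, rng, name="conv"):
        if in_ch < 1 or out_ch < 1:
            raise ValueError("channel counts must be positive")
        kh, kw = kernel
        fan_in = in_ch * kh * kw
        # He-style init: appropriate for the ReLU-dominated trunk
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, kh, kw))
        self.weight = Parameter(w, f"{name}.weight")
        self.bias = Parameter(np.zeros(out_ch), f"{name}.bias")
        self.kernel = (kh, kw)
        self.padding = tuple(padding)
        self.in_ch, self.out_ch = in_ch, out_ch
        self._xp: np.ndarray | None = None

    def parameters(self):
        return [self.weight, self.bias]

    def forward(self, x, *, train=False, rng=None):
        # the kernel is small, so the convolution runs as kh*kw shifted GEMMs
        # accumulated in NCHW layout, avoiding any im2col gather copy
        pt, pb, pl, pr = self.padding
        if any(self.padding):
            xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
        else:
            xp = np.asarray(x)
        kh, kw = self.kernel
        b = xp.shape[0]
        ho, wo = xp.shape[2] - kh + 1, xp.shape[3] - kw + 1
        w = self.weight.value
        out = np.empty((b, self.out_ch, ho * wo), dtype=xp.dtype)
        out[:] = self.bias.value[:, None]
        for i in range(kh):
            for j in range(kw):
                out += np.matmul(w[:, :, i, j], _shift_slices(xp, i, j, ho, wo))
        self._xp = xp
        return out.reshape(b, self.out_ch, ho, wo)

    def backward(self, dout):
        xp = self._xp
        kh, kw = self.kernel
        b, _, ho, wo = dout.shape
        d3 = np.ascontiguousarray(dout, dtype=dtype()).reshape(b, self.out_ch, ho * wo)
        for i in range(kh):
            for j in range(kw):
                sl = _shift_slices(xp, i, j, ho, wo)
                self.weight.grad[:, :, i, j] += np.matmul(
                    d3, sl.transpose(0, 2, 1)
                ).sum(axis=0)
        self.bias.grad += d3.sum(axis=(0, 2))
        # d(input) is a full correlation of dout with the flipped kernel,
        # computed with the same shifted-GEMM scheme
        pt, pb, pl, pr = self.padding
        dp = np.pad(
            np.asarray(dout, dtype=dtype()),
            ((0, 0), (0, 0), (kh - 1 - pt, kh - 1 - pb), (kw - 1 - pl, kw - 1 - pr)),
        )
        hin = xp.shape[2] - pt - pb
        win_ = xp.shape[3] - pl - pr
        w = self.weight.value
        dx = np.zeros((b, self.in_ch, hin * win_), dtype=dp.dtype)
        for i in range(kh):
            for j in range(kw):
                dx += np.matmul(
                    w[:, :, kh - 1 - i, kw - 1 - j].T,
                    _shift_slices(dp, i, j, hin, win_),
                )
        return dx.reshape(b, self.in_ch, hin, win_)


class Linear(Layer):
    def __init__(self, in_features, out_features, rng, name="linear"):
        if in_features < 1 or out_features < 1:
            raise ValueError("feature counts must be positive")
        bound = 1.0 / np.sqrt(in_features)
        w = rng.uniform(-bound, bound, size=(out_features, in_features))
        b = rng.uniform(-bound, bound, size=out_features)
        self.weight = Parameter(w, f"{name}.weight")
        self.bias = Parameter(b, f"{name}.bias")
        self._x = None

    def parameters(self):
        return [self.weight, self.bias]

    def forward(self, x, *, train=False, rng=None):
        self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, dout):
        dout = np.ascontiguousarray(dout, dtype=dtype())
        self.weight.grad += dout.T @ self._x
        self.bias.grad += dout.sum(axis=0)
        return dout @ self.weight.value


class ReLU(Layer):
    def forward(self, x, *, train=False, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dout):
        return np.where(self._mask, dout, 0)


class MaxPool2x2(Layer):
    """2x2 max pooling with stride 2; ties route the gradient to the first
    maximum, which keeps the backward pass deterministic."""

    def forward(self, x, *, train=False, rng=None):
        b, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2x2 needs even spatial dims, got {h}x{w}")
        x4 = (
            x.reshape(b, c, h // 2, 2, w // 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(b, c, h // 2, w // 2, 4)
        )
        self._idx = x4.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(x4, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        b, c, h, w = self._shape
        dx4 = np.zeros((b, c, h // 2, w // 2, 4), dtype=dout.dtype)
        np.put_along_axis(dx4, self._idx[..., None], dout[..., None], axis=-1)
        return (
            dx4.reshape(b, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(b, c, h, w)
        )


class Upsample2x(Layer):
    """Nearest-neighbour 2x spatial upsampling."""

    def forward(self, x, *, train=False, rng=None):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout):
        b, c, h, w = dout.shape
        return dout.reshape(b, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Dropout(Layer):
    """Inverted dropout: active only when ``train=True`` and p > 0."""

    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p
        self._mask = None

    def forward(self, x, *, train=False, rng=None):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("Dropout in train mode needs an rng")
        keep = 1.0 - self.p
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask
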