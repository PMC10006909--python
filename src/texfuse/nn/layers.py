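"""NumPy neural-network layers.

Inference uses float32 NCHW tensors and im2col-backed convolutions so the
heavy lifting is BLAS matmul.  Backward passes are implemented only for the
layers the trainable tiny CNN needs (Conv2d, Linear, ReLU, MaxPool2d,
GlobalAvgPool); the large backbones are forward-only feature extractors.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer", "Sequential", "Conv2d", "Linear", "BatchNorm2d", "LayerNorm2d",
    "ReLU", "SiLU", "GELU", "Sigmoid", "MaxPool2d", "AvgPool2d",
    "GlobalAvgPool", "Dropout", "softmax_cross_entropy",
]


class Layer:
    """Base layer: forward(x, train) -> y; params() yields (name, array) pairs."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - overridden
        raise NotImplementedError(f"{type(self).__name__} has no backward pass")

    def params(self):
        return []

    def grads(self):
        return []

    def __call__(self, x, train=False):
        return self.forward(x, train=train)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        for i, layer in enumerate(self.layers):
            for name, p in layer.params():
                yield f"{i}.{name}", p

    def grads(self):
        for i, layer in enumerate(self.layers):
            for name, g in layer.grads():
                yield f"{i}.{name}", g


def _pair(v) -> tuple[int, int]:
    return (v, v) if isinstance(v, int) else tuple(v)


def _im2col(x: np.ndarray, kh: int, kw: int, stride, pad, dilation: int = 1):
    """(N, C, H, W) -> windows (N, C, kh, kw, OH, OW) view after padding."""
    ph, pw = _pair(pad)
    sh_, sw_ = _pair(stride)
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    n, c, h, w = x.shape
    eff_kh = (kh - 1) * dilation + 1
    eff_kw = (kw - 1) * dilation + 1
    oh = (h - eff_kh) // sh_ + 1
    ow = (w - eff_kw) // sw_ + 1
    sn, sc, sh, sw = x.strides
    shape = (n, c, kh, kw, oh, ow)
    strides = (sn, sc, sh * dilation, sw * dilation, sh * sh_, sw * sw_)
    return np.lib.stride_tricks.as_strided(x, shape=shape, strides=strides), oh, ow


class Conv2d(Layer):
    """2-D convolution (cross-correlation) with stride, padding, dilation and groups.

    ``kernel`` and ``pad`` may be ints or (height, width) pairs.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel, stride: int = 1,
                 pad=0, dilation: int = 1, groups: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None):
        if in_ch % groups or out_ch % groups:
            raise ValueError("channel counts must be divisible by groups")
        rng = rng or np.random.default_rng(0)
        kh, kw = _pair(kernel)
        fan_in = (in_ch // groups) * kh * kw
        scale = np.sqrt(2.0 / fan_in)
        self.weight = (rng.standard_normal((out_ch, in_ch // groups, kh, kw))
                       * scale).astype(np.float32)
        self.bias = np.zeros(out_ch, dtype=np.float32) if bias else None
        self.stride, self.pad, self.dilation, self.groups = stride, pad, dilation, groups
        self.kernel = (kh, kw)
        self.dweight = None
        self.dbias = None
        self._cache = None

    def forward(self, x, train=False):
        x = x.astype(np.float32, copy=False)
        oc, icg, kh, kw = self.weight.shape
        g = self.groups
        cols, oh, ow = _im2col(x, kh, kw, self.stride, self.pad, self.dilation)
        n = x.shape[0]
        # (N, G, Cg*kh*kw, OH*OW)
        cols_m = cols.reshape(n, g, icg * kh * kw, oh * ow) if g > 1 else \
            cols.reshape(n, 1, icg * kh * kw, oh * ow)
        w_m = self.weight.reshape(g, oc // g, icg * kh * kw)
        out = np.einsum("ngkp,gok->ngop", cols_m, w_m, optimize=True)
        out = out.reshape(n, oc, oh, ow)
        if self.bias is not None:
            out += self.bias[None, :, None, None]
        if train:
            self._cache = (x, cols_m, (oh, ow))
        return out

    def backward(self, grad):
        if self.groups != 1 or self.dilation != 1 or not isinstance(self.pad, int) \
                or not isinstance(self.stride, int):
            raise NotImplementedError("backward supports groups=1, dilation=1, int stride/pad")
        x, cols_m, (oh, ow) = self._cache
        n, c, h, w = x.shape
        oc, icg, kh, kw = self.weight.shape
        g2 = grad.reshape(n, 1, oc, oh * ow)
        self.dweight = np.einsum("ngop,ngkp->ok", g2, cols_m,
                                 optimize=True).reshape(self.weight.shape)
        if self.bias is not None:
            self.dbias = grad.sum(axis=(0, 2, 3))
        w_flat = self.weight.reshape(oc, icg * kh * kw)
        dcols = np.einsum("ok,ngop->nkp", w_flat, g2, optimize=True)
        dcols = dcols.reshape(n, icg, kh, kw, oh, ow)
        dx_p = np.zeros((n, c, h + 2 * self.pad, w + 2 * self.pad), dtype=np.float32)
        for i in range(kh):
            for j in range(kw):
                dx_p[:, :, i : i + oh * self.stride : self.stride,
                     j : j + ow * self.stride : self.stride] += dcols[:, :, i, j]
        if self.pad:
            return dx_p[:, :, self.pad : -self.pad, self.pad : -self.pad]
        return dx_p

    def params(self):
        yield "weight", self.weight
        if self.bias is not None:
            yield "bias", self.bias

    def grads(self):
        yield "weight", self.dweight
        if self.bias is not None:
            yield "bias", self.dbias


class Linear(Layer):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / in_f)
        self.weight = (rng.standard_normal((out_f, in_f)) * scale).astype(np.float32)
        self.bias = np.zeros(out_f, dtype=np.float32)
        self.dweight = None
        self.dbias = None
        self._x = None

    def forward(self, x, train=False):
        x = x.astype(np.float32, copy=False)
        if train:
            self._x = x
        return x @ self.weight.T + self.bias

    def backward(self, grad):
        self.dweight = grad.T @ self._x
        self.dbias = grad.sum(axis=0)
        return grad @ self.weight

    def params(self):
        yield "weight", self.weight
        yield "bias", self.bias

    def grads(self):
        yield "weight", self.dweight
        yield "bias", self.dbias


class BatchNorm2d(Layer):
    """Inference-mode batch normalization (running stats; identity at random init)."""

    def __init__(self, ch: int, eps: float = 1e-5):
        self.gamma = np.ones(ch, dtype=np.float32)
        self.beta = np.zeros(ch, dtype=np.float32)
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)
        self.eps = eps

    def forward(self, x, train=False):
        inv = self.gamma / np.sqrt(self.running_var + self.eps)
        return x * inv[None, :, None, None] + (self.beta - self.running_mean * inv)[None, :, None, None]

    def params(self):
        yield "gamma", self.gamma
        yield "beta", self.beta


class LayerNorm2d(Layer):
    """Layer normalization over the channel dimension of an NCHW tensor."""

    def __init__(self, ch: int, eps: float = 1e-6):
        self.gamma = np.ones(ch, dtype=np.float32)
        self.beta = np.zeros(ch, dtype=np.float32)
        self.eps = eps

    def forward(self, x, train=False):
        mu = x.mean(axis=1, keepdims=True)
        var = x.var(axis=1, keepdims=True)
        xn = (x - mu) / np.sqrt(var + self.eps)
        return xn * self.gamma[None, :, None, None] + self.beta[None, :, None, None]

    def params(self):
        yield "gamma", self.gamma
        yield "beta", self.beta


class ReLU(Layer):
    def forward(self, x, train=False):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, grad):
        return grad * self._mask


class SiLU(Layer):
    def forward(self, x, train=False):
        return x / (1.0 + np.exp(-x))


class GELU(Layer):
    def forward(self, x, train=False):
        return 0.5 * x * (1.0 + np.tanh(np.sqrt(2.0 / np.pi) * (x + 0.044715 * x ** 3)))


class Sigmoid(Layer):
    def forward(self, x, train=False):
        return 1.0 / (1.0 + np.exp(-x))


class MaxPool2d(Layer):
    def __init__(self, kernel: int, stride: int | None = None, pad: int = 0):
        self.kernel = kernel
        self.stride = stride or kernel
        self.pad = pad

    def forward(self, x, train=False):
        if self.pad:
            xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad)),
                        constant_values=-np.inf)
        else:
            xp = x
        cols, oh, ow = _im2col(xp, self.kernel, self.kernel, self.stride, 0)
        flat = cols.reshape(*cols.shape[:2], self.kernel * self.kernel, oh, ow)
        out = flat.max(axis=2)
        if train:
            self._cache = (x.shape, flat.argmax(axis=2), oh, ow)
        return out

    def backward(self, grad):
        if self.pad:
            raise NotImplementedError("backward supports pad=0")
        shape, amax, oh, ow = self._cache
        n, c, h, w = shape
        dx = np.zeros(shape, dtype=np.float32)
        ri, ci = np.divmod(amax, self.kernel)
        orow = (np.arange(oh) * self.stride)[None, None, :, None]
        ocol = (np.arange(ow) * self.stride)[None, None, None, :]
        rows = (ri + orow).ravel()
        colsx = (ci + ocol).ravel()
        nn = np.repeat(np.arange(n), c * oh * ow)
        cc = np.tile(np.repeat(np.arange(c), oh * ow), n)
        np.add.at(dx, (nn, cc, rows, colsx), grad.ravel())
        return dx


class AvgPool2d(Layer):
    def __init__(self, kernel: int, stride: int | None = None, pad: int = 0):
        self.kernel = kernel
        self.stride = stride or kernel
        self.pad = pad

    def forward(self, x, train=False):
        cols, oh, ow = _im2col(x, self.kernel, self.kernel, self.stride, self.pad)
        return cols.mean(axis=(2, 3))


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C)."""

    def forward(self, x, train=False):
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        n, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None], self._shape) / (h * w)


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, p: float = 0.5, rng: np.random.Generator | None = None):
        self.p = p
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x, train=False):
        if not train or self.p <= 0:
            return x
        mask = self.rng.random(x.shape) >= self.p
        return x * mask / (1.0 - self.p)


def softmax_cross_entropy(logits: np.ndarray, targets: np.ndarray):
    """Mean cross-entropy loss and its gradient w.r.t. logits.

    ``targets`` are integer class indices of shape (N,).
    """
    z = logits - logits.max(axis=1, keepdims=True)
    expz = np.exp(z)
    probs = expz / expz.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = float(-np.mean(np.log(probs[np.arange(n), targets] + 1e-12)))
    grad = probs.copy()
    grad[np.arange(n), targets] -= 1.0
    return loss, grad / n
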