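"""Minimal NumPy neural-network layers with analytic backpropagation.

Only what the dense segmentation network needs: 3x3 and 1x1 convolutions,
batch normalization, ReLU, non-overlapping 2x2 max pooling, a stride-2 3x3
transposed convolution, a two-class softmax head, the soft Dice loss, and an
SGD-momentum optimizer.  Tensors are (N, C, H, W).  Every layer caches what its
backward pass needs during ``forward(..., train=True)``; gradients accumulate
into ``Param.grad`` and are zeroed by the optimizer step.

Correctness of the backward passes is guarded by numerical gradient checks in
the test suite.
"""

from __future__ import annotations

import numpy as np


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def he_normal(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    """Zero-mean normal weights with variance 2/fan_in."""
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Conv3x3(Layer):
    """Same-padding 3x3 convolution as nine shifted GEMMs on a flat buffer.

    The padded input is stored channel-major as one contiguous row per channel;
    a kernel tap at offset (di, dj) is then a contiguous view shifted by
    di*(W+2)+dj, so every tap is a plain BLAS matmul with no gather.  Tap
    spill-over lands in padding rows/columns that are cropped from the output.
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, dtype=np.float32):
        self.W = Param(he_normal(rng, (cout, cin, 3, 3), cin * 9, dtype))
        self.b = Param(np.zeros(cout, dtype=dtype))

    def params(self):
        return [self.W, self.b]

    def _flatten(self, x):
        """(N,C,H,W) -> contiguous (C, margin + N*(H+2)*(W+2) + margin) buffer."""
        n, c, h, w = x.shape
        s = w + 2
        L = n * (h + 2) * s
        m = s + 1
        buf = np.zeros((c, L + 2 * m), dtype=x.dtype)
        core = buf[:, m : m + L].reshape(c, n, h + 2, s)
        core[:, :, 1:-1, 1:-1] = x.transpose(1, 0, 2, 3)
        return buf, (n, h, w, s, L, m)

    def forward(self, x, train=True):
        buf, geom = self._flatten(x)
        n, h, w, s, L, m = geom
        cout = self.W.value.shape[0]
        y = np.zeros((cout, L), dtype=x.dtype)
        for i in range(3):
            for j in range(3):
                off = m + (i - 1) * s + (j - 1)
                y += self.W.value[:, :, i, j] @ buf[:, off : off + L]
        if train:
            self._buf, self._geom = buf, geom
        y = y.reshape(cout, n, h + 2, s)[:, :, 1:-1, 1:-1]
        return y.transpose(1, 0, 2, 3) + self.b.value[None, :, None, None]

    def backward(self, dy):
        buf, (n, h, w, s, L, m) = self._buf, self._geom
        cout = dy.shape[1]
        dyf = np.zeros((cout, n, h + 2, s), dtype=dy.dtype)
        dyf[:, :, 1:-1, 1:-1] = dy.transpose(1, 0, 2, 3)
        dyf = dyf.reshape(cout, L)
        dbuf = np.zeros_like(buf)
        for i in range(3):
            for j in range(3):
                off = m + (i - 1) * s + (j - 1)
                xs = buf[:, off : off + L]
                self.W.grad[:, :, i, j] += dyf @ xs.T
                dbuf[:, off : off + L] += self.W.value[:, :, i, j].T @ dyf
        self.b.grad += dy.sum(axis=(0, 2, 3))
        dx = dbuf[:, m : m + L].reshape(-1, n, h + 2, s)[:, :, 1:-1, 1:-1]
        self._buf = None
        return np.ascontiguousarray(dx.transpose(1, 0, 2, 3))


class Conv1x1(Layer):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator, dtype=np.float32):
        self.W = Param(he_normal(rng, (cout, cin), cin, dtype))
        self.b = Param(np.zeros(cout, dtype=dtype))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        xf = np.ascontiguousarray(x.transpose(1, 0, 2, 3)).reshape(c, -1)
        if train:
            self._xf, self._shape = xf, x.shape
        y = (self.W.value @ xf).reshape(-1, n, h, w).transpose(1, 0, 2, 3)
        return y + self.b.value[None, :, None, None]

    def backward(self, dy):
        n, c, h, w = self._shape
        dyf = np.ascontiguousarray(dy.transpose(1, 0, 2, 3)).reshape(dy.shape[1], -1)
        self.W.grad += dyf @ self._xf.T
        self.b.grad += dyf.sum(axis=1)
        self._xf = None
        dx = (self.W.value.T @ dyf).reshape(c, n, h, w)
        return np.ascontiguousarray(dx.transpose(1, 0, 2, 3))


class BatchNorm2d(Layer):
    """Per-channel batch normalization over (N, H, W).

    Training uses batch statistics and keeps exponential running estimates
    (decay 0.9) for inference.
    """

    def __init__(self, c: int, dtype=np.float32, eps: float = 1e-5, decay: float = 0.9):
        self.gamma = Param(np.ones(c, dtype=dtype))
        self.beta = Param(np.zeros(c, dtype=dtype))
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self.eps = eps
        self.decay = decay

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=True):
        # one-pass moments; normalization fused into a single affine y = a*x + b
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = np.square(x).mean(axis=(0, 2, 3)) - mean * mean
            np.maximum(var, 0, out=var)
            self.running_mean = self.decay * self.running_mean + (1 - self.decay) * mean
            self.running_var = self.decay * self.running_var + (1 - self.decay) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
        a = self.gamma.value * inv_std
        b = self.beta.value - mean * a
        if train:
            self._x, self._mean, self._inv_std = x, mean.astype(x.dtype), inv_std
        return a[None, :, None, None] * x + b[None, :, None, None]

    def backward(self, dy):
        x, mean, inv_std = self._x, self._mean, self._inv_std
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        dxhat_mean = dy.mean(axis=(0, 2, 3), keepdims=True)
        dxhat_xhat_mean = (dy * xhat).mean(axis=(0, 2, 3), keepdims=True)
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = (self.gamma.value * inv_std)[None, :, None, None]
        dx = g * (dy - dxhat_mean - xhat * dxhat_xhat_mean)
        self._x = None
        return dx


class ReLU(Layer):
    def forward(self, x, train=True):
        y = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy):
        dx = dy * self._mask
        self._mask = None
        return dx


class MaxPool2x2(Layer):
    """Non-overlapping 2x2 max pooling; input H, W must be even."""

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"max pooling requires even spatial dims, got {h}x{w}")
        xr = (
            x.reshape(n, c, h // 2, 2, w // 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h // 2, w // 2, 4)
        )
        idx = xr.argmax(axis=-1)
        y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx, self._shape = idx, x.shape
        return y

    def backward(self, dy):
        n, c, h, w = self._shape
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=-1)
        dx = (
            dxr.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )
        self._idx = None
        return dx


class TransposedConv3x3Stride2(Layer):
    """Stride-2 3x3 transposed convolution that exactly doubles H and W.

    Realized as zero interleaving (stride-2 upsampling) followed by a
    same-padding 3x3 convolution, which is algebraically a transposed
    convolution with output padding 1.
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, dtype=np.float32):
        self.conv = Conv3x3(cin, cout, rng, dtype)

    def params(self):
        return self.conv.params()

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        z = np.zeros((n, c, 2 * h, 2 * w), dtype=x.dtype)
        z[:, :, ::2, ::2] = x
        return self.conv.forward(z, train=train)

    def backward(self, dy):
        dz = self.conv.backward(dy)
        return dz[:, :, ::2, ::2]


def softmax2(scores: np.ndarray) -> np.ndarray:
    """Channel softmax for a two-channel score tensor (N, 2, H, W)."""
    s = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(s)
    return e / e.sum(axis=1, keepdims=True)


def soft_dice_loss(p: np.ndarray, y: np.ndarray, smooth: float = 1.0, with_grad: bool = False):
    """Soft Dice loss 1 - (2*sum(p*y)+eps) / (sum(p)+sum(y)+eps).

    ``p`` are foreground probabilities in [0, 1], ``y`` the binary target, both
    summed over the whole tensor (batch-aggregated Dice).  Returns the scalar
    loss, or ``(loss, dL/dp)`` when ``with_grad``.
    """
    p = np.asarray(p)
    y = np.asarray(y)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: probabilities {p.shape} vs labels {y.shape}")
    inter = float((p * y).sum())
    denom = float(p.sum()) + float(y.sum()) + smooth
    num = 2.0 * inter + smooth
    loss = 1.0 - num / denom
    if not with_grad:
        return loss
    grad = -(2.0 * y * denom - num) / (denom * denom)
    return loss, grad.astype(p.dtype)


def dice_grad_to_scores(prob: np.ndarray, dp_fg: np.ndarray) -> np.ndarray:
    """Chain a gradient w.r.t. foreground probability through the 2-class softmax."""
    pf = prob[:, 1]
    common = dp_fg * pf * (1.0 - pf)
    ds = np.empty_like(prob)
    ds[:, 1] = common
    ds[:, 0] = -common
    return ds


class SGDMomentum:
    """Classical momentum: v <- gamma*v + g; w <- w - lr*v."""

    def __init__(self, params: list[Param], lr: float, momentum: float):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.velocity = [np.zeros_like(p.value) for p in params]

    def step(self):
        for p, v in zip(self.params, self.velocity):
            v *= self.momentum
            v += p.grad
            p.value -= self.lr * v
            p.grad[...] = 0.0

    def reset(self):
        """Zero the momentum buffers (used after a rollback)."""
        self.velocity = [np.zeros_like(p.value) for p in self.params]
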