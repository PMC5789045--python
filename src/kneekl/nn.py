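"""Minimal NumPy neural-network engine used by the Siamese grading model.

Layers operate on NCHW float32 tensors and expose an explicit
``forward(x, ...) -> (out, cache)`` / ``backward(dout, cache) -> dx`` pair;
``backward`` accumulates parameter gradients in place (``Param.grad += ...``)
so a layer may be applied several times per step — this is exactly what weight
sharing across the two Siamese branches requires.

Convolutions are "valid" (no zero padding) with 3x3 kernels, computed as nine
offset-slice matmuls rather than an im2col buffer; for the small feature maps
used here this is both fast and memory-light on a single CPU.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Param", "Conv2d", "BatchNorm2d", "ReLU", "MaxPool2d",
           "GlobalAvgPool", "Linear", "Dropout", "Adam",
           "softmax", "cross_entropy"]


class Param:
    """A learnable array with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Conv2d:
    """Valid (unpadded) 2-D convolution with a square kernel."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)  # He initialisation for ReLU stacks
        self.W = Param(rng.normal(0.0, scale, (out_ch, in_ch, kernel, kernel)))
        self.b = Param(np.zeros(out_ch))
        self.kernel = kernel
        self.stride = stride

    def params(self):
        return [self.W, self.b]

    @staticmethod
    def out_size(n: int, kernel: int, stride: int) -> int:
        return (n - kernel) // stride + 1

    def forward(self, x: np.ndarray, train: bool = False):
        k, s = self.kernel, self.stride
        B, C, H, Wd = x.shape
        oh, ow = self.out_size(H, k, s), self.out_size(Wd, k, s)
        # one im2col materialisation per pass, laid out so the GEMM reshape is free
        cols = np.ascontiguousarray(
            np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
            [:, :, ::s, ::s].transpose(0, 2, 3, 1, 4, 5))   # (B, oh, ow, C, k, k)
        cols2d = cols.reshape(B * oh * ow, C * k * k)
        wf = self.W.value.reshape(self.W.value.shape[0], C * k * k)
        out2d = cols2d @ wf.T + self.b.value
        out = out2d.reshape(B, oh, ow, -1).transpose(0, 3, 1, 2)
        return np.ascontiguousarray(out, dtype=np.float32), (x.shape, cols2d)

    def backward(self, dout: np.ndarray, cache):
        shape, cols2d = cache
        k, s = self.kernel, self.stride
        B, O, oh, ow = dout.shape
        C = shape[1]
        dout2d = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(-1, O)
        self.W.grad += (dout2d.T @ cols2d).reshape(self.W.grad.shape)
        self.b.grad += dout2d.sum(axis=0)
        # col2im: one GEMM back to column space, then nine strided adds
        dcols = (dout2d @ self.W.value.reshape(O, -1)).reshape(B, oh, ow, C, k, k)
        dcols = dcols.transpose(0, 3, 1, 2, 4, 5)  # (B, C, oh, ow, k, k)
        dx = np.zeros(shape, dtype=dout.dtype)
        for ki in range(k):
            for kj in range(k):
                dx[:, :, ki : ki + s * (oh - 1) + 1 : s,
                   kj : kj + s * (ow - 1) + 1 : s] += dcols[:, :, :, :, ki, kj]
        return dx


class BatchNorm2d:
    """Per-channel batch normalisation with running statistics for inference."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        out = self.gamma.value[None, :, None, None] * xhat \
            + self.beta.value[None, :, None, None]
        return out.astype(np.float32), (xhat, inv_std, train)

    def backward(self, dout: np.ndarray, cache):
        xhat, inv_std, train = cache
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        g = (self.gamma.value * inv_std)[None, :, None, None]
        if not train:
            return dout * g
        n = dout.shape[0] * dout.shape[2] * dout.shape[3]
        dsum = dout.sum(axis=(0, 2, 3))[None, :, None, None]
        dxhat_sum = (dout * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        return g / n * (n * dout - dsum - xhat * dxhat_sum)


class ReLU:
    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = False):
        out = np.maximum(x, 0.0)
        return out, (x > 0)

    def backward(self, dout: np.ndarray, cache):
        return dout * cache


class MaxPool2d:
    """2x2 max pooling with stride 2; trailing odd rows/columns are dropped."""

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = False):
        B, C, H, W = x.shape
        h2, w2 = H // 2, W // 2
        xc = x[:, :, : 2 * h2, : 2 * w2]
        windows = xc.reshape(B, C, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = windows.reshape(B, C, h2, w2, 4)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        return out, (x.shape, idx)

    def backward(self, dout: np.ndarray, cache):
        (B, C, H, W), idx = cache
        h2, w2 = H // 2, W // 2
        dflat = np.zeros((B, C, h2, w2, 4), dtype=dout.dtype)
        np.put_along_axis(dflat, idx[..., None], dout[..., None], axis=-1)
        dxc = dflat.reshape(B, C, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        dx = np.zeros((B, C, H, W), dtype=dout.dtype)
        dx[:, :, : 2 * h2, : 2 * w2] = dxc.reshape(B, C, 2 * h2, 2 * w2)
        return dx


class GlobalAvgPool:
    """Collapse each activation map to its spatial mean: (B,C,H,W) -> (B,C)."""

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = False):
        return x.mean(axis=(2, 3)), x.shape

    def backward(self, dout: np.ndarray, cache):
        B, C, H, W = cache
        return np.broadcast_to(dout[:, :, None, None] / (H * W), cache).astype(dout.dtype)


class Linear:
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / in_dim)
        self.W = Param(rng.normal(0.0, scale, (out_dim, in_dim)))
        self.b = Param(np.zeros(out_dim))

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False):
        return x @ self.W.value.T + self.b.value, x

    def backward(self, dout: np.ndarray, cache):
        x = cache
        self.W.grad += dout.T @ x
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value


class Dropout:
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None):
        if not train or self.rate == 0.0:
            return x, None
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        mask = (rng.random(x.shape) >= self.rate) / np.float32(1.0 - self.rate)
        return x * mask.astype(np.float32), mask

    def backward(self, dout: np.ndarray, cache):
        if cache is None:
            return dout
        return dout * cache


class Adam:
    """Adam with decoupled-from-nothing classic L2 weight decay added to gradients."""

    def __init__(self, params: list[Param], lr: float = 1e-2,
                 weight_decay: float = 0.0, betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = 1e-12
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), (dlogits / n).astype(np.float32)
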