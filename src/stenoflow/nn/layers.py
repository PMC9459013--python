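"""Minimal float32 neural-network layers with explicit backpropagation.

Layout is channels-last: 2D activations are (N, H, W, C), 3D activations
(N, D, H, W, C), dense activations (N, F).  Convolutions are stride-1 with
'same' (asymmetric for even kernels) zero padding and are evaluated as a
sum of shifted GEMMs, so no im2col buffer is materialized.  Every layer
caches what its backward pass needs; `backward` must follow the matching
`forward`.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Dense", "Conv", "MaxPool", "ReLU", "Tanh", "Flatten", "Reshape", "Sequential"]


class Layer:
    def params(self):
        return []

    def forward(self, x):
        raise NotImplementedError

    def backward(self, grad):
        raise NotImplementedError


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


class Dense(Layer):
    def __init__(self, n_in, n_out, rng):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = Param(rng.uniform(-limit, limit, (n_in, n_out)))
        self.b = Param(np.zeros(n_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad):
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T


class Conv(Layer):
    """Stride-1 'same' convolution, kernel k per axis, 2 or 3 spatial dims."""

    def __init__(self, dim, c_in, c_out, k, rng):
        self.dim = dim
        self.k = k
        fan_in = c_in * k**dim
        fan_out = c_out * k**dim
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        self.W = Param(rng.uniform(-limit, limit, (k,) * dim + (c_in, c_out)))
        self.b = Param(np.zeros(c_out))
        # even kernels pad one less on the low side (matches common 'same')
        lo = (k - 1) // 2
        self._pad = (lo, k - 1 - lo)

    def params(self):
        return [self.W, self.b]

    def _offsets(self):
        k = self.k
        if self.dim == 2:
            return [(a, b) for a in range(k) for b in range(k)]
        return [(a, b, c) for a in range(k) for b in range(k) for c in range(k)]

    def forward(self, x):
        lo, hi = self._pad
        pad = [(0, 0)] + [(lo, hi)] * self.dim + [(0, 0)]
        xp = np.pad(x, pad)
        self._xp = xp
        spatial = x.shape[1 : 1 + self.dim]
        out = np.zeros(x.shape[: 1 + self.dim] + (self.b.value.shape[0],), dtype=x.dtype)
        for off in self._offsets():
            sl = (slice(None),) + tuple(
                slice(o, o + s) for o, s in zip(off, spatial)
            )
            out += self._xp[sl] @ self.W.value[off]
        out += self.b.value
        return out

    def backward(self, grad):
        lo, hi = self._pad
        spatial = grad.shape[1 : 1 + self.dim]
        dxp = np.zeros_like(self._xp)
        for off in self._offsets():
            sl = (slice(None),) + tuple(slice(o, o + s) for o, s in zip(off, spatial))
            patch = self._xp[sl]
            self.W.grad[off] += np.tensordot(patch, grad, axes=(range(self.dim + 1),) * 2)
            dxp[sl] += grad @ self.W.value[off].T
        self.b.grad += grad.sum(axis=tuple(range(self.dim + 1)))
        sl = (slice(None),) + tuple(
            slice(lo, d - hi) for d in self._xp.shape[1 : 1 + self.dim]
        ) + (slice(None),)
        return dxp[sl]


class MaxPool(Layer):
    """Non-overlapping max pooling by an integer factor per spatial axis.

    ``ceil_mode`` pads the high side with -inf so partial windows count
    (61 -> 21 at factor 3); otherwise trailing remainders are dropped
    (214 -> 71).
    """

    def __init__(self, dim, factor=3, ceil_mode=False):
        self.dim = dim
        self.f = factor
        self.ceil = ceil_mode

    def forward(self, x):
        f, d = self.f, self.dim
        spatial = x.shape[1 : 1 + d]
        if self.ceil:
            newsp = [-(-s // f) for s in spatial]
            pad = [(0, 0)] + [(0, n * f - s) for n, s in zip(newsp, spatial)] + [(0, 0)]
            xc = np.pad(x, pad, constant_values=-np.inf)
        else:
            newsp = [s // f for s in spatial]
            sl = (slice(None),) + tuple(slice(0, n * f) for n in newsp) + (slice(None),)
            xc = x[sl]
        self._in_shape = x.shape
        shape = [x.shape[0]]
        for n in newsp:
            shape += [n, f]
        shape += [x.shape[-1]]
        xr = xc.reshape(shape)
        axes = tuple(2 + 2 * i for i in range(d))
        out = xr.max(axis=axes)
        # mask for backward: ties share the gradient
        expand = out.reshape(
            [x.shape[0]] + [v for n in newsp for v in (n, 1)] + [x.shape[-1]]
        )
        mask = (xr == expand)
        self._mask = mask
        self._newsp = newsp
        self._count = mask.sum(axis=axes, keepdims=True)
        return out

    def backward(self, grad):
        f, d = self.f, self.dim
        gexp = grad.reshape(
            [grad.shape[0]] + [v for n in self._newsp for v in (n, 1)] + [grad.shape[-1]]
        )
        gr = np.where(self._mask, (gexp / self._count), 0.0)
        # collapse the window axes back into spatial axes
        full = [grad.shape[0]] + [n * f for n in self._newsp] + [grad.shape[-1]]
        gr = gr.reshape(full)
        out = np.zeros(self._in_shape, dtype=grad.dtype)
        sl = (slice(None),) + tuple(
            slice(0, min(n * f, s)) for n, s in zip(self._newsp, self._in_shape[1 : 1 + d])
        ) + (slice(None),)
        src = (slice(None),) + tuple(
            slice(0, min(n * f, s)) for n, s in zip(self._newsp, self._in_shape[1 : 1 + d])
        ) + (slice(None),)
        out[sl] = gr[src]
        return out


class ReLU(Layer):
    def forward(self, x):
        self._m = x > 0
        return np.where(self._m, x, 0.0)

    def backward(self, grad):
        return np.where(self._m, grad, 0.0)


class Tanh(Layer):
    def forward(self, x):
        self._y = np.tanh(x)
        return self._y

    def backward(self, grad):
        return (grad * (1.0 - self._y**2))


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, shape):
        self.shape = tuple(shape)

    def forward(self, x):
        self._in = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, grad):
        return grad.reshape(self._in)


class Sequential(Layer):
    def __init__(self, layers):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad

    def zero_grad(self):
        for p in self.params():
            p.grad[:] = 0.0

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))
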