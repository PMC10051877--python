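"""Small convolutional building blocks and an Adam optimizer.

Built on :mod:`synthmri.autodiff`; provides exactly what the generative
pyramid, the segmentation network and the binary classifier need:
3x3 convolutions, per-channel instance normalization, leaky rectifiers,
pooling/upsampling and the usual losses.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "Conv2d", "ConvBlock", "Sequential", "Adam",
    "instance_norm", "mse", "bce_with_logits",
]


class Conv2d:
    """3x3 (by default) convolution with bias, implemented as
    im2col + matmul so both backward passes stay inside the graph."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 1,
                 pad: int = 1, rng: np.random.Generator | None = None,
                 w_scale: float = 0.05):
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, w_scale, size=(c_out, c_in * k * k)).astype(ad.DTYPE)
        self.w = Tensor(w)
        self.b = Tensor(np.zeros((c_out,), dtype=ad.DTYPE))
        self.k, self.stride, self.pad = k, stride, pad
        self.c_in, self.c_out = c_in, c_out

    def __call__(self, x: Tensor) -> Tensor:
        N, C, H, W = x.shape
        Ho = (H + 2 * self.pad - self.k) // self.stride + 1
        Wo = (W + 2 * self.pad - self.k) // self.stride + 1
        cols = ad.im2col(x, self.k, self.stride, self.pad)
        out = ad.matmul(self.w, cols)                       # (N, c_out, L)
        out = ad.reshape(out, (N, self.c_out, Ho, Wo))
        return ad.add(out, ad.reshape(self.b, (1, self.c_out, 1, 1)))

    def params(self):
        return [self.w, self.b]


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize each (sample, channel) plane over its spatial extent.

    Composed from graph primitives so the gradient penalty can
    differentiate through it twice.
    """
    mu = ad.meant(x, axis=(2, 3), keepdims=True)
    xc = ad.sub(x, mu)
    var = ad.meant(ad.mul(xc, xc), axis=(2, 3), keepdims=True)
    xn = ad.mul(xc, ad.powc(ad.add_const(var, eps), -0.5))
    C = x.shape[1]
    return ad.add(ad.mul(xn, ad.reshape(gamma, (1, C, 1, 1))),
                  ad.reshape(beta, (1, C, 1, 1)))


class ConvBlock:
    """conv -> (instance norm) -> leaky ReLU, the unit both the
    generators and the critics are assembled from."""

    def __init__(self, c_in: int, c_out: int, rng, norm: bool = True,
                 slope: float = 0.2, k: int = 3, pad: int = 1):
        self.conv = Conv2d(c_in, c_out, k=k, pad=pad, rng=rng)
        self.norm = norm
        self.slope = slope
        if norm:
            self.gamma = Tensor(np.ones((c_out,), dtype=ad.DTYPE))
            self.beta = Tensor(np.zeros((c_out,), dtype=ad.DTYPE))

    def __call__(self, x: Tensor) -> Tensor:
        h = self.conv(x)
        if self.norm:
            h = instance_norm(h, self.gamma, self.beta)
        return ad.leaky_relu(h, self.slope)

    def params(self):
        p = self.conv.params()
        if self.norm:
            p += [self.gamma, self.beta]
        return p


class Sequential:
    def __init__(self, *layers):
        self.layers = list(layers)

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x

    def params(self):
        out = []
        for layer in self.layers:
            out += layer.params()
        return out


# ---------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------

def mse(a: Tensor, b: Tensor) -> Tensor:
    d = ad.sub(a, b)
    return ad.meant(ad.mul(d, d))


def bce_with_logits(z: Tensor, y: Tensor) -> Tensor:
    """Stable binary cross-entropy:
    max(z,0) - z*y + log(1 + exp(-|z|)), averaged."""
    loss = ad.sub(ad.relu(z), ad.mul(z, y))
    loss = ad.add(loss, ad.log(ad.add_const(ad.exp(ad.neg(ad.absolute(z))), 1.0)))
    return ad.meant(loss)


# ---------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------

class Adam:
    def __init__(self, params, lr: float = 5e-4, beta1: float = 0.5,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            gd = g.data if isinstance(g, Tensor) else g
            m *= self.b1
            m += (1.0 - self.b1) * gd
            v *= self.b2
            v += (1.0 - self.b2) * gd * gd
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
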