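"""Minimal neural-network engine for the slice-wise denoiser.

Implements exactly the pieces the denoiser needs: 3x3 same-padded 2-D
convolutions (direct numba-compiled kernels), ReLU, 2x2 average pooling,
nearest up-sampling, dropout, a residual 3-level U-net, and the ADAM
optimizer.  Forward activations are cached on the layer objects;
`backward` consumes them, so each forward must be paired with at most one
backward.

Everything is float32 during training and fully seeded; dropout is the
only stochastic component and is disabled outside training.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["SmallUNet2D", "Adam"]


@njit(fastmath=True)
def _conv3x3_fwd(xpad, W, b):
    N, C, Hp, Wp = xpad.shape
    O = W.shape[0]
    H, Wd = Hp - 2, Wp - 2
    out = np.empty((N, O, H, Wd), xpad.dtype)
    for n in range(N):
        for o in range(O):
            for h in range(H):
                row = out[n, o, h]
                for w in range(Wd):
                    row[w] = b[o]
                for c in range(C):
                    for ki in range(3):
                        xrow = xpad[n, c, h + ki]
                        for kj in range(3):
                            wv = W[o, c, ki, kj]
                            for w in range(Wd):
                                row[w] += wv * xrow[w + kj]
    return out


@njit(fastmath=True)
def _conv3x3_bwd_dx(dout, W):
    N, O, H, Wd = dout.shape
    C = W.shape[1]
    dxpad = np.zeros((N, C, H + 2, Wd + 2), dout.dtype)
    for n in range(N):
        for o in range(O):
            for h in range(H):
                drow = dout[n, o, h]
                for c in range(C):
                    for ki in range(3):
                        xrow = dxpad[n, c, h + ki]
                        for kj in range(3):
                            wv = W[o, c, ki, kj]
                            for w in range(Wd):
                                xrow[w + kj] += wv * drow[w]
    return dxpad


@njit(fastmath=True)
def _conv3x3_bwd_dw(dout, xpad):
    N, O, H, Wd = dout.shape
    C = xpad.shape[1]
    dW = np.zeros((O, C, 3, 3), dout.dtype)
    db = np.zeros(O, dout.dtype)
    for n in range(N):
        for o in range(O):
            for h in range(H):
                drow = dout[n, o, h]
                for w in range(Wd):
                    db[o] += drow[w]
                for c in range(C):
                    for ki in range(3):
                        xrow = xpad[n, c, h + ki]
                        for kj in range(3):
                            acc = dW[o, c, ki, kj]
                            for w in range(Wd):
                                acc += drow[w] * xrow[w + kj]
                            dW[o, c, ki, kj] = acc
    return dW, db


class _Conv3x3:
    """Same-padded 3x3 convolution with bias."""

    def __init__(self, c_in, c_out, rng):
        scale = np.sqrt(2.0 / (c_in * 9))
        self.W = (rng.normal(0.0, scale, (c_out, c_in, 3, 3))).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x):
        xpad = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        self._xpad = xpad
        return _conv3x3_fwd(xpad, self.W.astype(x.dtype), self.b.astype(x.dtype))

    def backward(self, dout):
        dW, db = _conv3x3_bwd_dw(dout, self._xpad)
        self.dW += dW
        self.db += db
        dxpad = _conv3x3_bwd_dx(dout, self.W.astype(dout.dtype))
        self._xpad = None
        return dxpad[:, :, 1:-1, 1:-1]

    @property
    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class _ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class _AvgPool2:
    def forward(self, x):
        N, C, H, W = x.shape
        self._shape = x.shape
        return x.reshape(N, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))

    def backward(self, dout):
        N, C, H, W = self._shape
        return np.repeat(np.repeat(dout, 2, axis=2), 2, axis=3) * np.float32(0.25)


class _Upsample2:
    def forward(self, x):
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dout):
        N, C, H, W = dout.shape
        return dout.reshape(N, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))


class _Dropout:
    def __init__(self, rate):
        self.rate = rate

    def forward(self, x, train, rng):
        if not train or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(np.float32) / np.float32(keep)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class SmallUNet2D:
    """Residual 3-level encoder-decoder applied to 2-D slices.

    Levels operate at full, half, and quarter resolution with ``n_filters``
    and ``2 * n_filters`` feature maps; skip connections add encoder
    features into the decoder, and the network output is added to its input
    (it learns a correction to the low-dose slice).
    """

    def __init__(self, n_filters=4, dropout=0.0, seed=0):
        rng = np.random.default_rng(seed)
        F = n_filters
        self.c1 = _Conv3x3(1, F, rng)
        self.c2 = _Conv3x3(F, F, rng)
        self.c3 = _Conv3x3(F, 2 * F, rng)
        self.c4 = _Conv3x3(2 * F, 2 * F, rng)
        self.c5 = _Conv3x3(2 * F, F, rng)
        self.c6 = _Conv3x3(F, F, rng)
        self.c7 = _Conv3x3(F, 1, rng)
        self.r = [_ReLU() for _ in range(6)]
        self.pool1, self.pool2 = _AvgPool2(), _AvgPool2()
        self.up1, self.up2 = _Upsample2(), _Upsample2()
        self.drop = _Dropout(dropout)

    def forward(self, x, train=False, rng=None):
        """x: (N, 1, H, W) float32 with H, W divisible by 4."""
        h1 = self.r[0].forward(self.c1.forward(x))
        h2 = self.r[1].forward(self.c2.forward(h1))
        h3 = self.r[2].forward(self.c3.forward(self.pool1.forward(h2)))
        h4 = self.r[3].forward(self.c4.forward(self.pool2.forward(h3)))
        h4 = self.drop.forward(h4, train, rng)
        u1 = self.up1.forward(h4) + h3
        h5 = self.r[4].forward(self.c5.forward(u1))
        u2 = self.up2.forward(h5) + h2
        h6 = self.r[5].forward(self.c6.forward(u2))
        return self.c7.forward(h6) + x

    def backward(self, dout):
        """Accumulate parameter gradients; returns gradient w.r.t. input."""
        dx_res = dout  # residual branch
        d6 = self.c7.backward(dout)
        du2 = self.c6.backward(self.r[5].backward(d6))
        dh2 = du2  # skip branch
        d5 = self.up2.backward(du2)
        du1 = self.c5.backward(self.r[4].backward(d5))
        dh3 = du1  # skip branch
        d4 = self.up1.backward(du1)
        d4 = self.drop.backward(d4)
        dp2 = self.c4.backward(self.r[3].backward(d4))
        dh3 = dh3 + self.pool2.backward(dp2)
        dp1 = self.c3.backward(self.r[2].backward(dh3))
        dh2 = dh2 + self.pool1.backward(dp1)
        dh1 = self.c2.backward(self.r[1].backward(dh2))
        dx = self.c1.backward(self.r[0].backward(dh1))
        return dx + dx_res

    @property
    def convs(self):
        return [self.c1, self.c2, self.c3, self.c4, self.c5, self.c6, self.c7]

    def zero_grad(self):
        for c in self.convs:
            c.dW[...] = 0
            c.db[...] = 0

    def parameters(self):
        out = []
        for c in self.convs:
            out.extend(c.params)
        return out

    def n_parameters(self):
        return sum(p.size for p, _ in self.parameters())

    def state_dict(self):
        d = {}
        for i, c in enumerate(self.convs):
            d[f"W{i}"] = c.W.copy()
            d[f"b{i}"] = c.b.copy()
        return d

    def load_state_dict(self, d):
        for i, c in enumerate(self.convs):
            c.W[...] = d[f"W{i}"]
            c.b[...] = d[f"b{i}"]


class Adam:
    """ADAM over a list of (param, grad) array pairs (updates in place)."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
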