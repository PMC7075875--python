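"""Minimal CPU convolutional-network core used by the adversarial corrector.

Implements exactly the pieces the corrector needs — 3x3 convolutions and
transposed convolutions (stride 1 or 2, "same" padding), leaky ReLU,
sigmoid, a global-average-pool + affine head, and the Adam and RMSProp
optimisers — with explicit forward/backward passes in float32.  Arrays are
laid out (batch, channels, height, width); convolutions are evaluated as
im2col matrix products so the heavy lifting stays inside BLAS.

Every layer caches what its backward pass needs; ``backward`` both
accumulates parameter gradients on the layer (``gW``, ``gb``) and returns
the gradient with respect to the layer input, so networks compose by
chaining calls.  All gradients are exact and are verified against finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


# ---------------------------------------------------------------------------
# im2col plumbing


def _im2col(xp: np.ndarray, k: int, stride: int):
    """Extract k x k windows at stride spacing from a padded (B,C,Hp,Wp) array.

    Returns (cols, h_out, w_out) with cols of shape (B*h_out*w_out, C*k*k).
    """
    b, c, hp, wp = xp.shape
    view = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    h_out, w_out = view.shape[2], view.shape[3]
    cols = view.transpose(0, 2, 3, 1, 4, 5).reshape(b * h_out * w_out, c * k * k)
    return np.ascontiguousarray(cols), h_out, w_out


def _col2im(cols: np.ndarray, b: int, c: int, hp: int, wp: int,
            h_out: int, w_out: int, k: int, stride: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add window columns back."""
    arr = cols.reshape(b, h_out, w_out, c, k, k).transpose(4, 5, 0, 3, 1, 2)
    xp = np.zeros((b, c, hp, wp), dtype=cols.dtype)
    for ki in range(k):
        for kj in range(k):
            xp[:, :, ki:ki + stride * h_out:stride,
               kj:kj + stride * w_out:stride] += arr[ki, kj]
    return xp


def he_normal(rng: np.random.Generator, shape, fan_in: int, scale: float = 1.0):
    return (rng.standard_normal(shape) * scale * np.sqrt(2.0 / fan_in)).astype(F32)


# ---------------------------------------------------------------------------
# Layers


class Conv2d:
    """3x3 convolution, zero 'same' padding, stride 1 or 2."""

    param_names = ("W", "b")

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 k: int = 3, stride: int = 1, weight_scale: float = 1.0):
        self.in_ch, self.out_ch, self.k, self.stride = in_ch, out_ch, k, stride
        self.pad = k // 2
        self.W = he_normal(rng, (out_ch, in_ch * k * k), in_ch * k * k, weight_scale)
        self.b = np.zeros(out_ch, dtype=F32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols, ho, wo = _im2col(xp, self.k, self.stride)
        out = cols @ self.W.T + self.b
        self._cache = (cols, (b, c, h, w), ho, wo)
        return out.reshape(b, ho, wo, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, g: np.ndarray) -> np.ndarray:
        cols, (b, c, h, w), ho, wo = self._cache
        p = self.pad
        gm = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, self.out_ch)
        self.gW = gm.T @ cols
        self.gb = gm.sum(axis=0)
        dcols = gm @ self.W
        dxp = _col2im(dcols, b, c, h + 2 * p, w + 2 * p, ho, wo, self.k, self.stride)
        return dxp[:, :, p:p + h, p:p + w]


class ConvTranspose2d:
    """3x3 transposed convolution; stride 2 doubles the spatial size."""

    param_names = ("W", "b")

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 k: int = 3, stride: int = 1, weight_scale: float = 1.0):
        self.in_ch, self.out_ch, self.k, self.stride = in_ch, out_ch, k, stride
        self.pad = k // 2
        self.W = he_normal(rng, (in_ch, out_ch * k * k), in_ch * k * k, weight_scale)
        self.b = np.zeros(out_ch, dtype=F32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        s, k, p = self.stride, self.k, self.pad
        h2, w2 = h * s, w * s
        xm = np.ascontiguousarray(x.transpose(0, 2, 3, 1)).reshape(-1, self.in_ch)
        cols = xm @ self.W  # (B*H*W, out_ch*k*k)
        out_pad = _col2im(cols, b, self.out_ch, h2 + 2 * p, w2 + 2 * p, h, w, k, s)
        out = out_pad[:, :, p:p + h2, p:p + w2] + self.b[None, :, None, None]
        self._cache = (xm, (b, h, w))
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        xm, (b, h, w) = self._cache
        s, k, p = self.stride, self.k, self.pad
        gp = np.pad(g, ((0, 0), (0, 0), (p, p), (p, p)))
        gcols, ho, wo = _im2col(gp, k, s)  # ho == h, wo == w
        self.gW = xm.T @ gcols
        self.gb = g.sum(axis=(0, 2, 3))
        dxm = gcols @ self.W.T
        return dxm.reshape(b, h, w, self.in_ch).transpose(0, 3, 1, 2)


class LeakyReLU:
    param_names = ()

    def __init__(self, slope: float = 0.2):
        self.slope = slope
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return np.where(self._mask, g, self.slope * g)


class Sigmoid:
    """Logistic activation; optional output clamping for stable log-losses."""

    param_names = ()

    def __init__(self, clamp_eps: float = 0.0):
        self.clamp_eps = clamp_eps
        self._y = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = 1.0 / (1.0 + np.exp(-x.astype(np.float64)))
        if self.clamp_eps:
            y = np.clip(y, self.clamp_eps, 1.0 - self.clamp_eps)
        self._y = y.astype(x.dtype)
        return self._y

    def backward(self, g: np.ndarray) -> np.ndarray:
        y = self._y
        return g * y * (1.0 - y)


class GlobalAvgPool:
    param_names = ()

    def __init__(self):
        self._hw = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._hw = x.shape[2:]
        return x.mean(axis=(2, 3))

    def backward(self, g: np.ndarray) -> np.ndarray:
        h, w = self._hw
        return np.broadcast_to(g[:, :, None, None] / (h * w),
                               g.shape + (h, w)).astype(g.dtype).copy()


class Dense:
    param_names = ("W", "b")

    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator):
        self.W = he_normal(rng, (out_f, in_f), in_f)
        self.b = np.zeros(out_f, dtype=F32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.gW = g.T @ self._x
        self.gb = g.sum(axis=0)
        return g @ self.W


# ---------------------------------------------------------------------------
# Blocks


class EncoderBlock:
    """Five convolutions; the first downsamples (stride 2), the middle layer
    halves the feature count, and a residual connection links the output of
    the first layer to the output of the last."""

    def __init__(self, in_ch: int, n: int, rng: np.random.Generator):
        mid = max(n // 2, 1)
        self.c1 = Conv2d(in_ch, n, rng, stride=2)
        self.c2 = Conv2d(n, n, rng)
        self.c3 = Conv2d(n, mid, rng)
        self.c4 = Conv2d(mid, n, rng)
        self.c5 = Conv2d(n, n, rng)
        self.a1, self.a2, self.a3, self.a4, self.a5 = (LeakyReLU() for _ in range(5))

    def layers(self):
        return [self.c1, self.c2, self.c3, self.c4, self.c5]

    def forward(self, x):
        h1 = self.a1.forward(self.c1.forward(x))
        h = self.a2.forward(self.c2.forward(h1))
        h = self.a3.forward(self.c3.forward(h))
        h = self.a4.forward(self.c4.forward(h))
        return self.a5.forward(self.c5.forward(h) + h1)

    def backward(self, g):
        g = self.a5.backward(g)
        g_res = g  # residual branch straight to h1
        g = self.c5.backward(g)
        g = self.a4.backward(g)
        g = self.c4.backward(g)
        g = self.a3.backward(g)
        g = self.c3.backward(g)
        g = self.a2.backward(g)
        g = self.c2.backward(g)
        g = self.a1.backward(g + g_res)
        return self.c1.backward(g)


class DecoderBlock:
    """Mirror of the encoder block with transposed convolutions: stride 1
    everywhere except the last layer, which upsamples by 2.  The residual
    connection links the first layer to the last stride-1 layer (the
    upsampling layer changes the spatial size, so the shortcut ends just
    before it)."""

    def __init__(self, in_ch: int, n: int, out_ch: int, rng: np.random.Generator):
        mid = max(n // 2, 1)
        self.t1 = ConvTranspose2d(in_ch, n, rng)
        self.t2 = ConvTranspose2d(n, n, rng)
        self.t3 = ConvTranspose2d(n, mid, rng)
        self.t4 = ConvTranspose2d(mid, n, rng)
        self.t5 = ConvTranspose2d(n, out_ch, rng, stride=2)
        self.a1, self.a2, self.a3, self.a4, self.a5 = (LeakyReLU() for _ in range(5))

    def layers(self):
        return [self.t1, self.t2, self.t3, self.t4, self.t5]

    def forward(self, x):
        h1 = self.a1.forward(self.t1.forward(x))
        h = self.a2.forward(self.t2.forward(h1))
        h = self.a3.forward(self.t3.forward(h))
        h4 = self.a4.forward(self.t4.forward(h) + h1)
        return self.a5.forward(self.t5.forward(h4))

    def backward(self, g):
        g = self.a5.backward(g)
        g = self.t5.backward(g)
        g = self.a4.backward(g)
        g_res = g
        g = self.t4.backward(g)
        g = self.a3.backward(g)
        g = self.t3.backward(g)
        g = self.a2.backward(g)
        g = self.t2.backward(g)
        g = self.a1.backward(g + g_res)
        return self.t1.backward(g)


# ---------------------------------------------------------------------------
# Networks


class _Network:
    """Parameter bookkeeping shared by the generator and discriminator."""

    def layers(self):  # pragma: no cover - overridden
        raise NotImplementedError

    def parameters(self):
        out = []
        for layer in self.layers():
            for name in layer.param_names:
                out.append((layer, name))
        return out

    def n_parameters(self) -> int:
        return sum(getattr(layer, name).size for layer, name in self.parameters())

    def state_list(self):
        return [getattr(layer, name).copy() for layer, name in self.parameters()]

    def load_state_list(self, arrays):
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(arrays)}")
        for (layer, name), arr in zip(params, arrays):
            current = getattr(layer, name)
            if current.shape != arr.shape:
                raise ValueError(f"shape mismatch for {name}: "
                                 f"{current.shape} vs {arr.shape}")
            setattr(layer, name, arr.astype(current.dtype).copy())


class UNetGenerator(_Network):
    """Hourglass encoder-decoder with symmetric skip connections.

    Encoder block i produces ``base_features * 2**i`` channels at resolution
    N / 2**(i+1); decoder blocks mirror the encoder, consuming the
    concatenation of the deeper decoder output with the same-resolution
    encoder skip.  A final 3x3 convolution maps back to one channel that is
    added to the network input (a global identity shortcut: the network
    predicts an additive artifact residual), and the sum is clipped to
    [0, 1].  The shortcut makes the identity mapping trivially
    representable, so short training runs start from input quality instead
    of having to relearn the image from scratch.
    """

    def __init__(self, n_blocks: int, base_features: int, input_size: int,
                 rng: np.random.Generator):
        if input_size % (2 ** n_blocks) != 0:
            raise ValueError(f"input_size {input_size} not divisible by "
                             f"2^{n_blocks}")
        self.n_blocks = n_blocks
        self.base_features = base_features
        self.input_size = input_size
        feats = [base_features * 2 ** i for i in range(n_blocks)]
        self.feats = feats
        self.enc = []
        for i in range(n_blocks):
            in_ch = 1 if i == 0 else feats[i - 1]
            self.enc.append(EncoderBlock(in_ch, feats[i], rng))
        self.dec = []
        for i in range(n_blocks - 1, -1, -1):
            in_ch = feats[i] if i == n_blocks - 1 else 2 * feats[i]
            out_ch = feats[i - 1] if i > 0 else feats[0]
            self.dec.append(DecoderBlock(in_ch, feats[i], out_ch, rng))
        self.final = Conv2d(feats[0], 1, rng, weight_scale=0.1)
        self._clip_mask = None

    def layers(self):
        out = []
        for blk in self.enc + self.dec:
            out.extend(blk.layers())
        out.append(self.final)
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 4 or x.shape[2] != self.input_size or x.shape[3] != self.input_size:
            raise ValueError(f"expected (B, 1, {self.input_size}, "
                             f"{self.input_size}) input, got {x.shape}")
        skips = []
        h = x.astype(F32, copy=False)
        for blk in self.enc:
            h = blk.forward(h)
            skips.append(h)
        b = self.n_blocks
        h = self.dec[0].forward(skips[b - 1])
        for j in range(1, b):
            level = b - 1 - j
            h = self.dec[j].forward(np.concatenate([h, skips[level]], axis=1))
        y = x + self.final.forward(h)
        self._clip_mask = (y > 0.0) & (y < 1.0)
        return np.clip(y, 0.0, 1.0)

    def backward(self, g: np.ndarray) -> np.ndarray:
        b = self.n_blocks
        g = np.where(self._clip_mask, g, 0.0).astype(F32)
        g_skip_in = g  # global identity shortcut straight to the input
        g = self.final.backward(g)
        skip_grads = [None] * b
        for j in range(b - 1, 0, -1):
            level = b - 1 - j
            gin = self.dec[j].backward(g)
            half = self.feats[level]
            g = gin[:, :half]
            skip_grads[level] = gin[:, half:]
        g_enc = self.dec[0].backward(g)  # grad wrt skips[b-1]
        for i in range(b - 1, -1, -1):
            total = g_enc if skip_grads[i] is None else g_enc + skip_grads[i]
            g_enc = self.enc[i].backward(total)
        return g_enc + g_skip_in

    def __call__(self, x):
        return self.forward(x)


class Discriminator(_Network):
    """Encoder stack identical to the generator's, followed by a global
    average pool and a single sigmoid unit giving P(real)."""

    def __init__(self, n_blocks: int, base_features: int, input_size: int,
                 rng: np.random.Generator, clamp_eps: float = 1e-7):
        if input_size % (2 ** n_blocks) != 0:
            raise ValueError(f"input_size {input_size} not divisible by "
                             f"2^{n_blocks}")
        self.n_blocks = n_blocks
        self.base_features = base_features
        self.input_size = input_size
        feats = [base_features * 2 ** i for i in range(n_blocks)]
        self.enc = []
        for i in range(n_blocks):
            in_ch = 1 if i == 0 else feats[i - 1]
            self.enc.append(EncoderBlock(in_ch, feats[i], rng))
        self.pool = GlobalAvgPool()
        self.head = Dense(feats[-1], 1, rng)
        self.out_act = Sigmoid(clamp_eps=clamp_eps)

    def layers(self):
        out = []
        for blk in self.enc:
            out.extend(blk.layers())
        out.append(self.head)
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = x.astype(F32, copy=False)
        for blk in self.enc:
            h = blk.forward(h)
        h = self.pool.forward(h)
        return self.out_act.forward(self.head.forward(h))[:, 0]

    def backward(self, g: np.ndarray) -> np.ndarray:
        g = self.out_act.backward(g[:, None])
        g = self.head.backward(g)
        g = self.pool.backward(g)
        for blk in reversed(self.enc):
            g = blk.backward(g)
        return g

    def __call__(self, x):
        return self.forward(x)


# ---------------------------------------------------------------------------
# Optimisers


class _Optimizer:
    def __init__(self, network: _Network, lr: float):
        self.params = network.parameters()
        self.lr = lr

    def step(self):  # pragma: no cover - overridden
        raise NotImplementedError


class Adam(_Optimizer):
    def __init__(self, network, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        super().__init__(network, lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(getattr(l, n)) for l, n in self.params]
        self.v = [np.zeros_like(getattr(l, n)) for l, n in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1 ** self.t
        corr2 = 1.0 - b2 ** self.t
        for i, (layer, name) in enumerate(self.params):
            g = getattr(layer, "g" + name)
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            update = (self.lr * (self.m[i] / corr1)
                      / (np.sqrt(self.v[i] / corr2) + self.eps))
            setattr(layer, name, (getattr(layer, name) - update).astype(F32))


class RMSProp(_Optimizer):
    def __init__(self, network, lr=1e-4, alpha=0.9, eps=1e-8):
        super().__init__(network, lr)
        self.alpha, self.eps = alpha, eps
        self.sq = [np.zeros_like(getattr(l, n)) for l, n in self.params]

    def step(self):
        a = self.alpha
        for i, (layer, name) in enumerate(self.params):
            g = getattr(layer, "g" + name)
            self.sq[i] = a * self.sq[i] + (1 - a) * g * g
            update = self.lr * g / (np.sqrt(self.sq[i]) + self.eps)
            setattr(layer, name, (getattr(layer, name) - update).astype(F32))
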