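"""Temporal convolutional encoder-decoder network (TCED-Net).

A 1-D U-Net-style encoder-decoder built from dilated *causal* convolutions:
the output at time t only reads inputs at t, t-d, ..., t-(k-1)d, i.e.

    y(n) = sum_{i=0}^{k-1} f(i) * x(n - d*i)

implemented by left-only zero padding of (k-1)*d samples.  Each level is a
residual temporal block (two stacked [dilated conv -> batch norm -> SELU ->
spatial dropout] layers plus a 1x1-projected residual), average pooling
(stride 2) downsamples between encoder levels, transposed convolutions
(kernel 2, stride 2) upsample in the decoder, and mirrored encoder feature
maps are concatenated in via skip connections.  A final 1x1 convolution
maps the first-level feature count to the output channels.

Everything here — forward pass, analytic backpropagation and the Adam
optimizer — is implemented directly on numpy arrays.  The network is fit
*online* on a single record (batch of one whole signal), so normalization
always uses current-record statistics; only dropout distinguishes training
from evaluation mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SELU_ALPHA = 1.6732632423543772
SELU_SCALE = 1.0507009873554805


@dataclass
class TCEDConfig:
    """Architecture and optimizer hyperparameters.

    Defaults follow the full-scale configuration: six levels with feature
    channels doubling 16..512, dilation rates [1,2,4,8,16,16], kernel 5,
    causal padding (k-1)*d, pooling/upsampling stride 2, Adam at 1e-3.
    """

    feature_channels: list = field(default_factory=lambda: [16, 32, 64, 128, 256, 512])
    dilation_rates: list = field(default_factory=lambda: [1, 2, 4, 8, 16, 16])
    kernel_size: int = 5
    conv_stride: int = 1
    resample_stride: int = 2
    dropout_rate: float = 0.1
    learning_rate: float = 1e-3
    input_length: int = 60000
    dtype: str = "float64"

    def __post_init__(self):
        if len(self.feature_channels) != len(self.dilation_rates):
            raise ValueError("feature_channels and dilation_rates must have equal length")
        if self.kernel_size < 2:
            raise ValueError("kernel_size must be >= 2")
        if self.conv_stride != 1 or self.resample_stride != 2:
            raise ValueError("only conv_stride=1, resample_stride=2 are supported")

    @property
    def n_levels(self) -> int:
        return len(self.feature_channels)

    @property
    def length_multiple(self) -> int:
        return 2 ** (self.n_levels - 1)

    @classmethod
    def reduced(cls, **kw) -> "TCEDConfig":
        """Desk-scale three-level variant for short records and CPU runs."""
        kw.setdefault("feature_channels", [8, 16, 32])
        kw.setdefault("dilation_rates", [1, 2, 4])
        return cls(**kw)


# ---------------------------------------------------------------------------
# functional reference op
# ---------------------------------------------------------------------------

def dilated_causal_conv(x: np.ndarray, kernel: np.ndarray, d: int) -> np.ndarray:
    """Multichannel dilated causal convolution (no bias).

    x : (C_in, N), kernel : (C_out, C_in, k), d >= 1.  Output (C_out, N);
    position n reads x at n, n-d, ..., n-(k-1)d with zeros off the left edge.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    kernel = np.asarray(kernel, dtype=float)
    if kernel.ndim == 1:
        kernel = kernel[None, None, :]
    if d < 1:
        raise ValueError("dilation must be >= 1")
    c_out, c_in, k = kernel.shape
    n = x.shape[1]
    y = np.zeros((c_out, n))
    for i in range(k):
        s = i * d
        if s < n:
            y[:, s:] += kernel[:, :, i] @ x[:, : n - s]
    return y


# ---------------------------------------------------------------------------
# layers (forward + analytic backward)
# ---------------------------------------------------------------------------

class Parameter:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)


class _Layer:
    def parameters(self):
        return []


class CausalConv1d(_Layer):
    """Dilated causal convolution with bias; left-pad (k-1)*d zeros."""

    def __init__(self, c_in, c_out, k, d, rng, dtype=np.float64):
        std = 1.0 / np.sqrt(c_in * k)  # LeCun normal, variance-preserving for SELU
        self.W = Parameter(rng.normal(0.0, std, size=(c_out, c_in, k)).astype(dtype))
        self.b = Parameter(np.zeros(c_out, dtype=dtype))
        self.k, self.d = k, d
        self._cache = None

    def parameters(self):
        return [self.W, self.b]

    def _stack(self, x):
        c_in, n = x.shape
        xs = np.zeros((self.k, c_in, n), dtype=x.dtype)
        for i in range(self.k):
            s = i * self.d
            if s < n:
                xs[i, :, s:] = x[:, : n - s]
        return xs.reshape(self.k * c_in, n)

    def forward(self, x):
        xs = self._stack(x)
        c_out = self.W.value.shape[0]
        wmat = self.W.value.transpose(0, 2, 1).reshape(c_out, -1)
        self._cache = (xs, x.shape)
        return wmat @ xs + self.b.value[:, None]

    def backward(self, dy):
        xs, (c_in, n) = self._cache
        c_out = self.W.value.shape[0]
        dwmat = dy @ xs.T
        self.W.grad += dwmat.reshape(c_out, self.k, c_in).transpose(0, 2, 1)
        self.b.grad += dy.sum(axis=1)
        wmat = self.W.value.transpose(0, 2, 1).reshape(c_out, -1)
        dxs = (wmat.T @ dy).reshape(self.k, c_in, n)
        dx = np.zeros((c_in, n), dtype=dy.dtype)
        for i in range(self.k):
            s = i * self.d
            if s < n:
                dx[:, : n - s] += dxs[i, :, s:]
        return dx


class BatchNorm1d(_Layer):
    """Per-channel normalization over the time axis (batch of one record)."""

    def __init__(self, c, eps=1e-5, dtype=np.float64):
        self.gamma = Parameter(np.ones(c, dtype=dtype))
        self.beta = Parameter(np.zeros(c, dtype=dtype))
        self.eps = eps
        self._cache = None

    def parameters(self):
        return [self.gamma, self.beta]

    def forward(self, x):
        mu = x.mean(axis=1, keepdims=True)
        var = x.var(axis=1, keepdims=True)
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * ivar
        self._cache = (xhat, ivar)
        return self.gamma.value[:, None] * xhat + self.beta.value[:, None]

    def backward(self, dy):
        xhat, ivar = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=1)
        self.beta.grad += dy.sum(axis=1)
        dxhat = dy * self.gamma.value[:, None]
        m1 = dxhat.mean(axis=1, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=1, keepdims=True)
        return ivar * (dxhat - m1 - xhat * m2)


class SELU(_Layer):
    def forward(self, x):
        self._x = x
        return SELU_SCALE * np.where(x > 0, x, SELU_ALPHA * np.expm1(x))

    def backward(self, dy):
        x = self._x
        return dy * SELU_SCALE * np.where(x > 0, 1.0, SELU_ALPHA * np.exp(np.minimum(x, 0.0)))


class SpatialDropout(_Layer):
    """Drops whole feature channels; identity in evaluation mode."""

    def __init__(self, rate):
        self.rate = rate
        self._mask = None

    def forward(self, x, train, rng):
        if train and self.rate > 0:
            keep = (rng.random(x.shape[0]) >= self.rate) / (1.0 - self.rate)
            self._mask = keep[:, None].astype(x.dtype)
            return x * self._mask
        self._mask = None
        return x

    def backward(self, dy):
        return dy * self._mask if self._mask is not None else dy


class AvgPool2(_Layer):
    def forward(self, x):
        if x.shape[1] % 2:
            raise ValueError("pooling requires even length")
        self._n = x.shape[1]
        return 0.5 * (x[:, 0::2] + x[:, 1::2])

    def backward(self, dy):
        dx = np.empty((dy.shape[0], self._n), dtype=dy.dtype)
        dx[:, 0::2] = 0.5 * dy
        dx[:, 1::2] = 0.5 * dy
        return dx


class UpConv2(_Layer):
    """Transposed convolution, kernel 2 stride 2: exact length doubling."""

    def __init__(self, c_in, c_out, rng, dtype=np.float64):
        std = 1.0 / np.sqrt(c_in * 2)
        self.W = Parameter(rng.normal(0.0, std, size=(2, c_out, c_in)).astype(dtype))
        self.b = Parameter(np.zeros(c_out, dtype=dtype))
        self._x = None

    def parameters(self):
        return [self.W, self.b]

    def forward(self, x):
        self._x = x
        c_out = self.W.value.shape[1]
        y = np.empty((c_out, 2 * x.shape[1]), dtype=x.dtype)
        y[:, 0::2] = self.W.value[0] @ x
        y[:, 1::2] = self.W.value[1] @ x
        return y + self.b.value[:, None]

    def backward(self, dy):
        x = self._x
        d0, d1 = dy[:, 0::2], dy[:, 1::2]
        self.W.grad[0] += d0 @ x.T
        self.W.grad[1] += d1 @ x.T
        self.b.grad += dy.sum(axis=1)
        return self.W.value[0].T @ d0 + self.W.value[1].T @ d1


class TemporalBlock(_Layer):
    """Residual block: 2x [dilated causal conv -> BN -> SELU -> spatial
    dropout], plus the input through a 1x1 conv when channel counts differ."""

    def __init__(self, c_in, c_out, k, d, dropout, rng, dtype=np.float64):
        self.conv1 = CausalConv1d(c_in, c_out, k, d, rng, dtype)
        self.bn1 = BatchNorm1d(c_out, dtype=dtype)
        self.act1 = SELU()
        self.drop1 = SpatialDropout(dropout)
        self.conv2 = CausalConv1d(c_out, c_out, k, d, rng, dtype)
        self.bn2 = BatchNorm1d(c_out, dtype=dtype)
        self.act2 = SELU()
        self.drop2 = SpatialDropout(dropout)
        self.res = CausalConv1d(c_in, c_out, 1, 1, rng, dtype) if c_in != c_out else None

    def parameters(self):
        ps = (self.conv1.parameters() + self.bn1.parameters()
              + self.conv2.parameters() + self.bn2.parameters())
        if self.res is not None:
            ps += self.res.parameters()
        return ps

    def forward(self, x, train=False, rng=None):
        rng = rng or np.random.default_rng(0)
        h = self.drop1.forward(self.act1.forward(self.bn1.forward(self.conv1.forward(x))),
                               train, rng)
        h = self.drop2.forward(self.act2.forward(self.bn2.forward(self.conv2.forward(h))),
                               train, rng)
        r = self.res.forward(x) if self.res is not None else x
        return h + r

    def backward(self, dy):
        dh = self.conv2.backward(self.bn2.backward(self.act2.backward(self.drop2.backward(dy))))
        dx = self.conv1.backward(self.bn1.backward(self.act1.backward(self.drop1.backward(dh))))
        dx = dx + (self.res.backward(dy) if self.res is not None else dy)
        return dx


# ---------------------------------------------------------------------------
# the full network
# ---------------------------------------------------------------------------

class TCEDNet:
    """Encoder-decoder with skip connections; fixed topology per config."""

    def __init__(self, config: TCEDConfig, c_in: int = 1, c_out: int = 1, seed: int = 0):
        self.config = config
        self.c_in, self.c_out = c_in, c_out
        self.dtype = np.dtype(config.dtype)
        rng = np.random.default_rng(seed)
        ch = config.feature_channels
        dil = config.dilation_rates
        k, p = config.kernel_size, config.dropout_rate
        dt = self.dtype
        L = config.n_levels

        self.enc = []
        prev = c_in
        for i in range(L):
            self.enc.append(TemporalBlock(prev, ch[i], k, dil[i], p, rng, dt))
            prev = ch[i]
        self.pools = [AvgPool2() for _ in range(L - 1)]
        self.ups, self.dec = [], []
        for i in range(L - 2, -1, -1):
            self.ups.append(UpConv2(ch[i + 1], ch[i], rng, dt))
            self.dec.append(TemporalBlock(2 * ch[i], ch[i], k, dil[i], p, rng, dt))
        self.head = CausalConv1d(ch[0], c_out, 1, 1, rng, dt)

    # -- parameter plumbing -------------------------------------------------
    def _layers(self):
        return self.enc + self.ups + self.dec + [self.head]

    def parameters(self):
        out = []
        for layer in self._layers():
            out.extend(layer.parameters())
        return out

    def named_parameters(self):
        names = []
        for i, blk in enumerate(self.enc):
            names.append((f"enc{i}", blk))
        for i, up in enumerate(self.ups):
            names.append((f"up{i}", up))
        for i, blk in enumerate(self.dec):
            names.append((f"dec{i}", blk))
        names.append(("head", self.head))
        out = []
        for name, layer in names:
            for j, p in enumerate(layer.parameters()):
                out.append((f"{name}.p{j}", p))
        return out

    def state_dict(self) -> dict:
        return {name: p.value.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, sd: dict) -> None:
        for name, p in self.named_parameters():
            p.value[...] = sd[name]

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        """x : (c_in, N) with N a multiple of 2**(levels-1). Output (c_out, N)."""
        x = np.atleast_2d(np.asarray(x, dtype=self.dtype))
        L = self.config.n_levels
        mult = self.config.length_multiple
        if x.shape[1] < mult:
            raise ValueError(f"input of {x.shape[1]} samples shorter than {mult}")
        if x.shape[1] % mult:
            raise ValueError(f"input length must be a multiple of {mult}; use pad_signal")
        rng = rng or np.random.default_rng(0)
        skips = []
        h = x
        for i in range(L):
            h = self.enc[i].forward(h, train, rng)
            if i < L - 1:
                skips.append(h)
                h = self.pools[i].forward(h)
        self._split = []
        for j in range(L - 1):
            up = self.ups[j].forward(h)
            skip = skips[-(j + 1)]
            self._split.append(skip.shape[0])
            h = self.dec[j].forward(np.concatenate([skip, up], axis=0), train, rng)
        return self.head.forward(h)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        L = self.config.n_levels
        dh = self.head.backward(dy)
        dskips = [None] * (L - 1)
        for j in range(L - 2, -1, -1):
            dcat = self.dec[j].backward(dh)
            c_skip = self._split[j]
            dskips[L - 2 - j] = dcat[:c_skip]
            dh = self.ups[j].backward(dcat[c_skip:])
        for i in range(L - 1, -1, -1):
            if i < L - 1:
                dh = self.pools[i].backward(dh)
                dh = dh + dskips[i]
            dh = self.enc[i].backward(dh)
        return dh

    def zero_grad(self):
        for p in self.parameters():
            p.grad[...] = 0.0


def init_network(config: TCEDConfig, c_in: int = 1, c_out: int = 1, seed: int = 0) -> TCEDNet:
    """Reproducible (seeded) LeCun-normal initialization, zero biases."""
    return TCEDNet(config, c_in=c_in, c_out=c_out, seed=seed)


def save_weights(net: TCEDNet, path) -> None:
    """Checkpoint the weights as an .npz keyed by layer name."""
    np.savez(path, **net.state_dict())


def load_weights(net: TCEDNet, path) -> TCEDNet:
    with np.load(path) as data:
        net.load_state_dict({k: data[k] for k in data.files})
    return net


def tced_forward(x: np.ndarray, net: TCEDNet, train_mode: bool = False, rng=None) -> np.ndarray:
    return net.forward(x, train=train_mode, rng=rng)


def pad_signal(x: np.ndarray, multiple: int) -> tuple:
    """Right-pad with zeros to a length multiple; returns (padded, original_n)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = x.shape[1]
    rem = (-n) % multiple
    if rem:
        x = np.pad(x, ((0, 0), (0, rem)))
    return x, n


class Adam:
    """Standard Adam (beta1=0.9, beta2=0.999) over a parameter list."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
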