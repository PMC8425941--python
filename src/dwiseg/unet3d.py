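"""Volumetric U-Net: construction, census, parameter count, width search.

The network is the classic encoder-decoder with skip concatenations:
``levels`` resolution stages (the deepest being the bottleneck), 3x3x3
"same" convolutions, 2x2x2 max-pooling on the way down, 2x2x2 transposed
convolutions on the way up, and a per-voxel probability head (sigmoid for a
1-channel head, channel softmax for a 2-channel head).  Forward pass,
backpropagation, and parameter handling are implemented directly on NumPy
arrays, so the package is self-contained and every gradient is explicit.

Two published facts pin the architecture down only partially: the layer
census (21 3x3x3 convolutions, four 2x2x2 poolings, four transposed
convolutions, four concatenations) and the total of 6,832,321 trainable
parameters.  The per-level channel widths are not published, so
:func:`find_width_config` searches a documented configuration family for a
width ladder whose closed-form parameter count hits the target exactly.
Note the parity argument: with bias terms, a convolution contributes
``c_out * (k^3 c_in + 1)`` parameters, which is even whenever ``c_out`` is
even — an odd printed total therefore forces a single-channel output head.

Tensors are channels-first ``(C, X, Y, Z)``; a volume enters as a single
channel.  All spatial shapes must be divisible by ``2**(levels-1)``.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict, replace
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .volume_io import ShapeError

__all__ = [
    "UNetConfig",
    "LayerCensus",
    "UNet3D",
    "NoExactMatchError",
    "WidthSearchSpace",
    "build_unet",
    "layer_census",
    "count_parameters",
    "closed_form_param_count",
    "feature_map_shape",
    "find_width_config",
]

_ACTIVATIONS = ("relu", "leaky_relu", "linear")

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UNetConfig:
    """Full architectural parameterization of the volumetric U-Net.

    ``decoder_extra_convs`` lists the decoder levels (0 = finest) that
    receive a third convolution after the skip concatenation; the default
    (``None``) places, for a 5-level net, the two extra convolutions after
    the first two concatenations in decoding order — which together with
    the 3x3x3 head yields the published 21-convolution census — and no
    extra convolutions for shallower nets.
    """

    levels: int = 5
    widths: tuple[int, ...] = (16, 32, 64, 128, 256)
    convs_per_block: int = 2
    decoder_extra_convs: tuple[int, ...] | None = None
    conv_kernel: tuple[int, int, int] = (3, 3, 3)
    pool_kernel: tuple[int, int, int] = (2, 2, 2)
    transpose_kernel: tuple[int, int, int] = (2, 2, 2)
    transpose_mode: str = "halve"  # 'halve': up to skip width; 'keep': same
    out_channels: int = 1
    head_kernel: tuple[int, int, int] = (3, 3, 3)
    use_bias: bool = True
    use_norm: bool = False
    activation: str = "relu"

    def __post_init__(self):
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if len(self.widths) != self.levels:
            raise ValueError(
                f"widths has {len(self.widths)} entries for {self.levels} levels"
            )
        if any(w < 1 for w in self.widths):
            raise ValueError(f"widths must be positive: {self.widths}")
        if self.out_channels not in (1, 2):
            raise ValueError("out_channels must be 1 or 2")
        if self.convs_per_block < 1:
            raise ValueError("convs_per_block must be >= 1")
        if self.transpose_mode not in ("halve", "keep"):
            raise ValueError("transpose_mode must be 'halve' or 'keep'")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"activation must be one of {_ACTIVATIONS}")
        if self.decoder_extra_convs is None:
            default = (self.levels - 2, self.levels - 3) if self.levels >= 5 else ()
            object.__setattr__(self, "decoder_extra_convs", default)
        bad = [l for l in self.decoder_extra_convs
               if not 0 <= l < self.levels - 1]
        if bad or len(set(self.decoder_extra_convs)) != len(
            self.decoder_extra_convs
        ):
            raise ValueError(
                "decoder_extra_convs must be distinct decoder levels in "
                f"[0, {self.levels - 2}]: {self.decoder_extra_convs}"
            )

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, source) -> "UNetConfig":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            d = json.loads(source)
        else:
            with open(source) as fh:
                d = json.load(fh)
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown UNetConfig keys: {sorted(unknown)}")
        for k in ("widths", "decoder_extra_convs", "conv_kernel",
                  "pool_kernel", "transpose_kernel", "head_kernel"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass(frozen=True)
class LayerCensus:
    """Counts of the graph operations the architecture description fixes."""

    n_conv3: int  # 3x3x3 convolutions (head included if 3x3x3)
    n_pool: int
    n_transpose: int
    n_concat: int

    def __post_init__(self):
        if min(self.n_conv3, self.n_pool, self.n_transpose, self.n_concat) < 0:
            raise ValueError("census counts must be non-negative")


# ---------------------------------------------------------------------------
# primitive layers (forward + explicit backward)
# ---------------------------------------------------------------------------


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


_CHUNK_ELEMS = 3_000_000  # im2col buffer budget (elements) per slab


def _conv3_same(x, W, b=None, out_dtype=np.float32):
    """'Same'-padded stride-1 3x3x3 convolution, slab-chunked along X."""
    cin, X, Y, Z = x.shape
    cout = W.shape[0]
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
    out = np.empty((cout, X, Y, Z), dtype=out_dtype)
    step = max(1, _CHUNK_ELEMS // max(1, cin * 27 * Y * Z))
    for x0 in range(0, X, step):
        x1 = min(X, x0 + step)
        win = sliding_window_view(
            xp[:, x0:x1 + 2], (3, 3, 3), axis=(1, 2, 3)
        )  # (cin, x1-x0, Y, Z, 3,3,3)
        o = np.tensordot(win, W, axes=([0, 4, 5, 6], [1, 2, 3, 4]))
        out[:, x0:x1] = np.moveaxis(o, -1, 0)
    if b is not None:
        out += b[:, None, None, None]
    return out


def _conv3_grad_w(x, gout):
    """Weight gradient of the same-padded 3x3x3 convolution."""
    cin, X, Y, Z = x.shape
    cout = gout.shape[0]
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
    gW = np.zeros((cout, cin, 3, 3, 3), dtype=np.float32)
    step = max(1, _CHUNK_ELEMS // max(1, cin * 27 * Y * Z))
    for x0 in range(0, X, step):
        x1 = min(X, x0 + step)
        win = sliding_window_view(
            xp[:, x0:x1 + 2], (3, 3, 3), axis=(1, 2, 3)
        )
        gW += np.tensordot(
            gout[:, x0:x1], win, axes=([1, 2, 3], [1, 2, 3])
        )
    return gW


class Conv3d:
    """3D convolution, stride 1, 'same' zero padding, kernel 3x3x3 or 1x1x1."""

    def __init__(self, cin, cout, kernel, bias, rng):
        self.cin, self.cout = cin, cout
        self.kernel = tuple(kernel)
        k3 = int(np.prod(self.kernel))
        fan_in = cin * k3
        std = np.sqrt(2.0 / fan_in)  # He fan-in, matched to ReLU blocks
        self.W = Param(rng.normal(0.0, std, (cout, cin, *self.kernel)))
        self.b = Param(np.zeros(cout)) if bias else None
        self._x = None

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def forward(self, x, train=False):
        if train:
            self._x = x
        if self.kernel == (3, 3, 3):
            b = self.b.value if self.b is not None else None
            return _conv3_same(x, self.W.value, b)
        # 1x1x1: pure channel mixing
        W1 = self.W.value.reshape(self.cout, self.cin)
        out = np.tensordot(W1, x, axes=(1, 0)).astype(np.float32)
        if self.b is not None:
            out += self.b.value[:, None, None, None]
        return out

    def backward(self, gout):
        x = self._x
        if self.kernel == (3, 3, 3):
            self.W.grad += _conv3_grad_w(x, gout)
            if self.b is not None:
                self.b.grad += gout.sum(axis=(1, 2, 3))
            Wf = np.ascontiguousarray(
                self.W.value.transpose(1, 0, 2, 3, 4)[:, :, ::-1, ::-1, ::-1]
            )
            return _conv3_same(gout, Wf)
        W1 = self.W.value.reshape(self.cout, self.cin)
        gflat = gout.reshape(self.cout, -1)
        self.W.grad += (gflat @ x.reshape(self.cin, -1).T).reshape(
            self.W.value.shape
        )
        if self.b is not None:
            self.b.grad += gout.sum(axis=(1, 2, 3))
        return np.tensordot(W1.T, gout, axes=(1, 0)).astype(np.float32)


class ConvTranspose3d:
    """2x2x2 transposed convolution with stride 2 (doubles each axis)."""

    def __init__(self, cin, cout, bias, rng):
        self.cin, self.cout = cin, cout
        self.kernel = (2, 2, 2)
        std = np.sqrt(2.0 / (cin * 8))
        self.W = Param(rng.normal(0.0, std, (cin, cout, 2, 2, 2)))
        self.b = Param(np.zeros(cout)) if bias else None
        self._x = None

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def forward(self, x, train=False):
        if train:
            self._x = x
        cin, X, Y, Z = x.shape
        t = np.tensordot(self.W.value, x, axes=([0], [0]))
        # (cout,2,2,2,X,Y,Z) -> (cout, X,2, Y,2, Z,2) -> (cout,2X,2Y,2Z)
        out = t.transpose(0, 4, 1, 5, 2, 6, 3).reshape(
            self.cout, 2 * X, 2 * Y, 2 * Z
        )
        out = np.ascontiguousarray(out, dtype=np.float32)
        if self.b is not None:
            out += self.b.value[:, None, None, None]
        return out

    def backward(self, gout):
        x = self._x
        cin, X, Y, Z = x.shape
        g6 = gout.reshape(self.cout, X, 2, Y, 2, Z, 2).transpose(
            0, 2, 4, 6, 1, 3, 5
        )  # (cout,2,2,2,X,Y,Z)
        gx = np.tensordot(
            self.W.value, g6, axes=([1, 2, 3, 4], [0, 1, 2, 3])
        ).astype(np.float32)
        self.W.grad += np.tensordot(x, g6, axes=([1, 2, 3], [4, 5, 6]))
        if self.b is not None:
            self.b.grad += gout.sum(axis=(1, 2, 3))
        return gx


class MaxPool3d:
    """2x2x2 max pooling with stride 2."""

    kernel = (2, 2, 2)

    def params(self):
        return []

    def forward(self, x, train=False):
        C, X, Y, Z = x.shape
        xr = x.reshape(C, X // 2, 2, Y // 2, 2, Z // 2, 2)
        xr = xr.transpose(0, 1, 3, 5, 2, 4, 6).reshape(
            C, X // 2, Y // 2, Z // 2, 8
        )
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx, self._shape = idx, (C, X, Y, Z)
        return np.ascontiguousarray(out)

    def backward(self, gout):
        C, X, Y, Z = self._shape
        g8 = np.zeros((C, X // 2, Y // 2, Z // 2, 8), dtype=np.float32)
        np.put_along_axis(g8, self._idx[..., None], gout[..., None], axis=-1)
        g = g8.reshape(C, X // 2, Y // 2, Z // 2, 2, 2, 2).transpose(
            0, 1, 4, 2, 5, 3, 6
        )
        return np.ascontiguousarray(g.reshape(C, X, Y, Z))


class ChannelNorm:
    """Instance normalization over spatial dims with per-channel affine."""

    eps = 1e-5

    def __init__(self, c):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        mu = x.mean(axis=(1, 2, 3), keepdims=True)
        var = x.var(axis=(1, 2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        if train:
            self._xhat, self._inv = xhat, inv
        return (
            self.gamma.value[:, None, None, None] * xhat
            + self.beta.value[:, None, None, None]
        ).astype(np.float32)

    def backward(self, gout):
        xhat, inv = self._xhat, self._inv
        n = float(np.prod(xhat.shape[1:]))
        self.gamma.grad += (gout * xhat).sum(axis=(1, 2, 3))
        self.beta.grad += gout.sum(axis=(1, 2, 3))
        gy = gout * self.gamma.value[:, None, None, None]
        mean_gy = gy.mean(axis=(1, 2, 3), keepdims=True)
        mean_gy_xhat = (gy * xhat).mean(axis=(1, 2, 3), keepdims=True)
        return ((gy - mean_gy - xhat * mean_gy_xhat) * inv).astype(np.float32)


class Activation:
    def __init__(self, kind):
        self.kind = kind

    def params(self):
        return []

    def forward(self, x, train=False):
        if self.kind == "relu":
            out = np.maximum(x, 0.0)
        elif self.kind == "leaky_relu":
            out = np.where(x > 0, x, 0.01 * x).astype(np.float32)
        else:  # linear
            out = x
        if train:
            self._x = x
        return out

    def backward(self, gout):
        if self.kind == "relu":
            return np.where(self._x > 0, gout, 0.0).astype(np.float32)
        if self.kind == "leaky_relu":
            return np.where(self._x > 0, gout, 0.01 * gout).astype(np.float32)
        return gout


class Concat:
    """Channel concatenation of the upsampled path with the skip tensor."""

    def params(self):
        return []

    def forward(self, up, skip, train=False):
        if train:
            self._split = up.shape[0]
        return np.concatenate([up, skip], axis=0)

    def backward(self, gout):
        s = self._split
        return gout[:s], gout[s:]


class _Head:
    """Probability head: sigmoid (1 channel) or channel softmax (2)."""

    def __init__(self, out_channels):
        self.out_channels = out_channels

    def params(self):
        return []

    def forward(self, z, train=False):
        if self.out_channels == 1:
            p = np.empty_like(z)
            np.negative(np.abs(z), out=p)
            np.exp(p, out=p)
            prob = np.where(z >= 0, 1.0 / (1.0 + p), p / (1.0 + p))
            prob = prob.astype(np.float32)
            if train:
                self._p = prob
            return prob  # (1, X, Y, Z)
        zs = z - z.max(axis=0, keepdims=True)
        e = np.exp(zs)
        prob = (e / e.sum(axis=0, keepdims=True)).astype(np.float32)
        if train:
            self._p = prob
        return prob  # (2, X, Y, Z); channel 1 = foreground

    def foreground(self, prob):
        return prob[0] if self.out_channels == 1 else prob[1]

    def backward(self, g_fg):
        """Map dL/d(foreground prob) to dL/d(logits)."""
        p = self._p
        if self.out_channels == 1:
            return (g_fg[None] * p * (1.0 - p)).astype(np.float32)
        p1 = p[1]
        s = g_fg * p1 * (1.0 - p1)
        return np.stack([-s, s]).astype(np.float32)


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------


class UNet3D:
    """A built U-Net: layer graph plus its configuration (the handle type)."""

    def __init__(self, config: UNetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config
        L = c.levels
        bias = c.use_bias

        def block(cin, width, n_convs):
            layers = []
            for j in range(n_convs):
                layers.append(Conv3d(cin if j == 0 else width, width,
                                     c.conv_kernel, bias, rng))
                if c.use_norm:
                    layers.append(ChannelNorm(width))
                layers.append(Activation(c.activation))
            return layers

        self.enc_blocks = []
        cin = 1
        for i in range(L):
            self.enc_blocks.append(block(cin, c.widths[i], c.convs_per_block))
            cin = c.widths[i]
        self.pools = [MaxPool3d() for _ in range(L - 1)]

        self.ups, self.concats, self.dec_blocks = [], [], []
        for lev in range(L - 2, -1, -1):  # decode deepest-first
            src = c.widths[lev + 1]
            tout = c.widths[lev] if c.transpose_mode == "halve" else src
            self.ups.append(ConvTranspose3d(src, tout, bias, rng))
            self.concats.append(Concat())
            n_convs = c.convs_per_block + (
                1 if lev in c.decoder_extra_convs else 0
            )
            self.dec_blocks.append(
                block(tout + c.widths[lev], c.widths[lev], n_convs)
            )
        self.head_conv = Conv3d(
            c.widths[0], c.out_channels, c.head_kernel, bias, rng
        )
        self.head = _Head(c.out_channels)

    # -- parameter plumbing -------------------------------------------------

    def _all_layers(self):
        for blk in self.enc_blocks:
            yield from blk
        yield from self.pools
        for up, cat, blk in zip(self.ups, self.concats, self.dec_blocks):
            yield up
            yield cat
            yield from blk
        yield self.head_conv
        yield self.head

    def parameters(self) -> list[Param]:
        out = []
        for layer in self._all_layers():
            out.extend(layer.params())
        return out

    def zero_grad(self):
        for p in self.parameters():
            p.grad[...] = 0.0

    def get_state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.parameters()]

    def set_state(self, state: Sequence[np.ndarray]):
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state does not match network parameters")
        for p, v in zip(params, state):
            p.value[...] = v

    # -- execution ----------------------------------------------------------

    def _check_shape(self, shape):
        div = 2 ** (self.config.levels - 1)
        for ax, n in enumerate(shape):
            if n % div:
                raise ShapeError(
                    f"axis {ax} extent {n} is not divisible by {div} "
                    f"(2**(levels-1) with levels={self.config.levels})"
                )

    def forward(self, vol: np.ndarray, train: bool = False) -> np.ndarray:
        """Map a 3D grid to a same-shaped foreground-probability grid."""
        vol = np.asarray(vol)
        if vol.ndim != 3:
            raise ShapeError(f"expected a 3D input, got {vol.ndim}D")
        self._check_shape(vol.shape)
        h = vol.astype(np.float32)[None]
        skips = []
        for i, blk in enumerate(self.enc_blocks):
            for layer in blk:
                h = layer.forward(h, train)
            if i < self.config.levels - 1:
                skips.append(h)
                h = self.pools[i].forward(h, train)
        for up, cat, blk in zip(self.ups, self.concats, self.dec_blocks):
            h = up.forward(h, train)
            h = cat.forward(h, skips.pop(), train)
            for layer in blk:
                h = layer.forward(h, train)
        z = self.head_conv.forward(h, train)
        prob = self.head.forward(z, train)
        return self.head.foreground(prob)

    def backward(self, g_prob: np.ndarray):
        """Backpropagate dLoss/d(foreground probability); fills Param.grad."""
        g = self.head.backward(g_prob.astype(np.float32))
        g = self.head_conv.backward(g)
        # decoder blocks run deepest-first, so unwinding them finest-first
        # yields the skip gradient for level 0 first
        skip_grads = []
        for up, cat, blk in zip(
            reversed(self.ups), reversed(self.concats),
            reversed(self.dec_blocks),
        ):
            for layer in reversed(blk):
                g = layer.backward(g)
            g, g_skip = cat.backward(g)
            skip_grads.append(g_skip)
            g = up.backward(g)
        for i in range(self.config.levels - 1, -1, -1):
            if i < self.config.levels - 1:
                g = self.pools[i].backward(g)
                g = g + skip_grads[i]
            for layer in reversed(self.enc_blocks[i]):
                g = layer.backward(g)


def build_unet(config: UNetConfig, seed: int = 0) -> UNet3D:
    """Construct the network with seeded He-style initialization."""
    return UNet3D(config, seed=seed)


# ---------------------------------------------------------------------------
# census / counting / shape arithmetic
# ---------------------------------------------------------------------------


def layer_census(net: UNet3D) -> LayerCensus:
    """Count 3x3x3 convolutions, poolings, transposes, concatenations."""
    n_conv3 = n_pool = n_transpose = n_concat = 0
    for layer in net._all_layers():
        if isinstance(layer, Conv3d) and layer.kernel == (3, 3, 3):
            n_conv3 += 1
        elif isinstance(layer, MaxPool3d):
            n_pool += 1
        elif isinstance(layer, ConvTranspose3d):
            n_transpose += 1
        elif isinstance(layer, Concat):
            n_concat += 1
    return LayerCensus(n_conv3, n_pool, n_transpose, n_concat)


def count_parameters(net: UNet3D) -> int:
    """Number of trainable scalars in a built network."""
    return int(sum(p.value.size for p in net.parameters()))


def closed_form_param_count(config: UNetConfig) -> int:
    """Per-layer closed-form parameter total (no construction needed).

    conv k^3, c_in -> c_out: k^3*c_in*c_out (+ c_out bias);
    transpose 2x2x2: 8*c_in*c_out (+ c_out); norm: 2*c per normalized conv.
    """
    c = config
    k3 = int(np.prod(c.conv_kernel))
    b = 1 if c.use_bias else 0
    total = 0

    def conv(cin, cout, kk):
        nonlocal total
        total += cout * (kk * cin + b)
        if c.use_norm:
            total += 2 * cout

    cin = 1
    for i in range(c.levels):
        for j in range(c.convs_per_block):
            conv(cin if j == 0 else c.widths[i], c.widths[i], k3)
        cin = c.widths[i]
    for lev in range(c.levels - 2, -1, -1):
        src = c.widths[lev + 1]
        tout = c.widths[lev] if c.transpose_mode == "halve" else src
        total += tout * (8 * src + b)
        n_convs = c.convs_per_block + (1 if lev in c.decoder_extra_convs else 0)
        for j in range(n_convs):
            conv(tout + c.widths[lev] if j == 0 else c.widths[lev],
                 c.widths[lev], k3)
    hk3 = int(np.prod(c.head_kernel))
    total += c.out_channels * (hk3 * c.widths[0] + b)
    return int(total)


def feature_map_shape(
    input_shape: tuple[int, int, int], level: int
) -> tuple[int, int, int]:
    """Spatial shape of the feature map at encoder depth ``level``.

    Each 2x2x2 pooling halves every axis, so depth ``level`` divides each
    axis by ``2**level``; the input must be divisible accordingly.
    """
    if level < 0:
        raise ValueError("level must be >= 0")
    div = 2**level
    out = []
    for ax, n in enumerate(input_shape):
        if n % div:
            raise ShapeError(
                f"axis {ax} extent {n} is not divisible by {div}"
            )
        out.append(n // div)
    return tuple(out)


# ---------------------------------------------------------------------------
# constrained width-configuration search
# ---------------------------------------------------------------------------


class NoExactMatchError(ValueError):
    """The width search found no configuration hitting the exact target."""

    def __init__(self, target, nearest):
        self.target = target
        self.nearest = nearest  # list of (config, count, delta)
        lines = [
            f"no searched configuration reaches exactly {target} parameters;"
            " nearest candidates:"
        ]
        for cfg, cnt, delta in nearest:
            lines.append(f"  widths={cfg.widths} count={cnt} delta={delta:+d}")
        super().__init__("\n".join(lines))


@dataclass(frozen=True)
class WidthSearchSpace:
    """Candidate grid for :func:`find_width_config`.

    Width ladders are monotone non-decreasing.  The first ``levels - 1``
    widths are enumerated on a grid (``base_widths`` for the first level,
    then multiples of ``step`` up to ``max_ratio`` times the previous
    width, capped at ``width_cap``); the bottleneck width — in which the
    parameter total is exactly quadratic — is solved in closed form and
    accepted when the root is a positive integer at most
    ``bottleneck_cap``.  Head kernel/channel variants, transpose-channel
    conventions, conv-per-block counts, extra-convolution placements, and
    bias/normalization toggles are enumerated exhaustively.
    """

    base_widths: tuple[int, ...] = tuple(range(4, 68, 4))
    step: int = 4
    max_ratio: float = 4.0
    width_cap: int = 512
    bottleneck_cap: int = 1024
    head_kernels: tuple[tuple[int, int, int], ...] = ((3, 3, 3), (1, 1, 1))
    head_channels: tuple[int, ...] = (1, 2)
    transpose_modes: tuple[str, ...] = ("halve", "keep")
    convs_per_block: tuple[int, ...] = (2, 1, 3)
    use_bias: tuple[bool, ...] = (True, False)
    use_norm: tuple[bool, ...] = (False, True)


_PREFIX_CACHE: dict = {}


def _enumerate_prefixes(space: WidthSearchSpace, n_free: int) -> np.ndarray:
    """Monotone width prefixes (w0 .. w_{levels-2}) on the search grid."""
    key = (space, n_free)
    if key in _PREFIX_CACHE:
        return _PREFIX_CACHE[key]
    prefixes = np.asarray(space.base_widths, dtype=np.int64)[:, None]
    for _ in range(n_free - 1):
        last = prefixes[:, -1]
        hi = np.minimum(
            (space.max_ratio * last).astype(np.int64), space.width_cap
        )
        counts = np.maximum((hi - last) // space.step + 1, 0)
        rep = np.repeat(prefixes, counts, axis=0)
        # offsets 0, step, 2*step, ... within each repeated group
        idx = np.arange(counts.sum()) - np.repeat(
            np.concatenate(([0], np.cumsum(counts)[:-1])), counts
        )
        nxt = rep[:, -1] + idx * space.step
        prefixes = np.column_stack([rep, nxt])
    _PREFIX_CACHE[key] = prefixes
    return prefixes


def _vec_param_coeffs(prefix, layout):
    """Closed-form total as A x^2 + B x + C in the bottleneck width x.

    ``prefix`` holds the known widths (N, levels-1); returns the scalar
    quadratic coefficient A and vectors B, C of shape (N,).  Every
    parameter term is a product of at most two channel counts, so tracking
    whether each operand is the unknown bottleneck width gives the exact
    polynomial in one vectorized pass.
    """
    (levels, cpb, extras, head_kernel, head_channels, tmode,
     use_bias, use_norm) = layout
    b = 1 if use_bias else 0
    nrm = 2 if use_norm else 0
    N = prefix.shape[0]
    widths: list = [prefix[:, i].astype(np.float64) for i in range(levels - 1)]
    widths.append(None)  # None marks the unknown bottleneck width
    A = 0.0
    B = np.zeros(N)
    C = np.zeros(N)

    def add_conv(cin, cout, k3=27):
        """cout * (k3*cin + b) + nrm*cout with operands possibly unknown."""
        nonlocal A, B, C
        if cout is None and cin is None:
            A += k3
            B += b + nrm
        elif cout is None:
            B += k3 * cin + b + nrm
        elif cin is None:
            B += k3 * cout
            C += cout * (b + nrm)
        else:
            C += cout * (k3 * cin + b + nrm)

    def add_sum_conv(c1, c2, cout, k3=27):
        """Like add_conv with cin = c1 + c2 (the concat input)."""
        nonlocal A, B, C
        # split: cout*k3*c1 + cout*k3*c2 + cout*(b+nrm)
        for cin in (c1, c2):
            if cout is None and cin is None:
                A += k3
            elif cout is None:
                B += k3 * cin
            elif cin is None:
                B += k3 * cout
            else:
                C += k3 * cin * cout
        if cout is None:
            B += b + nrm
        else:
            C += cout * (b + nrm)

    cin = 1.0
    for i in range(levels):
        for j in range(cpb):
            add_conv(cin if j == 0 else widths[i], widths[i])
        cin = widths[i]
    for lev in range(levels - 2, -1, -1):
        src = widths[lev + 1]
        tout = widths[lev] if tmode == "halve" else src
        add_conv(src, tout, k3=8)  # transpose: tout*(8*src + b), no norm
        if nrm and tout is not None:
            C -= nrm * tout  # transposes carry no norm layer
        elif nrm and tout is None:
            B -= nrm
        n_convs = cpb + (1 if lev in extras else 0)
        for j in range(n_convs):
            if j == 0:
                add_sum_conv(tout, widths[lev], widths[lev])
            else:
                add_conv(widths[lev], widths[lev])
    hk3 = int(np.prod(head_kernel))
    # head conv has no norm layer
    if widths[0] is None:
        B += head_channels * hk3
        C += head_channels * b
    else:
        C += head_channels * (hk3 * widths[0] + b)
    return A, B, C


def _layout_variants(census: LayerCensus, space: WidthSearchSpace):
    """Layouts (conv placement + toggles) compatible with the census."""
    if census.n_transpose != census.n_pool or census.n_concat != census.n_pool:
        raise ValueError(
            "census must have equal pool/transpose/concat counts "
            f"(a symmetric encoder-decoder), got {census}"
        )
    levels = census.n_pool + 1
    out = []
    for cpb in space.convs_per_block:
        base = cpb * levels + cpb * (levels - 1)
        for head_kernel in space.head_kernels:
            head_is_conv3 = tuple(head_kernel) == (3, 3, 3)
            n_extra = census.n_conv3 - base - (1 if head_is_conv3 else 0)
            if not 0 <= n_extra <= max(levels - 1, 0):
                continue
            extra_sets = list(
                itertools.combinations(range(levels - 2, -1, -1), n_extra)
            )
            for extras in extra_sets:
                for head_channels in space.head_channels:
                    for tmode in space.transpose_modes:
                        for use_bias in space.use_bias:
                            for use_norm in space.use_norm:
                                out.append(
                                    (levels, cpb, extras, tuple(head_kernel),
                                     head_channels, tmode, use_bias, use_norm)
                                )
    return out


def _layout_to_config(layout, widths) -> UNetConfig:
    (levels, cpb, extras, head_kernel, head_channels, tmode,
     use_bias, use_norm) = layout
    return UNetConfig(
        levels=levels,
        widths=tuple(int(w) for w in widths),
        convs_per_block=cpb,
        decoder_extra_convs=tuple(extras),
        transpose_mode=tmode,
        out_channels=head_channels,
        head_kernel=head_kernel,
        use_bias=use_bias,
        use_norm=use_norm,
    )


def _rank_key(cfg: UNetConfig):
    w = cfg.widths
    doubling = sum(w[i + 1] == 2 * w[i] for i in range(len(w) - 1))
    return (
        cfg.transpose_mode != "halve",
        cfg.head_kernel != (3, 3, 3),
        cfg.out_channels != 1,
        -doubling,
        max(w),
        w,
        cfg.decoder_extra_convs,
    )


def find_width_config(
    census: LayerCensus,
    target_params: int,
    search_space: WidthSearchSpace | None = None,
    n_report: int = 5,
) -> UNetConfig:
    """Search for a configuration matching a layer census and an exact
    parameter total.

    The census fixes the depth (``levels = n_pool + 1``) and the number of
    3x3x3 convolutions; the search enumerates how those convolutions are
    distributed (convs per block, extra decoder convolutions, head kernel)
    together with head channels, transpose-channel convention, and
    bias/normalization toggles, and scans width ladders using the
    closed-form parameter formula only — no network is built during the
    search.  Returns the best-ranked exact match (ranking prefers the
    conventional choices: 'halve' transposes, a 3x3x3 single-channel head,
    doubling ladders, small widths), or raises :class:`NoExactMatchError`
    reporting the nearest misses.
    """
    if target_params <= 0:
        raise ValueError("target_params must be positive")
    space = search_space or WidthSearchSpace()
    layouts = _layout_variants(census, space)
    if not layouts:
        raise NoExactMatchError(target_params, [])

    def _solve_layout(layout):
        """Exact integer bottleneck widths per prefix, or nearest misses."""
        levels = layout[0]
        n_free = levels - 1
        if n_free == 0:
            prefix = np.zeros((1, 0), dtype=np.int64)
            lower = np.ones(1)
        else:
            prefix = _enumerate_prefixes(space, n_free)
            lower = prefix[:, -1].astype(np.float64)
        A, B, C = _vec_param_coeffs(prefix, layout)
        cq = C - target_params
        with np.errstate(divide="ignore", invalid="ignore"):
            if A != 0:
                disc = B * B - 4 * A * cq
                valid = disc >= 0
                root = (-B + np.sqrt(np.where(valid, disc, 0.0))) / (2 * A)
            else:
                valid = B != 0
                root = np.where(valid, -cq / np.where(valid, B, 1.0), np.nan)
        root_i = np.round(root)
        ok = (
            valid
            & np.isfinite(root)
            & (np.abs(root - root_i) < 1e-6)
            & (root_i >= lower)
            & (root_i <= space.bottleneck_cap)
        )
        return prefix, root, root_i, ok, lower, (A, B, C)

    exact: list[UNetConfig] = []
    for layout in layouts:
        prefix, _root, root_i, ok, _lower, _ = _solve_layout(layout)
        for i in np.nonzero(ok)[0]:
            widths = list(prefix[i]) + [int(root_i[i])]
            cfg = _layout_to_config(layout, widths)
            if closed_form_param_count(cfg) == target_params:
                exact.append(cfg)
    if exact:
        exact.sort(key=_rank_key)
        return exact[0]

    # no exact hit: second pass collecting the nearest candidates
    nearest: list[tuple[UNetConfig, int, int]] = []
    for layout in layouts:
        prefix, root, root_i, _ok, lower, (A, B, C) = _solve_layout(layout)
        guess = np.clip(
            np.nan_to_num(root_i, nan=float(lower.max() if lower.size else 1)),
            lower, space.bottleneck_cap,
        )
        f = A * guess**2 + B * guess + C
        j = int(np.argmin(np.abs(f - target_params)))
        cfg = _layout_to_config(layout, list(prefix[j]) + [int(guess[j])])
        cnt = closed_form_param_count(cfg)
        nearest.append((cfg, cnt, cnt - target_params))
    nearest.sort(key=lambda t: abs(t[2]))
    raise NoExactMatchError(target_params, nearest[:n_report])
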