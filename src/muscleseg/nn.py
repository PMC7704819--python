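"""Minimal CPU neural-network core: layers, U-net graph, Adam, losses.

Everything is plain NumPy in float32 with explicit forward/backward passes.
Convolutions use im2col + BLAS matmul; each layer caches what its backward
pass needs, so a layer instance belongs to exactly one position in the
graph. Given a fixed seed the whole training loop is bit-deterministic on a
fixed BLAS configuration.

Array layout is (N, C, H, W).
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["UNet", "Adam", "softmax_cross_entropy", "sigmoid_bce", "sigmoid"]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Conv2d:
    """k x k convolution, stride 1, 'same' zero padding (k odd)."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        self.cin, self.cout, self.k = cin, cout, k
        fan_in = cin * k * k
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        # weights stored per kernel offset: W[i*k+j] is the contiguous
        # (cin, cout) block for tap (i, j), used directly in the GEMMs
        self.W = rng.normal(0.0, scale, (k * k, cin, cout)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._xs = None
        self._xshape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x is channels-last (n, h, w, c).

        The k x k convolution is evaluated as k^2 shifted GEMMs, which on
        CPU beats materializing the full im2col patch matrix; the shifted
        input slabs are cached for the weight-gradient pass.
        """
        n, h, w, c = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        k = self.k
        self._xshape = x.shape
        if k == 1:
            cols = x.reshape(n * h * w, c)
            self._xs = [cols]
            return (cols @ self.W[0] + self.b).reshape(n, h, w, self.cout)
        p = k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        out = np.empty((n * h * w, self.cout), dtype=np.float32)
        out[:] = self.b
        self._xs = []
        for i in range(k):
            for j in range(k):
                xs = np.ascontiguousarray(xp[:, i : i + h, j : j + w, :]).reshape(-1, c)
                self._xs.append(xs)
                out += xs @ self.W[i * k + j]
        return out.reshape(n, h, w, self.cout)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._xshape
        k = self.k
        g = np.ascontiguousarray(gy).reshape(n * h * w, self.cout)
        self.gb += g.sum(axis=0)
        if k == 1:
            self.gW[0] += self._xs[0].T @ g
            gx = (g @ self.W[0].T).reshape(n, h, w, c)
            self._xs = None
            return gx
        p = k // 2
        for t in range(k * k):
            self.gW[t] += self._xs[t].T @ g
        # input gradient: 'same' convolution of gy with the spatially
        # flipped, transposed kernel, again as shifted GEMMs
        gyp = np.pad(gy, ((0, 0), (p, p), (p, p), (0, 0)))
        gx = np.zeros((n * h * w, c), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                gs = np.ascontiguousarray(gyp[:, i : i + h, j : j + w, :]).reshape(-1, self.cout)
                gx += gs @ self.W[(k - 1 - i) * k + (k - 1 - j)].T
        self._xs = None
        return gx.reshape(n, h, w, c)

    def params(self) -> List[Tuple[str, np.ndarray, np.ndarray]]:
        return [("W", self.W, self.gW), ("b", self.b, self.gb)]


class GroupNorm:
    """Group normalization over (H, W, channel-group), batch-independent.

    Normalizes each sample's channel groups to zero mean / unit variance
    with learnable per-channel scale and shift. Unlike batch norm it has no
    running statistics, so training and inference are identical and
    deterministic at any batch size.
    """

    def __init__(self, channels: int, groups: int | None = None, eps: float = 1e-5):
        if groups is None:
            groups = next(g for g in (8, 4, 2, 1) if channels % g == 0)
        if channels % groups:
            raise ValueError(f"channels {channels} not divisible by groups {groups}")
        self.c, self.g, self.eps = channels, groups, eps
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        xg = x.reshape(n, h * w, self.g, c // self.g)
        mu = xg.mean(axis=(1, 3), keepdims=True)
        var = xg.var(axis=(1, 3), keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = ((xg - mu) * self._inv).reshape(n, h, w, c)
        return self._xhat * self.gamma + self.beta

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, h, w, c = gy.shape
        self.gbeta += gy.sum(axis=(0, 1, 2))
        self.ggamma += (gy * self._xhat).sum(axis=(0, 1, 2))
        dxhat = (gy * self.gamma).reshape(n, h * w, self.g, c // self.g)
        xhat = self._xhat.reshape(n, h * w, self.g, c // self.g)
        m1 = dxhat.mean(axis=(1, 3), keepdims=True)
        m2 = (dxhat * xhat).mean(axis=(1, 3), keepdims=True)
        gx = (dxhat - m1 - xhat * m2) * self._inv
        return gx.reshape(n, h, w, c).astype(np.float32)

    def params(self) -> List[Tuple[str, np.ndarray, np.ndarray]]:
        return [("gamma", self.gamma, self.ggamma), ("beta", self.beta, self.gbeta)]


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy * self._mask


class MaxPool2:
    """2x2 max pooling, stride 2. Ties route the gradient to the first
    maximal element in block raster order (deterministic)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        blocks = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        flat = np.ascontiguousarray(blocks).reshape(n, h // 2, w // 2, c, 4)
        self._arg = flat.argmax(axis=-1)
        self._xshape = x.shape
        return np.take_along_axis(flat, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._xshape
        flat = np.zeros((n, h // 2, w // 2, c, 4), dtype=np.float32)
        np.put_along_axis(flat, self._arg[..., None], gy[..., None], axis=-1)
        blocks = flat.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return np.ascontiguousarray(blocks).reshape(n, h, w, c)


class UpNearest2:
    """Nearest-neighbour 2x upsampling; backward sums each 2x2 block."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, h, w, c = gy.shape
        return gy.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class UNet:
    """Encoder-decoder with skip connections.

    ``depth`` pooling levels; channels double per level starting from
    ``base``; the decoder upsamples (nearest), concatenates the encoder
    feature of the same resolution, and applies two 3x3 conv+ReLU blocks;
    a final 1x1 convolution emits one score map per output class.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        depth: int,
        base: int,
        seed: int = 0,
        norm: str = "none",
    ):
        if depth < 2:
            raise ValueError("depth must be >= 2")
        if norm not in ("none", "group"):
            raise ValueError("norm must be 'none' or 'group'")
        rng = np.random.default_rng(seed)
        self.depth, self.base, self.norm = depth, base, norm
        self.in_channels, self.out_channels = in_channels, out_channels

        def block(cin, cout):
            layers = [Conv2d(cin, cout, 3, rng)]
            if norm == "group":
                layers.append(GroupNorm(cout))
            layers.append(ReLU())
            layers.append(Conv2d(cout, cout, 3, rng))
            if norm == "group":
                layers.append(GroupNorm(cout))
            layers.append(ReLU())
            return layers

        self.enc: List[List] = []
        cin = in_channels
        for d in range(depth):
            cout = base * 2**d
            self.enc.append(block(cin, cout))
            cin = cout
        cb = base * 2**depth
        self.bott = block(cin, cb)
        self.pools = [MaxPool2() for _ in range(depth)]
        self.ups = [UpNearest2() for _ in range(depth)]
        self.dec: List[List] = []
        cdeep = cb
        for d in reversed(range(depth)):
            cskip = base * 2**d
            self.dec.append(block(cdeep + cskip, cskip))
            cdeep = cskip
        self.head = Conv2d(base, out_channels, 1, rng)
        self.bottleneck_hw: Tuple[int, int] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x is (n, c, h, w); internals run channels-last for speed."""
        h, w = x.shape[2], x.shape[3]
        f = 2**self.depth
        if h % f or w % f:
            raise ValueError(
                f"input spatial size {h}x{w} not divisible by 2^depth={f}; "
                "pad the in-plane grid to a multiple before prediction"
            )
        x = np.ascontiguousarray(x.transpose(0, 2, 3, 1), dtype=np.float32)
        skips = []
        for d in range(self.depth):
            for layer in self.enc[d]:
                x = layer.forward(x)
            skips.append(x)
            x = self.pools[d].forward(x)
        for layer in self.bott:
            x = layer.forward(x)
        self.bottleneck_hw = (x.shape[1], x.shape[2])
        for i, d in enumerate(reversed(range(self.depth))):
            x = self.ups[i].forward(x)
            x = np.concatenate([skips[d], x], axis=3)
            for layer in self.dec[i]:
                x = layer.forward(x)
        out = self.head.forward(x)
        return np.ascontiguousarray(out.transpose(0, 3, 1, 2))

    def backward(self, gy: np.ndarray) -> None:
        """gy is (n, k, h, w), matching forward's return layout."""
        g = np.ascontiguousarray(gy.transpose(0, 2, 3, 1), dtype=np.float32)
        g = self.head.backward(g)
        gskips: Dict[int, np.ndarray] = {}
        # decoder blocks in reverse construction order (shallowest first);
        # dec[i] operates at encoder level d = depth - 1 - i
        for i in reversed(range(self.depth)):
            d = self.depth - 1 - i
            for layer in reversed(self.dec[i]):
                g = layer.backward(g)
            cskip = self.base * 2**d
            gskips[d] = g[..., :cskip]
            g = self.ups[i].backward(g[..., cskip:])
        for layer in reversed(self.bott):
            g = layer.backward(g)
        for d in reversed(range(self.depth)):
            g = self.pools[d].backward(g)
            g = g + gskips[d]
            for layer in reversed(self.enc[d]):
                g = layer.backward(g)

    # --- parameter plumbing -------------------------------------------------

    def _param_layers(self) -> List[Tuple[str, object]]:
        out = []
        for prefix, blocks in (("enc", self.enc), ("bott", [self.bott]), ("dec", self.dec)):
            for d, block in enumerate(blocks):
                for li, layer in enumerate(block):
                    if hasattr(layer, "params"):
                        out.append((f"{prefix}{d}_{li}", layer))
        out.append(("head", self.head))
        return out

    def parameters(self) -> List[Tuple[str, np.ndarray, np.ndarray]]:
        out = []
        for name, layer in self._param_layers():
            for pname, p, g in layer.params():
                out.append((f"{name}.{pname}", p, g))
        return out

    def n_parameters(self) -> int:
        return int(sum(p.size for _, p, _ in self.parameters()))

    def zero_grad(self) -> None:
        for _, _, g in self.parameters():
            g[...] = 0.0

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {name: p.copy() for name, p, _ in self.parameters()}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        for name, p, _ in self.parameters():
            if name not in state:
                raise KeyError(f"missing parameter {name} in state dict")
            if state[name].shape != p.shape:
                raise ValueError(f"shape mismatch for {name}")
            p[...] = state[name]


class Adam:
    def __init__(self, net: UNet, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.net, self.lr = net, lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {name: np.zeros_like(p) for name, p, _ in net.parameters()}
        self.v = {name: np.zeros_like(p) for name, p, _ in net.parameters()}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for name, p, g in self.net.parameters():
            m = self.m[name]
            v = self.v[name]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


def softmax_cross_entropy(logits: np.ndarray, target: np.ndarray) -> Tuple[float, np.ndarray]:
    """Mean categorical cross-entropy over all pixels.

    logits (N, K, H, W); target (N, H, W) integer class ids. Returns
    (loss, dloss/dlogits).
    """
    n, k, h, w = logits.shape
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    idx = target[:, None, :, :]
    logp = z - np.log(ez.sum(axis=1, keepdims=True))
    picked = np.take_along_axis(logp, idx, axis=1)
    npix = n * h * w
    loss = float(-picked.sum() / npix)
    grad = p.copy()
    np.put_along_axis(grad, idx, np.take_along_axis(grad, idx, axis=1) - 1.0, axis=1)
    return loss, (grad / npix).astype(np.float32)


def sigmoid_bce(logits: np.ndarray, target_onehot: np.ndarray) -> Tuple[float, np.ndarray]:
    """Mean per-map binary cross-entropy with logits.

    logits and target_onehot share shape (N, K, H, W); targets in {0,1}.
    """
    s = sigmoid(logits)
    eps = 1e-12
    loss = float(
        -(target_onehot * np.log(s + eps) + (1 - target_onehot) * np.log(1 - s + eps)).mean()
    )
    grad = ((s - target_onehot) / logits.size).astype(np.float32)
    return loss, grad
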