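"""Minimal numpy encoder-decoder segmentation networks.

A compact, dependency-free convolutional stack with hand-written
backpropagation, sized for CPU training on small (64-128 px) B-mode
phantoms. The topology is a two-resolution U-shape:

    conv(1->c) -> conv(c->c) --------------------┐
        └ avgpool/2 -> conv(c->2c) [-> conv]     │ skip
              └ upsample x2 ---------------------┴ concat -> conv(3c->c) -> conv(c->1) -> sigmoid

Model *variants* differ in base width ``c``, the optional extra bottleneck
conv, and the initialization seed; five such variants stand in for five
independently designed architectures in the ensemble experiments. The
interface (predict probabilities in [0, 1], train on a loss gradient
w.r.t. the probability map) is all the rest of the package relies on.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

__all__ = ["SegNet", "Adam", "save_checkpoint", "load_checkpoint"]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _im2col(x: np.ndarray, k: int = 3) -> np.ndarray:
    """(C, H, W) -> (H*W, C*k*k) patches with zero 'same' padding."""
    c, h, w = x.shape
    pad = k // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    # win: (C, H, W, k, k) -> (H, W, C, k, k) -> (H*W, C*k*k)
    return np.ascontiguousarray(win.transpose(1, 2, 0, 3, 4)).reshape(h * w, c * k * k)


class Conv2D:
    """3x3 'same' convolution with He-normal init."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, k: int = 3):
        self.c_in, self.c_out, self.k = c_in, c_out, k
        fan_in = c_in * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, c_in, k, k))
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._hw: tuple[int, int] = (0, 0)

    def forward(self, x: np.ndarray) -> np.ndarray:
        _, h, w = x.shape
        self._hw = (h, w)
        self._cols = _im2col(x, self.k)
        y = self._cols @ self.W.reshape(self.c_out, -1).T + self.b
        return y.T.reshape(self.c_out, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        h, w = self._hw
        dyf = dy.reshape(self.c_out, -1).T  # (H*W, c_out)
        self.dW += (dyf.T @ self._cols).reshape(self.W.shape)
        self.db += dy.sum(axis=(1, 2))
        # Gradient w.r.t. input: convolve dy with spatially flipped kernels,
        # channels transposed.
        wt = np.flip(self.W, axis=(2, 3)).transpose(1, 0, 2, 3)  # (c_in, c_out, k, k)
        cols_dy = _im2col(dy, self.k)
        dx = cols_dy @ wt.reshape(self.c_in, -1).T
        return dx.T.reshape(self.c_in, h, w)

    def params(self):
        return [("W", self), ("b", self)]


class _ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


def _avgpool2(x: np.ndarray) -> np.ndarray:
    c, h, w = x.shape
    return x.reshape(c, h // 2, 2, w // 2, 2).mean(axis=(2, 4))


def _avgpool2_back(dy: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(dy, 2, axis=1), 2, axis=2) / 4.0


def _upsample2(x: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)


def _upsample2_back(dy: np.ndarray) -> np.ndarray:
    c, h, w = dy.shape
    return dy.reshape(c, h // 2, 2, w // 2, 2).sum(axis=(2, 4))


class SegNet:
    """Two-level encoder-decoder emitting a per-pixel tumor probability map."""

    def __init__(self, base_channels: int = 8, extra_conv: bool = False, seed: int = 0):
        self.config = {"base_channels": base_channels, "extra_conv": extra_conv, "seed": seed}
        rng = np.random.default_rng(seed)
        c = base_channels
        self.enc1 = Conv2D(1, c, rng)
        self.enc2 = Conv2D(c, c, rng)
        self.bott1 = Conv2D(c, 2 * c, rng)
        self.bott2 = Conv2D(2 * c, 2 * c, rng) if extra_conv else None
        self.dec1 = Conv2D(3 * c, c, rng)
        self.out = Conv2D(c, 1, rng)
        self._relus = [_ReLU() for _ in range(5)]

    # -- plumbing -----------------------------------------------------------
    def conv_layers(self) -> list[Conv2D]:
        layers = [self.enc1, self.enc2, self.bott1, self.dec1, self.out]
        if self.bott2 is not None:
            layers.insert(3, self.bott2)
        return layers

    def zero_grad(self) -> None:
        for layer in self.conv_layers():
            layer.dW[...] = 0.0
            layer.db[...] = 0.0

    def get_weights(self) -> list[np.ndarray]:
        out = []
        for layer in self.conv_layers():
            out.extend([layer.W.copy(), layer.b.copy()])
        return out

    def set_weights(self, weights: list[np.ndarray]) -> None:
        it = iter(weights)
        for layer in self.conv_layers():
            layer.W[...] = next(it)
            layer.b[...] = next(it)

    # -- forward / backward -------------------------------------------------
    def forward(self, image: np.ndarray) -> np.ndarray:
        """image (H, W) in [0,1] -> probability map (H, W); caches for backward."""
        x = np.asarray(image, dtype=np.float64)[None]
        if x.shape[1] % 2 or x.shape[2] % 2:
            raise ValueError("image height and width must be even")
        r = self._relus
        e1 = r[0].forward(self.enc1.forward(x))
        e2 = r[1].forward(self.enc2.forward(e1))
        b = r[2].forward(self.bott1.forward(_avgpool2(e2)))
        if self.bott2 is not None:
            b = r[3].forward(self.bott2.forward(b))
        u = _upsample2(b)
        cat = np.concatenate([e2, u], axis=0)
        d = r[4].forward(self.dec1.forward(cat))
        logits = self.out.forward(d)[0]
        self._c = self.config["base_channels"]
        self._prob = _sigmoid(logits)
        return self._prob

    def backward(self, dloss_dprob: np.ndarray) -> None:
        """Accumulate parameter gradients given d(loss)/d(probability map)."""
        r = self._relus
        dlogits = dloss_dprob * self._prob * (1.0 - self._prob)
        d = self.out.backward(dlogits[None])
        dcat = self.dec1.backward(r[4].backward(d))
        c = self._c
        de2_skip, du = dcat[:c], dcat[c:]
        db = _upsample2_back(du)
        if self.bott2 is not None:
            db = self.bott2.backward(r[3].backward(db))
        dp = self.bott1.backward(r[2].backward(db))
        de2 = de2_skip + _avgpool2_back(dp)
        de1 = self.enc2.backward(r[1].backward(de2))
        self.enc1.backward(r[0].backward(de1))

    def predict(self, image: np.ndarray) -> np.ndarray:
        """Probability map without keeping gradients alive for the caller."""
        return self.forward(image).copy()


class Adam:
    """Adam over every conv parameter of a SegNet."""

    def __init__(self, net: SegNet, lr: float = 1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.net, self.lr, self.b1, self.b2, self.eps = net, lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in self._params()]
        self.v = [np.zeros_like(p) for p in self._params()]

    def _params(self):
        out = []
        for layer in self.net.conv_layers():
            out.extend([layer.W, layer.b])
        return out

    def _grads(self):
        out = []
        for layer in self.net.conv_layers():
            out.extend([layer.dW, layer.db])
        return out

    def step(self) -> None:
        self.t += 1
        for i, (p, g) in enumerate(zip(self._params(), self._grads())):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def save_checkpoint(path: str | Path, net: SegNet, extra: dict | None = None) -> None:
    """Persist weights as .npz with a JSON sidecar holding the config."""
    path = Path(path)
    arrays = {f"p{i}": w for i, w in enumerate(net.get_weights())}
    np.savez(path, **arrays)
    sidecar = {"model": net.config, **(extra or {})}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path: str | Path) -> tuple[SegNet, dict]:
    path = Path(path)
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    cfg = sidecar["model"]
    net = SegNet(cfg["base_channels"], cfg["extra_conv"], cfg["seed"])
    with np.load(path) as data:
        weights = [data[f"p{i}"] for i in range(len(data.files))]
    net.set_weights(weights)
    return net, sidecar
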