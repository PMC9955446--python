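"""Minimal NumPy layer framework with hand-written backprop.

Only what the two-block residual classifier needs: im2col convolution,
ReLU, residual blocks, elementwise (inverted) dropout, global average
pooling, a dense head, softmax cross-entropy and Adam. Layers are
deliberately stateful: ``forward`` caches what ``backward`` needs, and
parameter gradients accumulate on the layer until ``zero_grad``.

DropWeak-wrapped layers (``Conv2d``/``Dense`` with a ``DropWeakSpec``)
sample fresh masks per stochastic forward pass from the generator they
are handed; masks are treated as constants in backward, so gradients
flow to the master weights through surviving entries only.
"""

from __future__ import annotations

import numpy as np

from .convops import col2im, im2col, out_size
from .masking import DropWeakSpec, sample_node_mask, sample_weight_mask, weak_weight_mask

DTYPE = np.float32


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(DTYPE)


class Layer:
    name: str = ""

    def forward(self, x: np.ndarray, stochastic: bool, rng: np.random.Generator | None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}

    def zero_grad(self) -> None:
        for g in self.grads().values():
            g[...] = 0.0


def _dropweak_factors(
    W: np.ndarray, spec: DropWeakSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """(per-weight multiplier, per-output-unit multiplier) for one pass.

    Inactive mechanisms consume no draws (same stream contract as
    :func:`dropweak.masking.sample_mask_set`).
    """
    if np.ndim(spec.weight_drop_prob) == 0 and float(spec.weight_drop_prob) == 0.0:
        wmask = np.ones(W.shape)
    else:
        wmask = sample_weight_mask(W.shape, spec.weight_drop_prob, rng)
    n_out = W.shape[0] if W.ndim == 4 else W.shape[1]
    if spec.node_drop_prob == 0.0:
        nmask = np.ones(n_out)
    else:
        nmask = sample_node_mask(n_out, spec.node_drop_prob, rng)
    kfac = wmask * weak_weight_mask(W, spec.weak_rule)
    if spec.scale_mode == "inverted":
        rho = np.asarray(spec.weight_drop_prob, dtype=float)
        keep = 1.0 - rho
        kfac = kfac * np.where(keep > 0, 1.0 / np.where(keep > 0, keep, 1.0), 1.0)
        if spec.node_drop_prob < 1.0:
            nmask = nmask / (1.0 - spec.node_drop_prob)
    return kfac.astype(DTYPE), nmask.astype(DTYPE)


class Conv2d(Layer):
    """3x3-style cross-correlation layer, optionally DropWeak-wrapped."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        ksize: int,
        rng: np.random.Generator,
        stride: int = 1,
        pad: int = 1,
        dropweak: DropWeakSpec | None = None,
        name: str = "conv",
    ):
        self.name = name
        self.stride, self.pad, self.ksize = stride, pad, ksize
        self.W = he_init(rng, (c_out, c_in, ksize, ksize), c_in * ksize * ksize)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.dropweak = dropweak
        self._cache: tuple | None = None

    def forward(self, x, stochastic, rng):
        n, c, h, w = x.shape
        c_out = self.W.shape[0]
        ho, wo = out_size(h, w, self.ksize, self.ksize, self.stride, self.pad)
        if stochastic and self.dropweak is not None:
            assert rng is not None
            kfac, nfac = _dropweak_factors(self.W, self.dropweak, rng)
        else:
            kfac, nfac = None, None
        w_eff = self.W if kfac is None else self.W * kfac
        cols = im2col(x, self.ksize, self.ksize, self.stride, self.pad)
        out = cols @ w_eff.reshape(c_out, -1).T + self.b
        if nfac is not None:
            out = out * nfac
        self._cache = (cols, x.shape, w_eff, kfac, nfac, (n, ho, wo, c_out))
        return np.ascontiguousarray(out.reshape(n, ho, wo, c_out).transpose(0, 3, 1, 2))

    def backward(self, dout):
        cols, x_shape, w_eff, kfac, nfac, (n, ho, wo, c_out) = self._cache
        dmat = dout.transpose(0, 2, 3, 1).reshape(n * ho * wo, c_out)
        if nfac is not None:
            dmat = dmat * nfac
        dw_eff = (dmat.T @ cols).reshape(self.W.shape)
        self.dW += dw_eff if kfac is None else dw_eff * kfac
        self.db += dmat.sum(axis=0)
        dcols = dmat @ w_eff.reshape(c_out, -1)
        return col2im(dcols, x_shape, self.ksize, self.ksize, self.stride, self.pad).astype(DTYPE)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}


class Dense(Layer):
    def __init__(
        self,
        n_in: int,
        n_out: int,
        rng: np.random.Generator,
        dropweak: DropWeakSpec | None = None,
        name: str = "fc",
    ):
        self.name = name
        self.W = he_init(rng, (n_in, n_out), n_in)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.dropweak = dropweak
        self._cache: tuple | None = None

    def forward(self, x, stochastic, rng):
        if stochastic and self.dropweak is not None:
            assert rng is not None
            kfac, nfac = _dropweak_factors(self.W, self.dropweak, rng)
        else:
            kfac, nfac = None, None
        w_eff = self.W if kfac is None else self.W * kfac
        out = x @ w_eff + self.b
        if nfac is not None:
            out = out * nfac
        self._cache = (x, w_eff, kfac, nfac)
        return out

    def backward(self, dout):
        x, w_eff, kfac, nfac = self._cache
        if nfac is not None:
            dout = dout * nfac
        dw_eff = x.T @ dout
        self.dW += dw_eff if kfac is None else dw_eff * kfac
        self.db += dout.sum(axis=0)
        return dout @ w_eff.T

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}


class ReLU(Layer):
    def __init__(self, name: str = "relu"):
        self.name = name
        self._mask: np.ndarray | None = None

    def forward(self, x, stochastic, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Dropout(Layer):
    """Elementwise inverted dropout (node-only regularization)."""

    def __init__(self, p: float, name: str = "dropout"):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must lie in [0, 1)")
        self.name = name
        self.p = p
        self._mask: np.ndarray | None = None

    def forward(self, x, stochastic, rng):
        if not stochastic or self.p == 0.0:
            self._mask = None
            return x
        assert rng is not None
        self._mask = (rng.random(x.shape) >= self.p).astype(DTYPE) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class GlobalAvgPool(Layer):
    def __init__(self, name: str = "gap"):
        self.name = name
        self._shape: tuple | None = None

    def forward(self, x, stochastic, rng):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], (n, c, h, w)).astype(DTYPE) / (h * w)


class ResidualBlock(Layer):
    """y = relu(conv2(relu(conv1(x))) + x); channel count preserved."""

    def __init__(
        self,
        channels: int,
        rng: np.random.Generator,
        dropweak: DropWeakSpec | None = None,
        name: str = "res",
    ):
        self.name = name
        self.conv1 = Conv2d(channels, channels, 3, rng, dropweak=dropweak, name=f"{name}.conv1")
        self.conv2 = Conv2d(channels, channels, 3, rng, dropweak=dropweak, name=f"{name}.conv2")
        self._m1: np.ndarray | None = None
        self._mout: np.ndarray | None = None

    def forward(self, x, stochastic, rng):
        a = self.conv1.forward(x, stochastic, rng)
        self._m1 = a > 0
        h = a * self._m1
        s = self.conv2.forward(h, stochastic, rng) + x
        self._mout = s > 0
        return s * self._mout

    def backward(self, dout):
        ds = dout * self._mout
        dh = self.conv2.backward(ds)
        da = dh * self._m1
        return self.conv1.backward(da) + ds

    def params(self):
        return {f"conv1.{k}": v for k, v in self.conv1.params().items()} | {
            f"conv2.{k}": v for k, v in self.conv2.params().items()
        }

    def grads(self):
        return {f"conv1.{k}": v for k, v in self.conv1.grads().items()} | {
            f"conv2.{k}": v for k, v in self.conv2.grads().items()
        }


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, labels: np.ndarray, eps: float = 1e-12) -> float:
    n = probs.shape[0]
    return float(-np.log(probs[np.arange(n), labels] + eps).mean())


class Adam:
    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}

    def step(self, named_params: dict[str, np.ndarray], named_grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for key, p in named_params.items():
            g = named_grads[key]
            m = self._m.setdefault(key, np.zeros_like(p))
            v = self._v.setdefault(key, np.zeros_like(p))
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
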