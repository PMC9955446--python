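"""The DropWeak masking scheme.

DropWeak combines three mechanisms in a single stochastic pass over a
weight tensor:

* **node dropout** — whole output units (or conv output channels) are
  dropped with probability ``node_drop_prob``, as in classic DropOut;
* **per-weight dropping** — individual weights are dropped with
  probability ``weight_drop_prob`` (a scalar, or a per-weight array
  ``rho`` of the weight tensor's shape), as in DropConnect;
* **weak-weight zeroing** — weights of low magnitude are zeroed
  deterministically, under either an absolute threshold or a quantile
  rule, on the view used for the pass only.

All masking is non-destructive: masks are applied to a per-pass *view*
of the master weights, so dropped or zeroed entries automatically rejoin
at the next pass. With ``scale_mode='inverted'`` the surviving
Bernoulli-masked entries are rescaled by ``1/(1-rho)`` (and kept nodes
by ``1/(1-node_drop_prob)``) so the masked pass is unbiased for the
dense pass; the deterministic weak mask is never compensated.

Mask-sampling convention: every mask entry is decided by a single
uniform draw ``u`` with *keep iff u >= drop_probability*, so the scheme
reduces exactly (stream-for-stream) to plain DropOut when
``weight_drop_prob = 0`` with no weak rule, and to plain DropConnect
when ``node_drop_prob = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Union

import numpy as np

from .convops import conv2d_forward

__all__ = [
    "WeakRule",
    "absolute",
    "quantile",
    "DropWeakSpec",
    "StochasticMaskSet",
    "MaskedWeightView",
    "sample_weight_mask",
    "sample_node_mask",
    "weak_weight_mask",
    "sample_mask_set",
    "effective_weights",
    "apply_dropweak",
    "mc_activation_estimate",
    "magnitude_inverse_rho",
]


@dataclass(frozen=True)
class WeakRule:
    """Deterministic low-magnitude zeroing rule.

    ``absolute``: zero entries with ``|w| < value`` (strict, so tau=0 is
    a no-op). ``quantile``: zero the ``floor(value * n)`` entries of
    smallest ``|w|``, ties broken by flat index ascending so the mask is
    a total-order deterministic function of the weights.
    """

    kind: Literal["absolute", "quantile"]
    value: float

    def __post_init__(self) -> None:
        if self.kind not in ("absolute", "quantile"):
            raise ValueError(f"unknown weak rule kind {self.kind!r}")
        if self.kind == "absolute" and self.value < 0:
            raise ValueError("absolute threshold tau must be >= 0")
        if self.kind == "quantile" and not 0.0 <= self.value <= 1.0:
            raise ValueError("quantile q must lie in [0, 1]")


def absolute(tau: float) -> WeakRule:
    return WeakRule("absolute", float(tau))


def quantile(q: float) -> WeakRule:
    return WeakRule("quantile", float(q))


RhoLike = Union[float, np.ndarray]


@dataclass(frozen=True)
class DropWeakSpec:
    """Hyperparameters of one DropWeak-wrapped weight tensor.

    Parameters
    ----------
    node_drop_prob:
        Probability of dropping each output unit / channel.
    weight_drop_prob:
        Per-weight drop probability rho; scalar or an array matching the
        weight tensor's shape.
    weak_rule:
        Low-magnitude zeroing rule; default quantile(0.10) (scale-free,
        robust to weight-norm drift). ``None`` disables weak zeroing.
    scale_mode:
        ``'inverted'`` (default) rescales survivors so the masked pass
        is unbiased for the dense pass; ``'none'`` applies raw masks.
    """

    node_drop_prob: float = 0.0
    weight_drop_prob: RhoLike = 0.0
    weak_rule: WeakRule | None = field(default_factory=lambda: quantile(0.10))
    scale_mode: Literal["inverted", "none"] = "inverted"

    def __post_init__(self) -> None:
        if not 0.0 <= self.node_drop_prob <= 1.0:
            raise ValueError("node_drop_prob must lie in [0, 1]")
        rho = np.asarray(self.weight_drop_prob, dtype=float)
        if rho.size == 0 or np.any(rho < 0) or np.any(rho > 1):
            raise ValueError("weight_drop_prob entries must lie in [0, 1]")
        if self.scale_mode not in ("inverted", "none"):
            raise ValueError(f"unknown scale_mode {self.scale_mode!r}")

    @staticmethod
    def off() -> "DropWeakSpec":
        """A spec under which every pass equals the dense pass."""
        return DropWeakSpec(0.0, 0.0, weak_rule=None, scale_mode="none")


@dataclass
class StochasticMaskSet:
    """One realized set of masks for a single forward pass.

    ``weak_mask`` is a deterministic function of the weights and the
    weak rule; the other two are Bernoulli draws. ``seed_state`` records
    the substream the draws came from.
    """

    node_mask: np.ndarray
    weight_mask: np.ndarray
    weak_mask: np.ndarray
    seed_state: str = ""


@dataclass(frozen=True)
class MaskedWeightView:
    """Non-destructive effective-weight view for one pass."""

    effective_weights: np.ndarray
    base_weights_untouched: bool = True


def _check_prob(p: RhoLike, name: str) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1) or not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must lie in [0, 1]")
    return arr


def sample_weight_mask(
    shape: tuple[int, ...], rho: RhoLike, rng: np.random.Generator
) -> np.ndarray:
    """Bernoulli keep-mask over a weight tensor: 0 with probability rho."""
    if len(shape) == 0 or int(np.prod(shape)) == 0:
        raise ValueError("weight shape must be nonempty")
    rho_arr = _check_prob(rho, "rho")
    if rho_arr.ndim > 0 and rho_arr.shape != tuple(shape):
        raise ValueError(f"rho shape {rho_arr.shape} does not match weights {tuple(shape)}")
    return (rng.random(shape) >= rho_arr).astype(float)


def sample_node_mask(n_units: int, p_node: float, rng: np.random.Generator) -> np.ndarray:
    """Bernoulli keep-mask over output units: 0 with probability p_node."""
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    p = float(_check_prob(p_node, "p_node"))
    return (rng.random(n_units) >= p).astype(float)


def weak_weight_mask(weights: np.ndarray, weak_rule: WeakRule | None) -> np.ndarray:
    """Deterministic mask zeroing low-magnitude weights.

    Idempotent in the sense that re-deriving the mask from the same
    weights and rule always yields the same array.
    """
    w = np.asarray(weights, dtype=float)
    if not np.all(np.isfinite(w)):
        raise ValueError("weights must be finite")
    if weak_rule is None:
        return np.ones_like(w)
    if weak_rule.kind == "absolute":
        return (np.abs(w) >= weak_rule.value).astype(float)
    # quantile: drop the floor(q*n) smallest |w|, ties by flat index
    n = w.size
    k = int(np.floor(weak_rule.value * n))
    mask = np.ones(n)
    if k > 0:
        order = np.lexsort((np.arange(n), np.abs(w).ravel()))
        mask[order[:k]] = 0.0
    return mask.reshape(w.shape)


def _n_output_units(weights: np.ndarray) -> int:
    # dense weights are (n_in, n_out); conv kernels are (C_out, C_in, kh, kw)
    if weights.ndim == 2:
        return weights.shape[1]
    if weights.ndim == 4:
        return weights.shape[0]
    raise ValueError(f"unsupported weight rank {weights.ndim}")


def _rho_is_off(rho: RhoLike) -> bool:
    return np.ndim(rho) == 0 and float(rho) == 0.0


def sample_mask_set(
    weights: np.ndarray,
    spec: DropWeakSpec,
    rng: np.random.Generator,
    seed_state: str = "",
) -> StochasticMaskSet:
    """Draw one full mask realization (weight mask, then node mask).

    An inactive mechanism (scalar rho = 0, or node_drop_prob = 0)
    consumes no draws from the stream, so the scheme is stream-for-stream
    identical to plain DropOut when only node dropout is active, and to
    plain DropConnect when only weight dropping is active.
    """
    if _rho_is_off(spec.weight_drop_prob):
        weight_mask = np.ones(weights.shape)
    else:
        weight_mask = sample_weight_mask(weights.shape, spec.weight_drop_prob, rng)
    n_out = _n_output_units(weights)
    if spec.node_drop_prob == 0.0:
        node_mask = np.ones(n_out)
    else:
        node_mask = sample_node_mask(n_out, spec.node_drop_prob, rng)
    weak_mask = weak_weight_mask(weights, spec.weak_rule)
    return StochasticMaskSet(node_mask, weight_mask, weak_mask, seed_state)


def effective_weights(
    weights: np.ndarray, masks: StochasticMaskSet, spec: DropWeakSpec
) -> MaskedWeightView:
    """W ⊙ weight_mask ⊙ weak_mask, with inverted-scaling compensation.

    The weak mask never receives compensation: it is a deterministic
    zeroing, not a Bernoulli thinning.
    """
    if masks.weight_mask.shape != weights.shape or masks.weak_mask.shape != weights.shape:
        raise ValueError("mask shape does not match weight shape")
    eff = weights * masks.weight_mask * masks.weak_mask
    if spec.scale_mode == "inverted":
        rho = np.asarray(spec.weight_drop_prob, dtype=float)
        keep = 1.0 - rho
        scale = np.where(keep > 0, 1.0 / np.where(keep > 0, keep, 1.0), 1.0)
        eff = eff * scale
    return MaskedWeightView(eff)


def _node_scale(spec: DropWeakSpec) -> float:
    if spec.scale_mode == "inverted" and spec.node_drop_prob < 1.0:
        return 1.0 / (1.0 - spec.node_drop_prob)
    return 1.0


def apply_dropweak(
    weights: np.ndarray,
    inputs: np.ndarray,
    masks: StochasticMaskSet,
    spec: DropWeakSpec,
    bias: np.ndarray | None = None,
    stride: int = 1,
    pad: int = 1,
) -> np.ndarray:
    """One masked weight application (pre-activation).

    Dense weights ``(n_in, n_out)`` with inputs ``(N, n_in)`` give an
    affine output ``(N, n_out)``; conv kernels ``(C_out, C_in, kh, kw)``
    with inputs ``(N, C_in, H, W)`` give a cross-correlation output, the
    node mask acting per output channel. With all masks at 1 and
    ``scale_mode='none'`` the result is bit-identical to the dense pass.
    """
    view = effective_weights(weights, masks, spec)
    nscale = _node_scale(spec)
    if weights.ndim == 2:
        if inputs.ndim != 2 or inputs.shape[1] != weights.shape[0]:
            raise ValueError("input shape does not conform to dense weights")
        out = inputs @ view.effective_weights
        if bias is not None:
            out = out + bias
        return out * (masks.node_mask * nscale)
    out = conv2d_forward(inputs, view.effective_weights, bias, stride=stride, pad=pad)
    return out * (masks.node_mask * nscale)[None, :, None, None]


def mc_activation_estimate(
    weights: np.ndarray,
    inputs: np.ndarray,
    spec: DropWeakSpec,
    n_samples: int,
    rng: np.random.Generator,
    bias: np.ndarray | None = None,
    stride: int = 1,
    pad: int = 1,
) -> np.ndarray:
    """Monte-Carlo mean of ``n_samples`` independent masked applications.

    Under inverted scaling this converges to the deterministic dense
    output by the law of large numbers.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    acc: np.ndarray | None = None
    for _ in range(n_samples):
        masks = sample_mask_set(weights, spec, rng)
        out = apply_dropweak(weights, inputs, masks, spec, bias=bias, stride=stride, pad=pad)
        acc = out if acc is None else acc + out
    assert acc is not None
    return acc / n_samples


def magnitude_inverse_rho(weights: np.ndarray, rho_max: float) -> np.ndarray:
    """Per-weight drop schedule: smaller |w| gets a higher drop probability.

    rho_ij = rho_max * (rank-percentile of -|w_ij|), ties broken by flat
    index, so the weakest weight has rho ~= rho_max and the strongest 0.
    """
    if not 0.0 <= rho_max <= 1.0:
        raise ValueError("rho_max must lie in [0, 1]")
    w = np.asarray(weights, dtype=float)
    n = w.size
    if n == 1:
        return np.zeros_like(w)
    order = np.lexsort((np.arange(n), np.abs(w).ravel()))
    ranks = np.empty(n)
    ranks[order] = np.arange(n - 1, -1, -1)  # smallest |w| -> highest rank
    return (rho_max * ranks / (n - 1)).reshape(w.shape)
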