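"""Low-level 2-D cross-correlation primitives (im2col / col2im).

Shared by the masking core (for masked convolution application) and the
network layers. Layout conventions: images are ``(N, C, H, W)``; kernels
are ``(C_out, C_in, kh, kw)``; cross-correlation (no kernel flip), a
single integer stride, edge-replicate padding. Replicate (not zero)
padding matters here: on standardized images a zero pad is a strong
artificial feature at the border, which both hurts the classifier and
plants spurious attention-map peaks along the image edge.
"""

from __future__ import annotations

import numpy as np

__all__ = ["im2col", "col2im", "conv2d_forward", "out_size"]


def out_size(h: int, w: int, kh: int, kw: int, stride: int, pad: int) -> tuple[int, int]:
    return (h + 2 * pad - kh) // stride + 1, (w + 2 * pad - kw) // stride + 1


def im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int) -> np.ndarray:
    """Unfold ``(N, C, H, W)`` into ``(N * Ho * Wo, C * kh * kw)`` patches."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)), mode="edge")
    windows = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride, :, :]  # (N, C, Ho, Wo, kh, kw)
    ho, wo = windows.shape[2], windows.shape[3]
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
    return np.ascontiguousarray(cols)


def col2im(
    dcols: np.ndarray,
    x_shape: tuple[int, int, int, int],
    kh: int,
    kw: int,
    stride: int,
    pad: int,
) -> np.ndarray:
    """Adjoint of :func:`im2col`: scatter-add patch gradients back to images."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho, wo = out_size(h, w, kh, kw, stride, pad)
    buf = np.zeros((n, c * hp * wp), dtype=dcols.dtype)

    # flat index (within one sample) of every element of every patch
    ci, ki, kj = np.meshgrid(np.arange(c), np.arange(kh), np.arange(kw), indexing="ij")
    patch_flat = (ci * hp * wp + ki * wp + kj).reshape(1, -1)  # (1, C*kh*kw)
    oi, oj = np.meshgrid(np.arange(ho) * stride, np.arange(wo) * stride, indexing="ij")
    origin = (oi * wp + oj).reshape(-1, 1)  # (Ho*Wo, 1)
    idx = (origin + patch_flat).reshape(-1)  # per-sample scatter targets

    d = dcols.reshape(n, ho * wo * c * kh * kw)
    for i in range(n):  # np.add.at over the sample axis in one shot is slower
        buf[i] = np.bincount(idx, weights=d[i], minlength=c * hp * wp)
    buf = buf.reshape(n, c, hp, wp)
    if pad:
        # adjoint of edge-replicate padding: fold pad-strip gradients
        # onto the edge pixels (rows first, then columns, so corners
        # accumulate correctly)
        buf[:, :, pad, :] += buf[:, :, :pad, :].sum(axis=2)
        buf[:, :, hp - pad - 1, :] += buf[:, :, hp - pad :, :].sum(axis=2)
        buf = buf[:, :, pad : hp - pad, :]
        buf[:, :, :, pad] += buf[:, :, :, :pad].sum(axis=3)
        buf[:, :, :, wp - pad - 1] += buf[:, :, :, wp - pad :].sum(axis=3)
        buf = buf[:, :, :, pad : wp - pad]
    return buf


def conv2d_forward(
    x: np.ndarray, kernels: np.ndarray, bias: np.ndarray | None = None, stride: int = 1, pad: int = 1
) -> np.ndarray:
    """Plain dense cross-correlation; used for masked-weight application."""
    c_out, c_in, kh, kw = kernels.shape
    n, c, h, w = x.shape
    if c != c_in:
        raise ValueError(f"input has {c} channels, kernels expect {c_in}")
    ho, wo = out_size(h, w, kh, kw, stride, pad)
    cols = im2col(x, kh, kw, stride, pad)
    out = cols @ kernels.reshape(c_out, -1).T
    if bias is not None:
        out = out + bias
    return out.reshape(n, ho, wo, c_out).transpose(0, 3, 1, 2)
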