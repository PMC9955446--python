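"""Grad-CAM class-attention maps, with Monte-Carlo averaging.

Channel weights are the spatial average of the gradient of the
pre-SoftMax *score margin* of the target class — its logit minus the
mean of the other logits — with respect to a convolutional feature map;
the map is the ReLU of the weight-sum of the channels, bilinearly
upsampled to input size and max-normalized. The margin rather than the
raw logit is used because SoftMax probabilities are invariant to
common-mode logit shifts: features that raise every class score equally
carry no class evidence, yet they dominate raw-logit maps and drag the
peak off the discriminative region. ``mc_gradcam`` averages the
*pre-normalization* maps of T stochastic passes (fresh DropWeak/DropOut
masks per pass) before normalizing, preserving relative magnitudes
across passes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import zoom

from .model import ResidualClassifier
from .rng import substream

__all__ = ["GradCamMap", "gradcam", "mc_gradcam", "write_heatmap"]


@dataclass
class GradCamMap:
    heat: np.ndarray  # H x W in [0,1]; max = 1 unless identically 0
    target_class: int
    source_layer: str
    n_mc: int = 1


def _raw_cam(
    model: ResidualClassifier,
    image: np.ndarray,
    target_class: int,
    layer: str,
    stochastic: bool,
    rng: np.random.Generator | None,
) -> np.ndarray:
    logits = model.forward_logits(image[None] if image.ndim == 2 else image, stochastic, rng)
    if not 0 <= target_class < logits.shape[1]:
        raise ValueError(f"target_class {target_class} out of range")
    acts = model.stage_output(layer)
    if acts.ndim != 4:
        raise ValueError(f"stage {layer!r} is not a convolutional feature map")
    # gradient of the score margin z_c - mean(z_other): common-mode
    # components cancel, matching what SoftMax actually responds to
    n_classes = logits.shape[1]
    dlogits = np.full_like(logits, -1.0 / (n_classes - 1))
    dlogits[:, target_class] = 1.0
    dacts = model.backward_logits(dlogits, stop_at=layer)
    model.zero_grad()  # attention maps must not pollute training gradients
    weights = dacts.mean(axis=(2, 3))  # 1 x C
    cam = np.maximum((weights[:, :, None, None] * acts).sum(axis=1), 0.0)[0]
    h, w = model.cfg.input_size
    return zoom(cam, (h / cam.shape[0], w / cam.shape[1]), order=1)


def _normalize(raw: np.ndarray) -> np.ndarray:
    peak = raw.max()
    return raw / peak if peak > 0 else np.zeros_like(raw)


def gradcam(
    model: ResidualClassifier, image: np.ndarray, target_class: int, layer: str | None = None
) -> GradCamMap:
    """Single deterministic-pass attention map for ``target_class``."""
    layer = layer or model.default_cam_layer
    raw = _raw_cam(model, image, target_class, layer, stochastic=False, rng=None)
    return GradCamMap(_normalize(raw), target_class, layer, n_mc=1)


def mc_gradcam(
    model: ResidualClassifier,
    image: np.ndarray,
    target_class: int,
    layer: str | None = None,
    T: int = 25,
    seed: int = 0,
) -> GradCamMap:
    """Mean of T per-pass raw maps under fresh stochastic masks."""
    if T < 1:
        raise ValueError("T must be >= 1")
    layer = layer or model.default_cam_layer
    acc = None
    for t in range(T):
        rng = substream(seed, "cam-pass", t)
        raw = _raw_cam(model, image, target_class, layer, stochastic=True, rng=rng)
        acc = raw if acc is None else acc + raw
    return GradCamMap(_normalize(acc / T), target_class, layer, n_mc=T)


def write_heatmap(
    cam: GradCamMap, out_dir: str | Path, stem: str = "gradcam", image: np.ndarray | None = None
) -> Path:
    """8-bit grayscale heat PNG (+ optional overlay PNG) with JSON sidecar."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    heat8 = np.round(cam.heat * 255).astype(np.uint8)
    path = out / f"{stem}.png"
    iio.imwrite(path, heat8)
    if image is not None:
        gray = np.clip(image, 0, 1)
        rgb = np.stack([np.clip(gray + 0.6 * cam.heat, 0, 1), gray, gray], axis=-1)
        iio.imwrite(out / f"{stem}_overlay.png", np.round(rgb * 255).astype(np.uint8))
    (out / f"{stem}.json").write_text(
        json.dumps(
            {"target_class": cam.target_class, "layer": cam.source_layer, "n_mc": cam.n_mc},
            indent=1,
        )
    )
    return path
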