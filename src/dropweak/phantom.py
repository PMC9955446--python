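"""Synthetic CT-like phantom datasets with ground truth.

Generates grayscale patches containing a single lung-nodule analog on a
textured background, at desk scale (default 64x64, 1 mm ~ 1 pixel so the
clinically reported 3-30 mm nodule range maps to 3-30 px):

* **benign**: a small smooth disc (diameters from the lower range);
* **malignant**: a larger disc whose boundary is deformed by low-order
  radial harmonics — a spiculation analog;
* **background**: spatially correlated Gaussian texture plus a radial
  vignette and additive pixel noise.

Two knobs mirror the two uncertainty sources the estimators probe:
``label_noise_rate`` flips labels independently (an aleatoric source;
the clean label is retained), and :func:`generate_ood` regenerates the
*same* nodules over shifted background statistics (covariate shift, an
epistemic source, labels untouched).

Everything is a pure function of the spec's seed: the same spec yields
a bit-identical dataset.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .rng import substream

__all__ = [
    "SyntheticSpec",
    "OODShift",
    "SyntheticSample",
    "SyntheticDataset",
    "generate_dataset",
    "generate_ood",
    "write_dataset",
    "load_npz_bundle",
]


@dataclass(frozen=True)
class OODShift:
    """Covariate-shift parameters for epistemic probing."""

    texture_sd_factor: float = 2.0
    invert_vignette: bool = False
    intensity_offset: float = 0.0


@dataclass(frozen=True)
class SyntheticSpec:
    n_images: int = 2000
    image_size: int = 64
    benign_diameter_range: tuple[float, float] = (3.0, 9.0)
    malignant_diameter_range: tuple[float, float] = (12.0, 30.0)
    benign_irregularity: float = 0.03
    malignant_irregularity: float = 0.25
    nodule_contrast: float = 0.35
    texture_sd: float = 0.08
    texture_scale: float = 3.0  # px; correlation length of the background
    vignette_strength: float = 0.25
    pixel_noise_sd: float = 0.04
    label_noise_rate: float = 0.05
    class_balance: float = 0.5  # malignant fraction
    seed: int = 0
    ood_shift: OODShift | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.label_noise_rate < 0.5:
            raise ValueError("label_noise_rate must lie in [0, 0.5)")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must lie in (0, 1)")
        for lo, hi in (self.benign_diameter_range, self.malignant_diameter_range):
            if lo <= 0 or hi < lo:
                raise ValueError("diameter ranges must be positive and ordered")
            if hi >= self.image_size:
                raise ValueError("nodule diameter exceeds the image size")
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")


@dataclass
class SyntheticSample:
    image: np.ndarray
    label: int  # 0 benign, 1 malignant (possibly noise-flipped)
    clean_label: int
    nodule_mask: np.ndarray
    metadata: dict


@dataclass
class SyntheticDataset:
    images: np.ndarray  # N x H x W in [0,1]
    labels: np.ndarray
    clean_labels: np.ndarray
    masks: np.ndarray  # N x H x W bool
    metadata: pd.DataFrame
    spec: SyntheticSpec

    def __len__(self) -> int:
        return len(self.images)

    def __getitem__(self, i: int) -> SyntheticSample:
        return SyntheticSample(
            self.images[i],
            int(self.labels[i]),
            int(self.clean_labels[i]),
            self.masks[i],
            self.metadata.iloc[i].to_dict(),
        )

    @property
    def samples(self) -> list[SyntheticSample]:
        return [self[i] for i in range(len(self))]


def _nodule(
    size: int, cx: float, cy: float, diameter: float, irregularity: float, rng: np.random.Generator
) -> np.ndarray:
    """Binary mask of one disc with radial-harmonic boundary deformation."""
    yy, xx = np.mgrid[0:size, 0:size]
    dx, dy = xx - cx, yy - cy
    r = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    radius = diameter / 2.0
    boundary = np.ones_like(theta) * radius
    for k in range(2, 6):  # low-order harmonics: lobulated/spiculated outline
        amp = irregularity * rng.uniform(0.3, 1.0) / (k - 1)
        phase = rng.uniform(0, 2 * np.pi)
        boundary = boundary + radius * amp * np.cos(k * theta + phase)
    return r <= boundary


def _background(
    size: int,
    rng: np.random.Generator,
    texture_sd: float,
    texture_scale: float,
    vignette_strength: float,
    invert_vignette: bool,
    intensity_offset: float,
) -> np.ndarray:
    field = gaussian_filter(rng.standard_normal((size, size)), sigma=texture_scale)
    sd = field.std()
    if sd > 0:
        field *= texture_sd / sd
    yy, xx = np.mgrid[0:size, 0:size]
    r2 = ((xx - size / 2) ** 2 + (yy - size / 2) ** 2) / (size / 2) ** 2
    vignette = vignette_strength * r2
    base = 0.40 + intensity_offset
    return base + field + (vignette if invert_vignette else -vignette)


def _generate(spec: SyntheticSpec, shift: OODShift | None) -> SyntheticDataset:
    size = spec.image_size
    label_rng = substream(spec.seed, "labels")
    noise_rng = substream(spec.seed, "label-noise")
    tex_factor = shift.texture_sd_factor if shift else 1.0
    invert = shift.invert_vignette if shift else False
    offset = shift.intensity_offset if shift else 0.0

    clean = (label_rng.random(spec.n_images) < spec.class_balance).astype(int)
    flips = noise_rng.random(spec.n_images) < spec.label_noise_rate
    labels = np.where(flips, 1 - clean, clean)

    images = np.empty((spec.n_images, size, size), dtype=float)
    masks = np.empty((spec.n_images, size, size), dtype=bool)
    meta = []
    for i in range(spec.n_images):
        # nodule geometry depends only on (seed, i): identical across OOD shifts
        g = substream(spec.seed, "nodule", i)
        lo, hi = (
            spec.malignant_diameter_range if clean[i] else spec.benign_diameter_range
        )
        diameter = g.uniform(lo, hi)
        irregularity = spec.malignant_irregularity if clean[i] else spec.benign_irregularity
        margin = diameter / 2 + 2
        cx, cy = g.uniform(margin, size - margin, size=2)
        mask = _nodule(size, cx, cy, diameter, irregularity, g)

        bg_rng = substream(spec.seed, "background", i)
        img = _background(
            size, bg_rng, spec.texture_sd * tex_factor, spec.texture_scale,
            spec.vignette_strength, invert, offset,
        )
        soft = gaussian_filter(mask.astype(float), sigma=0.7)  # soft nodule edge
        img = img + spec.nodule_contrast * soft
        img = img + substream(spec.seed, "pixel-noise", i).normal(0, spec.pixel_noise_sd, (size, size))
        images[i] = np.clip(img, 0.0, 1.0)
        # ground truth is the nodule's rendered support: every pixel where
        # it contributes >= 2% of its contrast (the soft edge included),
        # i.e. the nodule as it actually appears in the image
        masks[i] = soft > 0.02
        meta.append({"diameter": diameter, "irregularity": irregularity, "cx": cx, "cy": cy})

    return SyntheticDataset(images, labels, clean.copy(), masks, pd.DataFrame(meta), spec)


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """In-distribution phantom dataset, fully determined by the spec."""
    return _generate(spec, spec.ood_shift)


def generate_ood(spec: SyntheticSpec, shift: OODShift) -> SyntheticDataset:
    """Same nodules and labels as ``generate_dataset(spec)``, but with
    shifted background statistics (covariate shift only)."""
    return _generate(spec, shift)


def write_dataset(
    dataset: SyntheticDataset,
    out_dir: str | Path,
    splits: dict[str, np.ndarray] | None = None,
    write_png: bool = True,
) -> Path:
    """Write PNGs, a manifest CSV, an NPZ bundle and the spec echo.

    Manifest columns: ``path,label,clean_label,split,fold``.
    """
    import imageio.v3 as iio

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    split_of = np.full(len(dataset), "", dtype=object)
    if splits:
        for name, idx in splits.items():
            split_of[idx] = name
    rows = []
    for i in range(len(dataset)):
        rel = f"images/sample_{i:05d}.png"
        if write_png:
            iio.imwrite(out / rel, np.round(dataset.images[i] * 255).astype(np.uint8))
        rows.append(
            {
                "path": rel,
                "label": int(dataset.labels[i]),
                "clean_label": int(dataset.clean_labels[i]),
                "split": split_of[i],
                "fold": "",
            }
        )
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    np.savez_compressed(
        out / "bundle.npz",
        images=dataset.images,  # float64: the bundle round-trips losslessly
        labels=dataset.labels,
        clean_labels=dataset.clean_labels,
        masks=dataset.masks,
    )
    spec_dict = asdict(dataset.spec)
    (out / "spec.json").write_text(json.dumps(spec_dict, indent=1))
    return manifest


def load_npz_bundle(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    with np.load(path) as npz:
        return (
            npz["images"].astype(float),
            npz["labels"],
            npz["clean_labels"],
            npz["masks"],
        )
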