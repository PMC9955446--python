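"""Manifest-driven image loading.

A manifest is a CSV with columns ``path,label[,clean_label,split,fold]``;
paths are PNG files relative to the manifest's directory (8-bit
grayscale) or a single shared NPZ bundle. Pixel values are returned in
[0,1], row-major, origin top-left; row order is preserved.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_images", "read_manifest"]


def read_manifest(manifest: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(manifest)
    if frame.empty:
        raise ValueError(f"manifest {manifest} lists no images")
    if "path" not in frame.columns or "label" not in frame.columns:
        raise ValueError("manifest must have 'path' and 'label' columns")
    return frame


def read_images(manifest: str | Path) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Load every image listed in a manifest, in manifest order.

    Returns ``(images, labels, manifest_frame)`` with images as an
    ``(N, H, W)`` float array in [0,1] and integer-coded labels.
    """
    import imageio.v3 as iio

    manifest = Path(manifest)
    frame = read_manifest(manifest)
    root = manifest.parent
    images = []
    for rel in frame["path"]:
        path = root / rel
        if not path.exists():
            raise FileNotFoundError(f"manifest references missing image: {path}")
        arr = iio.imread(path)
        if arr.ndim != 2:
            raise ValueError(f"{path} is not a grayscale image (shape {arr.shape})")
        images.append(arr.astype(float) / 255.0)
    return np.stack(images), frame["label"].to_numpy(dtype=int), frame
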