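"""Dataset container and APTOS-dialect readers (image dir + labels CSV)."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image

__all__ = ["Dataset", "load_dataset", "resize_image"]


@dataclass
class Dataset:
    """Images, ordinal grades, and stable string ids."""

    images: np.ndarray          # (n, S, S, 3) float64 in [0, 1]
    labels: np.ndarray          # (n,) int
    ids: list[str]
    n_classes: int

    def __post_init__(self):
        if len(self.images) != len(self.labels) or len(self.images) != len(self.ids):
            raise ValueError("images, labels and ids must align")

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, idx: Sequence[int]) -> "Dataset":
        idx = np.asarray(idx, dtype=int)
        return Dataset(self.images[idx], self.labels[idx],
                       [self.ids[i] for i in idx], self.n_classes)


def resize_image(pixels: np.ndarray, size: int) -> np.ndarray:
    """Bilinear resize of an H x W x 3 float image to size x size."""
    pixels = np.asarray(pixels, dtype=np.float64)
    if pixels.shape[0] == size and pixels.shape[1] == size:
        return pixels
    im = Image.fromarray(np.round(np.clip(pixels, 0, 1) * 255).astype(np.uint8))
    im = im.resize((size, size), Image.BILINEAR)
    return np.asarray(im, dtype=np.float64) / 255.0


def load_dataset(images_dir: str, labels_csv: str, image_size: int,
                 n_classes: Optional[int] = None) -> Dataset:
    """Read `id_code,diagnosis` labels plus PNG/JPEG images, resized."""
    df = pd.read_csv(labels_csv)
    if not {"id_code", "diagnosis"} <= set(df.columns):
        raise ValueError("labels CSV must have columns id_code,diagnosis")
    img_dir = Path(images_dir)
    images, labels, ids = [], [], []
    for _, row in df.iterrows():
        stem = str(row["id_code"])
        path = None
        for ext in (".png", ".jpg", ".jpeg", ".PNG", ".JPG"):
            cand = img_dir / (stem + ext)
            if cand.exists():
                path = cand
                break
        if path is None:
            raise FileNotFoundError(f"no image found for id {stem!r}")
        arr = np.asarray(Image.open(path).convert("RGB"),
                         dtype=np.float64) / 255.0
        images.append(resize_image(arr, image_size))
        labels.append(int(row["diagnosis"]))
        ids.append(stem)
    labels = np.asarray(labels, dtype=int)
    if n_classes is None:
        n_classes = int(labels.max()) + 1
    return Dataset(np.stack(images), labels, ids, n_classes)
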