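"""Synthetic fundus-like images with graded lesion burden.

The generator emulates the gross appearance of retinal photographs —
a reddish-orange circular field of view on black background, smooth
intensity variation, dark curvilinear vessels — and superimposes three
lesion surrogates whose expected counts grow with the ordinal grade:

* microaneurysm-like bright dots (radius 1-2 px, +0.4 luminance),
  count ~ Poisson(lambda_ma * grade);
* exudate-like yellow blobs (radius 2-5 px, RGB shifted toward yellow),
  count ~ Poisson(lambda_ex * grade);
* hemorrhage-like dark blobs (radius 2-5 px, -0.5 luminance),
  count ~ Poisson(lambda_he * max(0, grade - 1)).

Grade 0 images therefore contain no lesions by construction. The grade
semantics are synthetic ordinal surrogates, not clinical DR criteria;
they exist so that every stage of the pipeline is exercisable and the
labels are learnable, not to claim photographic realism.

Default class proportions follow the APTOS2019 grade distribution
(1805/370/999/193/295 of 3662 images).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from PIL import Image
from scipy.ndimage import zoom as nd_zoom

__all__ = [
    "GradedImage", "DatasetSpec", "APTOS_CLASS_COUNTS", "APTOS_CLASS_PROBS",
    "LESION_RATES", "generate_image", "generate_arrays", "generate_dataset",
    "sample_grades", "field_of_view_mask",
]

APTOS_CLASS_COUNTS = (1805, 370, 999, 193, 295)
APTOS_CLASS_PROBS = tuple(c / sum(APTOS_CLASS_COUNTS) for c in APTOS_CLASS_COUNTS)

#: Poisson rates per grade step: (microaneurysms, exudates, hemorrhages)
LESION_RATES = (2.0, 1.5, 1.0)

_BASE_COLOR = np.array([0.72, 0.38, 0.12])  # reddish-orange fundus tint


@dataclass
class GradedImage:
    """H x W x 3 image in [0, 1] with its ordinal grade and lesion tally."""

    pixels: np.ndarray
    grade: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        p = np.asarray(self.pixels, dtype=np.float64)
        if p.ndim != 3 or p.shape[2] != 3:
            raise ValueError("pixels must be H x W x 3")
        if p.min() < 0 or p.max() > 1:
            raise ValueError("pixels must lie in [0, 1]")
        self.pixels = p


@dataclass
class DatasetSpec:
    """Recipe for a reproducible synthetic dataset."""

    n_images: int
    class_probs: tuple = APTOS_CLASS_PROBS
    image_size: int = 64
    seed: int = 0

    def __post_init__(self):
        probs = np.asarray(self.class_probs, dtype=np.float64)
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("class_probs must sum to 1")
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        self.class_probs = tuple(probs)

    @property
    def n_classes(self) -> int:
        return len(self.class_probs)


def field_of_view_mask(size: int) -> np.ndarray:
    """Boolean disc: True inside the inscribed circular field of view."""
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    dist = np.sqrt((yy - c) ** 2 + (xx - c) ** 2)
    return dist <= size / 2.0


def _smooth_noise(rng: np.random.Generator, size: int, cells: int = 5,
                  amplitude: float = 0.08) -> np.ndarray:
    """Perlin-like low-frequency field: coarse noise, bilinearly upsampled."""
    coarse = rng.uniform(-1.0, 1.0, size=(cells, cells))
    fine = nd_zoom(coarse, size / cells, order=1)[:size, :size]
    if fine.shape != (size, size):  # guard rounding of the zoom factor
        pad = np.zeros((size, size))
        pad[:fine.shape[0], :fine.shape[1]] = fine
        fine = pad
    return amplitude * fine


def _disc(size: int, cy: float, cx: float, radius: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2


def _draw_vessel(img: np.ndarray, rng: np.random.Generator) -> None:
    """Dark curvilinear stroke: a quadratic Bezier across the disc."""
    size = img.shape[0]
    c = (size - 1) / 2.0
    r = size / 2.0
    ang = rng.uniform(0, 2 * np.pi, size=2)
    p0 = np.array([c + 0.9 * r * np.sin(ang[0]), c + 0.9 * r * np.cos(ang[0])])
    p2 = np.array([c + 0.9 * r * np.sin(ang[1]), c + 0.9 * r * np.cos(ang[1])])
    p1 = np.array([c, c]) + rng.uniform(-0.4, 0.4, size=2) * r
    thickness = rng.uniform(0.6, 1.4)
    for t in np.linspace(0, 1, 4 * size):
        pt = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t ** 2 * p2
        mask = _disc(size, pt[0], pt[1], thickness)
        img[mask] = np.clip(img[mask] - 0.3 * 0.08, 0, 1)  # gentle repeated darkening


def _lesion_center(rng: np.random.Generator, size: int) -> tuple[float, float]:
    c = (size - 1) / 2.0
    r = 0.85 * size / 2.0
    while True:
        y, x = rng.uniform(-1, 1, size=2) * r
        if y * y + x * x <= r * r:
            return c + y, c + x


def generate_image(grade: int, size: int = 64,
                   rng: Optional[np.random.Generator] = None,
                   n_classes: int = 5) -> GradedImage:
    """Render one synthetic fundus-like image for the given grade."""
    if not (0 <= grade < n_classes):
        raise ValueError(f"grade {grade} outside 0..{n_classes - 1}")
    if rng is None:
        rng = np.random.default_rng(0)
    lam_ma, lam_ex, lam_he = LESION_RATES

    img = np.broadcast_to(_BASE_COLOR, (size, size, 3)).copy()
    img += _smooth_noise(rng, size)[..., None]
    for _ in range(int(rng.integers(2, 7))):
        _draw_vessel(img, rng)

    n_ma = int(rng.poisson(lam_ma * grade))
    n_ex = int(rng.poisson(lam_ex * grade))
    n_he = int(rng.poisson(lam_he * max(0, grade - 1)))
    for _ in range(n_ma):  # bright dots
        cy, cx = _lesion_center(rng, size)
        mask = _disc(size, cy, cx, rng.uniform(1.0, 2.0))
        img[mask] += 0.4
    for _ in range(n_ex):  # yellowish deposits
        cy, cx = _lesion_center(rng, size)
        mask = _disc(size, cy, cx, rng.uniform(2.0, 5.0))
        img[mask] += np.array([0.15, 0.25, -0.10])
    for _ in range(n_he):  # dark blots
        cy, cx = _lesion_center(rng, size)
        mask = _disc(size, cy, cx, rng.uniform(2.0, 5.0))
        img[mask] -= 0.5

    img = np.clip(img, 0.0, 1.0)
    img[~field_of_view_mask(size)] = 0.0
    return GradedImage(img, grade, meta={
        "microaneurysms": n_ma, "exudates": n_ex, "hemorrhages": n_he})


def _image_rng(seed: int, index: int) -> np.random.Generator:
    """One independent stream per image id, for reproducible generation."""
    return np.random.default_rng(np.random.SeedSequence([seed, index]))


def sample_grades(spec: DatasetSpec) -> np.ndarray:
    """Draw the per-image grades (multinomial over class_probs)."""
    label_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 10 ** 9]))
    return label_rng.choice(spec.n_classes, size=spec.n_images,
                            p=np.asarray(spec.class_probs)).astype(int)


def generate_arrays(spec: DatasetSpec) -> tuple[np.ndarray, np.ndarray, list[dict]]:
    """In-memory dataset: (images (n,S,S,3), grades (n,), per-image meta)."""
    grades = sample_grades(spec)
    images = np.empty((spec.n_images, spec.image_size, spec.image_size, 3))
    metas = []
    for i, g in enumerate(grades):
        gi = generate_image(int(g), spec.image_size, _image_rng(spec.seed, i),
                            n_classes=spec.n_classes)
        images[i] = gi.pixels
        metas.append(gi.meta)
    return images, grades.astype(int), metas


def generate_dataset(spec: DatasetSpec, out_dir: str) -> tuple[Path, Path]:
    """Write `images/<id>.png` plus `labels.csv` (`id_code,diagnosis`).

    The layout mirrors the APTOS2019 release so the same reader ingests
    real data if the user supplies it. Returns (images_dir, csv_path).
    """
    out = Path(out_dir)
    img_dir = out / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    images, grades, _ = generate_arrays(spec)
    csv_path = out / "labels.csv"
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id_code", "diagnosis"])
        for i, g in enumerate(grades):
            name = f"syn_{i:05d}"
            arr = np.round(images[i] * 255.0).astype(np.uint8)
            Image.fromarray(arr).save(img_dir / f"{name}.png")
            writer.writerow([name, int(g)])
    return img_dir, csv_path
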