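"""Deterministic synthetic leaf-image fixtures.

Real nutrient-deficiency and disease datasets carry their class identity in
color and lesion motifs on the leaf surface. The generator emulates that at
toy scale: each class gets a base leaf hue from an evenly spaced hue wheel
plus a class-specific number and color of circular lesion blobs, drawn on a
textured soil-like background with additive Gaussian pixel noise. Classes
are therefore linearly separable from mean color alone — deliberately, so
that small-model overfit and protocol tests are meaningful.

Identical spec + seed reproduces bit-identical images.
"""

from __future__ import annotations

import colorsys
import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = ["SyntheticSpec", "generate_images", "generate_dataset"]


@dataclass(frozen=True)
class SyntheticSpec:
    n_classes: int = 8
    images_per_class: int = 50
    image_size: int = 256
    noise_sd: float = 8.0            # additive Gaussian noise, 0..255 intensity units
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.images_per_class < 1:
            raise ValueError("images_per_class must be >= 1")
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def class_names(self) -> list[str]:
        return [f"class_{c:02d}" for c in range(self.n_classes)]


def _class_palette(n_classes: int) -> list[dict]:
    """Per-class motif parameters: leaf hue, lesion color and blob count."""
    palette = []
    for c in range(n_classes):
        hue = c / n_classes
        leaf = np.array(colorsys.hsv_to_rgb(hue, 0.65, 0.70)) * 255.0
        lesion = np.array(colorsys.hsv_to_rgb((hue + 0.5) % 1.0, 0.85, 0.85)) * 255.0
        palette.append({"leaf": leaf, "lesion": lesion, "n_blobs": 1 + c % 4})
    return palette


def _render(size: int, motif: dict, rng: np.random.Generator, noise_sd: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    cx, cy = size / 2, size / 2

    # textured brownish background
    bg = np.array([120.0, 105.0, 80.0])
    img = bg[None, None, :] + 18.0 * np.sin(2 * np.pi * xx / (size / 5))[:, :, None] \
        + 12.0 * np.cos(2 * np.pi * yy / (size / 7))[:, :, None]

    # leaf ellipse with jittered axes and tilt
    a = size * rng.uniform(0.30, 0.38)
    b = size * rng.uniform(0.18, 0.26)
    theta = rng.uniform(0, np.pi)
    xr = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
    yr = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
    inside = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
    shade = 1.0 - 0.25 * ((xr / a) ** 2 + (yr / b) ** 2)
    img[inside] = motif["leaf"][None, :] * shade[inside, None]

    # class-specific lesion blobs on the leaf
    for _ in range(motif["n_blobs"]):
        r = size * rng.uniform(0.04, 0.08)
        ox = cx + rng.uniform(-0.5, 0.5) * a
        oy = cy + rng.uniform(-0.5, 0.5) * b
        blob = (xx - ox) ** 2 + (yy - oy) ** 2 <= r ** 2
        img[blob & inside] = motif["lesion"]

    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def generate_images(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """All fixture images in memory: (N, S, S, 3) uint8 plus integer labels,
    ordered class-major then image index (deterministic)."""
    rng = np.random.default_rng(spec.seed)
    palette = _class_palette(spec.n_classes)
    images, labels = [], []
    for c in range(spec.n_classes):
        for _ in range(spec.images_per_class):
            images.append(_render(spec.image_size, palette[c], rng, spec.noise_sd))
            labels.append(c)
    return np.stack(images), np.asarray(labels, dtype=np.int64)


def generate_dataset(spec: SyntheticSpec, out_dir: str | Path) -> list[tuple[Path, int]]:
    """Write the fixture as a class-per-subfolder PNG tree plus a
    ``manifest.csv`` of (path, label) rows; returns the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    images, labels = generate_images(spec)
    names = spec.class_names()
    manifest: list[tuple[Path, int]] = []
    i = 0
    for c in range(spec.n_classes):
        cls_dir = out_dir / names[c]
        cls_dir.mkdir(exist_ok=True)
        for j in range(spec.images_per_class):
            path = cls_dir / f"img_{j:04d}.png"
            Image.fromarray(images[i]).save(path)
            manifest.append((path, c))
            i += 1
    with open(out_dir / "manifest.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "label"])
        for path, label in manifest:
            writer.writerow([path.relative_to(out_dir).as_posix(), label])
    return manifest
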