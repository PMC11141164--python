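"""Seeded phantom segmentation datasets.

Generates lesion-like binary phantoms (noisy ellipse blobs on a darker
background) and organ-like multi-label phantoms (disjoint regions with
distinct intensity bands), with exact ground-truth masks by
construction.  Everything is driven by a single seed so every stage of
the pipeline is testable without external data.

Intensities are floats in [0, 1] in memory and 8-bit grayscale on disk;
masks store raw integer labels (no palette scaling).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from PIL import Image


class GenerationError(RuntimeError):
    pass


@dataclass
class PhantomSpec:
    """Recipe for a phantom dataset.

    Radius bounds are fractions of the image side; ``noise_sigma`` is the
    standard deviation of additive Gaussian noise on [0, 1] intensities.
    """

    n_images: int = 16
    img_size: int = 64
    mode: Literal["binary", "multiclass"] = "binary"
    n_classes: int = 2
    blob_count: tuple[int, int] = (1, 3)
    blob_radius: tuple[float, float] = (0.08, 0.25)
    noise_sigma: float = 0.03
    texture: bool = False
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.blob_radius
        if hi >= 0.5:
            raise ValueError("blob radius must stay below half the image")
        if lo <= 0 or lo > hi:
            raise ValueError("invalid blob radius range")
        if self.mode == "multiclass" and self.n_classes < 3:
            raise ValueError("multiclass phantoms need n_classes >= 3")
        if self.img_size < 8:
            raise ValueError("img_size too small")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("blob_count", "blob_radius"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _ellipse_mask(size: int, rng: np.random.Generator, r_lo: float, r_hi: float,
                  margin: float = 0.0) -> np.ndarray:
    ry = rng.uniform(r_lo, r_hi) * size
    rx = rng.uniform(r_lo, r_hi) * size
    theta = rng.uniform(0, np.pi)
    cy = rng.uniform(margin + ry, size - margin - ry)
    cx = rng.uniform(margin + rx, size - margin - rx)
    yy, xx = np.mgrid[0:size, 0:size]
    y, x = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = x * ct + y * st
    v = -x * st + y * ct
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def _render(mask_levels: np.ndarray, spec: PhantomSpec,
            rng: np.random.Generator) -> np.ndarray:
    """Map integer labels to intensity bands, add texture and noise."""
    k = max(int(mask_levels.max()), 1)
    image = np.full(mask_levels.shape, 0.2)
    for label in range(1, k + 1):
        image[mask_levels == label] = 0.2 + 0.6 * label / k
    if spec.texture:
        freq = rng.uniform(2, 5, size=2)
        phase = rng.uniform(0, 2 * np.pi, size=2)
        yy, xx = np.mgrid[0:spec.img_size, 0:spec.img_size] / spec.img_size
        image = image + 0.05 * np.sin(2 * np.pi * freq[0] * yy + phase[0]) \
                      * np.sin(2 * np.pi * freq[1] * xx + phase[1])
    if spec.noise_sigma > 0:
        image = image + rng.normal(0, spec.noise_sigma, image.shape)
    return np.clip(image, 0.0, 1.0)


def make_binary_phantoms(spec: PhantomSpec) -> list[tuple[np.ndarray, np.ndarray]]:
    """Lesion-like phantoms: 1-3 bright ellipse blobs on a dark background."""
    if spec.mode != "binary":
        raise ValueError("spec.mode must be 'binary'")
    rng = np.random.default_rng(spec.seed)
    out = []
    for _ in range(spec.n_images):
        n_blobs = rng.integers(spec.blob_count[0], spec.blob_count[1] + 1)
        mask = np.zeros((spec.img_size, spec.img_size), dtype=bool)
        for _ in range(n_blobs):
            mask |= _ellipse_mask(spec.img_size, rng, *spec.blob_radius)
        if not mask.any():  # pragma: no cover - radius bounds prevent this
            raise GenerationError("generated an empty foreground")
        image = _render(mask.astype(np.int32), spec, rng)
        out.append((image.astype(np.float32), mask.astype(np.uint8)))
    return out


def make_multiclass_phantoms(spec: PhantomSpec, max_retries: int = 200
                             ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Organ-like phantoms: K-1 disjoint regions with distinct intensities."""
    if spec.mode != "multiclass":
        raise ValueError("spec.mode must be 'multiclass'")
    rng = np.random.default_rng(spec.seed)
    out = []
    for _ in range(spec.n_images):
        mask = np.zeros((spec.img_size, spec.img_size), dtype=np.uint8)
        for label in range(1, spec.n_classes):
            placed = False
            for _ in range(max_retries):
                cand = _ellipse_mask(spec.img_size, rng, *spec.blob_radius)
                if not (cand & (mask > 0)).any():
                    mask[cand] = label
                    placed = True
                    break
            if not placed:
                raise GenerationError(
                    f"could not place region {label} without overlap after "
                    f"{max_retries} retries; reduce blob_radius or n_classes")
        image = _render(mask.astype(np.int32), spec, rng)
        out.append((image.astype(np.float32), mask))
    return out


def make_phantoms(spec: PhantomSpec) -> list[tuple[np.ndarray, np.ndarray]]:
    if spec.mode == "binary":
        return make_binary_phantoms(spec)
    return make_multiclass_phantoms(spec)


# -- disk layout: root/{images,masks}/NNNN.png -------------------------

def write_dataset(dataset, directory) -> None:
    root = Path(directory)
    (root / "images").mkdir(parents=True, exist_ok=True)
    (root / "masks").mkdir(parents=True, exist_ok=True)
    for i, (image, mask) in enumerate(dataset):
        stem = f"{i:04d}.png"
        img8 = np.round(np.clip(image, 0, 1) * 255).astype(np.uint8)
        Image.fromarray(img8, mode="L").save(root / "images" / stem)
        Image.fromarray(mask.astype(np.uint8), mode="L").save(root / "masks" / stem)


def read_dataset(directory, n_classes: int | None = None
                 ) -> list[tuple[np.ndarray, np.ndarray]]:
    root = Path(directory)
    img_dir, mask_dir = root / "images", root / "masks"
    if not img_dir.is_dir() or not mask_dir.is_dir():
        raise FileNotFoundError(f"{root} must contain images/ and masks/")
    out = []
    for img_path in sorted(img_dir.glob("*.png")):
        mask_path = mask_dir / img_path.name
        if not mask_path.exists():
            raise FileNotFoundError(f"missing mask for {img_path.name}")
        image = np.asarray(Image.open(img_path).convert("L"), dtype=np.float32) / 255.0
        mask = np.asarray(Image.open(mask_path), dtype=np.int64)
        if n_classes is not None and mask.max() >= n_classes:
            raise ValueError(
                f"{mask_path.name} contains label {mask.max()} >= n_classes={n_classes}")
        out.append((image, mask))
    if not out:
        raise FileNotFoundError(f"no images found under {img_dir}")
    return out


def split_dataset(dataset, ratio: float = 0.75, seed: int = 0):
    """Seeded shuffle split; default 3:1 train/test."""
    if len(dataset) < 4:
        raise ValueError("need at least 4 items to split")
    order = np.random.default_rng(seed).permutation(len(dataset))
    n_train = int(round(len(dataset) * ratio))
    train = [dataset[i] for i in order[:n_train]]
    test = [dataset[i] for i in order[n_train:]]
    return train, test
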