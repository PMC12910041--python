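"""Synthetic three-class histology-texture image generator.

Emulates the *structure* of a balanced three-class H&E lung-histopathology
benchmark (benign / adenocarcinoma / squamous cell carcinoma): RGB images on
a pink–purple stain-like background carrying class-conditional texture
primitives. No claim of histological realism is made — the contract is purely
parametric class separation under a single ``separability`` knob.

Every primitive is an anisotropic Gaussian spot with a continuous "ring"
parameter, so the three classes live on a shared parameter manifold:

* density   — expected number of primitives per image,
* elongation — aspect-ratio excess of the spot (0 = round),
* ringness  — morph from solid blob (0) to annulus (1).

Class offsets on these parameters are scaled by ``separability``; at
separability 0 the three classes draw from identical distributions, so no
classifier can beat chance, while at high separability class 0 shows sparse
round blobs, class 1 medium-density annuli and class 2 dense elongated
streaks. Generation is fully deterministic given the config seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "ConfigurationError",
    "SynthConfig",
    "LabeledImageSet",
    "DEFAULT_CLASS_NAMES",
    "generate_split",
    "generate_dataset",
    "write_image_directory",
    "make_paired_correctness",
]

DEFAULT_CLASS_NAMES = (
    "Lung_Adenocarcinoma",
    "Lung_Benign_Tissue",
    "Lung_Squamous_Cell_Carcinoma",
)

_SPLIT_INDEX = {"train": 0, "val": 1, "test": 2}

# Background (eosin-pink) and primitive (hematoxylin-purple) palette anchors.
_BACKGROUND_RGB = np.array([0.90, 0.72, 0.83])
_PRIMITIVE_RGB = np.array([0.42, 0.26, 0.58])

# Base texture parameters and per-class offsets (scaled by separability).
_BASE_DENSITY = 22.0          # expected primitives per 64x64 image
_DENSITY_DELTA = (-0.60, 0.0, 0.85)
_BASE_ELONGATION = 0.35
_ELONGATION_DELTA = (-0.35, 0.0, 1.30)
_BASE_RINGNESS = 0.30
_RINGNESS_DELTA = (-0.30, 0.65, -0.15)


class ConfigurationError(ValueError):
    """A config field violates its documented range."""


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic generator.

    ``separability`` in [0, 1] scales between-class texture differences;
    ``noise_sd`` is additive Gaussian pixel noise in [0, 1] intensity units;
    ``palette_jitter`` in [0, 1] scales per-image background hue perturbation.
    Identical configs produce bit-identical outputs.
    """

    n_per_class: int
    image_size: int = 64
    separability: float = 0.9
    noise_sd: float = 0.05
    palette_jitter: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ConfigurationError(f"n_per_class must be >= 1, got {self.n_per_class}")
        if self.image_size < 16:
            raise ConfigurationError(f"image_size must be >= 16, got {self.image_size}")
        if not 0.0 <= self.separability <= 1.0:
            raise ConfigurationError(
                f"separability must lie in [0, 1], got {self.separability}"
            )
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not 0.0 <= self.palette_jitter <= 1.0:
            raise ConfigurationError(
                f"palette_jitter must lie in [0, 1], got {self.palette_jitter}"
            )


@dataclass(frozen=True)
class LabeledImageSet:
    """RGB images with integer class labels and a class-name table."""

    images: np.ndarray            # (N, H, W, 3) float32 in [0, 1]
    labels: np.ndarray            # (N,) int64 in 0..C-1
    class_names: tuple[str, ...]
    split_tag: str = ""

    def __post_init__(self) -> None:
        images = np.asarray(self.images, dtype=np.float32)
        labels = np.asarray(self.labels, dtype=np.int64)
        if images.ndim != 4 or images.shape[-1] != 3:
            raise ValueError(f"images must be (N, H, W, 3), got {images.shape}")
        if len(images) != len(labels):
            raise ValueError("images and labels have different lengths")
        if labels.size and (labels.min() < 0 or labels.max() >= len(self.class_names)):
            raise ValueError("labels outside 0..C-1")
        object.__setattr__(self, "images", images)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "class_names", tuple(self.class_names))

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def subset(self, indices: np.ndarray, split_tag: str | None = None) -> "LabeledImageSet":
        return LabeledImageSet(
            images=self.images[indices],
            labels=self.labels[indices],
            class_names=self.class_names,
            split_tag=self.split_tag if split_tag is None else split_tag,
        )


def _class_texture_params(class_id: int, separability: float) -> tuple[float, float, float]:
    density = _BASE_DENSITY * (1.0 + separability * _DENSITY_DELTA[class_id])
    elongation = max(0.0, _BASE_ELONGATION + separability * _ELONGATION_DELTA[class_id])
    ringness = float(np.clip(_BASE_RINGNESS + separability * _RINGNESS_DELTA[class_id], 0.0, 1.0))
    return density, elongation, ringness


def _render_image(
    rng: np.random.Generator,
    size: int,
    density: float,
    elongation: float,
    ringness: float,
    noise_sd: float,
    palette_jitter: float,
) -> np.ndarray:
    scale = size / 64.0
    bg = _BACKGROUND_RGB + palette_jitter * rng.uniform(-0.08, 0.08, size=3)
    img = np.broadcast_to(bg, (size, size, 3)).astype(np.float64).copy()

    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    n_prim = rng.poisson(density * scale * scale)
    for _ in range(n_prim):
        cx, cy = rng.uniform(0, size, size=2)
        theta = rng.uniform(0, np.pi)
        radius = rng.uniform(2.2, 4.2) * scale
        a = radius * (1.0 + elongation)  # major axis
        b = radius                        # minor axis
        dx, dy = xx - cx, yy - cy
        u = (dx * np.cos(theta) + dy * np.sin(theta)) / a
        v = (-dx * np.sin(theta) + dy * np.cos(theta)) / b
        r = np.sqrt(u * u + v * v)
        solid = np.exp(-(r * r) * 2.0)
        ring = np.exp(-((r - 1.0) ** 2) / (2 * 0.18**2))
        profile = (1.0 - ringness) * solid + ringness * ring
        alpha = 0.85 * profile
        img = img * (1.0 - alpha[..., None]) + _PRIMITIVE_RGB * alpha[..., None]

    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0).astype(np.float32)


def generate_split(
    cfg: SynthConfig,
    class_names: Sequence[str] = DEFAULT_CLASS_NAMES,
    split_tag: str = "train",
) -> LabeledImageSet:
    """Generate a balanced split: exactly ``cfg.n_per_class`` images per class.

    Class ids follow the order of ``class_names``. The RNG stream is derived
    from ``(cfg.seed, split_tag)`` so train/val/test splits from the same seed
    never share samples, while identical configs are bit-reproducible.
    """
    if len(class_names) != 3:
        raise ConfigurationError(f"exactly 3 class names required, got {len(class_names)}")
    split_key = _SPLIT_INDEX.get(split_tag, 9)
    images = []
    labels = []
    for class_id in range(3):
        density, elongation, ringness = _class_texture_params(class_id, cfg.separability)
        rng = np.random.default_rng(
            np.random.SeedSequence(cfg.seed, spawn_key=(split_key, class_id))
        )
        for _ in range(cfg.n_per_class):
            images.append(
                _render_image(
                    rng, cfg.image_size, density, elongation, ringness,
                    cfg.noise_sd, cfg.palette_jitter,
                )
            )
            labels.append(class_id)
    return LabeledImageSet(
        images=np.stack(images),
        labels=np.asarray(labels),
        class_names=tuple(class_names),
        split_tag=split_tag,
    )


def generate_dataset(
    cfg: SynthConfig,
    n_val_per_class: int,
    n_test_per_class: int,
    class_names: Sequence[str] = DEFAULT_CLASS_NAMES,
) -> tuple[LabeledImageSet, LabeledImageSet, LabeledImageSet]:
    """Convenience wrapper producing disjoint train/val/test splits.

    ``cfg.n_per_class`` sizes the training split; the validation and test
    splits reuse the same texture parameters with independent RNG streams.
    """
    train = generate_split(cfg, class_names, "train")
    val = generate_split(replace(cfg, n_per_class=n_val_per_class), class_names, "val")
    test = generate_split(replace(cfg, n_per_class=n_test_per_class), class_names, "test")
    return train, val, test


def write_image_directory(
    image_set: LabeledImageSet, root_path: str | Path
) -> list[dict]:
    """Write the set as 8-bit PNGs under one subdirectory per class.

    Returns the manifest (one dict per image: path, label, class_name, split)
    and writes it as ``manifest.csv`` under the root. An empty set produces an
    empty manifest and creates no directories.
    """
    import imageio.v3 as iio

    root = Path(root_path)
    manifest: list[dict] = []
    if len(image_set) == 0:
        return manifest
    try:
        root.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover
        raise OSError(f"cannot create output directory {root}: {exc}") from exc

    per_class_counter = [0] * image_set.n_classes
    for img, label in zip(image_set.images, image_set.labels):
        class_name = image_set.class_names[label]
        class_dir = root / class_name
        class_dir.mkdir(exist_ok=True)
        idx = per_class_counter[label]
        per_class_counter[label] += 1
        name = f"{image_set.split_tag or 'img'}_{idx:05d}.png"
        path = class_dir / name
        iio.imwrite(path, np.round(img * 255).astype(np.uint8))
        manifest.append(
            {
                "path": str(Path(class_name) / name),
                "label": int(label),
                "class_name": class_name,
                "split": image_set.split_tag,
            }
        )
    with open(root / "manifest.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["path", "label", "class_name", "split"])
        writer.writeheader()
        writer.writerows(manifest)
    return manifest


def make_paired_correctness(
    n: int, b: int, c: int, n11: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Build two boolean correctness vectors with an exact concordance table.

    Returns ``(correct_A, correct_B)`` of length ``n`` whose pairing yields
    exactly ``n11`` both-correct, ``b`` A-only-correct, ``c`` B-only-correct
    and ``n - n11 - b - c`` both-wrong samples, in a seed-shuffled order.
    Intended as a fixture generator for paired significance testing.
    """
    for name, value in (("n", n), ("b", b), ("c", c), ("n11", n11)):
        if value < 0:
            raise ValueError(f"{name} must be non-negative")
    n00 = n - n11 - b - c
    if n00 < 0:
        raise ValueError(f"infeasible counts: n11 + b + c = {n11 + b + c} exceeds n = {n}")
    correct_a = np.concatenate(
        [np.ones(n11 + b, dtype=bool), np.zeros(c + n00, dtype=bool)]
    )
    correct_b = np.concatenate(
        [np.ones(n11, dtype=bool), np.zeros(b, dtype=bool),
         np.ones(c, dtype=bool), np.zeros(n00, dtype=bool)]
    )
    order = np.random.default_rng(seed).permutation(n)
    return correct_a[order], correct_b[order]
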