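"""Image-directory loading, preprocessing, train-only augmentation,
stratified splitting and balanced class weights.

The preprocessing contract mirrors standard practice for CNN histopathology
pipelines: resize to a fixed square resolution with bilinear interpolation,
scale 8-bit intensities to [0, 1], and (train split only) apply random
horizontal flips, small rotations and zooms. Validation and test data pass
through bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .synthgen import ConfigurationError, LabeledImageSet

__all__ = [
    "AugmentConfig",
    "ClassWeightTable",
    "ContractViolation",
    "load_image_directory",
    "resize_and_scale",
    "augment_batch",
    "stratified_split",
    "balanced_class_weights",
    "steps_per_epoch",
]

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg"}


class ContractViolation(RuntimeError):
    """An operation was invoked outside its documented pipeline stage."""


@dataclass(frozen=True)
class AugmentConfig:
    """Train-time augmentation magnitudes.

    ``rotation_degrees`` is the canonical unit (default ±5°). Some training
    frameworks express rotation as a fraction of a full turn instead; setting
    ``rotation_as_fraction`` reinterprets the value that way (0.05 turn = 18°).
    """

    horizontal_flip: bool = True
    rotation_degrees: float = 5.0
    zoom_fraction: float = 0.05
    enabled: bool = True
    rotation_as_fraction: bool = False

    def __post_init__(self) -> None:
        if self.rotation_degrees < 0:
            raise ConfigurationError(
                f"rotation_degrees must be >= 0, got {self.rotation_degrees}"
            )
        if not 0.0 <= self.zoom_fraction <= 0.5:
            raise ConfigurationError(
                f"zoom_fraction must lie in [0, 0.5], got {self.zoom_fraction}"
            )

    @property
    def max_rotation_degrees(self) -> float:
        if self.rotation_as_fraction:
            return self.rotation_degrees * 360.0
        return self.rotation_degrees


@dataclass(frozen=True)
class ClassWeightTable:
    """Per-class loss multipliers w_c; the balanced heuristic w_c = N/(C n_c)
    satisfies sum_c n_c w_c = N exactly and gives all-ones for balanced data."""

    weights: dict[int, float]

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("all class weights must be positive")

    def as_array(self, n_classes: int | None = None) -> np.ndarray:
        n = n_classes if n_classes is not None else max(self.weights) + 1
        out = np.ones(n)
        for c, w in self.weights.items():
            out[c] = w
        return out


def load_image_directory(
    root_path: str | Path,
    class_order: Sequence[str] | None = None,
    split_tag: str = "",
) -> LabeledImageSet:
    """Load a one-subdirectory-per-class image tree into a LabeledImageSet.

    Labels follow sorted class-name order unless ``class_order`` is given.
    Intensities are scaled to [0, 1] floats. Undecodable files are collected
    and reported together in the raised error.
    """
    import imageio.v3 as iio

    root = Path(root_path)
    if not root.is_dir():
        raise IOError(f"not a directory: {root}")
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if class_order is not None:
        by_name = {d.name: d for d in class_dirs}
        missing = [n for n in class_order if n not in by_name]
        if missing:
            raise IOError(f"class directories not found under {root}: {missing}")
        class_dirs = [by_name[n] for n in class_order]
    if not class_dirs:
        raise IOError(f"no class subdirectories under {root}")

    images, labels, bad_files = [], [], []
    for label, class_dir in enumerate(class_dirs):
        files = sorted(
            p for p in class_dir.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES
        )
        for path in files:
            try:
                arr = iio.imread(path)
            except Exception:
                bad_files.append(str(path))
                continue
            if arr.ndim == 2:
                arr = np.stack([arr] * 3, axis=-1)
            images.append(arr[..., :3].astype(np.float32) / 255.0)
            labels.append(label)
    if bad_files:
        raise IOError(f"undecodable image files: {bad_files}")
    if not images:
        raise IOError(f"no decodable images under {root}")
    return LabeledImageSet(
        images=np.stack(images),
        labels=np.asarray(labels),
        class_names=tuple(d.name for d in class_dirs),
        split_tag=split_tag,
    )


def resize_and_scale(image_set: LabeledImageSet, target_size: int) -> LabeledImageSet:
    """Resize all images to target_size x target_size with bilinear
    interpolation, keeping intensities in [0, 1]."""
    from skimage.transform import resize

    if target_size < 8:
        raise ConfigurationError(f"target_size must be >= 8, got {target_size}")
    h, w = image_set.images.shape[1:3]
    if (h, w) == (target_size, target_size):
        return image_set
    resized = np.stack(
        [
            resize(img, (target_size, target_size), order=1, mode="reflect",
                   anti_aliasing=h > target_size, preserve_range=True)
            for img in image_set.images
        ]
    ).astype(np.float32)
    return LabeledImageSet(
        images=np.clip(resized, 0.0, 1.0),
        labels=image_set.labels,
        class_names=image_set.class_names,
        split_tag=image_set.split_tag,
    )


def _affine_warp(img: np.ndarray, angle_deg: float, zoom: float) -> np.ndarray:
    """Rotate by angle and zoom about the image centre in one bilinear warp
    with edge reflection (single interpolation, no black borders)."""
    from skimage.transform import AffineTransform, warp

    h, w = img.shape[:2]
    centre = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    # output -> input map: translate to centre, rotate back, unzoom, translate out
    tform = (
        AffineTransform(translation=-centre)
        + AffineTransform(rotation=-np.deg2rad(angle_deg), scale=1.0 / zoom)
        + AffineTransform(translation=centre)
    )
    return warp(img, tform.inverse, order=1, mode="reflect", preserve_range=True)


def augment_batch(
    images: np.ndarray,
    cfg: AugmentConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Independently flip (p = 0.5), rotate by U(-r, +r) degrees and zoom by
    U(1 - z, 1 + z) about the centre, with bilinear interpolation and edge
    reflection. Output shape equals input shape.

    Calling this on a non-training pipeline (cfg.enabled False) is a contract
    violation: validation and test images must stay bit-identical.
    """
    if not cfg.enabled:
        raise ContractViolation(
            "augment_batch called with augmentation disabled; validation/test "
            "data must not be augmented"
        )
    images = np.asarray(images)
    out = np.empty_like(images, dtype=np.float32)
    max_rot = cfg.max_rotation_degrees
    for i, img in enumerate(images):
        work = img
        if cfg.horizontal_flip and rng.random() < 0.5:
            work = work[:, ::-1]
        angle = rng.uniform(-max_rot, max_rot) if max_rot > 0 else 0.0
        zoom = rng.uniform(1 - cfg.zoom_fraction, 1 + cfg.zoom_fraction) \
            if cfg.zoom_fraction > 0 else 1.0
        if angle != 0.0 or zoom != 1.0:
            work = _affine_warp(work, angle, zoom)
        out[i] = work
    return np.clip(out, 0.0, 1.0)


def stratified_split(
    image_set: LabeledImageSet,
    fractions: tuple[float, float, float],
    seed: int = 0,
) -> tuple[LabeledImageSet, LabeledImageSet, LabeledImageSet]:
    """Split into disjoint train/val/test sets with per-class counts
    proportional to ``fractions`` (rounding error at most 1 per class)."""
    fractions = tuple(float(f) for f in fractions)
    if any(f < 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must be non-negative and sum to 1, got {fractions}")
    rng = np.random.default_rng(seed)
    buckets: list[list[int]] = [[], [], []]
    for class_id in range(image_set.n_classes):
        idx = np.nonzero(image_set.labels == class_id)[0]
        n_c = len(idx)
        n_positive_splits = sum(1 for f in fractions if f > 0)
        if n_c < n_positive_splits:
            raise ValueError(
                f"class {class_id} has {n_c} samples, fewer than the "
                f"{n_positive_splits} non-empty splits requested"
            )
        idx = rng.permutation(idx)
        cuts = [int(round(sum(fractions[: k + 1]) * n_c)) for k in range(3)]
        start = 0
        for k, cut in enumerate(cuts):
            buckets[k].extend(idx[start:cut].tolist())
            start = cut
    tags = ("train", "val", "test")
    return tuple(
        image_set.subset(np.asarray(sorted(b), dtype=int), split_tag=tag)
        for b, tag in zip(buckets, tags)
    )


def balanced_class_weights(labels: Sequence[int]) -> ClassWeightTable:
    """Balanced-heuristic weights w_c = N / (C * n_c).

    Every class 0..C-1 (C = max label + 1) must be present.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("cannot compute class weights from empty labels")
    n_classes = int(labels.max()) + 1
    counts = np.bincount(labels, minlength=n_classes)
    empty = np.nonzero(counts == 0)[0]
    if empty.size:
        raise ValueError(f"class {empty[0]} has no samples")
    n = labels.size
    return ClassWeightTable(
        weights={c: n / (n_classes * counts[c]) for c in range(n_classes)}
    )


def steps_per_epoch(n_samples: int, batch_size: int) -> int:
    """Number of optimizer steps per epoch: ceil(n_samples / batch_size)."""
    if n_samples <= 0 or batch_size <= 0:
        raise ValueError("n_samples and batch_size must be positive")
    return math.ceil(n_samples / batch_size)
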