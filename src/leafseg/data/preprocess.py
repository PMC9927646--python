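"""Preprocessing, augmentation and dataset splitting.

The pipeline mirrors standard practice for field-acquired leaf imagery:
median filtering against sensor noise, resizing to the working resolution,
exact right-angle rotation/mirror augmentation, and a seeded train/test
split that keeps all augmented variants of one base image in the same
partition so the test set never sees a transform of a training image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from scipy import ndimage

from .scenes import AnnotatedSample

DEFAULT_TRANSFORMS = ("identity", "rot90", "rot180", "rot270", "hflip")


def median_filter(image: np.ndarray, k: int = 3) -> np.ndarray:
    """Per-channel k x k median filter with reflective edge padding."""
    if k < 1 or k % 2 == 0:
        raise ValueError(f"median filter size must be odd and positive, got {k}")
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 raster, got shape {image.shape}")
    if k == 1:
        return image.copy()
    out = np.empty_like(image)
    for ch in range(3):
        out[:, :, ch] = ndimage.median_filter(image[:, :, ch], size=k, mode="reflect")
    return out


def resize_to(array: np.ndarray, size: int | tuple[int, int]) -> np.ndarray:
    """Resize an image (bilinear) or a mask (nearest neighbour).

    2-D arrays are treated as label masks and resized with nearest-neighbour
    interpolation, so the value set is preserved; 3-D arrays are treated as
    images and resized bilinearly.
    """
    h, w = (size, size) if isinstance(size, int) else size
    if h <= 0 or w <= 0:
        raise ValueError(f"target size must be positive, got {(h, w)}")
    if array.shape[:2] == (h, w):
        return array.copy()
    if array.ndim == 2:
        pil = Image.fromarray(array)
        return np.asarray(pil.resize((w, h), Image.NEAREST))
    pil = Image.fromarray(array)
    return np.asarray(pil.resize((w, h), Image.BILINEAR))


def _transform_array(arr: np.ndarray, name: str) -> np.ndarray:
    if name == "identity":
        return arr.copy()
    if name == "rot90":
        return np.rot90(arr, 1).copy()
    if name == "rot180":
        return np.rot90(arr, 2).copy()
    if name == "rot270":
        return np.rot90(arr, 3).copy()
    if name == "hflip":
        return np.fliplr(arr).copy()
    if name == "vflip":
        return np.flipud(arr).copy()
    raise ValueError(f"unknown transform {name!r}")


def augment(
    sample: AnnotatedSample, transforms=DEFAULT_TRANSFORMS
) -> list[AnnotatedSample]:
    """Apply each named transform identically to image and mask.

    90/270-degree rotations require a square sample.
    """
    h, w = sample.mask.shape
    out = []
    for name in transforms:
        if name in ("rot90", "rot270") and h != w:
            raise ValueError(f"{name} requires a square sample, got {h}x{w}")
        out.append(
            AnnotatedSample(
                image=_transform_array(sample.image, name),
                mask=_transform_array(sample.mask, name),
                provenance=sample.provenance,
                base_id=sample.base_id,
                transform=name,
            )
        )
    return out


@dataclass
class DatasetSplit:
    """A seeded train/test partition of annotated samples."""

    train: list[AnnotatedSample] = field(default_factory=list)
    test: list[AnnotatedSample] = field(default_factory=list)
    split_fraction: float = 0.8
    split_seed: int = 0


def split_dataset(
    samples: list[AnnotatedSample], fraction: float = 0.8, seed: int = 0
) -> DatasetSplit:
    """Deterministic shuffle-and-partition grouped by base sample.

    All augmented variants sharing a ``base_id`` land in the same partition.
    With equally-sized groups the train size is round(fraction * total).
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to split")
    groups: dict[str, list[AnnotatedSample]] = {}
    for i, s in enumerate(samples):
        key = s.base_id if s.base_id is not None else f"__solo_{i}"
        groups.setdefault(key, []).append(s)
    keys = sorted(groups)
    rng = np.random.default_rng(seed)
    rng.shuffle(keys)
    target = round(fraction * len(samples))
    train: list[AnnotatedSample] = []
    test: list[AnnotatedSample] = []
    for key in keys:
        bucket = train if len(train) < target else test
        bucket.extend(groups[key])
    if not train or not test:
        raise ValueError("split produced an empty partition; adjust fraction")
    return DatasetSplit(train=train, test=test, split_fraction=fraction,
                        split_seed=seed)
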