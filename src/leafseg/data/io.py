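"""PNG and manifest I/O for annotated samples.

Images are stored as RGB PNGs, masks as single-channel PNGs with values
{0, 1}.  A dataset manifest is one JSON file listing, per sample,
(image_path, mask_path, base_id, split).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image

from .preprocess import DatasetSplit
from .scenes import AnnotatedSample


def save_image(path: str | Path, image: np.ndarray):
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(image).save(path)


def save_mask(path: str | Path, mask: np.ndarray):
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(mask.astype(np.uint8), mode="L").save(path)


def load_image(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def load_mask(path: str | Path) -> np.ndarray:
    mask = np.asarray(Image.open(path).convert("L"))
    # tolerate 0/255 encodings from external annotation tools
    if mask.max() > 1:
        mask = (mask > 127).astype(np.uint8)
    return mask.astype(np.uint8)


def save_split(split: DatasetSplit, root: str | Path) -> Path:
    """Write images, masks and a manifest under ``root``; returns manifest path."""
    root = Path(root)
    entries = []
    for part, samples in (("train", split.train), ("test", split.test)):
        for i, s in enumerate(samples):
            stem = f"{part}_{i:05d}"
            image_path = root / "images" / f"{stem}.png"
            mask_path = root / "masks" / f"{stem}.png"
            save_image(image_path, s.image)
            save_mask(mask_path, s.mask)
            entries.append(
                {
                    "image_path": str(image_path.relative_to(root)),
                    "mask_path": str(mask_path.relative_to(root)),
                    "base_id": s.base_id,
                    "split": part,
                }
            )
    manifest = {
        "split_fraction": split.split_fraction,
        "split_seed": split.split_seed,
        "samples": entries,
    }
    manifest_path = root / "manifest.json"
    manifest_path.parent.mkdir(parents=True, exist_ok=True)
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest_path


def load_split(manifest_path: str | Path) -> DatasetSplit:
    """Load a dataset split from a manifest written by :func:`save_split`."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    split = DatasetSplit(
        split_fraction=manifest.get("split_fraction", 0.8),
        split_seed=manifest.get("split_seed", 0),
    )
    for entry in manifest["samples"]:
        sample = AnnotatedSample(
            image=load_image(root / entry["image_path"]),
            mask=load_mask(root / entry["mask_path"]),
            provenance=str(root / entry["image_path"]),
            base_id=entry.get("base_id"),
        )
        (split.train if entry["split"] == "train" else split.test).append(sample)
    return split
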