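"""Rasterisation of Labelme polygon annotations to label masks.

Only the stable core of the Labelme document is relied on:
``shapes[].{label, points, shape_type}``.  A pixel (r, c) is sampled at its
center (c + 0.5, r + 0.5) in the annotation's (x, y) coordinates; points on
a polygon edge count as inside.  Later shapes overwrite earlier ones.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import shapely

FOREGROUND_LABELS = frozenset({"leaf", "foreground", "fg", "1"})
BACKGROUND_LABELS = frozenset({"background", "bg", "0"})


class LabelmeParseError(ValueError):
    """Raised when an annotation document cannot be rasterised."""


def _load_document(annotation) -> dict:
    if isinstance(annotation, dict):
        return annotation
    if isinstance(annotation, str) and annotation.lstrip().startswith("{"):
        try:
            return json.loads(annotation)
        except json.JSONDecodeError as exc:
            raise LabelmeParseError(f"malformed JSON: {exc}") from exc
    if isinstance(annotation, (str, Path)):
        try:
            with open(annotation) as fh:
                return json.load(fh)
        except json.JSONDecodeError as exc:
            raise LabelmeParseError(f"malformed JSON in {annotation}: {exc}") from exc
    raise LabelmeParseError(f"unsupported annotation input: {type(annotation)!r}")


def rasterize_labelme(
    annotation,
    image_size: int | tuple[int, int],
    foreground_labels=FOREGROUND_LABELS,
    background_labels=BACKGROUND_LABELS,
) -> np.ndarray:
    """Rasterise polygon shapes into a {0,1} mask of ``image_size``.

    Parameters
    ----------
    annotation
        A Labelme document: parsed dict, JSON string, or path to a file.
    image_size
        Output raster size; int for a square canvas or an (H, W) pair.

    Returns
    -------
    numpy.ndarray of uint8, shape (H, W), values in {0, 1}.
    """
    doc = _load_document(annotation)
    if "shapes" not in doc or not isinstance(doc["shapes"], list):
        raise LabelmeParseError("document has no 'shapes' list")
    h, w = (image_size, image_size) if isinstance(image_size, int) else image_size
    mask = np.zeros((h, w), dtype=np.uint8)
    if not doc["shapes"]:
        return mask

    # pixel centers in annotation (x, y) coordinates
    xs = np.arange(w) + 0.5
    ys = np.arange(h) + 0.5
    gx, gy = np.meshgrid(xs, ys)

    for idx, shape in enumerate(doc["shapes"]):
        label = shape.get("label")
        where = f"shape #{idx} (label={label!r})"
        if shape.get("shape_type", "polygon") != "polygon":
            raise LabelmeParseError(
                f"{where}: unsupported shape_type {shape.get('shape_type')!r}"
            )
        if label in foreground_labels:
            value = 1
        elif label in background_labels:
            value = 0
        else:
            raise LabelmeParseError(f"{where}: unknown label")
        points = shape.get("points")
        if not points or len(points) < 3:
            raise LabelmeParseError(f"{where}: polygon needs >= 3 points")
        try:
            poly = shapely.Polygon([(float(x), float(y)) for x, y in points])
        except (TypeError, ValueError) as exc:
            raise LabelmeParseError(f"{where}: bad points: {exc}") from exc
        if not poly.is_valid:
            poly = poly.buffer(0)
        # intersects == inside-or-on-boundary for a point against a polygon
        inside = shapely.intersects_xy(poly, gx, gy)
        mask[inside] = value
    return mask
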