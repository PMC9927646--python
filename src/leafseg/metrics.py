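"""Segmentation evaluation: PA, MPA, MIoU and Boundary IoU.

The first three are computed from the pixel confusion matrix ``p``, where
``p[i, j]`` counts pixels of true class ``i`` predicted as class ``j``:

    PA   = sum_i p_ii / sum_ij p_ij
    MPA  = mean_i ( p_ii / sum_j p_ij )
    MIoU = mean_i ( p_ii / (sum_j p_ij + sum_j p_ji - p_ii) )

Classes absent from the truth (zero row, or zero union for IoU) are
excluded from the per-class means so single-class crops remain scored.

Boundary IoU restricts both masks to a band within ``d`` pixels of their
own contour before intersecting:

    BIoU = |(G_d ∩ G) ∩ (P_d ∩ P)| / |(G_d ∩ G) ∪ (P_d ∩ P)|

A foreground pixel belongs to the contour when any 4-neighbour is
background or lies outside the image.  As ``d`` grows past the image
diagonal, BIoU reduces exactly to the foreground IoU.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


class MetricError(ValueError):
    """Raised when a metric is undefined for the given inputs."""


def confusion(pred: np.ndarray, truth: np.ndarray, num_classes: int = 2) -> np.ndarray:
    """Pixel confusion matrix; entry (i, j) = # pixels of true i predicted j.

    Matrices are additive over images: summing per-image matrices gives the
    pooled dataset matrix.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise MetricError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    p, t = pred.ravel().astype(np.int64), truth.ravel().astype(np.int64)
    if p.size and (p.min() < 0 or p.max() >= num_classes):
        raise MetricError(f"prediction labels outside [0, {num_classes})")
    if t.size and (t.min() < 0 or t.max() >= num_classes):
        raise MetricError(f"truth labels outside [0, {num_classes})")
    counts = np.bincount(t * num_classes + p, minlength=num_classes * num_classes)
    return counts.reshape(num_classes, num_classes)


def pixel_accuracy(cm: np.ndarray) -> float:
    total = cm.sum()
    if total == 0:
        raise MetricError("pixel accuracy undefined for an empty confusion matrix")
    return float(np.trace(cm) / total)


def mean_pixel_accuracy(cm: np.ndarray) -> float:
    """Mean per-class recall over classes that occur in the truth."""
    rows = cm.sum(axis=1)
    present = rows > 0
    if not present.any():
        raise MetricError("no class has true pixels")
    recalls = np.diag(cm)[present] / rows[present]
    return float(recalls.mean())


def mean_iou(cm: np.ndarray) -> tuple[float, np.ndarray]:
    """MIoU and per-class IoU; classes with zero union are excluded (NaN)."""
    inter = np.diag(cm).astype(np.float64)
    union = cm.sum(axis=1) + cm.sum(axis=0) - inter
    per_class = np.full(cm.shape[0], np.nan)
    valid = union > 0
    if not valid.any():
        raise MetricError("all class unions are zero")
    per_class[valid] = inter[valid] / union[valid]
    return float(np.nanmean(per_class)), per_class


@dataclass
class BoundaryBand:
    """Pixels within ``d`` of a mask's contour."""

    band: np.ndarray
    d: int
    source: str = ""
    empty_foreground: bool = False


def mask_contour(mask: np.ndarray) -> np.ndarray:
    """Foreground pixels with a background 4-neighbour or on the image border."""
    fg = np.asarray(mask).astype(bool)
    padded = np.pad(fg, 1, constant_values=False)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    return fg & ~interior


def boundary_band(mask: np.ndarray, d: int, source: str = "") -> BoundaryBand:
    """All pixels whose Euclidean distance to the mask contour is <= d."""
    if d < 1:
        raise MetricError(f"boundary width d must be >= 1, got {d}")
    contour = mask_contour(mask)
    if not contour.any():
        if not np.asarray(mask).any():
            warnings.warn("empty foreground: boundary band is empty", stacklevel=2)
            return BoundaryBand(
                band=np.zeros_like(contour), d=d, source=source, empty_foreground=True
            )
        # all-foreground mask: every pixel touches the image border contour
        contour = np.zeros_like(contour)
        contour[0, :] = contour[-1, :] = contour[:, 0] = contour[:, -1] = True
    dist = ndimage.distance_transform_edt(~contour)
    return BoundaryBand(band=dist <= d, d=d, source=source)


def default_boundary_width(shape: tuple[int, int]) -> int:
    """The conventional band width: 2% of the image diagonal, at least 1."""
    diag = float(np.hypot(*shape))
    return max(1, round(0.02 * diag))


def boundary_iou(G: np.ndarray, P: np.ndarray, d: int | None = None) -> float:
    """Boundary IoU of truth ``G`` and prediction ``P`` with band width ``d``."""
    G = np.asarray(G).astype(bool)
    P = np.asarray(P).astype(bool)
    if G.shape != P.shape:
        raise MetricError(f"shape mismatch: {G.shape} vs {P.shape}")
    if d is None:
        d = default_boundary_width(G.shape)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        g_band = boundary_band(G, d, source="truth").band
        p_band = boundary_band(P, d, source="prediction").band
    g_set = g_band & G
    p_set = p_band & P
    union = (g_set | p_set).sum()
    if union == 0:
        return 1.0  # both boundary-restricted sets empty: identical
    return float((g_set & p_set).sum() / union)


@dataclass
class MetricsReport:
    """Dataset-level evaluation summary."""

    PA: float
    MPA: float
    MIoU: float
    BIoU: float
    per_class_iou: list = field(default_factory=list)
    d_used: int = 1
    n_images: int = 0

    def to_dict(self) -> dict:
        return {
            "PA": self.PA,
            "MPA": self.MPA,
            "MIoU": self.MIoU,
            "BIoU": self.BIoU,
            "per_class_iou": [
                None if np.isnan(v) else float(v) for v in self.per_class_iou
            ],
            "d_used": self.d_used,
            "n_images": self.n_images,
        }


def evaluate(
    preds: list[np.ndarray],
    truths: list[np.ndarray],
    d: int | None = None,
    num_classes: int = 2,
) -> MetricsReport:
    """Score a list of predictions against ground truth.

    PA/MPA/MIoU are computed from the confusion matrix pooled over all
    images; BIoU (whose band construction is inherently per-image) is the
    mean of per-image scores.
    """
    if len(preds) == 0 or len(preds) != len(truths):
        raise MetricError("need equal-length, non-empty prediction/truth lists")
    cm = np.zeros((num_classes, num_classes), dtype=np.int64)
    bious = []
    d_used = d
    for p, t in zip(preds, truths):
        cm += confusion(p, t, num_classes)
        if d_used is None:
            d_used = default_boundary_width(t.shape)
        bious.append(boundary_iou(t, p, d_used))
    miou, per_class = mean_iou(cm)
    return MetricsReport(
        PA=pixel_accuracy(cm),
        MPA=mean_pixel_accuracy(cm),
        MIoU=miou,
        BIoU=float(np.mean(bious)),
        per_class_iou=list(per_class),
        d_used=int(d_used),
        n_images=len(preds),
    )
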