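"""Procedural leaf scenes with paired segmentation masks.

Scenes emulate the five field conditions a leaf-phenotyping dataset exhibits:
normal leaves, spotted lesions, regional lesions, occluded blades and uneven
illumination.  The leaf silhouette is a star-convex region whose radius
follows a harmonic series r(theta) = R * (1 + sum_n a_n cos(n*theta + phi_n)),
clipped positive, which yields lobed leaf-like outlines with a controllable
boundary — the property the boundary-IoU metric is sensitive to.  The
background carries distractor blobs standing in for soil and neighbouring
leaves.

A scene type changes appearance only; the mask is identical across scene
types for a fixed seed, except occlusion, where occluded leaf pixels are
relabelled background.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np


class SceneType(str, Enum):
    NORMAL = "normal"
    SPOTTED_LESIONS = "spotted_lesions"
    REGIONAL_LESIONS = "regional_lesions"
    OCCLUDED = "occluded"
    UNEVEN_ILLUMINATION = "uneven_illumination"


class SceneSpecError(ValueError):
    """Raised for an invalid scene specification."""


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one generated scene.

    image_size must be a multiple of 32 so that five stride-2 stages divide
    the raster evenly.  occluder_fraction is the fraction of leaf pixels an
    occluder removes (only used by the ``occluded`` scene type).
    """

    scene_type: SceneType = SceneType.NORMAL
    image_size: int = 512
    leaf_lobes: int = 5
    lesion_count: int = 12
    occluder_fraction: float = 0.3
    illumination_gradient: tuple[float, float] = (0.55, 1.35)
    rng_seed: int = 0

    def __post_init__(self):
        try:
            object.__setattr__(self, "scene_type", SceneType(self.scene_type))
        except ValueError as exc:
            raise SceneSpecError(f"unknown scene type: {self.scene_type!r}") from exc
        if self.image_size < 32 or self.image_size % 32:
            raise SceneSpecError(
                f"image_size must be >= 32 and a multiple of 32, got {self.image_size}"
            )
        if not 0.0 <= self.occluder_fraction < 1.0:
            raise SceneSpecError(
                f"occluder_fraction must be in [0, 1), got {self.occluder_fraction}"
            )
        if self.leaf_lobes < 0 or self.lesion_count < 0:
            raise SceneSpecError("leaf_lobes and lesion_count must be non-negative")


@dataclass
class AnnotatedSample:
    """An RGB image with its per-pixel {0 background, 1 leaf} mask."""

    image: np.ndarray  # H x W x 3 uint8
    mask: np.ndarray  # H x W uint8, values in {0, 1}
    provenance: object = None
    base_id: str | None = None
    transform: str = "identity"

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError(
                f"image {self.image.shape[:2]} and mask {self.mask.shape} disagree"
            )
        values = np.unique(self.mask)
        if not np.isin(values, [0, 1]).all():
            raise ValueError(f"mask values must be in {{0,1}}, got {values}")


def _leaf_mask(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Star-convex lobed silhouette on the pixel grid."""
    s = spec.image_size
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64) + 0.5
    cy = s * (0.5 + 0.08 * rng.uniform(-1, 1))
    cx = s * (0.5 + 0.08 * rng.uniform(-1, 1))
    theta = np.arctan2(yy - cy, xx - cx)
    rho = np.hypot(yy - cy, xx - cx)
    base_r = s * rng.uniform(0.26, 0.34)
    n_harmonics = rng.integers(3, 8)  # 3..7 harmonics
    orders = list(rng.choice(np.arange(2, 9), size=n_harmonics, replace=False))
    if spec.leaf_lobes and spec.leaf_lobes not in orders:
        orders[0] = spec.leaf_lobes
    profile = np.ones_like(theta)
    for n in orders:
        amp = rng.uniform(0.04, 0.16) * (1.6 if n == spec.leaf_lobes else 1.0)
        phase = rng.uniform(0, 2 * np.pi)
        profile = profile + amp * np.cos(n * theta + phase)
    radius = np.clip(base_r * profile, s * 0.02, None)
    return (rho <= radius).astype(np.uint8)


def _blob(shape_hw, center, radius, rng) -> np.ndarray:
    """Soft-edged irregular blob used for distractors and lesions."""
    yy, xx = np.mgrid[0 : shape_hw[0], 0 : shape_hw[1]].astype(np.float64)
    theta = np.arctan2(yy - center[0], xx - center[1])
    wobble = 1.0 + 0.3 * np.cos(rng.integers(2, 6) * theta + rng.uniform(0, 2 * np.pi))
    return np.hypot(yy - center[0], xx - center[1]) <= radius * wobble


def _background(s: int, rng: np.random.Generator) -> np.ndarray:
    """Cluttered soil-toned backdrop with distractor blobs."""
    img = np.empty((s, s, 3))
    soil = np.array([112.0, 84.0, 56.0])
    img[:] = soil + rng.normal(0, 9, size=(s, s, 3))
    for _ in range(10):
        center = rng.uniform(0, s, size=2)
        radius = rng.uniform(0.04, 0.16) * s
        color = np.array(
            [rng.uniform(60, 130), rng.uniform(90, 150), rng.uniform(40, 90)]
        )
        blob = _blob((s, s), center, radius, rng)
        img[blob] = 0.5 * img[blob] + 0.5 * color
    return img


def _paint_leaf(img: np.ndarray, mask: np.ndarray, rng: np.random.Generator):
    s = mask.shape[0]
    leaf = np.array([52.0, 132.0, 58.0]) + rng.normal(0, 6, size=3)
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    shading = 1.0 + 0.15 * np.sin(2 * np.pi * (yy + xx) / (1.7 * s) + rng.uniform(0, 6))
    img[mask == 1] = (leaf[None, :] * shading[mask == 1, None]) + rng.normal(
        0, 5, size=(int(mask.sum()), 3)
    )


def _apply_lesions(img, mask, rng, count, regional: bool):
    """Brown lesion textures inside the leaf; appearance only."""
    s = mask.shape[0]
    fg = np.argwhere(mask == 1)
    if len(fg) == 0:
        return
    lesion_color = np.array([128.0, 92.0, 44.0])
    if regional:
        count, rad_lo, rad_hi = 1, 0.10, 0.20
    else:
        rad_lo, rad_hi = 0.01, 0.03
    for _ in range(count):
        center = fg[rng.integers(len(fg))].astype(np.float64)
        radius = rng.uniform(rad_lo, rad_hi) * s
        blob = _blob((s, s), center, radius, rng) & (mask == 1)
        img[blob] = 0.25 * img[blob] + 0.75 * (
            lesion_color + rng.normal(0, 8, size=3)
        )


def _apply_occlusion(img, mask, rng, fraction: float):
    """Remove ``fraction`` of leaf pixels under an occluder; relabels mask."""
    fg = np.argwhere(mask == 1)
    n_remove = int(round(fraction * len(fg)))
    if n_remove == 0:
        return
    if n_remove >= len(fg):
        raise SceneSpecError("occluder would remove every leaf pixel")
    anchor = fg[rng.integers(len(fg))].astype(np.float64)
    dist = np.hypot(fg[:, 0] - anchor[0], fg[:, 1] - anchor[1])
    order = np.argsort(dist, kind="stable")
    removed = fg[order[:n_remove]]
    occluder_color = np.array([70.0, 96.0, 48.0]) + rng.normal(0, 4, size=3)
    img[removed[:, 0], removed[:, 1]] = occluder_color + rng.normal(
        0, 6, size=(n_remove, 3)
    )
    mask[removed[:, 0], removed[:, 1]] = 0


def _apply_illumination(img, rng, lo_hi: tuple[float, float]):
    s = img.shape[0]
    lo, hi = lo_hi
    angle = rng.uniform(0, 2 * np.pi)
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    t = (np.cos(angle) * xx + np.sin(angle) * yy) / (s * np.hypot(1, 1))
    t = (t - t.min()) / (t.max() - t.min())
    img *= (lo + (hi - lo) * t)[:, :, None]


def generate_sample(spec: SceneSpec) -> AnnotatedSample:
    """Generate one scene; a pure function of ``spec`` (bit-reproducible).

    Independent child RNG streams drive the silhouette, the backdrop and the
    scene-type decoration, so masks agree across scene types at equal seeds.
    """
    seeds = np.random.SeedSequence(spec.rng_seed).spawn(3)
    rng_shape = np.random.default_rng(seeds[0])
    rng_paint = np.random.default_rng(seeds[1])
    rng_scene = np.random.default_rng(seeds[2])

    mask = _leaf_mask(spec, rng_shape)
    if mask.sum() == 0 or mask.sum() == mask.size:
        raise SceneSpecError("degenerate silhouette: mask lacks both classes")
    img = _background(spec.image_size, rng_paint)
    _paint_leaf(img, mask, rng_paint)

    st = spec.scene_type
    if st is SceneType.SPOTTED_LESIONS:
        _apply_lesions(img, mask, rng_scene, spec.lesion_count, regional=False)
    elif st is SceneType.REGIONAL_LESIONS:
        _apply_lesions(img, mask, rng_scene, spec.lesion_count, regional=True)
    elif st is SceneType.OCCLUDED:
        _apply_occlusion(img, mask, rng_scene, spec.occluder_fraction)
    elif st is SceneType.UNEVEN_ILLUMINATION:
        _apply_illumination(img, rng_scene, spec.illumination_gradient)

    if mask.sum() == 0:
        raise SceneSpecError("no foreground left after occlusion")
    image = np.clip(img, 0, 255).astype(np.uint8)
    return AnnotatedSample(
        image=image,
        mask=mask,
        provenance=spec,
        base_id=f"{spec.scene_type.value}-{spec.rng_seed}",
    )


def generate_dataset(
    n_per_scene: int,
    image_size: int = 512,
    seed: int = 0,
    scene_types: tuple[SceneType, ...] = tuple(SceneType),
) -> list[AnnotatedSample]:
    """Generate ``n_per_scene`` samples of every scene type."""
    samples = []
    counter = 0
    for st in scene_types:
        for _ in range(n_per_scene):
            spec = SceneSpec(
                scene_type=st,
                image_size=image_size,
                rng_seed=seed * 1_000_003 + counter,
            )
            samples.append(generate_sample(spec))
            counter += 1
    return samples
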