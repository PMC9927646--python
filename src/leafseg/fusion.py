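"""Composite-backbone fusion: wiring assisting features into the lead.

Every assisting stage A_i feeds the parallel and all lower lead stages
(L_k for k <= i).  Each edge carries a 1x1 projection to the target stage's
input channel count, batch normalisation, and bilinear resizing to the
target's spatial size.  Where several sources meet one lead stage, each
source channel is scaled by a weight-contribution factor derived from its
projection batch norm,

    omega_i = |gamma_i| / sum_j |gamma_j|,

normalised across the sources feeding that site, and the scaled features
are element-summed.  The absolute value keeps the factors non-negative
convex weights (batch-norm scales may be negative); channels the network
learns to be unimportant receive small gamma and are suppressed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .backbones import AssistBackbone, FeaturePyramid, LeadBackbone, PlanError
from .backbones.assist import ASSIST_STAGE_IDS
from .backbones.lead import LEAD_STAGE_IDS
from .nn import BatchNorm2d, Conv2d, Module, Tensor, bilinear_resize


@dataclass(frozen=True)
class CompositeTopology:
    """Directed assist->lead edge set; acyclic because the assisting
    backbone runs to completion before the lead consumes any injection."""

    edges: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        for src, dst in self.edges:
            if src not in ASSIST_STAGE_IDS or dst not in LEAD_STAGE_IDS:
                raise PlanError(f"unknown stage in edge {src}->{dst}")

    @staticmethod
    def dense() -> "CompositeTopology":
        """Default: A_i feeds every lead stage L_k with k <= i."""
        edges = tuple(
            (f"A{i}", f"L{k}") for i in range(5) for k in range(i + 1)
        )
        return CompositeTopology(edges)

    @staticmethod
    def parallel_only() -> "CompositeTopology":
        return CompositeTopology(tuple((f"A{i}", f"L{i}") for i in range(5)))

    @staticmethod
    def empty() -> "CompositeTopology":
        return CompositeTopology(())

    @staticmethod
    def from_strings(specs: list[str]) -> "CompositeTopology":
        """Parse edges given as "Ai->Lk" strings."""
        edges = []
        for s in specs:
            try:
                src, dst = s.split("->")
            except ValueError as exc:
                raise PlanError(f"bad edge spec {s!r}") from exc
            edges.append((src.strip(), dst.strip()))
        return CompositeTopology(tuple(edges))

    def to_strings(self) -> list[str]:
        return [f"{src}->{dst}" for src, dst in self.edges]

    def targets(self) -> dict[str, list[str]]:
        by_target: dict[str, list[str]] = {}
        for src, dst in self.edges:
            by_target.setdefault(dst, []).append(src)
        return by_target


@dataclass
class FusionWeights:
    """Batch-norm scale factors and the importances derived from them.

    ``gamma`` has shape (S,) or (S, C): one entry (or channel vector) per
    source feeding a fusion site.  ``omega`` is |gamma| normalised across
    sources, so it is non-negative and sums to one over the source axis.
    """

    gamma: np.ndarray
    site: str = ""
    omega: np.ndarray = field(init=False)

    def __post_init__(self):
        self.gamma = np.asarray(self.gamma, dtype=np.float64)
        mag = np.abs(self.gamma)
        total = mag.sum(axis=0, keepdims=True)
        if np.any(total == 0):
            warnings.warn(
                f"all-zero batch-norm scales at fusion site {self.site!r}; "
                "falling back to uniform importances",
                stacklevel=2,
            )
            uniform = np.full_like(mag, 1.0 / mag.shape[0])
            self.omega = np.where(total == 0, uniform, mag / np.where(total == 0, 1, total))
        else:
            self.omega = mag / total


def bn_weighted_fuse(features: list, weights: FusionWeights):
    """Scale each source by its importance and element-sum.

    ``features`` is a list of S equally-shaped rasters (NCHW tensors or
    arrays); ``weights.omega`` is broadcast per source (shape (S,)) or per
    source and channel (shape (S, C)).
    """
    if len(features) != weights.omega.shape[0]:
        raise ValueError(
            f"{len(features)} features but {weights.omega.shape[0]} weight rows"
        )
    shapes = {tuple(f.shape) for f in features}
    if len(shapes) != 1:
        raise ValueError(f"features must share a shape, got {shapes}")
    out = None
    for f, om in zip(features, weights.omega):
        om_arr = np.asarray(om, dtype=np.float64)
        scale = om_arr.reshape(1, -1, 1, 1) if om_arr.ndim else om_arr
        term = f * Tensor(scale) if isinstance(f, Tensor) else f * scale
        out = term if out is None else out + term
    return out


class FusionEdge(Module):
    """1x1 projection + batch norm for one assist->lead edge."""

    def __init__(self, in_ch, out_ch, rng):
        super().__init__()
        self.proj = Conv2d(in_ch, out_ch, 1, bias=False, rng=rng)
        self.bn = BatchNorm2d(out_ch)

    def forward(self, x, target_hw):
        return bilinear_resize(self.bn(self.proj(x)), target_hw)


def project_resize(feature, target_channels: int, target_hw, seed: int = 0):
    """Functional 1x1 projection + bilinear resize (spec-level operation)."""
    if target_channels < 1 or min(target_hw) < 1:
        raise ValueError("target channels and size must be positive")
    conv = Conv2d(feature.shape[1], target_channels, 1,
                  rng=np.random.default_rng(seed))
    return bilinear_resize(conv(feature), tuple(target_hw))


class CompositeFusion(Module):
    """All fusion edges of a topology, grouped by target lead stage."""

    def __init__(self, topology: CompositeTopology, assist_channels: dict,
                 lead_input_channels: dict, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.topology = topology
        self.edges: dict[str, FusionEdge] = {}
        for src, dst in topology.edges:
            self.edges[f"{src}->{dst}"] = FusionEdge(
                assist_channels[src], lead_input_channels[dst], rng
            )

    def _site_sources(self) -> dict[str, list[str]]:
        return self.topology.targets()

    def _omega_tensors(self, sources: list[str], dst: str) -> list[Tensor]:
        """Per-source importance vectors |gamma| / sum|gamma| as graph tensors."""
        gammas = [self.edges[f"{src}->{dst}"].bn.gamma.abs() for src in sources]
        total = gammas[0]
        for g in gammas[1:]:
            total = total + g
        eps = 1e-12  # guards the all-zero corner without leaving the graph
        return [g / (total + eps) for g in gammas]

    def injections(self, assist_pyramid: FeaturePyramid,
                   lead_input_hw: dict[str, tuple[int, int]]) -> dict[str, Tensor]:
        """Assemble the additive injection for every targeted lead stage."""
        out: dict[str, Tensor] = {}
        for dst, sources in self._site_sources().items():
            target_hw = lead_input_hw[dst]
            feats = [
                self.edges[f"{src}->{dst}"](assist_pyramid[src].tensor, target_hw)
                for src in sources
            ]
            omegas = self._omega_tensors(sources, dst)
            total = None
            for f, om in zip(feats, omegas):
                term = f * om.reshape(1, -1, 1, 1)
                total = term if total is None else total + term
            out[dst] = total
        return out

    def site_weights(self) -> dict[str, FusionWeights]:
        """Current fusion weights per site (target lead stage)."""
        sites = {}
        for dst, sources in self._site_sources().items():
            gamma = np.stack(
                [self.edges[f"{src}->{dst}"].bn.gamma.data for src in sources]
            )
            sites[dst] = FusionWeights(gamma=gamma, site=dst)
        return sites


def composite_forward(lead: LeadBackbone, assist: AssistBackbone,
                      fusion: CompositeFusion, image):
    """Run assist fully, inject its fused features, then run the lead.

    Returns the (lead_pyramid, assist_pyramid) pair.
    """
    assist_pyramid = assist(image)
    h, w = image.shape[2], image.shape[3]
    lead_input_hw = {
        sid: (h // s, w // s) for sid, s in lead.stage_input_strides().items()
    }
    injections = fusion.injections(assist_pyramid, lead_input_hw)
    lead_pyramid = lead(image, injections)
    return lead_pyramid, assist_pyramid
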