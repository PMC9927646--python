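"""Xception-style lead backbone with five stages L0-L4.

The entry stage L0 uses plain 3x3 convolutions; L1-L4 bodies are built from
3x3 separable convolutions with 1x1-convolution residual shortcuts that
perform channel lift and residual transfer.  Spatial reduction lives in the
first separable convolution of a stage (stride 2), giving cumulative strides
(2, 4, 8, 8, 16): the L4 tap is the output-stride-16 feature the ASPP head
consumes, while the deep L3 stack (16 repeats at full width by default)
refines features without further downsampling.

Each stage accepts an optional additive injection on its input, which is how
the composite fusion wires assisting-backbone features into the lead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..nn import BatchNorm2d, Conv2d, Module, SeparableConv2d
from .base import FeaturePyramid

LEAD_STAGE_IDS = ("L0", "L1", "L2", "L3", "L4")


class PlanError(ValueError):
    """Raised for an inconsistent backbone stage plan."""


@dataclass(frozen=True)
class StagePlan:
    stage_id: str
    repeats: int
    out_channels: int
    stride: int
    block_kind: str  # "conv" | "separable_conv"

    def __post_init__(self):
        if self.stride not in (1, 2):
            raise PlanError(f"{self.stage_id}: stride must be 1 or 2")
        if self.repeats < 1 or self.out_channels < 1:
            raise PlanError(f"{self.stage_id}: repeats/channels must be positive")
        if self.block_kind not in ("conv", "separable_conv"):
            raise PlanError(f"{self.stage_id}: unknown block kind {self.block_kind!r}")


def default_lead_plan(
    widths=(64, 128, 256, 728, 1024), l3_repeats: int = 16
) -> list[StagePlan]:
    """Full-size plan following the usual Xception width progression."""
    strides = (2, 2, 2, 1, 2)
    kinds = ("conv",) + ("separable_conv",) * 4
    repeats = (1, 1, 1, l3_repeats, 1)
    return [
        StagePlan(sid, r, c, s, k)
        for sid, r, c, s, k in zip(LEAD_STAGE_IDS, repeats, widths, strides, kinds)
    ]


def tiny_lead_plan() -> list[StagePlan]:
    """Desk-scale preset (<= 32 channels, two L3 repeats)."""
    return default_lead_plan(widths=(8, 16, 16, 24, 32), l3_repeats=2)


class ConvStage(Module):
    """Entry stage: two plain 3x3 conv-BN-ReLU layers, first one strided."""

    def __init__(self, in_ch, out_ch, stride, rng):
        super().__init__()
        mid = max(out_ch // 2, 1)
        self.conv1 = Conv2d(in_ch, mid, 3, stride=stride, padding=1, rng=rng)
        self.bn1 = BatchNorm2d(mid)
        self.conv2 = Conv2d(mid, out_ch, 3, padding=1, rng=rng)
        self.bn2 = BatchNorm2d(out_ch)

    def forward(self, x):
        x = self.bn1(self.conv1(x)).relu()
        return self.bn2(self.conv2(x)).relu()


class XceptionBlock(Module):
    """Two separable convs with a 1x1 shortcut for channel rise/stride."""

    def __init__(self, in_ch, out_ch, stride, rng):
        super().__init__()
        self.sep1 = SeparableConv2d(in_ch, out_ch, stride=stride, rng=rng)
        self.bn1 = BatchNorm2d(out_ch)
        self.sep2 = SeparableConv2d(out_ch, out_ch, rng=rng)
        self.bn2 = BatchNorm2d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.short_conv = Conv2d(in_ch, out_ch, 1, stride=stride, bias=False,
                                     rng=rng)
            self.short_bn = BatchNorm2d(out_ch)
        else:
            self.short_conv = None
            self.short_bn = None

    def forward(self, x):
        shortcut = x if self.short_conv is None else self.short_bn(self.short_conv(x))
        y = self.bn1(self.sep1(x)).relu()
        y = self.bn2(self.sep2(y))
        return (y + shortcut).relu()


class LeadStage(Module):
    def __init__(self, plan: StagePlan, in_ch: int, rng):
        super().__init__()
        self.plan = plan
        self.in_channels = in_ch
        if plan.block_kind == "conv":
            self.blocks = [ConvStage(in_ch, plan.out_channels, plan.stride, rng)]
            for _ in range(plan.repeats - 1):
                self.blocks.append(
                    ConvStage(plan.out_channels, plan.out_channels, 1, rng)
                )
        else:
            self.blocks = [XceptionBlock(in_ch, plan.out_channels, plan.stride, rng)]
            for _ in range(plan.repeats - 1):
                self.blocks.append(
                    XceptionBlock(plan.out_channels, plan.out_channels, 1, rng)
                )

    def forward(self, x):
        for block in self.blocks:
            x = block(x)
        return x


class LeadBackbone(Module):
    """Five-stage lead encoder with per-stage taps and input injections."""

    def __init__(self, plan: list[StagePlan], in_channels: int = 3,
                 rng: np.random.Generator | None = None):
        super().__init__()
        validate_lead_plan(plan)
        rng = rng or np.random.default_rng(0)
        self.plan = list(plan)
        self.in_channels = in_channels
        self.stages = []
        ch = in_channels
        for sp in plan:
            self.stages.append(LeadStage(sp, ch, rng))
            ch = sp.out_channels

    def stage_input_channels(self) -> dict[str, int]:
        return {st.plan.stage_id: st.in_channels for st in self.stages}

    def stage_input_strides(self) -> dict[str, int]:
        strides = {}
        cum = 1
        for sp in self.plan:
            strides[sp.stage_id] = cum
            cum *= sp.stride
        return strides

    def stage_output_channels(self) -> dict[str, int]:
        return {sp.stage_id: sp.out_channels for sp in self.plan}

    def forward(self, x, injections: dict | None = None) -> FeaturePyramid:
        injections = injections or {}
        unknown = set(injections) - set(LEAD_STAGE_IDS)
        if unknown:
            raise PlanError(f"injections reference unknown stages: {sorted(unknown)}")
        pyramid = FeaturePyramid()
        cum = 1
        for stage in self.stages:
            sid = stage.plan.stage_id
            if sid in injections:
                inj = injections[sid]
                if inj.shape != x.shape:
                    raise PlanError(
                        f"injection for {sid} has shape {inj.shape}, "
                        f"stage input is {x.shape}"
                    )
                x = x + inj
            x = stage(x)
            cum *= stage.plan.stride
            pyramid.add(sid, x, cum)
        return pyramid


def validate_lead_plan(plan: list[StagePlan]):
    if len(plan) != 5:
        raise PlanError(f"lead plan needs exactly 5 stages, got {len(plan)}")
    ids = tuple(sp.stage_id for sp in plan)
    if ids != LEAD_STAGE_IDS:
        raise PlanError(f"stage ids must be {LEAD_STAGE_IDS}, got {ids}")
    cum = 1
    for sp in plan:
        cum *= sp.stride
    if cum != 16:
        raise PlanError(f"cumulative stride at the L4 tap must be 16, got {cum}")


def build_lead(plan: list[StagePlan] | None = None, in_channels: int = 3,
               seed: int = 0) -> LeadBackbone:
    """Construct the lead backbone from a stage plan (default: full size)."""
    return LeadBackbone(plan or default_lead_plan(), in_channels,
                        np.random.default_rng(seed))


def forward_lead(backbone: LeadBackbone, image, injections=None) -> FeaturePyramid:
    """Run the lead backbone; ``injections`` maps stage id -> additive raster."""
    return backbone(image, injections)
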