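"""CoAtNet-style assisting backbone: convolution stem, MBConv stages,
relative-attention stages.

Stage ladder (cumulative strides 2, 4, 8, 16, 32):

* A0 — plain 3x3 convolution stem.
* A1, A2 — inverted-bottleneck MBConv blocks (1x1 expand, depthwise 3x3,
  1x1 project) with residual transfer, repeated 2 and 4 times by default.
* A3, A4 — relative self-attention + position-wise FFN blocks (repeats 8
  and 2), where the h x w x c raster is flattened to (h*w) x c tokens,
  scores are scaled dot products plus a translation-indexed relative bias,
  and the softmax-weighted values are reshaped back to a raster.

Downsampling inside MBConv lives in the depthwise convolution; inside the
attention stages a stride-2 average pool precedes the first block, with a
1x1 strided projection carrying the residual.  Pre-normalisation (layer
norm over channels) is applied before attention and FFN.  A global-pool +
fully-connected classifier tail exists only for standalone pre-training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ..nn import (
    BatchNorm2d,
    Conv2d,
    DepthwiseConv2d,
    LayerNorm,
    Linear,
    Module,
    Parameter,
    Tensor,
    avg_pool2d,
    softmax,
)
from .base import FeaturePyramid
from .lead import PlanError

ASSIST_STAGE_IDS = ("A0", "A1", "A2", "A3", "A4")


@dataclass(frozen=True)
class AssistPlan:
    """Stage widths, repeats and attention geometry of the assisting backbone."""

    widths: tuple[int, int, int, int, int] = (64, 96, 192, 384, 768)
    repeats: tuple[int, int, int, int] = (2, 4, 8, 2)  # A1..A4
    ffn_expansion: int = 4
    head_dim: int = 32
    input_size: int = 512  # grid the relative-bias tables are built for

    def __post_init__(self):
        if len(self.widths) != 5 or len(self.repeats) != 4:
            raise PlanError("assist plan needs 5 widths and 4 repeat counts")
        if self.ffn_expansion < 1:
            raise PlanError("ffn_expansion must be >= 1")
        for stage_width in self.widths[3:]:
            if stage_width % self.head_dim:
                raise PlanError(
                    f"attention width {stage_width} not divisible by head_dim "
                    f"{self.head_dim}"
                )
        if self.input_size < 32 or self.input_size % 32:
            raise PlanError("input_size must be >= 32 and a multiple of 32")

    def heads(self, stage_width: int) -> int:
        return stage_width // self.head_dim


def tiny_assist_plan(input_size: int = 64) -> AssistPlan:
    """Desk-scale preset with single-repeat stages and 8-channel heads."""
    return AssistPlan(
        widths=(8, 16, 16, 24, 32),
        repeats=(1, 1, 1, 1),
        head_dim=8,
        input_size=input_size,
    )


class ConvStem(Module):
    """A0: two 3x3 convolutions, the first with stride 2."""

    def __init__(self, in_ch, out_ch, rng):
        super().__init__()
        self.conv1 = Conv2d(in_ch, out_ch, 3, stride=2, padding=1, rng=rng)
        self.bn1 = BatchNorm2d(out_ch)
        self.conv2 = Conv2d(out_ch, out_ch, 3, padding=1, rng=rng)
        self.bn2 = BatchNorm2d(out_ch)

    def forward(self, x):
        x = self.bn1(self.conv1(x)).relu()
        return self.bn2(self.conv2(x)).relu()


class MBConvBlock(Module):
    """Inverted bottleneck: 1x1 expand -> depthwise 3x3 -> 1x1 project."""

    def __init__(self, in_ch, out_ch, stride, expansion=4, rng=None):
        super().__init__()
        if stride not in (1, 2):
            raise PlanError(f"MBConv stride must be 1 or 2, got {stride}")
        rng = rng or np.random.default_rng(0)
        hidden = in_ch * expansion
        self.pre_bn = BatchNorm2d(in_ch)
        self.expand = Conv2d(in_ch, hidden, 1, rng=rng)
        self.bn1 = BatchNorm2d(hidden)
        self.depthwise = DepthwiseConv2d(hidden, 3, stride=stride, padding=1, rng=rng)
        self.bn2 = BatchNorm2d(hidden)
        self.project = Conv2d(hidden, out_ch, 1, rng=rng)
        self.stride = stride
        if stride == 1 and in_ch == out_ch:
            self.short_conv = None
        else:
            self.short_conv = Conv2d(in_ch, out_ch, 1, rng=rng)

    def forward(self, x):
        if self.short_conv is None:
            shortcut = x
        else:
            pooled = avg_pool2d(x, 2) if self.stride == 2 else x
            shortcut = self.short_conv(pooled)
        y = self.pre_bn(x)
        y = self.bn1(self.expand(y)).relu()
        y = self.bn2(self.depthwise(y)).relu()
        y = self.project(y)
        return shortcut + y


def mbconv_block(x, in_ch: int, out_ch: int, stride: int, expansion: int = 4,
                 seed: int = 0):
    """Functional MBConv wrapper (fresh random weights; mainly for tests)."""
    block = MBConvBlock(in_ch, out_ch, stride, expansion,
                        np.random.default_rng(seed))
    return block(x)


def _relative_index(h: int, w: int) -> np.ndarray:
    """(h*w, h*w) lookup into a (2h-1)*(2w-1) translation-indexed table."""
    rows = np.repeat(np.arange(h), w)
    cols = np.tile(np.arange(w), h)
    dr = rows[:, None] - rows[None, :] + (h - 1)
    dc = cols[:, None] - cols[None, :] + (w - 1)
    return dr * (2 * w - 1) + dc


class RelAttention(Module):
    """Multi-head self-attention with a relative positional bias.

    The bias table is a trainable (heads, (2h-1)*(2w-1)) parameter built for
    ``grid_hw``; at other input sizes the table is bilinearly resampled (as a
    constant) to the required translation range.
    """

    def __init__(self, in_ch, out_ch, heads, head_dim=None, grid_hw=(8, 8),
                 rng=None):
        super().__init__()
        if head_dim is None:
            if in_ch % heads:
                raise PlanError(f"channels {in_ch} not divisible by heads {heads}")
            head_dim = in_ch // heads
        rng = rng or np.random.default_rng(0)
        self.heads, self.head_dim = heads, head_dim
        inner = heads * head_dim
        self.wq = Linear(in_ch, inner, bias=False, rng=rng)
        self.wk = Linear(in_ch, inner, bias=False, rng=rng)
        self.wv = Linear(in_ch, inner, bias=False, rng=rng)
        self.wo = Linear(inner, out_ch, rng=rng)
        self.grid_hw = tuple(grid_hw)
        h, w = self.grid_hw
        self.rel_bias = Parameter(np.zeros((heads, (2 * h - 1) * (2 * w - 1))))
        self._index_cache: dict[tuple[int, int], np.ndarray] = {}

    def _bias_for(self, h: int, w: int):
        key = (h, w)
        if key not in self._index_cache:
            self._index_cache[key] = _relative_index(h, w)
        idx = self._index_cache[key]
        h0, w0 = self.grid_hw
        if (h, w) == (h0, w0):
            return self.rel_bias[:, idx]  # trainable path
        # off-design size: resample the table bilinearly, used as a constant
        table = self.rel_bias.data.reshape(self.heads, 2 * h0 - 1, 2 * w0 - 1)
        zoom = ((2 * h - 1) / (2 * h0 - 1), (2 * w - 1) / (2 * w0 - 1))
        resampled = np.stack(
            [ndimage.zoom(t, zoom, order=1, grid_mode=True, mode="nearest")
             for t in table]
        )
        return Tensor(resampled.reshape(self.heads, -1)[:, idx])

    def forward(self, x):
        n, c, h, w = x.shape
        tokens = x.reshape(n, c, h * w).transpose(0, 2, 1)  # N, L, C
        L = h * w

        def split_heads(t):
            return t.reshape(n, L, self.heads, self.head_dim).transpose(0, 2, 1, 3)

        q = split_heads(self.wq(tokens))
        k = split_heads(self.wk(tokens))
        v = split_heads(self.wv(tokens))
        score = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.head_dim))
        score = score + self._bias_for(h, w)  # broadcast over batch
        attn = softmax(score, axis=-1)
        out = attn @ v  # N, heads, L, head_dim
        out = out.transpose(0, 2, 1, 3).reshape(n, L, self.heads * self.head_dim)
        out = self.wo(out)
        return out.transpose(0, 2, 1).reshape(n, -1, h, w)

    def attention_matrix(self, x) -> np.ndarray:
        """Row-stochastic softmax scores for the given input (diagnostics)."""
        n, c, h, w = x.shape
        tokens = x.reshape(n, c, h * w).transpose(0, 2, 1)
        L = h * w
        q = self.wq(tokens).reshape(n, L, self.heads, self.head_dim).transpose(0, 2, 1, 3)
        k = self.wk(tokens).reshape(n, L, self.heads, self.head_dim).transpose(0, 2, 1, 3)
        score = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.head_dim))
        score = score + self._bias_for(h, w)
        return softmax(score, axis=-1).data


def rel_attention(x, layer: RelAttention):
    """Functional relative-attention application (spec-level operation)."""
    return layer(x)


class FFN(Module):
    """Position-wise two-layer feed-forward expansion with residual."""

    def __init__(self, ch, expansion=4, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.fc1 = Linear(ch, ch * expansion, rng=rng)
        self.fc2 = Linear(ch * expansion, ch, rng=rng)

    def forward(self, x):
        n, c, h, w = x.shape
        tokens = x.reshape(n, c, h * w).transpose(0, 2, 1)
        y = self.fc2(self.fc1(tokens).relu())
        return x + y.transpose(0, 2, 1).reshape(n, c, h, w)


def ffn(x, expansion: int = 4, seed: int = 0):
    """Functional FFN wrapper (fresh random weights; mainly for tests)."""
    return FFN(x.shape[1], expansion, np.random.default_rng(seed))(x)


class AttentionBlock(Module):
    """Pre-norm relative attention + FFN, with pooled strided entry."""

    def __init__(self, in_ch, out_ch, stride, heads, head_dim, expansion,
                 grid_hw, rng):
        super().__init__()
        self.stride = stride
        self.norm1 = LayerNorm(in_ch)
        self.attn = RelAttention(in_ch, out_ch, heads, head_dim, grid_hw, rng)
        self.short_conv = (
            None if (stride == 1 and in_ch == out_ch)
            else Conv2d(in_ch, out_ch, 1, rng=rng)
        )
        self.norm2 = LayerNorm(out_ch)
        self.ffn = FFN(out_ch, expansion, rng)

    def forward(self, x):
        if self.stride == 2:
            x = avg_pool2d(x, 2)
        shortcut = x if self.short_conv is None else self.short_conv(x)
        y = shortcut + self.attn(self.norm1(x))
        return self.ffn(self.norm2(y))


class AssistBackbone(Module):
    """Five-stage assisting encoder with taps A0..A4 (strides 2..32)."""

    def __init__(self, plan: AssistPlan | None = None, in_channels: int = 3,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.plan = plan or AssistPlan()
        rng = rng or np.random.default_rng(0)
        p = self.plan
        w0, w1, w2, w3, w4 = p.widths
        self.stem = ConvStem(in_channels, w0, rng)
        self.stage1 = self._mbconv_stage(w0, w1, p.repeats[0], p, rng)
        self.stage2 = self._mbconv_stage(w1, w2, p.repeats[1], p, rng)
        grid3 = (p.input_size // 16, p.input_size // 16)
        grid4 = (p.input_size // 32, p.input_size // 32)
        self.stage3 = self._attn_stage(w2, w3, p.repeats[2], grid3, p, rng)
        self.stage4 = self._attn_stage(w3, w4, p.repeats[3], grid4, p, rng)

    @staticmethod
    def _mbconv_stage(in_ch, out_ch, repeats, plan, rng):
        blocks = [MBConvBlock(in_ch, out_ch, 2, plan.ffn_expansion, rng)]
        blocks += [
            MBConvBlock(out_ch, out_ch, 1, plan.ffn_expansion, rng)
            for _ in range(repeats - 1)
        ]
        return blocks

    @staticmethod
    def _attn_stage(in_ch, out_ch, repeats, grid_hw, plan, rng):
        heads = plan.heads(out_ch)
        blocks = [
            AttentionBlock(in_ch, out_ch, 2, heads, plan.head_dim,
                           plan.ffn_expansion, grid_hw, rng)
        ]
        blocks += [
            AttentionBlock(out_ch, out_ch, 1, heads, plan.head_dim,
                           plan.ffn_expansion, grid_hw, rng)
            for _ in range(repeats - 1)
        ]
        return blocks

    def stage_output_channels(self) -> dict[str, int]:
        return dict(zip(ASSIST_STAGE_IDS, self.plan.widths))

    def stage_strides(self) -> dict[str, int]:
        return dict(zip(ASSIST_STAGE_IDS, (2, 4, 8, 16, 32)))

    def forward(self, x) -> FeaturePyramid:
        h, w = x.shape[2], x.shape[3]
        if h % 32 or w % 32:
            raise PlanError(f"input size ({h},{w}) must be divisible by 32")
        pyramid = FeaturePyramid()
        x = self.stem(x)
        pyramid.add("A0", x, 2)
        for sid, stage, stride in (
            ("A1", self.stage1, 4),
            ("A2", self.stage2, 8),
            ("A3", self.stage3, 16),
            ("A4", self.stage4, 32),
        ):
            for block in stage:
                x = block(x)
            pyramid.add(sid, x, stride)
        return pyramid


class AssistClassifier(Module):
    """Global pooling + FC tail for optional standalone pre-training."""

    def __init__(self, backbone: AssistBackbone, n_classes: int, rng=None):
        super().__init__()
        self.backbone = backbone
        self.fc = Linear(backbone.plan.widths[-1], n_classes,
                         rng=rng or np.random.default_rng(0))

    def forward(self, x):
        pyramid = self.backbone(x)
        pooled = pyramid["A4"].tensor.mean(axis=(2, 3))
        return self.fc(pooled)


def build_assist(plan: AssistPlan | None = None, in_channels: int = 3,
                 seed: int = 0) -> AssistBackbone:
    return AssistBackbone(plan, in_channels, np.random.default_rng(seed))


def forward_assist(backbone: AssistBackbone, image) -> FeaturePyramid:
    return backbone(image)
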