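"""Encoder-decoder segmentation network over the composite backbone.

The encoder applies atrous spatial pyramid pooling (ASPP) to the lead
backbone's output-stride-16 tap: a 1x1 convolution, three 3x3 atrous
convolutions at dilation rates 6/12/18, and an image-pooling branch, all
concatenated and projected by 1x1 convolution into the high-level feature.
The decoder upsamples the high-level feature four times, fuses it with
1x1-projected low-level features (the assisting backbone's A1 tap at
output stride 4), refines with 3x3 convolutions, applies two dropout
layers, then upsamples four times more and projects to class logits.  A
per-pixel softmax turns logits into probabilities; the arg-max class is
the prediction.

Training minimises L = L_comp + lambda * L_assist: the main cross-entropy
through the full network, plus assistant supervision — cross-entropy of a
lightweight head on the assisting backbone's low-level path — weighted by
lambda (default 0.3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .backbones import (
    AssistBackbone,
    AssistPlan,
    LeadBackbone,
    StagePlan,
    default_lead_plan,
    tiny_assist_plan,
    tiny_lead_plan,
)
from .fusion import CompositeFusion, CompositeTopology
from .nn import (
    BatchNorm2d,
    Conv2d,
    Dropout,
    Module,
    Tensor,
    bilinear_resize,
    concat,
    log_softmax,
    no_grad,
    softmax,
)

DEFAULT_LAMBDA = 0.3


@dataclass(frozen=True)
class AsppConfig:
    rates: tuple[int, int, int] = (6, 12, 18)
    out_channels: int = 256

    @property
    def branch_count(self) -> int:
        return 2 + len(self.rates)  # 1x1, three atrous, image pooling


class Aspp(Module):
    """Atrous spatial pyramid pooling over a stride-16 feature map."""

    def __init__(self, in_ch: int, cfg: AsppConfig, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        c = cfg.out_channels
        self.cfg = cfg
        self.b_1x1 = Conv2d(in_ch, c, 1, rng=rng)
        self.bn_1x1 = BatchNorm2d(c)
        self.atrous = []
        self.atrous_bn = []
        for rate in cfg.rates:
            self.atrous.append(
                Conv2d(in_ch, c, 3, padding=rate, dilation=rate, rng=rng)
            )
            self.atrous_bn.append(BatchNorm2d(c))
        self.pool_conv = Conv2d(in_ch, c, 1, rng=rng)  # image pooling branch
        self.merge = Conv2d(c * self.cfg.branch_count, c, 1, rng=rng)
        self.merge_bn = BatchNorm2d(c)

    def forward(self, x):
        h, w = x.shape[2], x.shape[3]
        if h < 1 or w < 1:
            raise ValueError("ASPP input has empty spatial extent")
        branches = [self.bn_1x1(self.b_1x1(x)).relu()]
        for conv, bn in zip(self.atrous, self.atrous_bn):
            branches.append(bn(conv(x)).relu())
        pooled = x.mean(axis=(2, 3), keepdims=True)
        pooled = self.pool_conv(pooled).relu()
        branches.append(bilinear_resize(pooled, (h, w)))
        merged = concat(branches, axis=1)
        return self.merge_bn(self.merge(merged)).relu()


class Decoder(Module):
    """Fuse high-level (stride 16) with low-level (stride 4) features."""

    def __init__(self, high_ch: int, low_ch: int, n_classes: int,
                 refine_ch: int = 256, low_proj_ch: int = 48,
                 dropout_rates=(0.5, 0.1), rng=None,
                 dropout_rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.low_proj = Conv2d(low_ch, low_proj_ch, 1, rng=rng)
        self.low_bn = BatchNorm2d(low_proj_ch)
        self.refine1 = Conv2d(high_ch + low_proj_ch, refine_ch, 3, padding=1,
                              rng=rng)
        self.refine_bn1 = BatchNorm2d(refine_ch)
        self.refine2 = Conv2d(refine_ch, refine_ch, 3, padding=1, rng=rng)
        self.refine_bn2 = BatchNorm2d(refine_ch)
        dropout_rng = dropout_rng or np.random.default_rng(0)
        self.drop1 = Dropout(dropout_rates[0], rng=dropout_rng)
        self.drop2 = Dropout(dropout_rates[1], rng=dropout_rng)
        self.classifier = Conv2d(refine_ch, n_classes, 1, rng=rng)

    def forward(self, high, low):
        if high.shape[2] * 4 != low.shape[2] * 1:
            raise ValueError(
                f"expected low-level at stride 4 and high-level at stride 16; "
                f"got spatial {high.shape[2:]} vs {low.shape[2:]}"
            )
        up = bilinear_resize(high, (high.shape[2] * 4, high.shape[3] * 4))
        low = self.low_bn(self.low_proj(low)).relu()
        y = concat([up, low], axis=1)
        y = self.refine_bn1(self.refine1(y)).relu()
        y = self.drop1(y)
        y = self.refine_bn2(self.refine2(y)).relu()
        y = self.drop2(y)
        y = bilinear_resize(y, (y.shape[2] * 4, y.shape[3] * 4))
        return self.classifier(y)


class AssistantHead(Module):
    """1x1 conv + upsample on the assisting low-level tap; feeds L_assist only."""

    def __init__(self, in_ch: int, n_classes: int, stride: int = 4, rng=None):
        super().__init__()
        self.conv = Conv2d(in_ch, n_classes, 1, rng=rng or np.random.default_rng(0))
        self.stride = stride

    def forward(self, low):
        logits = self.conv(low)
        return bilinear_resize(
            logits, (logits.shape[2] * self.stride, logits.shape[3] * self.stride)
        )


def predict(logits) -> np.ndarray:
    """Per-pixel softmax arg-max; ties break toward the lower class index."""
    data = logits.data if isinstance(logits, Tensor) else np.asarray(logits)
    probs = np.exp(data - data.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    return probs.argmax(axis=1).astype(np.uint8)


def cross_entropy(y, p, eps: float = 1e-7, reduction: str = "sum") -> float:
    """Binary cross-entropy of foreground probabilities ``p`` against labels.

    Computes sum_i -(y_i log p_i + (1 - y_i) log(1 - p_i)) with natural
    logarithms, after clipping p into [eps, 1 - eps].  ``reduction`` is
    "sum" (the per-image total) or "mean" (divided by the pixel count).
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    p = np.asarray(p, dtype=np.float64).ravel()
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: y has {y.size}, p has {p.size}")
    p = np.clip(p, eps, 1.0 - eps)
    total = float(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)).sum())
    if reduction == "sum":
        return total
    if reduction == "mean":
        return total / y.size
    raise ValueError(f"unknown reduction {reduction!r}")


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean per-pixel cross-entropy of (N, K, H, W) logits vs integer labels.

    For K = 2 this equals the binary form of :func:`cross_entropy` evaluated
    on the softmax foreground probability.
    """
    n, k, h, w = logits.shape
    logp = log_softmax(logits, axis=1)
    onehot = np.zeros((n, k, h, w))
    lab = np.asarray(labels).reshape(n, h, w)
    for cls in range(k):
        onehot[:, cls][lab == cls] = 1.0
    return -(logp * Tensor(onehot)).sum() / float(n * h * w)


@dataclass
class LossReport:
    """The composite loss decomposition L = L_comp + lambda * L_assist."""

    l_comp: float
    l_assist: float
    lam: float
    total: float = field(init=False)

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError(f"lambda must be non-negative, got {self.lam}")
        self.total = self.l_comp + self.lam * self.l_assist


def total_loss(l_comp: float, l_assist: float, lam: float = DEFAULT_LAMBDA) -> LossReport:
    """Combine the main and assistant losses; lambda = 0 disables assistance."""
    if not (np.isfinite(l_comp) and np.isfinite(l_assist)):
        raise ValueError("losses must be finite")
    return LossReport(l_comp=float(l_comp), l_assist=float(l_assist), lam=float(lam))


@dataclass
class ModelConfig:
    """Architecture hyperparameters of the composite segmentation network."""

    lead_plan: list[StagePlan] = field(default_factory=default_lead_plan)
    assist_plan: AssistPlan = field(default_factory=AssistPlan)
    topology: CompositeTopology = field(default_factory=CompositeTopology.dense)
    aspp: AsppConfig = field(default_factory=AsppConfig)
    n_classes: int = 2
    input_size: int = 512
    lambda_assist: float = DEFAULT_LAMBDA
    dropout_rates: tuple[float, float] = (0.5, 0.1)
    refine_channels: int = 256
    low_proj_channels: int = 48
    use_composite: bool = True
    use_assistant_supervision: bool = True
    seed: int = 0


def tiny_model_config(input_size: int = 64, **overrides) -> ModelConfig:
    """Desk-scale configuration used by tests and worked examples."""
    cfg = ModelConfig(
        lead_plan=tiny_lead_plan(),
        assist_plan=tiny_assist_plan(input_size=input_size),
        aspp=AsppConfig(out_channels=32),
        input_size=input_size,
        refine_channels=32,
        low_proj_channels=16,
    )
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


class CompositeSegNet(Module):
    """The full composite-backbone encoder-decoder.

    With ``use_composite`` off the network is exactly the plain
    lead-backbone encoder-decoder (a DeepLab-v3+-style model): no assisting
    forward pass, and the decoder's low-level input comes from the lead L1
    tap instead of the assisting A1 tap.
    """

    def __init__(self, config: ModelConfig | None = None):
        super().__init__()
        cfg = config or ModelConfig()
        self.config = cfg
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
        self.lead = LeadBackbone(cfg.lead_plan, rng=rng)
        lead_out = self.lead.stage_output_channels()
        self.composite_enabled = cfg.use_composite and bool(cfg.topology.edges)
        self.assistant_enabled = cfg.use_assistant_supervision and cfg.use_composite
        if cfg.use_composite:
            self.assist = AssistBackbone(cfg.assist_plan, rng=rng)
            assist_out = self.assist.stage_output_channels()
            self.fusion = CompositeFusion(
                cfg.topology, assist_out, self.lead.stage_input_channels(), rng
            )
            low_ch = assist_out["A1"]
            self.assistant_head = AssistantHead(low_ch, cfg.n_classes, rng=rng)
        else:
            self.assist = None
            self.fusion = None
            self.assistant_head = None
            low_ch = lead_out["L1"]
        self._low_ch = low_ch
        self.aspp = Aspp(lead_out["L4"], cfg.aspp, rng)
        self.decoder = Decoder(
            cfg.aspp.out_channels,
            low_ch,
            cfg.n_classes,
            refine_ch=cfg.refine_channels,
            low_proj_ch=cfg.low_proj_channels,
            dropout_rates=cfg.dropout_rates,
            rng=rng,
            dropout_rng=np.random.default_rng(
                np.random.SeedSequence(cfg.seed).spawn(1)[0]
            ),
        )

    # -- toggles ----------------------------------------------------------
    def disable_composite(self):
        """Reduce to the plain lead-backbone encoder-decoder.

        Requires the lead L1 and assisting A1 taps to have equal channel
        counts (true for the shipped presets) so the decoder's low-level
        projection applies unchanged.
        """
        if self.assist is not None:
            lead_l1 = self.lead.stage_output_channels()["L1"]
            if lead_l1 != self._low_ch:
                raise ValueError(
                    f"cannot reduce: lead L1 has {lead_l1} channels but the "
                    f"decoder was built for {self._low_ch}"
                )
        self.composite_enabled = False
        self.assistant_enabled = False
        return self

    def enable_composite(self):
        if self.assist is None:
            raise ValueError("model was built without an assisting backbone")
        self.composite_enabled = True
        self.assistant_enabled = self.config.use_assistant_supervision
        return self

    # -- forward ----------------------------------------------------------
    def _as_input(self, image) -> Tensor:
        if isinstance(image, Tensor):
            return image
        arr = np.asarray(image, dtype=np.float64)
        if arr.ndim == 3:  # H, W, C -> 1, C, H, W
            arr = arr.transpose(2, 0, 1)[None]
        if arr.max() > 1.5:
            arr = arr / 255.0
        return Tensor(arr)

    def forward(self, image):
        """Return (main logits, assistant logits or None), both at input size."""
        x = self._as_input(image)
        if self.composite_enabled:
            assist_pyramid = self.assist(x)
            h, w = x.shape[2], x.shape[3]
            lead_input_hw = {
                sid: (h // s, w // s)
                for sid, s in self.lead.stage_input_strides().items()
            }
            injections = self.fusion.injections(assist_pyramid, lead_input_hw)
            lead_pyramid = self.lead(x, injections)
            low = assist_pyramid["A1"].tensor
            assist_logits = (
                self.assistant_head(low) if self.assistant_enabled else None
            )
        else:
            lead_pyramid = self.lead(x)
            low = lead_pyramid["L1"].tensor
            assist_logits = None
        high = self.aspp(lead_pyramid["L4"].tensor)
        logits = self.decoder(high, low)
        return logits, assist_logits

    def forward_lead_only(self, image):
        """The plain lead-backbone path, regardless of composite state."""
        x = self._as_input(image)
        lead_pyramid = self.lead(x)
        high = self.aspp(lead_pyramid["L4"].tensor)
        return self.decoder(high, lead_pyramid["L1"].tensor)

    # -- loss / inference --------------------------------------------------
    def loss(self, image, labels) -> tuple[Tensor, LossReport]:
        """Differentiable total loss plus its scalar decomposition."""
        logits, assist_logits = self.forward(image)
        l_comp = softmax_cross_entropy(logits, labels)
        lam = self.config.lambda_assist
        if assist_logits is not None and lam > 0:
            l_assist = softmax_cross_entropy(assist_logits, labels)
            total = l_comp + lam * l_assist
            report = total_loss(l_comp.item(), l_assist.item(), lam)
        else:
            l_assist_val = 0.0
            total = l_comp
            report = total_loss(l_comp.item(), l_assist_val, lam)
        return total, report

    def predict_mask(self, image) -> np.ndarray:
        """Inference: integer class mask (squeezes the batch axis if 1)."""
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                logits, _ = self.forward(image)
            mask = predict(logits)
        finally:
            if was_training:
                self.train()
        return mask[0] if mask.shape[0] == 1 else mask

    def softmax_probabilities(self, image) -> np.ndarray:
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                logits, _ = self.forward(image)
            return softmax(logits, axis=1).data
        finally:
            if was_training:
                self.train()
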