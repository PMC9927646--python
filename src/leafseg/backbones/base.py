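"""Shared feature-pyramid container for backbone stage taps."""

from __future__ import annotations

from dataclasses import dataclass, field

from ..nn import Tensor


@dataclass
class PyramidLevel:
    stage_id: str
    tensor: Tensor
    stride: int  # cumulative spatial reduction vs. the input image

    @property
    def channels(self) -> int:
        return self.tensor.shape[1]


@dataclass
class FeaturePyramid:
    """Ordered per-stage feature rasters with stride/channel metadata."""

    levels: list[PyramidLevel] = field(default_factory=list)

    def add(self, stage_id: str, tensor: Tensor, stride: int):
        self.levels.append(PyramidLevel(stage_id, tensor, stride))

    def __getitem__(self, stage_id: str) -> PyramidLevel:
        for level in self.levels:
            if level.stage_id == stage_id:
                return level
        raise KeyError(f"no stage {stage_id!r} in pyramid")

    def __contains__(self, stage_id: str) -> bool:
        return any(level.stage_id == stage_id for level in self.levels)

    def stage_ids(self) -> list[str]:
        return [level.stage_id for level in self.levels]
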