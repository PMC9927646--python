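"""Run configuration: YAML/JSON schema, validation, seeding and manifests.

A run config is a small tree of sections (data, model, train, finetune)
with defaults matching the shipped training recipes.  Unknown keys are
rejected with the offending field path, so typos surface immediately.
One global seed fans out to per-component seeds through
``numpy.random.SeedSequence`` so components draw independent streams.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .backbones import AssistPlan, default_lead_plan, tiny_assist_plan, tiny_lead_plan
from .fusion import CompositeTopology
from .network import AsppConfig, ModelConfig
from .train import FinetuneConfig, TrainConfig

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Raised on schema violations, with the offending field path."""


@dataclass
class DataConfig:
    image_size: int = 512
    n_per_scene: int = 4
    augment: bool = True
    split_fraction: float = 0.8
    median_filter_k: int = 3


@dataclass
class RunConfig:
    schema_version: int = SCHEMA_VERSION
    seed: int = 0
    preset: str = "full"  # "full" | "tiny"
    data: DataConfig = field(default_factory=DataConfig)
    model: dict = field(default_factory=dict)  # overrides onto the preset
    train: TrainConfig = field(default_factory=TrainConfig)
    finetune: FinetuneConfig = field(default_factory=FinetuneConfig)


_SECTION_TYPES = {
    "data": DataConfig,
    "train": TrainConfig,
    "finetune": FinetuneConfig,
}


def _fill_dataclass(cls, payload: dict, path: str):
    field_map = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in payload.items():
        if key not in field_map:
            raise ConfigError(f"unknown key {path}.{key}" if path else
                              f"unknown key {key}")
        ftype = field_map[key].type
        if isinstance(value, dict) and key in ("phase1", "phase2"):
            value = _fill_dataclass(TrainConfig, value, f"{path}.{key}")
        if key in ("betas",) and isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML/JSON config file; empty file -> defaults."""
    payload = {}
    if path is not None:
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
    if not isinstance(payload, dict):
        raise ConfigError("config root must be a mapping")
    cfg = RunConfig()
    for key, value in payload.items():
        if key in _SECTION_TYPES:
            if not isinstance(value, dict):
                raise ConfigError(f"section {key} must be a mapping")
            setattr(cfg, key, _fill_dataclass(_SECTION_TYPES[key], value, key))
        elif key in ("schema_version", "seed", "preset"):
            setattr(cfg, key, value)
        elif key == "model":
            if not isinstance(value, dict):
                raise ConfigError("section model must be a mapping")
            allowed = {f.name for f in dataclasses.fields(ModelConfig)} | {
                "topology", "lead_widths", "l3_repeats", "assist_widths",
                "assist_repeats",
            }
            for sub in value:
                if sub not in allowed:
                    raise ConfigError(f"unknown key model.{sub}")
            cfg.model = value
        else:
            raise ConfigError(f"unknown key {key}")
    if cfg.preset not in ("full", "tiny"):
        raise ConfigError(f"unknown preset {cfg.preset!r}")
    return cfg


def to_dict(cfg: RunConfig) -> dict:
    out = dataclasses.asdict(cfg)
    return out


def save_config(cfg: RunConfig, path: str | Path):
    with open(path, "w") as fh:
        yaml.safe_dump(to_dict(cfg), fh, sort_keys=True)


def build_model_config(cfg: RunConfig) -> ModelConfig:
    """Materialise the ModelConfig for the configured preset + overrides."""
    size = cfg.data.image_size
    if cfg.preset == "tiny":
        mc = ModelConfig(
            lead_plan=tiny_lead_plan(),
            assist_plan=tiny_assist_plan(input_size=size),
            aspp=AsppConfig(out_channels=32),
            input_size=size,
            refine_channels=32,
            low_proj_channels=16,
        )
    else:
        mc = ModelConfig(
            lead_plan=default_lead_plan(),
            assist_plan=AssistPlan(input_size=size),
            input_size=size,
        )
    mc.seed = cfg.seed
    overrides = dict(cfg.model)
    if "lead_widths" in overrides or "l3_repeats" in overrides:
        widths = tuple(overrides.pop("lead_widths", [p.out_channels for p in mc.lead_plan]))
        l3 = overrides.pop("l3_repeats", mc.lead_plan[3].repeats)
        mc.lead_plan = default_lead_plan(widths=widths, l3_repeats=l3)
    if "assist_widths" in overrides or "assist_repeats" in overrides:
        mc.assist_plan = AssistPlan(
            widths=tuple(overrides.pop("assist_widths", mc.assist_plan.widths)),
            repeats=tuple(overrides.pop("assist_repeats", mc.assist_plan.repeats)),
            ffn_expansion=mc.assist_plan.ffn_expansion,
            head_dim=mc.assist_plan.head_dim,
            input_size=size,
        )
    if "topology" in overrides:
        mc.topology = CompositeTopology.from_strings(overrides.pop("topology"))
    for key, value in overrides.items():
        setattr(mc, key, value)
    return mc


def spawn_seed(seed: int, component: str) -> int:
    """Derive a per-component seed from the global one via a fixed hash."""
    digest = hashlib.sha256(f"{seed}:{component}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunManifest:
    """Provenance record written once per run directory."""

    config_hash: str
    seed: int
    package_version: str
    command: str
    input_manifest: str | None = None
    outputs: dict = field(default_factory=dict)

    @staticmethod
    def create(cfg: RunConfig, command: str, **kwargs) -> "RunManifest":
        from . import __version__

        canonical = json.dumps(to_dict(cfg), sort_keys=True)
        return RunManifest(
            config_hash=hashlib.sha256(canonical.encode()).hexdigest()[:16],
            seed=cfg.seed,
            package_version=__version__,
            command=command,
            **kwargs,
        )

    def write(self, run_dir: str | Path) -> Path:
        run_dir = Path(run_dir)
        run_dir.mkdir(parents=True, exist_ok=True)
        path = run_dir / "run_manifest.json"
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
        return path
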