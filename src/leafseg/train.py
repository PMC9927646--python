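"""Training regimes: from scratch, and freeze-then-fine-tune.

Both regimes optimise the composite loss with Adam and a
reduce-on-plateau learning-rate rule: when the best epoch loss has not
improved for ``plateau_patience`` consecutive epochs the learning rate is
halved (``plateau_factor`` = 0.5), bounded below by ``min_lr`` = 0, and
the patience counter resets.  Training stops early once the best loss
stops changing by more than ``min_delta`` over a patience window.

The fine-tune regime runs two phases: first the two backbones are frozen
while the encoder-decoder head trains (higher learning rate, larger
batch), then everything is unfrozen at a lower rate.  Frozen parameters
are bitwise untouched; frozen modules also run in eval mode so their
batch-norm statistics stay fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .data import DatasetSplit
from .metrics import MetricsReport, evaluate
from .network import CompositeSegNet
from .nn import Adam, Tensor, load_checkpoint, save_checkpoint


@dataclass
class TrainConfig:
    """Optimiser / schedule hyperparameters of one training phase."""

    regime: str = "scratch"  # "scratch" | "finetune"
    lr: float = 5e-4
    batch_size: int = 4
    epochs: int = 200
    betas: tuple[float, float] = (0.9, 0.999)
    adam_eps: float = 1e-8
    lambda_assist: float = 0.3
    plateau_patience: int = 5
    plateau_factor: float = 0.5
    min_lr: float = 0.0
    min_delta: float = 1e-6
    seed: int = 0
    max_steps: int | None = None  # optional hard cap on optimisation steps
    eval_every: int = 0  # 0: no mid-training evaluation
    boundary_d: int | None = None


def scratch_config(**overrides) -> TrainConfig:
    """From-scratch defaults: Adam, lr 5e-4, batch 4, 200 epochs."""
    return replace(TrainConfig(), **overrides)


@dataclass
class FinetuneConfig:
    """Two-phase schedule: backbone freezing, then full fine-tuning."""

    phase1: TrainConfig = field(
        default_factory=lambda: TrainConfig(regime="finetune", lr=1e-4,
                                            batch_size=8, epochs=100)
    )
    phase2: TrainConfig = field(
        default_factory=lambda: TrainConfig(regime="finetune", lr=5e-5,
                                            batch_size=4, epochs=100)
    )


class PlateauScheduler:
    """Halve the learning rate after ``patience`` non-improving epochs."""

    def __init__(self, lr: float, patience: int = 5, factor: float = 0.5,
                 min_lr: float = 0.0, min_delta: float = 0.0):
        self.lr = lr
        self.patience = patience
        self.factor = factor
        self.min_lr = min_lr
        self.min_delta = min_delta
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, loss: float) -> float:
        if loss < self.best - self.min_delta:
            self.best = loss
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs >= self.patience:
                self.lr = max(self.min_lr, self.lr * self.factor)
                self.bad_epochs = 0
        return self.lr


def plateau_step(loss_history, current_lr: float,
                 cfg: TrainConfig | None = None) -> float:
    """Learning rate after replaying ``loss_history`` from ``current_lr``."""
    if len(loss_history) == 0:
        raise ValueError("loss history must be non-empty")
    cfg = cfg or TrainConfig()
    sched = PlateauScheduler(current_lr, cfg.plateau_patience,
                             cfg.plateau_factor, cfg.min_lr)
    for loss in loss_history:
        sched.step(loss)
    return sched.lr


@dataclass
class TrainLog:
    """Per-epoch records; serialises to CSV."""

    records: list[dict] = field(default_factory=list)
    unfreeze_epoch: int | None = None

    def append(self, **record):
        self.records.append(record)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def to_csv(self, path):
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.to_dataframe().to_csv(path, index=False)

    @property
    def final_loss(self) -> float:
        return self.records[-1]["loss_total"] if self.records else np.nan


def _to_batch(samples) -> tuple[np.ndarray, np.ndarray]:
    images = np.stack(
        [s.image.transpose(2, 0, 1).astype(np.float64) / 255.0 for s in samples]
    )
    labels = np.stack([s.mask.astype(np.int64) for s in samples])
    return images, labels


def evaluate_model(model: CompositeSegNet, samples,
                   d: int | None = None) -> MetricsReport:
    """Score the model's predictions on a list of annotated samples."""
    preds, truths = [], []
    for s in samples:
        preds.append(model.predict_mask(s.image))
        truths.append(s.mask)
    return evaluate(preds, truths, d=d)


def _run_epochs(model, samples, cfg: TrainConfig, optimizer, scheduler,
                log: TrainLog, *, epochs, phase, eval_samples,
                step_counter) -> bool:
    """Inner loop shared by both regimes; returns True when stopped early."""
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0xE9)))
    best = np.inf
    stale = 0
    for epoch in range(epochs):
        order = rng.permutation(len(samples))
        losses, comps, assists = [], [], []
        for start in range(0, len(samples), cfg.batch_size):
            batch = [samples[i] for i in order[start : start + cfg.batch_size]]
            images, labels = _to_batch(batch)
            total, report = model.loss(Tensor(images), labels)
            model.zero_grad()
            total.backward()
            optimizer.step()
            losses.append(report.total)
            comps.append(report.l_comp)
            assists.append(report.l_assist)
            step_counter[0] += 1
            if cfg.max_steps and step_counter[0] >= cfg.max_steps:
                break
        epoch_loss = float(np.mean(losses))
        optimizer.lr = scheduler.step(epoch_loss)
        record = {
            "phase": phase,
            "epoch": len(log.records),
            "lr": optimizer.lr,
            "loss_comp": float(np.mean(comps)),
            "loss_assist": float(np.mean(assists)),
            "loss_total": epoch_loss,
            "miou": np.nan,
            "biou": np.nan,
        }
        if cfg.eval_every and (epoch + 1) % cfg.eval_every == 0 and eval_samples:
            report = evaluate_model(model, eval_samples, d=cfg.boundary_d)
            record["miou"], record["biou"] = report.MIoU, report.BIoU
        log.append(**record)
        if cfg.max_steps and step_counter[0] >= cfg.max_steps:
            return False
        # early stop: best loss no longer changes significantly
        if epoch_loss < best - cfg.min_delta:
            best = epoch_loss
            stale = 0
        else:
            stale += 1
            if stale > cfg.plateau_patience:
                return True
    return False


def train_scratch(model: CompositeSegNet, split: DatasetSplit,
                  cfg: TrainConfig | None = None):
    """Train from random initialisation on the split's training samples."""
    cfg = cfg or scratch_config()
    if not split.train:
        raise ValueError("training split is empty")
    model.config.lambda_assist = cfg.lambda_assist
    model.train()
    optimizer = Adam(model.parameters(), cfg.lr, cfg.betas, cfg.adam_eps)
    scheduler = PlateauScheduler(cfg.lr, cfg.plateau_patience,
                                 cfg.plateau_factor, cfg.min_lr, cfg.min_delta)
    log = TrainLog()
    _run_epochs(model, split.train, cfg, optimizer, scheduler, log,
                epochs=cfg.epochs, phase="scratch",
                eval_samples=split.test, step_counter=[0])
    return model, log


def _backbone_modules(model: CompositeSegNet):
    mods = [model.lead]
    if model.assist is not None:
        mods.append(model.assist)
    return mods


def freeze_backbones(model: CompositeSegNet, frozen: bool = True):
    """Freeze (or unfreeze) both composite backbones.

    Freezing removes the parameters from optimisation and switches the
    modules to eval mode so batch-norm running statistics stay fixed too.
    """
    for mod in _backbone_modules(model):
        mod.requires_grad_(not frozen)
        mod.train(not frozen)
    return model


def train_finetune(model: CompositeSegNet, pretrained_checkpoints: dict | None,
                   split: DatasetSplit, cfg: FinetuneConfig | None = None):
    """Two-phase fine-tuning from (optionally) pre-trained backbones.

    ``pretrained_checkpoints`` maps "lead"/"assist" to checkpoint paths
    written by :func:`leafseg.nn.save_checkpoint` for the respective
    backbone module.
    """
    cfg = cfg or FinetuneConfig()
    if not split.train:
        raise ValueError("training split is empty")
    if pretrained_checkpoints:
        for name, mod in (("lead", model.lead), ("assist", model.assist)):
            path = pretrained_checkpoints.get(name)
            if path is None:
                continue
            if mod is None:
                raise ValueError(f"checkpoint given for absent backbone {name!r}")
            try:
                load_checkpoint(mod, path)
            except (KeyError, ValueError) as exc:
                raise ValueError(
                    f"checkpoint/plan mismatch for backbone {name!r}: {exc}"
                ) from exc

    log = TrainLog()
    step_counter = [0]

    # phase 1: frozen backbones, train the encoder-decoder head
    model.train()
    freeze_backbones(model, True)
    p1 = cfg.phase1
    model.config.lambda_assist = p1.lambda_assist
    optimizer = Adam(model.parameters(), p1.lr, p1.betas, p1.adam_eps)
    scheduler = PlateauScheduler(p1.lr, p1.plateau_patience, p1.plateau_factor,
                                 p1.min_lr, p1.min_delta)
    _run_epochs(model, split.train, p1, optimizer, scheduler, log,
                epochs=p1.epochs, phase="freeze",
                eval_samples=split.test, step_counter=step_counter)

    # phase 2: unfreeze everything at the lower rate
    log.unfreeze_epoch = len(log.records)
    freeze_backbones(model, False)
    model.train()
    p2 = cfg.phase2
    model.config.lambda_assist = p2.lambda_assist
    optimizer = Adam(model.parameters(), p2.lr, p2.betas, p2.adam_eps)
    scheduler = PlateauScheduler(p2.lr, p2.plateau_patience, p2.plateau_factor,
                                 p2.min_lr, p2.min_delta)
    _run_epochs(model, split.train, p2, optimizer, scheduler, log,
                epochs=p2.epochs, phase="finetune",
                eval_samples=split.test, step_counter=step_counter)
    return model, log


def pretrain_backbones(model: CompositeSegNet, out_dir, tag: str = "pretrained"):
    """Write both backbone checkpoints (offline pre-training entry point)."""
    out_dir = Path(out_dir)
    paths = {}
    manifest = {"tag": tag}
    save_checkpoint(model.lead, out_dir / "lead", manifest)
    paths["lead"] = str(out_dir / "lead")
    if model.assist is not None:
        save_checkpoint(model.assist, out_dir / "assist", manifest)
        paths["assist"] = str(out_dir / "assist")
    return paths


def overfit_tiny(seed: int = 0, steps: int = 300, lr: float = 2e-3,
                 image_size: int = 64):
    """Overfit the tiny preset on four synthetic scenes (a learnability check).

    Four 64 x 64 scenes (normal, spotted lesions, occluded, uneven
    illumination) are fitted for at most ``steps`` optimisation steps at
    batch size 4.  Returns (model, log, train-set metrics report).
    """
    from .data import SceneSpec, SceneType, generate_sample
    from .network import CompositeSegNet, tiny_model_config

    types = (SceneType.NORMAL, SceneType.SPOTTED_LESIONS, SceneType.OCCLUDED,
             SceneType.UNEVEN_ILLUMINATION)
    samples = [
        generate_sample(
            SceneSpec(scene_type=t, image_size=image_size,
                      rng_seed=seed * 1009 + i)
        )
        for i, t in enumerate(types)
    ]
    split = DatasetSplit(train=samples, test=samples)
    model = CompositeSegNet(tiny_model_config(input_size=image_size, seed=seed))
    # spend the whole step budget: no early stopping for this demonstration
    cfg = TrainConfig(lr=lr, batch_size=4, epochs=steps, max_steps=steps,
                      seed=seed, min_delta=0.0, plateau_patience=10**9)
    model, log = train_scratch(model, split, cfg)
    report = evaluate_model(model, samples)
    return model, log, report


def ablation_run(split: DatasetSplit, model_factory, cfg: TrainConfig,
                 toggles=((True, True), (True, False), (False, False)),
                 d: int | None = None) -> pd.DataFrame:
    """Train the 2x2 (composite, assistant supervision) toggle grid.

    ``model_factory(composite, assistant) -> CompositeSegNet`` builds a
    fresh seeded model per configuration.  Returns one row per toggle
    combination with MIoU and BIoU on the test samples.
    """
    rows = []
    for composite, assistant in toggles:
        if assistant and not composite:
            continue  # assistant supervision requires the assisting backbone
        model = model_factory(composite, assistant)
        run_cfg = replace(cfg, lambda_assist=cfg.lambda_assist if assistant else 0.0)
        model, _ = train_scratch(model, split, run_cfg)
        report = evaluate_model(model, split.test, d=d)
        rows.append(
            {
                "composite": composite,
                "assistant_supervision": assistant,
                "MIoU": report.MIoU,
                "BIoU": report.BIoU,
                "MPA": report.MPA,
                "PA": report.PA,
            }
        )
    return pd.DataFrame(rows)
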