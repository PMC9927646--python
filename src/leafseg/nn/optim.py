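"""Optimisers and checkpoint serialisation."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .layers import Module


class Adam:
    """Adaptive-moment estimation with bias-corrected first/second moments.

    Parameters whose ``requires_grad`` flag is False at step time are
    skipped, which is how backbone freezing is realised.
    """

    def __init__(self, params, lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self._m = {}
        self._v = {}
        self._t = {}

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p in self.params:
            if not p.requires_grad or p.grad is None:
                continue
            key = id(p)
            if key not in self._m:
                self._m[key] = np.zeros_like(p.data)
                self._v[key] = np.zeros_like(p.data)
                self._t[key] = 0
            self._t[key] += 1
            t = self._t[key]
            m = self._m[key] = self.beta1 * self._m[key] + (1 - self.beta1) * p.grad
            v = self._v[key] = self.beta2 * self._v[key] + (1 - self.beta2) * p.grad**2
            mhat = m / (1 - self.beta1**t)
            vhat = v / (1 - self.beta2**t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def save_checkpoint(module: Module, path: str | Path, manifest: dict | None = None):
    """Write a flat name->array archive plus a JSON manifest sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path.with_suffix(".npz"), **module.state_dict())
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(manifest or {}, fh, indent=2, sort_keys=True)


def load_checkpoint(module: Module, path: str | Path) -> dict:
    """Load an archive written by :func:`save_checkpoint` into ``module``."""
    path = Path(path)
    with np.load(path.with_suffix(".npz")) as archive:
        state = {k: archive[k] for k in archive.files}
    module.load_state_dict(state)
    manifest_path = path.with_suffix(".json")
    if manifest_path.exists():
        with open(manifest_path) as fh:
            return json.load(fh)
    return {}
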