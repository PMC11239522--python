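"""Adam with linear warmup and cosine decay.

Stands in for the exotic flat-and-anneal optimizers used in some cell
segmentation pipelines: the schedule (warmup fraction then cosine decay to a
floor) captures the part that matters for stable small-batch training.
"""

from __future__ import annotations

import numpy as np


class AdamW:
    def __init__(self, params: dict, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0,
                 total_steps: int | None = None, warmup_frac: float = 0.1,
                 final_lr_frac: float = 0.1):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.total_steps = total_steps
        self.warmup_steps = (
            max(1, int(warmup_frac * total_steps)) if total_steps else 0
        )
        self.final_lr_frac = final_lr_frac
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def current_lr(self) -> float:
        if not self.total_steps:
            return self.lr
        if self.t <= self.warmup_steps:
            return self.lr * self.t / self.warmup_steps
        frac = (self.t - self.warmup_steps) / max(
            1, self.total_steps - self.warmup_steps
        )
        cos = 0.5 * (1.0 + np.cos(np.pi * min(frac, 1.0)))
        return self.lr * (self.final_lr_frac + (1 - self.final_lr_frac) * cos)

    def step(self, grads: dict) -> None:
        self.t += 1
        lr = self.current_lr()
        for k, p in self.params.items():
            g = grads[k]
            if self.weight_decay and k.endswith(".W"):
                g = g + self.weight_decay * p
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * (g * g)
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p -= (lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
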