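"""Deep-learning cell detection: a 3D UNet voxel classifier, its training
recipe, and whole-stack sliding-window inference.

The training recipe follows the standard light-sheet c-Fos setup: Mish
activations, binary cross-entropy on voxel labels, initial learning rate
1e-3, batch size 4, and *no* model selection — the checkpoint after the
final epoch is the model.  Raw intensities are normalized per volume to the
1st-99th percentile range before both training and inference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .nn import UNet3D, AdamW
from .nn import layers as L
from .types import ImageStack, MaskStack, ProbabilityStack

F32 = np.float32


@dataclass
class UNetConfig:
    in_channels: int = 1
    out_channels: int = 1
    base_features: int = 16
    depth: int = 5
    activation: str = "mish"
    loss: str = "bce"
    lr: float = 1e-3
    batch_size: int = 4
    epochs: int = 500
    seed: int = 0
    augment: bool = True

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.activation != "mish" or self.loss != "bce":
            raise ValueError("only mish activation and bce loss are supported")


@dataclass
class TrainedModel:
    config: UNetConfig
    net: UNet3D
    training_log: list[float] = field(default_factory=list)
    checkpoint_policy: str = "last"

    def predict_proba(self, vol: np.ndarray) -> np.ndarray:
        return self.net.predict_proba(vol)


def build_unet(config: UNetConfig) -> TrainedModel:
    """Seeded construction; two builds with the same config are identical."""
    net = UNet3D(
        depth=config.depth,
        base_features=config.base_features,
        in_channels=config.in_channels,
        seed=config.seed,
    )
    return TrainedModel(config=config, net=net)


# ------------------------------------------------------------- normalization

def normalize_intensity(vol: np.ndarray, p_low: float = 1.0, p_high: float = 99.0) -> np.ndarray:
    """Scale a volume so its [p_low, p_high] percentile range maps to [0, 1].

    Robust to the hot pixels and empty background that dominate light-sheet
    stacks.  Values outside the range are clipped to [-0.5, 1.5].

    The percentile pool excludes voxels that would skew the scale away from
    the tissue signal: zeros (padding and ventricle-masked regions) and
    extreme outliers above median + 8 robust sigma (unmasked ventricle
    lumens, which can occupy several percent of a stack and would otherwise
    capture the upper percentile).  This keeps the scaling of a stack
    identical whether or not its ventricles are masked.
    """
    v = vol.astype(F32)
    pool = v[v > 0]
    if pool.size:
        med = np.median(pool)
        mad = np.median(np.abs(pool - med)) * F32(1.4826)
        if mad > 0:
            pool = pool[pool <= med + 8 * mad]
    lo, hi = np.percentile(pool if pool.size else v, [p_low, p_high])
    if hi <= lo:
        return np.zeros_like(v)
    return np.clip((v - lo) / F32(hi - lo), -0.5, 1.5).astype(F32)


def _augment(raw: np.ndarray, lab: np.ndarray, rng: np.random.Generator):
    """Random axis flips and a random 90-degree rotation in the xy plane."""
    for ax in range(3):
        if rng.random() < 0.5:
            raw = np.flip(raw, axis=ax)
            lab = np.flip(lab, axis=ax)
    k = int(rng.integers(0, 4))
    if k:
        raw = np.rot90(raw, k, axes=(1, 2))
        lab = np.rot90(lab, k, axes=(1, 2))
    return np.ascontiguousarray(raw), np.ascontiguousarray(lab)


# ------------------------------------------------------------------ training

def train(model: TrainedModel, patches: list[tuple[np.ndarray, np.ndarray]],
          config: UNetConfig | None = None) -> TrainedModel:
    """Train in place and return the last-epoch checkpoint.

    ``patches`` is a list of (raw, label) 3D arrays of equal shape; labels
    must be binary.  The returned model carries the full per-epoch mean-loss
    log; no model selection happens — the final state is the checkpoint.
    """
    cfg = config or model.config
    if not patches:
        raise ValueError("empty training set")
    for raw, lab in patches:
        if raw.shape != lab.shape:
            raise ValueError("raw/label shape mismatch")
        u = np.unique(lab)
        if not np.isin(u, [0, 1]).all():
            raise ValueError("labels must be binary {0,1}")
    norm = [(normalize_intensity(r), l.astype(F32)) for r, l in patches]
    rng = np.random.default_rng(cfg.seed)
    steps_per_epoch = int(np.ceil(len(norm) / cfg.batch_size))
    opt = AdamW(model.net.params, lr=cfg.lr,
                total_steps=cfg.epochs * steps_per_epoch)
    log = model.training_log
    for _epoch in range(cfg.epochs):
        order = rng.permutation(len(norm))
        losses = []
        for s in range(steps_per_epoch):
            idx = order[s * cfg.batch_size:(s + 1) * cfg.batch_size]
            batch = [norm[i] for i in idx]
            if cfg.augment:
                batch = [_augment(r, l, rng) for r, l in batch]
            xb = np.stack([r for r, _ in batch])[:, None]
            yb = np.stack([l for _, l in batch])[:, None]
            logits, cache = model.net.forward(xb, train=True)
            loss, dz = L.bce_with_logits(logits, yb)
            grads = model.net.backward(dz, cache)
            opt.step(grads)
            losses.append(loss)
        log.append(float(np.mean(losses)))
    return model


# ----------------------------------------------------------------- inference

def _gaussian_importance(window: tuple[int, int, int]) -> np.ndarray:
    """Center-weighted blending map (sigma = window/8), floored at 1e-3."""
    grids = [
        np.exp(-0.5 * ((np.arange(w) - (w - 1) / 2) / (w / 8.0)) ** 2)
        for w in window
    ]
    w = grids[0][:, None, None] * grids[1][None, :, None] * grids[2][None, None, :]
    return np.maximum(w, 1e-3).astype(F32)


def sliding_window_infer(model, stack: ImageStack, window=(64, 64, 64),
                         overlap: float = 0.25, blend: str = "gaussian") -> ProbabilityStack:
    """Tile the stack with overlapping windows, run the model per window and
    blend overlapping probabilities by weighted averaging.

    ``model`` is anything exposing ``predict_proba((D,H,W) float) -> (D,H,W)``
    probabilities.  Borders are reflect-padded to fit the tiling and cropped
    back, so the output shape equals the input shape.
    """
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    if blend not in ("gaussian", "uniform"):
        raise ValueError("blend must be 'gaussian' or 'uniform'")
    div = 1
    net = getattr(model, "net", None)
    if net is not None:
        div = 2 ** (net.depth - 1)
    window = tuple(int(np.ceil(w / div) * div) for w in window)

    vol = normalize_intensity(stack.voxels)
    shape = vol.shape
    pad = [max(0, w - s) for w, s in zip(window, shape)]
    if any(pad):
        vol = np.pad(vol, [(0, p) for p in pad], mode="reflect")
    pshape = vol.shape

    strides = [max(1, int(round(w * (1 - overlap)))) for w in window]
    starts = []
    for dim, w, st in zip(pshape, window, strides):
        s = list(range(0, dim - w + 1, st))
        if s[-1] != dim - w:
            s.append(dim - w)
        starts.append(s)

    wmap = _gaussian_importance(window) if blend == "gaussian" else np.ones(window, F32)
    acc = np.zeros(pshape, dtype=F32)
    den = np.zeros(pshape, dtype=F32)
    for z0 in starts[0]:
        for y0 in starts[1]:
            for x0 in starts[2]:
                sl = (slice(z0, z0 + window[0]), slice(y0, y0 + window[1]),
                      slice(x0, x0 + window[2]))
                p = model.predict_proba(vol[sl])
                acc[sl] += p * wmap
                den[sl] += wmap
    out = (acc / den)[: shape[0], : shape[1], : shape[2]]
    return ProbabilityStack(np.clip(out, 0.0, 1.0), stack.spacing_um)


def binarize(prob: ProbabilityStack, threshold: float = 0.5) -> MaskStack:
    """Threshold a probability map; ties (p == threshold) count as foreground."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    return MaskStack((prob.values >= threshold).astype(np.uint8), prob.spacing_um)


# ---------------------------------------------------------------- checkpoints

def save_checkpoint(model: TrainedModel, path) -> None:
    path = Path(path)
    meta = {
        "config": asdict(model.config),
        "training_log": model.training_log,
        "checkpoint_policy": model.checkpoint_policy,
    }
    np.savez(path, __meta__=json.dumps(meta), **model.net.params)


def load_checkpoint(path) -> TrainedModel:
    path = Path(path)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"),
                 allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        params = {k: z[k] for k in z.files if k != "__meta__"}
    cfg = UNetConfig(**meta["config"])
    model = build_unet(cfg)
    for k in model.net.params:
        if k not in params:
            raise ValueError(f"checkpoint missing parameter {k}")
        model.net.params[k] = params[k].copy()
    model.training_log = list(meta["training_log"])
    return model


class ConstantModel:
    """Stub emitting a constant probability; used to test blending."""

    def __init__(self, p: float):
        self.p = float(p)

    def predict_proba(self, vol: np.ndarray) -> np.ndarray:
        return np.full(vol.shape, self.p, dtype=F32)
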