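"""A compact 3D encoder-decoder segmentation network.

Symmetric UNet: two 3x3x3 convolutions (Mish) per resolution level, 2x max
pooling down, nearest-neighbour upsampling + skip concatenation up, and a
1x1x1 logit head.  Feature widths double per level from ``base_features``.
Weights live in a flat ``{name: array}`` dict so checkpoints are plain npz
files; ``forward``/``backward`` implement the full chain rule by hand.

Tensors are channels-first: ``(N, C, D, H, W)``.
"""

from __future__ import annotations

import numpy as np

from . import layers as L

F32 = np.float32


class UNet3D:
    def __init__(self, depth: int = 3, base_features: int = 8, in_channels: int = 1,
                 seed: int = 0):
        if depth < 2:
            raise ValueError("depth must be >= 2")
        self.depth = depth
        self.base_features = base_features
        self.in_channels = in_channels
        # BasicUNet-style widths: doubling starts at the second level
        self.features = [base_features] + [
            base_features * 2 ** (i - 1) for i in range(1, depth)
        ]
        self.params: dict[str, np.ndarray] = {}
        self._init_params(np.random.default_rng(seed))

    # ------------------------------------------------------------- parameters
    def _add(self, name: str, p: dict) -> None:
        self.params[f"{name}.W"] = p["W"]
        self.params[f"{name}.b"] = p["b"]

    def _init_params(self, rng: np.random.Generator) -> None:
        f = self.features
        c_prev = self.in_channels
        for i in range(self.depth):  # encoder + bottleneck double convs
            self._add(f"enc{i}.c0", L.conv3_init(rng, c_prev, f[i]))
            self._add(f"enc{i}.c1", L.conv3_init(rng, f[i], f[i]))
            c_prev = f[i]
        for i in range(self.depth - 2, -1, -1):
            self._add(f"dec{i}.c0", L.conv3_init(rng, f[i] + f[i + 1], f[i]))
            self._add(f"dec{i}.c1", L.conv3_init(rng, f[i], f[i]))
        self._add("head", L.conv1_init(rng, f[0], 1))
        # start from a low-foreground prior: somata occupy well under 1% of
        # a stack, and a 0.5 prior wastes the early epochs unlearning it
        prior = 0.01
        self.params["head.b"][:] = np.log(prior / (1 - prior))

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def _p(self, name: str) -> dict:
        return {"W": self.params[f"{name}.W"], "b": self.params[f"{name}.b"]}

    # ----------------------------------------------------------------- forward
    def _double_conv(self, name: str, x, cache, keep: bool):
        a, xp = L.conv3_forward(x, self._p(f"{name}.c0"), return_padded=True)
        h = L.mish_forward(a)
        b, hp = L.conv3_forward(h, self._p(f"{name}.c1"), return_padded=True)
        y = L.mish_forward(b)
        if keep:
            cache[name] = (xp, a, hp, b)
        return y

    def forward(self, x: np.ndarray, train: bool = False):
        """x: (N, C, D, H, W) with D,H,W divisible by 2**(depth-1).

        Returns logits of shape (N, 1, D, H, W); with ``train=True`` also a
        cache consumed by :meth:`backward`.
        """
        div = 2 ** (self.depth - 1)
        if any(s % div for s in x.shape[2:]):
            raise ValueError(f"spatial dims {x.shape[2:]} not divisible by {div}")
        cache: dict = {}
        skips = []
        h = x.astype(F32, copy=False)
        for i in range(self.depth - 1):
            s = self._double_conv(f"enc{i}", h, cache, train)
            skips.append(s)
            h, idx = L.maxpool2_forward(s)
            if train:
                cache[f"pool{i}"] = (idx, s.shape)
        h = self._double_conv(f"enc{self.depth - 1}", h, cache, train)
        for i in range(self.depth - 2, -1, -1):
            up = L.upsample2_forward(h)
            cat = np.concatenate([skips[i], up], axis=1)
            if train:
                cache[f"split{i}"] = skips[i].shape[1]
            h = self._double_conv(f"dec{i}", cat, cache, train)
        logits = L.conv1_forward(h, self._p("head"))
        if train:
            cache["head_in"] = h
            return logits, cache
        return logits

    # ---------------------------------------------------------------- backward
    def _double_conv_bwd(self, name: str, dy, cache, grads, need_dx=True):
        xp, a, hp, b = cache.pop(name)
        db_ = L.mish_backward(b, dy)
        dh, dW1, db1 = L.conv3_backward(hp, self._p(f"{name}.c1"), db_)
        da = L.mish_backward(a, dh)
        dx, dW0, db0 = L.conv3_backward(xp, self._p(f"{name}.c0"), da, need_dx)
        grads[f"{name}.c1.W"] = dW1
        grads[f"{name}.c1.b"] = db1
        grads[f"{name}.c0.W"] = dW0
        grads[f"{name}.c0.b"] = db0
        return dx

    def backward(self, dlogits: np.ndarray, cache: dict) -> dict:
        grads: dict[str, np.ndarray] = {}
        hin = cache.pop("head_in")
        dh, dWh, dbh = L.conv1_backward(hin, self._p("head"), dlogits)
        grads["head.W"] = dWh
        grads["head.b"] = dbh
        dskip = {}
        for i in range(0, self.depth - 1):
            dcat = self._double_conv_bwd(f"dec{i}", dh, cache, grads)
            nskip = cache.pop(f"split{i}")
            dskip[i] = dcat[:, :nskip]
            dh = L.upsample2_backward(dcat[:, nskip:])
        dh = self._double_conv_bwd(f"enc{self.depth - 1}", dh, cache, grads)
        for i in range(self.depth - 2, -1, -1):
            idx, shape = cache.pop(f"pool{i}")
            ds = L.maxpool2_backward(dh, idx, shape) + dskip[i]
            dh = self._double_conv_bwd(f"enc{i}", ds, cache, grads, need_dx=(i > 0))
        return grads

    # -------------------------------------------------------------- prediction
    def predict_proba(self, vol: np.ndarray) -> np.ndarray:
        """vol: (D, H, W) float -> foreground probability (D, H, W)."""
        logits = self.forward(vol[None, None].astype(F32))
        return L.sigmoid(logits)[0, 0]
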