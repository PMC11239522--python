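"""Core value types shared across the pipeline.

Conventions used everywhere: coordinates are 0-based and ordered (z, y, x);
bounding boxes are half-open ``(z0, y0, x0, z1, y1, x1)``; image stacks are
unsigned 16-bit; masks are {0,1} uint8.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ImageStack:
    """A 3D grayscale volume with per-axis physical voxel spacing in µm."""

    voxels: np.ndarray  # (D, H, W) uint16
    spacing_um: tuple[float, float, float]  # (z, y, x)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or any(s <= 0 for s in self.voxels.shape):
            raise ValueError("voxels must be a non-empty 3D array")
        if self.voxels.dtype != np.uint16:
            if self.voxels.min() < 0 or self.voxels.max() > 65535:
                raise ValueError("intensities outside the 16-bit range")
            self.voxels = self.voxels.astype(np.uint16)
        self.spacing_um = tuple(float(s) for s in self.spacing_um)
        if len(self.spacing_um) != 3 or any(s <= 0 for s in self.spacing_um):
            raise ValueError("spacing_um must be three positive values (z, y, x)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def is_isotropic(self) -> bool:
        s = self.spacing_um
        return abs(s[0] - s[1]) < 1e-9 and abs(s[1] - s[2]) < 1e-9


@dataclass
class MaskStack:
    """A binary {0,1} volume paired with the resolution it lives at."""

    mask: np.ndarray  # (D, H, W) uint8 in {0,1}
    spacing_um: tuple[float, float, float]

    def __post_init__(self):
        self.mask = np.asarray(self.mask)
        vals = np.unique(self.mask)
        if not np.isin(vals, [0, 1]).all():
            raise ValueError("mask must contain only {0,1}")
        self.mask = self.mask.astype(np.uint8)
        self.spacing_um = tuple(float(s) for s in self.spacing_um)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape


@dataclass
class ProbabilityStack:
    """Per-voxel foreground probability in [0, 1]."""

    values: np.ndarray  # (D, H, W) float32
    spacing_um: tuple[float, float, float]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("probabilities must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class CellInstance:
    """One detected (or ground-truth) cell."""

    label: int
    center_zyx: tuple[float, float, float]
    volume_vox: int
    bbox: tuple[int, int, int, int, int, int]  # half-open (z0,y0,x0,z1,y1,x1)

    def __post_init__(self):
        if self.label <= 0:
            raise ValueError("instance labels must be positive")
        if self.volume_vox < 1:
            raise ValueError("volume_vox must be >= 1")
        z0, y0, x0, z1, y1, x1 = self.bbox
        c = self.center_zyx
        if not (z0 <= c[0] < z1 and y0 <= c[1] < y1 and x0 <= c[2] < x1):
            raise ValueError("center must lie inside the bounding box")


@dataclass
class LabeledVolume:
    """Integer-labelled instance volume; 0 is background."""

    labels: np.ndarray  # (D, H, W) int32
    instances: list[CellInstance] = field(default_factory=list)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int32)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def __len__(self) -> int:
        return len(self.instances)
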