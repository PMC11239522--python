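"""Affine point transforms between stack and atlas physical (µm) space."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np


@dataclass
class AffineTransform:
    """Maps stack µm coordinates (z, y, x) to atlas µm coordinates.

    ``matrix`` is 3x4 row-major: ``atlas_um = A @ [z, y, x, 1]``.
    """

    matrix: np.ndarray
    source_spacing_um: tuple[float, float, float]
    target_spacing_um: float

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (3, 4):
            raise ValueError("matrix must be 3x4")
        if not np.isfinite(self.matrix).all():
            raise ValueError("matrix entries must be finite")
        if abs(np.linalg.det(self.matrix[:, :3])) < 1e-12:
            raise ValueError("linear part is singular")
        self.source_spacing_um = tuple(float(s) for s in self.source_spacing_um)
        self.target_spacing_um = float(self.target_spacing_um)

    @classmethod
    def identity(cls, source_spacing_um, target_spacing_um) -> "AffineTransform":
        return cls(np.hstack([np.eye(3), np.zeros((3, 1))]),
                   source_spacing_um, target_spacing_um)

    def apply_um(self, pts_um: np.ndarray) -> np.ndarray:
        """(N, 3) stack µm points -> (N, 3) atlas µm points."""
        pts = np.atleast_2d(np.asarray(pts_um, dtype=float))
        return pts @ self.matrix[:, :3].T + self.matrix[:, 3]

    def apply_voxels(self, pts_vox: np.ndarray) -> np.ndarray:
        """(N, 3) stack voxel coordinates -> (N, 3) atlas voxel coordinates."""
        um = np.atleast_2d(np.asarray(pts_vox, dtype=float)) * self.source_spacing_um
        return self.apply_um(um) / self.target_spacing_um

    def inverse(self) -> "AffineTransform":
        a = np.linalg.inv(self.matrix[:, :3])
        t = -a @ self.matrix[:, 3]
        inv = AffineTransform.__new__(AffineTransform)
        inv.matrix = np.hstack([a, t[:, None]])
        inv.source_spacing_um = (self.target_spacing_um,) * 3
        inv.target_spacing_um = float(np.mean(self.source_spacing_um))
        return inv

    # --------------------------------------------------------------------- IO
    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "matrix_3x4_row_major": self.matrix.tolist(),
            "source_spacing_um_zyx": list(self.source_spacing_um),
            "target_spacing_um": self.target_spacing_um,
            "convention": "atlas_um = A @ [z_um, y_um, x_um, 1]; "
                          "coordinates 0-based voxel centers",
        }, indent=1))

    @classmethod
    def from_json(cls, path) -> "AffineTransform":
        d = json.loads(Path(path).read_text())
        return cls(np.array(d["matrix_3x4_row_major"], dtype=float),
                   tuple(d["source_spacing_um_zyx"]),
                   float(d["target_spacing_um"]))
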