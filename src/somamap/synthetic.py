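"""Synthetic cleared-brain data with known ground truth.

Generates (i) toy atlases — recursive rectangular partitions with a
hierarchical ontology, a ventricle leaf and a fiber-tract leaf — and (ii)
image stacks that emulate immunolabeled somata in cleared tissue: compact
Gaussian blobs on a noisy background with a smooth multiplicative
illumination field and bright ventricle lumens.  Every scene carries its
ground-truth cell list, label mask, ventricle mask and the exact
stack-to-atlas affine, so each downstream stage can be validated without
any acquired data.

The defaults mirror a scaled-down c-Fos acquisition: soma radius 6 ± 1 µm,
peak-to-background signal-to-noise ratio ~4, and a ±15% linear illumination
gradient across the field of view.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .ontology import AtlasVolume, Ontology, RegionNode
from .transform import AffineTransform
from .types import CellInstance, ImageStack

BACKGROUND = 200.0  # mean parenchyma counts (16-bit scale)
NOISE_SIGMA = 25.0  # additive noise sd; peak amplitude = snr * sigma
VENTRICLE_BRIGHTNESS = 3.0  # lumen background multiplier


# -------------------------------------------------------------- toy atlases

def _random_color(rng) -> tuple[int, int, int]:
    return tuple(int(c) for c in rng.integers(40, 256, size=3))


def generate_toy_atlas(shape, levels: int, regions_per_split: int = 2,
                       seed: int = 0) -> AtlasVolume:
    """Recursive rectangular partition nested ``levels`` deep, with a
    ventricle leaf and a fiber-tract leaf carved in as children of the root.

    The partition splits each box along its longest axis into
    ``regions_per_split`` slabs at slightly randomized positions, giving
    ``regions_per_split**(levels-1)`` gray-matter leaves.  Deterministic for
    a fixed seed.  Atlas spacing is fixed at 50 µm/voxel.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < 8 for s in shape):
        raise ValueError("shape must be 3D with every axis >= 8 voxels")
    if not 2 <= levels <= 11:
        raise ValueError("levels must be in 2..11")
    if regions_per_split < 2:
        raise ValueError("regions_per_split must be >= 2")
    rng = np.random.default_rng(seed)
    labels = np.zeros(shape, dtype=np.int32)

    next_id = [1]

    def new_id() -> int:
        nid = next_id[0]
        next_id[0] += 1
        return nid

    nodes: list[RegionNode] = []
    root = RegionNode(new_id(), "ROOT", "toy brain", None, 1, _random_color(rng))
    nodes.append(root)

    # (box, parent_id, level); box is half-open ((z0,y0,x0),(z1,y1,x1))
    boxes = [(((0, 0, 0), shape), root.id, 1)]
    for _depth in range(levels - 1):
        nxt = []
        for (lo, hi), parent, lev in boxes:
            size = [hi[i] - lo[i] for i in range(3)]
            ax = int(np.argmax(size))
            cuts = [lo[ax]]
            for j in range(1, regions_per_split):
                base = lo[ax] + j * size[ax] / regions_per_split
                jitter = rng.uniform(-0.1, 0.1) * size[ax] / regions_per_split
                cuts.append(int(np.clip(round(base + jitter),
                                        cuts[-1] + 1, hi[ax] - (regions_per_split - j))))
            cuts.append(hi[ax])
            for j in range(regions_per_split):
                clo, chi = list(lo), list(hi)
                clo[ax], chi[ax] = cuts[j], cuts[j + 1]
                node = RegionNode(new_id(), f"R{next_id[0]-1}",
                                  f"region {next_id[0]-1}", parent, lev + 1,
                                  _random_color(rng))
                nodes.append(node)
                nxt.append(((tuple(clo), tuple(chi)), node.id, lev + 1))
        boxes = nxt
    for (lo, hi), nid, _lev in boxes:
        labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = nid

    # ventricle: a cylindrical lumen along z through the volume center
    vent = RegionNode(new_id(), "VL", "ventricle lumen", root.id, 2,
                      _random_color(rng), is_ventricle=True)
    nodes.append(vent)
    zz, yy, xx = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    r = max(2.0, min(shape[1], shape[2]) / 10.0)
    cy, cx = shape[1] / 2.0, shape[2] / 2.0
    labels[((yy - cy) ** 2 + (xx - cx) ** 2) <= r * r] = vent.id

    # fiber tract: a thin slab offset from the center
    fib = RegionNode(new_id(), "fxs", "fiber tracts", root.id, 2,
                     _random_color(rng), is_fiber_tract=True)
    nodes.append(fib)
    y0 = int(0.72 * shape[1])
    th = max(1, shape[1] // 16)
    labels[:, y0:y0 + th, :] = fib.id

    return AtlasVolume(labels, spacing_um=50.0, ontology=Ontology(nodes))


# ------------------------------------------------------------------- scenes

@dataclass
class SyntheticScene:
    stack: ImageStack
    label_mask: np.ndarray  # (D,H,W) uint8, ground-truth cell voxels
    cells: list[CellInstance]
    cell_regions: list[int]  # generating leaf region per cell
    ventricle_mask: np.ndarray  # (D,H,W) uint8
    atlas_transform: AffineTransform
    seed: int
    atlas: AtlasVolume | None = field(default=None, repr=False)

    def __post_init__(self):
        if not (self.stack.shape == self.label_mask.shape == self.ventricle_mask.shape):
            raise ValueError("stack, label_mask, ventricle_mask shapes differ")
        for c in self.cells:
            z, y, x = (int(v) for v in c.center_zyx)
            if not self.label_mask[z, y, x]:
                raise ValueError(f"cell {c.label} center not foreground")


def _truncnorm(rng, mean, sd, low, n):
    out = rng.normal(mean, sd, size=n)
    bad = out < low
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out < low
    return out


def generate_scene(atlas: AtlasVolume, upscale: int = 4,
                   cells_per_mm3=30.0, cell_radius_um=(25.0, 4.0),
                   snr: float = 4.0, illumination_gradient: float = 0.3,
                   seed: int = 0) -> SyntheticScene:
    """Render a synthetic image stack over an atlas.

    ``cells_per_mm3`` is either a scalar (applied to every gray-matter leaf)
    or a mapping {leaf region id: density}.  Cell centers follow a
    homogeneous Poisson point process per region; each cell is a Gaussian
    blob whose binary support is a sphere of the drawn radius.  The stored
    affine is the exact stack-to-atlas map (identity in µm, since the stack
    is the upscaled atlas grid).
    """
    if upscale < 1:
        raise ValueError("upscale must be >= 1")
    if snr <= 0:
        raise ValueError("snr must be positive")
    rng = np.random.default_rng(seed)
    ont = atlas.ontology
    leaves = ont.leaves()
    if isinstance(cells_per_mm3, dict):
        unknown = set(cells_per_mm3) - set(leaves)
        if unknown:
            raise ValueError(f"unknown region ids in density map: {sorted(unknown)}")
        density = {int(k): float(v) for k, v in cells_per_mm3.items()}
    else:
        density = {l: float(cells_per_mm3) for l in leaves
                   if not (ont[l].is_ventricle or ont[l].is_fiber_tract)}
    if any(v < 0 for v in density.values()):
        raise ValueError("densities must be >= 0")

    spacing = atlas.spacing_um / upscale
    shape = tuple(s * upscale for s in atlas.shape)
    vvox_mm3 = (atlas.spacing_um * 1e-3) ** 3

    # --- sample non-overlapping cell centers region by region
    mean_r, sd_r = cell_radius_um
    centers, radii, regions = [], [], []
    for rid in sorted(density):
        d = density[rid]
        if d == 0:
            continue
        coords = np.argwhere(atlas.labels == rid)
        if coords.size == 0:
            continue
        n = rng.poisson(d * len(coords) * vvox_mm3)
        if n == 0:
            continue
        # rejected placements (border clip / blob overlap) are resampled so
        # the per-region count stays Poisson(d * V)
        accepted, attempts = 0, 0
        while accepted < n and attempts < 50 * n + 100:
            attempts += 1
            pick = coords[rng.integers(0, len(coords))]
            p = (pick + rng.random(3)) * upscale  # full-res voxel coords
            r = float(_truncnorm(rng, mean_r, sd_r, 1.5, 1)[0])
            if np.any(np.floor(p) < 1) or np.any(p > np.array(shape) - 2):
                continue
            ok = True
            for q, rq in zip(centers, radii):
                if np.sum((np.asarray(q) - p) ** 2) * spacing ** 2 < (r + rq + 2 * spacing) ** 2:
                    ok = False
                    break
            if ok:
                centers.append(tuple(p))
                radii.append(r)
                regions.append(rid)
                accepted += 1

    # --- render blobs
    img = np.full(shape, BACKGROUND, dtype=np.float64)
    label_mask = np.zeros(shape, dtype=np.uint8)
    amp = snr * NOISE_SIGMA
    cells: list[CellInstance] = []
    for i, (c, r) in enumerate(zip(centers, radii)):
        r_vox = r / spacing
        w = int(np.ceil(r_vox)) + 2
        sl = tuple(slice(max(0, int(c[a]) - w), min(shape[a], int(c[a]) + w + 1))
                   for a in range(3))
        zz, yy, xx = np.meshgrid(*[np.arange(s.start, s.stop) for s in sl],
                                 indexing="ij")
        d2 = ((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2) * spacing ** 2
        sigma = r / 1.5
        img[sl] += amp * np.exp(-d2 / (2 * sigma ** 2))
        support = d2 <= r * r
        # the voxel containing the center always belongs to the cell
        support[tuple(int(c[a]) - sl[a].start for a in range(3))] = True
        label_mask[sl][support] = 1
        vox = np.argwhere(support)
        lo = vox.min(axis=0) + [s.start for s in sl]
        hi = vox.max(axis=0) + [s.start for s in sl] + 1
        cells.append(CellInstance(
            label=i + 1, center_zyx=tuple(float(v) for v in c),
            volume_vox=int(support.sum()),
            bbox=(int(lo[0]), int(lo[1]), int(lo[2]),
                  int(hi[0]), int(hi[1]), int(hi[2]))))

    # --- ventricles, illumination, noise
    vent_leaves = [l for l in leaves if ont[l].is_ventricle]
    vent_atlas = np.isin(atlas.labels, vent_leaves)
    ventricle_mask = np.kron(vent_atlas, np.ones((upscale,) * 3, dtype=bool))
    # lumens are bright with a smooth falloff (scattering, label diffusion),
    # not a razor edge
    lumen = ndimage.gaussian_filter(ventricle_mask.astype(np.float64), 2.0)
    img += BACKGROUND * (VENTRICLE_BRIGHTNESS - 1.0) * lumen

    yy = np.arange(shape[1]) / shape[1] - 0.5
    xx = np.arange(shape[2]) / shape[2] - 0.5
    illum = 1.0 + illumination_gradient * (xx[None, :] + 0.5 * yy[:, None])
    img *= illum[None, :, :]
    img += rng.normal(0.0, NOISE_SIGMA, size=shape)
    stack = ImageStack(np.clip(img, 0, 65535).astype(np.uint16),
                       spacing_um=(spacing,) * 3)

    tx = AffineTransform.identity((spacing,) * 3, atlas.spacing_um)
    return SyntheticScene(stack=stack, label_mask=label_mask, cells=cells,
                          cell_regions=regions,
                          ventricle_mask=ventricle_mask.astype(np.uint8),
                          atlas_transform=tx, seed=seed, atlas=atlas)


# ------------------------------------------------------------------ patches

def sample_patches(scene: SyntheticScene, n: int, patch_size=(100, 100, 100),
                   stratify_by_signal: bool = False, seed: int = 0):
    """Draw ``n`` random (raw, label) patch pairs from a scene.

    With ``stratify_by_signal`` the returned list is ranked by foreground
    voxel count (descending), ready for :func:`stratified_split`.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    patch_size = tuple(int(p) for p in patch_size)
    shape = scene.stack.shape
    if any(p > s for p, s in zip(patch_size, shape)):
        raise ValueError(f"patch_size {patch_size} exceeds scene shape {shape}")
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n):
        corner = [int(rng.integers(0, s - p + 1)) for s, p in zip(shape, patch_size)]
        sl = tuple(slice(c, c + p) for c, p in zip(corner, patch_size))
        pairs.append((scene.stack.voxels[sl].copy(), scene.label_mask[sl].copy()))
    if stratify_by_signal:
        pairs.sort(key=lambda rl: int(rl[1].sum()), reverse=True)
    return pairs


def stratified_split(pairs, n_test: int, seed: int = 0):
    """Split patch pairs into (train, test) so that both cover the full range
    of signal content.

    Pairs are ranked by foreground voxel count and the test set is drawn
    systematically across the ranking (every len/n_test-th patch, with a
    seeded phase), so high- and low-signal strata appear in both splits in
    proportion.
    """
    if not 0 < n_test < len(pairs):
        raise ValueError("n_test must be in 1..len(pairs)-1")
    ranked = sorted(range(len(pairs)), key=lambda i: int(pairs[i][1].sum()),
                    reverse=True)
    stride = len(pairs) / n_test
    phase = np.random.default_rng(seed).random()
    test_idx = {ranked[int((j + phase) * stride) % len(pairs)] for j in range(n_test)}
    while len(test_idx) < n_test:  # collisions from rounding
        for i in ranked:
            if i not in test_idx:
                test_idx.add(i)
                break
    train = [pairs[i] for i in range(len(pairs)) if i not in test_idx]
    test = [pairs[i] for i in sorted(test_idx)]
    return train, test


# ----------------------------------------------------------------------- IO

def write_scene(scene: SyntheticScene, outdir) -> None:
    """Write a scene as TIFF stacks + CSV ground truth + JSON sidecars."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "raw.tif", scene.stack.voxels)
    tifffile.imwrite(out / "cell_mask.tif", scene.label_mask * np.uint8(255))
    tifffile.imwrite(out / "ventricle_mask.tif", scene.ventricle_mask * np.uint8(255))
    rows = [{
        "id": c.label, "z": c.center_zyx[0], "y": c.center_zyx[1],
        "x": c.center_zyx[2], "volume_vox": c.volume_vox, "region_id": rid,
    } for c, rid in zip(scene.cells, scene.cell_regions)]
    pd.DataFrame(rows, columns=["id", "z", "y", "x", "volume_vox", "region_id"]
                 ).to_csv(out / "cells.csv", index=False)
    scene.atlas_transform.to_json(out / "transform.json")
    if scene.atlas is not None:
        tifffile.imwrite(out / "atlas.tif", scene.atlas.labels.astype(np.int32))
        scene.atlas.ontology.to_json(out / "ontology.json")
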