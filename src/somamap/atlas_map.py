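"""Atlas alignment and cell-to-region assignment.

The downsampled brain is aligned to an isotropic atlas template with a
12-parameter affine (moments initialization, normalized-mutual-information
refinement).  Deformable registration is deliberately out of scope: the
transform interface also imports externally computed affines, so a point
transform produced by a dedicated registration tool can be dropped in.

Cell center points travel: stack voxel -> physical µm -> affine -> atlas
µm -> atlas voxel (floor) -> region label.  Out-of-atlas cells get region 0
and are reported, never dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .ontology import AtlasVolume, Ontology
from .transform import AffineTransform
from .types import CellInstance, ImageStack


# ------------------------------------------------------------- registration

def _nmi(a: np.ndarray, b: np.ndarray, bins: int = 32) -> float:
    """Studholme normalized mutual information (H(A)+H(B))/H(A,B).

    ``a`` is the resampled moving image, ``b`` the fixed template.  The
    histogram pool excludes voxels outside the moving image's support
    (exact zeros from resampling), with fixed [0,1] bin edges, preventing
    the border-truncation bias of a union-foreground pool.
    """
    ref = b > 0.02
    fg = (a > 0) & (ref | (a > 0.02))
    if fg.sum() < 100:
        return 0.0
    h, _, _ = np.histogram2d(a[fg], b[fg], bins=bins, range=[[0, 1], [0, 1]])
    p = h / h.sum()
    pa = p.sum(axis=1)
    pb = p.sum(axis=0)
    nz = p > 0
    hab = -np.sum(p[nz] * np.log(p[nz]))
    ha = -np.sum(pa[pa > 0] * np.log(pa[pa > 0]))
    hb = -np.sum(pb[pb > 0] * np.log(pb[pb > 0]))
    return (ha + hb) / hab if hab > 0 else 0.0


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized cross-correlation over the moving image's support.

    For mono-modal alignment NCC has a single sharp optimum and, unlike
    histogram NMI, offers no reward for transforms that degenerate the
    intensity distribution — on desk-scale volumes NMI's optimum can sit
    several voxels from the true transform.  Restricting the pool to the
    moving support removes the bias that resampling zeros otherwise add;
    the pool-shrinkage exploit this opens up is closed by the caller's
    translation trust region (see :func:`register_affine`).
    """
    sup = a > 0
    if sup.sum() < 100:
        return 0.0
    x = a[sup] - a[sup].mean()
    y = b[sup] - b[sup].mean()
    d = np.sqrt((x * x).sum() * (y * y).sum())
    return float((x * y).sum() / d) if d > 0 else 0.0


def _ncc_full(a: np.ndarray, b: np.ndarray) -> float:
    """NCC over the full template domain: sliding content out of the frame
    pairs zeros against template structure and is penalized, which makes
    this variant robust for the initial translation capture."""
    x = a - a.mean()
    y = b - b.mean()
    d = np.sqrt((x * x).sum() * (y * y).sum())
    return float((x * y).sum() / d) if d > 0 else 0.0


def _norm01(v: np.ndarray) -> np.ndarray:
    v = v.astype(np.float32)
    lo, hi = np.percentile(v, [1, 99])
    if hi <= lo:
        raise ValueError("degenerate (all-constant) image")
    return np.clip((v - lo) / (hi - lo), 0, 1)


def _params_to_matrix(p, com_m, com_t):
    """12 params (t, log-scale, rotations, shears) -> voxel-space (M, t)."""
    t = p[0:3]
    s = np.exp(p[3:6])
    rz, ry, rx = p[6:9]
    cz, sz = np.cos(rz), np.sin(rz)
    cy, sy = np.cos(ry), np.sin(ry)
    cx, sx = np.cos(rx), np.sin(rx)
    Rz = np.array([[1, 0, 0], [0, cz, -sz], [0, sz, cz]])
    Ry = np.array([[cy, 0, -sy], [0, 1, 0], [sy, 0, cy]])
    Rx = np.array([[cx, -sx, 0], [sx, cx, 0], [0, 0, 1]])
    Sh = np.eye(3)
    Sh[0, 1], Sh[0, 2], Sh[1, 2] = p[9:12]
    M = Rz @ Ry @ Rx @ Sh @ np.diag(s)
    # moving voxel v -> template voxel: M @ (v - com_m) + com_t + t
    off = com_t + t - M @ com_m
    return M, off


def register_affine(moving: ImageStack, atlas_template: ImageStack,
                    init: str = "moments", metric: str = "ncc",
                    seed: int = 0) -> AffineTransform:
    """Affine alignment of an isotropic stack to an isotropic template.

    Initialization places centers of mass on top of each other and matches
    per-axis second moments; a staged, bounded Powell search over the 12
    affine parameters then maximizes the similarity metric — normalized
    cross-correlation by default, normalized mutual information as an
    option for multi-modal pairs.  Deterministic (the optimizer is
    derivative-free and seeded subsampling is not used at these volume
    sizes).
    """
    if init != "moments" or metric not in ("ncc", "nmi"):
        raise ValueError("supported: init='moments', metric in {'ncc','nmi'}")
    sim = _ncc if metric == "ncc" else _nmi
    if not (moving.is_isotropic and atlas_template.is_isotropic):
        raise ValueError("both volumes must be isotropic")
    mov = _norm01(moving.voxels)
    tpl = _norm01(atlas_template.voxels)

    def moments(v):
        w = v / v.sum()
        idx = np.indices(v.shape).reshape(3, -1)
        com = idx @ w.ravel()
        var = (idx ** 2) @ w.ravel() - com ** 2
        return com, np.sqrt(np.maximum(var, 1e-9))

    com_m, sd_m = moments(mov)
    com_t, sd_t = moments(tpl)
    p0 = np.zeros(12)
    p0[3:6] = np.log(sd_t / sd_m)

    def _resample(p):
        M, _off = _params_to_matrix(p, com_m, com_t)
        try:
            Minv = np.linalg.inv(M)
        except np.linalg.LinAlgError:
            return None
        return ndimage.affine_transform(
            mov, Minv, offset=com_m - Minv @ (com_t + p[0:3]),
            output_shape=tpl.shape, order=1, mode="constant", cval=0.0)

    def make_objective(fn):
        def objective(p):
            res = _resample(p)
            return 1.0 if res is None else -fn(res, tpl)
        return objective

    # Staged, bounded refinement.  Stage 1 captures translation with
    # full-domain NCC (robust: sliding content out of frame is penalized);
    # later stages refine scale/rotation/shear with the support-restricted
    # metric (sharp at sub-voxel scale) inside a translation trust region
    # of +-3 voxels around the captured translation, which closes the
    # pool-shrinkage exploit of support-restricted metrics.
    span = max(tpl.shape) * 0.35
    lo = np.array([-span] * 3 + [-0.25] * 3 + [-0.2] * 3 + [-0.1] * 3)
    hi = -lo
    capture = make_objective(_ncc_full if metric == "ncc" else _nmi)
    refine = make_objective(sim)
    stages = [(slice(0, 3), capture), (slice(0, 6), refine),
              (slice(0, 12), refine), (slice(0, 12), refine)]
    p = p0.copy()
    b_lo = p0 + lo
    b_hi = p0 + hi
    for i, (free, objective) in enumerate(stages):
        def stage_obj(q, free=free, base=p.copy(), objective=objective):
            full = base.copy()
            full[free] = q
            return objective(full)
        f_init = stage_obj(p[free])
        res = optimize.minimize(
            stage_obj, p[free], method="Powell",
            bounds=list(zip(b_lo[free], b_hi[free])),
            options={"maxiter": 30, "xtol": 3e-4, "ftol": 1e-7})
        # bounded Powell may wander off a sharp optimum and report a point
        # worse than its start; never accept a regression
        if res.fun <= f_init:
            p[free] = res.x
        if i == 0:  # trust region around the captured translation
            b_lo[0:3] = p[0:3] - 3.0
            b_hi[0:3] = p[0:3] + 3.0
    M, off = _params_to_matrix(p, com_m, com_t)

    # voxel-space (M, off) -> µm-space 3x4 matrix
    s_m = moving.spacing_um[0]
    s_t = atlas_template.spacing_um[0]
    A = M * (s_t / s_m)
    t_um = off * s_t
    return AffineTransform(np.hstack([A, t_um[:, None]]),
                           moving.spacing_um, s_t)


def import_point_transform(path) -> AffineTransform:
    """Load an externally produced affine (JSON, 3x4 row-major); validated
    exactly like an internally estimated one."""
    return AffineTransform.from_json(path)


# ----------------------------------------------------------------- mapping

@dataclass
class MappedCell:
    cell: CellInstance
    atlas_zyx: tuple[int, int, int]
    region_id: int  # 0 = outside atlas / unassigned
    region_acronym: str
    region_color: tuple[int, int, int]


def map_cells(cells: list[CellInstance], source_spacing_um,
              transform: AffineTransform, atlas: AtlasVolume) -> list[MappedCell]:
    """Assign every cell an atlas voxel and region.

    Every input cell appears exactly once in the output; cells landing
    outside the atlas bounds or on background voxels get region 0.
    """
    if any(s <= 0 for s in source_spacing_um):
        raise ValueError("spacings must be positive")
    out: list[MappedCell] = []
    if not cells:
        return out
    pts = np.array([c.center_zyx for c in cells], dtype=float)
    um = pts * np.asarray(source_spacing_um)
    atlas_vox = np.floor(transform.apply_um(um) / atlas.spacing_um).astype(int)
    shape = np.array(atlas.shape)
    for c, av in zip(cells, atlas_vox):
        inside = bool(np.all(av >= 0) and np.all(av < shape))
        rid = int(atlas.labels[tuple(av)]) if inside else 0
        if rid and rid in atlas.ontology:
            node = atlas.ontology[rid]
            out.append(MappedCell(c, tuple(int(v) for v in av), rid,
                                  node.acronym, node.color))
        else:
            out.append(MappedCell(c, tuple(int(v) for v in av), 0,
                                  "unassigned", (0, 0, 0)))
    return out


# ------------------------------------------------------------------- tables

CELL_COLUMNS = ["label", "z", "y", "x", "volume_vox",
                "atlas_z", "atlas_y", "atlas_x",
                "region_id", "region_acronym", "region_color_hex"]
REGION_COLUMNS = ["region_id", "acronym", "level", "n_cells",
                  "region_volume_mm3", "density_cells_per_mm3"]


def make_tables(mapped: list[MappedCell], atlas: AtlasVolume,
                sample_id: str = "sample"):
    """The two canonical outputs: a per-cell table (one row per cell, with
    coordinates in both spaces and the region color code) and a region count
    table covering every leaf region, zero-filled, plus an 'unassigned' row.
    """
    cell_rows = [{
        "label": m.cell.label,
        "z": m.cell.center_zyx[0], "y": m.cell.center_zyx[1],
        "x": m.cell.center_zyx[2], "volume_vox": m.cell.volume_vox,
        "atlas_z": m.atlas_zyx[0], "atlas_y": m.atlas_zyx[1],
        "atlas_x": m.atlas_zyx[2], "region_id": m.region_id,
        "region_acronym": m.region_acronym,
        "region_color_hex": "{:02X}{:02X}{:02X}".format(*m.region_color),
    } for m in mapped]
    cells_df = pd.DataFrame(cell_rows, columns=CELL_COLUMNS)

    counts = cells_df["region_id"].value_counts().to_dict() if len(cells_df) else {}
    vox_counts = atlas.leaf_voxel_counts()
    vol_per_vox = (atlas.spacing_um * 1e-3) ** 3
    region_rows = []
    for rid in atlas.ontology.leaves():
        node = atlas.ontology[rid]
        vol = vox_counts.get(rid, 0) * vol_per_vox
        n = int(counts.get(rid, 0))
        region_rows.append({
            "region_id": rid, "acronym": node.acronym, "level": node.level,
            "n_cells": n, "region_volume_mm3": vol,
            "density_cells_per_mm3": n / vol if vol > 0 else 0.0,
        })
    region_rows.append({
        "region_id": 0, "acronym": "unassigned", "level": 0,
        "n_cells": int(counts.get(0, 0)), "region_volume_mm3": 0.0,
        "density_cells_per_mm3": 0.0,
    })
    region_df = pd.DataFrame(region_rows, columns=REGION_COLUMNS)
    region_df.attrs["sample_id"] = sample_id
    return cells_df, region_df


def aggregate_to_level(region_df: pd.DataFrame, ontology: Ontology,
                       level: int) -> pd.DataFrame:
    """Fold leaf counts onto each leaf's unique ancestor at ``level``.

    Leaves already at or above the level keep their own row; volumes
    aggregate identically and total cells are conserved (the unassigned row
    passes through untouched).
    """
    if not 1 <= level <= ontology.max_level:
        raise ValueError(f"level {level} outside ontology range")
    agg: dict[int, dict] = {}
    unassigned = None
    for row in region_df.itertuples():
        if row.region_id == 0:
            unassigned = row
            continue
        anc = ontology.ancestor_at_level(row.region_id, level)
        node = ontology[anc]
        a = agg.setdefault(anc, {
            "region_id": anc, "acronym": node.acronym, "level": node.level,
            "n_cells": 0, "region_volume_mm3": 0.0,
        })
        a["n_cells"] += row.n_cells
        a["region_volume_mm3"] += row.region_volume_mm3
    rows = sorted(agg.values(), key=lambda r: r["region_id"])
    for r in rows:
        r["density_cells_per_mm3"] = (
            r["n_cells"] / r["region_volume_mm3"] if r["region_volume_mm3"] > 0 else 0.0)
    if unassigned is not None:
        rows.append({
            "region_id": 0, "acronym": "unassigned", "level": 0,
            "n_cells": unassigned.n_cells, "region_volume_mm3": 0.0,
            "density_cells_per_mm3": 0.0,
        })
    out = pd.DataFrame(rows, columns=REGION_COLUMNS)
    out.attrs["sample_id"] = region_df.attrs.get("sample_id", "sample")
    return out


def write_cells_swc(mapped: list[MappedCell], path) -> None:
    """SWC-like point export (id, type, x, y, z, radius, parent=-1) for
    interoperability with swc-based point-transport tools."""
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for m in mapped:
            z, y, x = m.cell.center_zyx
            r = (3.0 * m.cell.volume_vox / (4.0 * np.pi)) ** (1 / 3)
            fh.write(f"{m.cell.label} 1 {x:.3f} {y:.3f} {z:.3f} {r:.3f} -1\n")
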