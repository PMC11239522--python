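"""Result rendering: cells color-coded by atlas region in image space, and
group density maps in atlas space.

The image-space overlay is a region-id-valued volume plus a color lookup
table (rather than baked RGB): each cell's voxels are painted with the id
of its atlas region, so thresholding on the painted value in any viewer
isolates a region, and the LUT supplies the region colors.
"""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import ndimage

from .atlas_map import MappedCell
from .ontology import AtlasVolume, Ontology
from .types import LabeledVolume


# -------------------------------------------------------------- cell overlay

def colorize_cells(labeled: LabeledVolume, mapped: list[MappedCell],
                   ontology: Ontology):
    """Repaint each cell's voxels with its region id.

    Returns ``(region_id_volume, lut)`` where the LUT is a DataFrame of
    (region_id, acronym, R, G, B).  Unassigned cells are painted with a
    reserved id one above the ontology's maximum.
    """
    ids = {c.label for c in labeled.instances}
    for m in mapped:
        if m.cell.label not in ids:
            raise ValueError(f"mapped cell label {m.cell.label} not in volume")
    unassigned_id = max(n.id for n in ontology.nodes) + 1
    out = np.zeros(labeled.shape, dtype=np.int32)
    lut_rows = {}
    for m in mapped:
        rid = m.region_id if m.region_id else unassigned_id
        z0, y0, x0, z1, y1, x1 = m.cell.bbox
        sub = labeled.labels[z0:z1, y0:y1, x0:x1] == m.cell.label
        out[z0:z1, y0:y1, x0:x1][sub] = rid
        if rid not in lut_rows:
            if m.region_id:
                node = ontology[m.region_id]
                lut_rows[rid] = (rid, node.acronym, *node.color)
            else:
                lut_rows[rid] = (rid, "unassigned", 255, 255, 255)
    lut = pd.DataFrame(sorted(lut_rows.values()),
                       columns=["region_id", "acronym", "R", "G", "B"])
    return out, lut


def lut_to_rgb(region_vol: np.ndarray, lut: pd.DataFrame) -> np.ndarray:
    """Expand a region-id volume to an RGB volume using the LUT."""
    maxid = int(region_vol.max())
    table = np.zeros((maxid + 1, 3), dtype=np.uint8)
    for r in lut.itertuples():
        if r.region_id <= maxid:
            table[r.region_id] = (r.R, r.G, r.B)
    return table[region_vol]


# -------------------------------------------------------------- density maps

def density_map(mapped_per_sample: list[list[MappedCell]], atlas: AtlasVolume,
                sigma_vox: float = 2.0, normalize_per_sample: bool = False) -> np.ndarray:
    """Group mean of per-sample smoothed cell-center histograms in atlas
    space.

    Each sample contributes a 3D histogram of its mapped cell centers at
    atlas resolution (unassigned/out-of-bounds cells excluded), optionally
    divided by its total mapped count, then Gaussian-smoothed with
    ``sigma_vox`` and averaged over samples.
    """
    if sigma_vox < 0:
        raise ValueError("sigma must be >= 0")
    if not mapped_per_sample:
        raise ValueError("no samples")
    acc = np.zeros(atlas.shape, dtype=np.float64)
    for mapped in mapped_per_sample:
        hist = np.zeros(atlas.shape, dtype=np.float64)
        pts = [m.atlas_zyx for m in mapped if m.region_id != 0]
        if pts:
            pts = np.asarray(pts)
            np.add.at(hist, (pts[:, 0], pts[:, 1], pts[:, 2]), 1.0)
        if normalize_per_sample and hist.sum() > 0:
            hist /= hist.sum()
        if sigma_vox > 0:
            hist = ndimage.gaussian_filter(hist, sigma_vox)
        acc += hist
    return acc / len(mapped_per_sample)


def projection_figure(vol: np.ndarray, axis: int = 0, output=None,
                      mode: str = "max", cmap: str = "inferno",
                      title: str | None = None):
    """Write a max- or mean-intensity projection with a colorbar to PNG."""
    if axis not in (0, 1, 2):
        raise ValueError("axis must be 0, 1 or 2")
    if mode == "max":
        img = vol.max(axis=axis)
    elif mode == "mean":
        img = vol.mean(axis=axis)
    else:
        raise ValueError("mode must be 'max' or 'mean'")
    fig, ax = plt.subplots(figsize=(5, 5))
    im = ax.imshow(img, cmap=cmap)
    ax.axis("off")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8, label="cells / voxel")
    if output is not None:
        fig.savefig(output, dpi=120, bbox_inches="tight")
        plt.close(fig)
        return None
    return fig, img
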