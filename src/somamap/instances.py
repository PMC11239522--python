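"""Instance extraction: connected components of a binary segmentation and
size filtering.

Touching cells are *not* split (plain connected components, as in the
standard light-sheet c-Fos stack); the size filter removes debris below and
clumps/artifacts above user-defined voxel-count bounds (inclusive).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from .types import CellInstance, LabeledVolume, MaskStack

#: map 6/18/26 neighborhood to scikit-image connectivity ranks
_CONN = {6: 1, 18: 2, 26: 3}

#: default size bounds (voxels) at the c-Fos acquisition scale
DEFAULT_MIN_VOX = 4
DEFAULT_MAX_VOX = 5000


def connected_components(mask: MaskStack | np.ndarray,
                         connectivity: int = 26) -> LabeledVolume:
    """Label maximal connected foreground components.

    Labels are assigned in deterministic order: sorted by the flat index of
    each component's first (lexicographically smallest) voxel.  Each
    instance carries its unweighted centroid, voxel volume and half-open
    bounding box.
    """
    if connectivity not in _CONN:
        raise ValueError("connectivity must be 6, 18 or 26")
    arr = mask.mask if isinstance(mask, MaskStack) else np.asarray(mask)
    vals = np.unique(arr)
    if not np.isin(vals, [0, 1]).all():
        raise ValueError("mask must be binary {0,1}")
    lab, n = measure.label(arr, connectivity=_CONN[connectivity],
                           return_num=True)
    lab = lab.astype(np.int32)
    if n == 0:
        return LabeledVolume(lab, [])
    # relabel so component order is lexicographic by first voxel
    flat_idx = np.arange(lab.size, dtype=np.int64).reshape(lab.shape)
    firsts = ndimage.minimum(flat_idx, labels=lab, index=np.arange(1, n + 1))
    order = np.argsort(firsts, kind="stable")
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[1 + order] = np.arange(1, n + 1)
    lab = remap[lab]

    objects = ndimage.find_objects(lab)
    centroids = ndimage.center_of_mass(arr, labels=lab, index=np.arange(1, n + 1))
    volumes = ndimage.sum_labels(arr, labels=lab, index=np.arange(1, n + 1))
    instances = []
    for i in range(n):
        sl = objects[i]
        instances.append(CellInstance(
            label=i + 1,
            center_zyx=tuple(float(c) for c in centroids[i]),
            volume_vox=int(volumes[i]),
            bbox=(sl[0].start, sl[1].start, sl[2].start,
                  sl[0].stop, sl[1].stop, sl[2].stop),
        ))
    return LabeledVolume(lab, instances)


def filter_by_size(vol: LabeledVolume, min_vox: int = DEFAULT_MIN_VOX,
                   max_vox: int = DEFAULT_MAX_VOX) -> LabeledVolume:
    """Keep instances with volume in [min_vox, max_vox] (inclusive bounds);
    removed voxels become background and survivors are relabeled 1..k in
    their original order."""
    if not 1 <= min_vox <= max_vox:
        raise ValueError("require 1 <= min_vox <= max_vox")
    keep = [c for c in vol.instances
            if min_vox <= c.volume_vox <= max_vox]
    remap = np.zeros(max([c.label for c in vol.instances], default=0) + 1,
                     dtype=np.int32)
    new_instances = []
    for new_label, c in enumerate(keep, start=1):
        remap[c.label] = new_label
        new_instances.append(CellInstance(
            label=new_label, center_zyx=c.center_zyx,
            volume_vox=c.volume_vox, bbox=c.bbox))
    return LabeledVolume(remap[vol.labels], new_instances)


# ------------------------------------------------------------------------ IO

def cells_to_frame(vol: LabeledVolume) -> pd.DataFrame:
    rows = [{
        "label": c.label, "z": c.center_zyx[0], "y": c.center_zyx[1],
        "x": c.center_zyx[2], "volume_vox": c.volume_vox,
        "bbox_z0": c.bbox[0], "bbox_y0": c.bbox[1], "bbox_x0": c.bbox[2],
        "bbox_z1": c.bbox[3], "bbox_y1": c.bbox[4], "bbox_x1": c.bbox[5],
    } for c in vol.instances]
    cols = ["label", "z", "y", "x", "volume_vox",
            "bbox_z0", "bbox_y0", "bbox_x0", "bbox_z1", "bbox_y1", "bbox_x1"]
    return pd.DataFrame(rows, columns=cols)


def frame_to_cells(df: pd.DataFrame) -> list[CellInstance]:
    return [CellInstance(
        label=int(r.label), center_zyx=(float(r.z), float(r.y), float(r.x)),
        volume_vox=int(r.volume_vox),
        bbox=(int(r.bbox_z0), int(r.bbox_y0), int(r.bbox_x0),
              int(r.bbox_z1), int(r.bbox_y1), int(r.bbox_x1)))
        for r in df.itertuples()]
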