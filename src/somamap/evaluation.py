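"""Two-track segmentation evaluation: voxelwise (volumetric) and
instance-wise, with global aggregation across test patches.

Volumetric scores compare every predicted voxel against the reference
annotation.  Instance scores use the overlap rule standard in cell-detection
benchmarking:

* a predicted instance sharing >= 1 voxel with any reference instance is a
  true positive;
* a predicted instance with zero reference overlap is a false positive;
* a reference instance with zero predicted overlap is a false negative.

The rule counts true positives on *predictions* and false negatives on
*references*; when two predictions hit the same reference cell both count
as TP, so TP + FN can exceed the number of reference cells.  This asymmetry
is intentional and preserved.

Scores are always computed from counts aggregated over all patches first
("global" aggregation) — never by averaging per-patch scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .instances import connected_components
from .types import LabeledVolume, MaskStack

#: sentinel for a metric whose denominator is zero
UNDEFINED = float("nan")


@dataclass
class EvalCounts:
    vox_tp: int = 0
    vox_fp: int = 0
    vox_fn: int = 0
    vox_tn: int = 0
    inst_tp: int = 0
    inst_fp: int = 0
    inst_fn: int = 0

    def __add__(self, other: "EvalCounts") -> "EvalCounts":
        return EvalCounts(*(getattr(self, f) + getattr(other, f)
                            for f in self.__dataclass_fields__))


@dataclass
class EvalScores:
    dice: float
    sensitivity: float
    precision: float

    @property
    def f1(self) -> float:
        """Alias: the Dice of instance counts is the instance F1 score."""
        return self.dice


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); returning NaN")
        return UNDEFINED
    return num / den


def _scores(tp: int, fp: int, fn: int) -> EvalScores:
    return EvalScores(
        dice=_ratio(2 * tp, 2 * tp + fp + fn, "dice"),
        sensitivity=_ratio(tp, tp + fn, "sensitivity"),
        precision=_ratio(tp, tp + fp, "precision"),
    )


def dice_from_precision_sensitivity(precision: float, sensitivity: float) -> float:
    """Instance Dice (F1) as the harmonic mean of precision and sensitivity."""
    if precision + sensitivity == 0:
        return UNDEFINED
    return 2 * precision * sensitivity / (precision + sensitivity)


# ------------------------------------------------------------------ counting

def voxel_confusion(pred: MaskStack | np.ndarray,
                    ref: MaskStack | np.ndarray) -> EvalCounts:
    """Exact voxelwise confusion counts between two binary volumes."""
    p = (pred.mask if isinstance(pred, MaskStack) else np.asarray(pred)).astype(bool)
    r = (ref.mask if isinstance(ref, MaskStack) else np.asarray(ref)).astype(bool)
    if p.shape != r.shape:
        raise ValueError("shape mismatch")
    return EvalCounts(
        vox_tp=int((p & r).sum()), vox_fp=int((p & ~r).sum()),
        vox_fn=int((~p & r).sum()), vox_tn=int((~p & ~r).sum()),
    )


def instance_match(pred: LabeledVolume, ref: LabeledVolume,
                   iou_threshold: float = 0.0) -> EvalCounts:
    """Instance-level TP/FP/FN under the >=1-voxel overlap rule.

    With ``iou_threshold`` > 0 a stricter criterion is applied: a predicted
    instance only counts as TP if its best IoU against a single reference
    instance reaches the threshold.
    """
    if pred.labels.shape != ref.labels.shape:
        raise ValueError("shape mismatch")
    pl, rl = pred.labels, ref.labels
    n_pred = len(pred.instances)
    n_ref = len(ref.instances)
    both = (pl > 0) & (rl > 0)
    if iou_threshold <= 0:
        tp_pred = np.unique(pl[both])
        hit_ref = np.unique(rl[both])
        inst_tp = len(tp_pred)
    else:
        pr = np.stack([pl[both], rl[both]], axis=1)
        uniq, cnt = np.unique(pr, axis=0, return_counts=True)
        vol_p = {c.label: c.volume_vox for c in pred.instances}
        vol_r = {c.label: c.volume_vox for c in ref.instances}
        tp_set, hit = set(), set()
        for (a, b), inter in zip(uniq, cnt):
            iou = inter / (vol_p[int(a)] + vol_r[int(b)] - inter)
            if iou >= iou_threshold:
                tp_set.add(int(a))
                hit.add(int(b))
        inst_tp = len(tp_set)
        hit_ref = np.array(sorted(hit))
    return EvalCounts(
        inst_tp=inst_tp,
        inst_fp=n_pred - inst_tp,
        inst_fn=n_ref - len(hit_ref),
    )


def evaluate_patch(pred_mask, ref_mask, connectivity: int = 26) -> EvalCounts:
    """Full per-patch counts: voxel confusion + instance matching."""
    vox = voxel_confusion(pred_mask, ref_mask)
    inst = instance_match(connected_components(pred_mask, connectivity),
                          connected_components(ref_mask, connectivity))
    return vox + inst


def aggregate_and_score(per_patch: list[EvalCounts]):
    """Sum counts over patches, then apply the score formulas once.

    Returns ``(volumetric_scores, instance_scores, total_counts)``.
    """
    if not per_patch:
        raise ValueError("no patches to aggregate")
    total = per_patch[0]
    for c in per_patch[1:]:
        total = total + c
    vol = _scores(total.vox_tp, total.vox_fp, total.vox_fn)
    inst = _scores(total.inst_tp, total.inst_fp, total.inst_fn)
    return vol, inst, total


# ------------------------------------------------- method-comparison report

def tp_comparison_report(tp_counts: dict[str, int], ours: str) -> dict:
    """Fold-difference report of true-positive counts between methods.

    For each competitor the report states how many times more cells the
    ``ours`` method captured (``fold_more_tp``) and the same figure as a
    percentage increase (``percent_more_tp``).
    """
    if ours not in tp_counts:
        raise KeyError(f"{ours!r} not in counts")
    ref = tp_counts[ours]
    out = {}
    for name, tp in tp_counts.items():
        if name == ours:
            continue
        out[name] = {
            "tp": tp,
            "fold_more_tp": UNDEFINED if tp == 0 else ref / tp,
            "percent_more_tp": UNDEFINED if tp == 0 else 100.0 * (ref / tp - 1.0),
        }
    return out
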