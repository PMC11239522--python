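"""End-to-end orchestration: one config, one call, all stages.

Stage order mirrors the standard whole-brain mapping pipeline: downsample
-> ventricle mask (optional) -> sliding-window inference -> binarize ->
connected components -> size filter -> atlas registration (or imported
transform) -> cell-to-atlas mapping -> tables -> visualization.  Every
intermediate is written as a standard file (TIFF/CSV/JSON) so stages can be
re-used independently, and a JSON run report records versions, seeds,
timings and per-stage counts.  Re-running over a completed output directory
skips finished stages unless forced.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .atlas_map import (make_tables, map_cells, register_affine,
                        import_point_transform)
from .instances import (cells_to_frame, connected_components, filter_by_size,
                        frame_to_cells)
from .ontology import AtlasVolume, Ontology
from .segmentation import (TrainedModel, UNetConfig, binarize, build_unet,
                           load_checkpoint, save_checkpoint,
                           sliding_window_infer, train)
from .evaluation import aggregate_and_score, evaluate_patch
from .types import ImageStack, MaskStack
from .ventricle import (VoxelClassifier, apply_mask, downsample_iso,
                        predict_mask, upsample_mask)
from .visualization import colorize_cells, density_map, projection_figure
from .transform import AffineTransform


@dataclass
class PipelineConfig:
    """Paths, stage toggles and numeric knobs for one sample run."""

    raw_stack: str
    model_checkpoint: str
    output_dir: str
    atlas_labels: str | None = None
    ontology: str | None = None
    atlas_template: str | None = None
    ventricle_classifier: str | None = None
    point_transform: str | None = None  # pre-computed affine JSON

    mask_ventricles: bool = True
    spacing_um: tuple[float, float, float] = (6.0, 1.625, 1.625)
    atlas_spacing_um: float = 50.0
    target_um: float = 25.0
    window: tuple[int, int, int] = (64, 64, 64)
    overlap: float = 0.25
    threshold: float = 0.5
    upsample_threshold: float = 0.5
    mask_dilation_vox: int = 2
    connectivity: int = 26
    min_size_vox: int = 4
    max_size_vox: int = 5000
    sigma_vox: float = 2.0
    alpha: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap in [0,1)")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold in (0,1)")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6/18/26")
        if not 1 <= self.min_size_vox <= self.max_size_vox:
            raise ValueError("bad size bounds")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        d = json.loads(Path(path).read_text())
        for k in ("spacing_um", "window"):
            if k in d and d[k] is not None:
                d[k] = tuple(d[k])
        return cls(**d)


def _log(report: dict, stage: str, t0: float, **info) -> None:
    entry = {"stage": stage, "seconds": round(time.time() - t0, 3), **info}
    report["stages"].append(entry)
    print(json.dumps(entry))


def run_pipeline(config: PipelineConfig, force: bool = False) -> dict:
    """Execute every stage; returns (and writes) the run report.

    Stages whose outputs already exist are skipped unless ``force``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": config.seed,
                    "config": asdict(config), "stages": []}

    raw = ImageStack(tifffile.imread(config.raw_stack), config.spacing_um)

    # ---- downsample (for registration and ventricle classification)
    t0 = time.time()
    ds_path = out / "downsampled.tif"
    if ds_path.exists() and not force:
        ds = ImageStack(tifffile.imread(ds_path), (config.target_um,) * 3)
        _log(report, "downsample", t0, skipped=True)
    else:
        ds = downsample_iso(raw, config.target_um)
        tifffile.imwrite(ds_path, ds.voxels)
        _log(report, "downsample", t0, shape=list(ds.shape))

    # ---- ventricle masking
    t0 = time.time()
    masked = raw
    if config.mask_ventricles:
        if config.ventricle_classifier is None:
            raise ValueError("mask_ventricles=True requires a classifier path")
        vm_path = out / "ventricle_mask_fullres.tif"
        if vm_path.exists() and not force:
            up = MaskStack(tifffile.imread(vm_path), raw.spacing_um)
            _log(report, "ventricle_mask", t0, skipped=True)
        else:
            clf = VoxelClassifier.load(config.ventricle_classifier)
            vent_ds = predict_mask(clf, ds)
            up = upsample_mask(vent_ds, raw.shape,
                               threshold=config.upsample_threshold,
                               target_spacing_um=raw.spacing_um,
                               dilate_vox=config.mask_dilation_vox)
            tifffile.imwrite(vm_path, up.mask)
            _log(report, "ventricle_mask", t0,
                 ventricle_voxels=int(up.mask.sum()))
        masked = apply_mask(raw, up)

    # ---- inference
    t0 = time.time()
    prob_path = out / "probability.tif"
    model = load_checkpoint(config.model_checkpoint)
    if prob_path.exists() and not force:
        prob_vals = tifffile.imread(prob_path)
        from .types import ProbabilityStack
        prob = ProbabilityStack(prob_vals, raw.spacing_um)
        _log(report, "inference", t0, skipped=True)
    else:
        prob = sliding_window_infer(model, masked, window=config.window,
                                    overlap=config.overlap)
        tifffile.imwrite(prob_path, prob.values.astype(np.float32))
        _log(report, "inference", t0)

    # ---- binarize + instances + size filter
    t0 = time.time()
    cells_path = out / "cells.csv"
    if cells_path.exists() and not force:
        cells = frame_to_cells(pd.read_csv(cells_path))
        _log(report, "instances", t0, skipped=True, n_cells=len(cells))
    else:
        seg = binarize(prob, config.threshold)
        vol = connected_components(seg, config.connectivity)
        n_raw = len(vol.instances)
        vol = filter_by_size(vol, config.min_size_vox, config.max_size_vox)
        tifffile.imwrite(out / "instance_labels.tif",
                         vol.labels.astype(np.int32))
        cells_to_frame(vol).to_csv(cells_path, index=False)
        cells = vol.instances
        _log(report, "instances", t0, n_components=n_raw,
             n_cells=len(cells))

    if config.atlas_labels is None:
        report["n_cells"] = len(cells)
        (out / "report.json").write_text(json.dumps(report, indent=1))
        return report

    ontology = Ontology.from_json(config.ontology)
    atlas = AtlasVolume(tifffile.imread(config.atlas_labels),
                        config.atlas_spacing_um, ontology)

    # ---- registration / transform import
    t0 = time.time()
    tx_path = out / "transform.json"
    if tx_path.exists() and not force:
        tx = AffineTransform.from_json(tx_path)
        _log(report, "register", t0, skipped=True)
    elif config.point_transform is not None:
        tx = import_point_transform(config.point_transform)
        tx.to_json(tx_path)
        _log(report, "register", t0, imported=True)
    else:
        if config.atlas_template is None:
            raise ValueError("need atlas_template or point_transform")
        tpl = ImageStack(tifffile.imread(config.atlas_template),
                         (config.atlas_spacing_um,) * 3)
        ds_iso = downsample_iso(ds, config.atlas_spacing_um) \
            if config.target_um < config.atlas_spacing_um else ds
        tx = register_affine(ds_iso, tpl, seed=config.seed)
        tx.to_json(tx_path)
        _log(report, "register", t0)

    # ---- mapping + tables
    t0 = time.time()
    mapped = map_cells(cells, raw.spacing_um, tx, atlas)
    cells_df, region_df = make_tables(mapped, atlas,
                                      sample_id=out.name)
    cells_df.to_csv(out / "cells_mapped.csv", index=False)
    region_df.to_csv(out / "region_counts.csv", index=False)
    _log(report, "map", t0,
         n_mapped=len(mapped),
         n_unassigned=int((cells_df["region_id"] == 0).sum()))

    # ---- visualization
    t0 = time.time()
    labels = tifffile.imread(out / "instance_labels.tif") \
        if (out / "instance_labels.tif").exists() else None
    if labels is not None:
        from .types import LabeledVolume
        lv = LabeledVolume(labels, cells)
        overlay, lut = colorize_cells(lv, mapped, ontology)
        tifffile.imwrite(out / "cells_by_region.tif", overlay.astype(np.int32))
        lut.to_csv(out / "region_lut.csv", index=False)
    dmap = density_map([mapped], atlas, sigma_vox=config.sigma_vox)
    tifffile.imwrite(out / "density_map.tif", dmap.astype(np.float32))
    projection_figure(dmap, axis=0, output=out / "density_projection.png")
    _log(report, "visualize", t0)

    report["n_cells"] = len(cells)
    (out / "report.json").write_text(json.dumps(report, indent=1))
    return report


# ---------------------------------------------------------------- training

@dataclass
class TrainConfig:
    """Configuration for (re-)training the segmentation model."""

    patch_dir: str
    output_dir: str
    epochs: int = 500
    lr: float = 1e-3
    batch_size: int = 4
    base_features: int = 16
    depth: int = 5
    seed: int = 0
    start_checkpoint: str | None = None  # fine-tune from here
    n_test: int = 0  # held-out patches for the final evaluation report
    connectivity: int = 26


def load_patch_pairs(patch_dir) -> list[tuple[np.ndarray, np.ndarray]]:
    """Read paired raw_*.tif / label_*.tif patches from a directory."""
    d = Path(patch_dir)
    raws = sorted(d.glob("raw_*.tif"))
    if not raws:
        raise ValueError(f"no raw_*.tif patches in {d}")
    pairs = []
    for rp in raws:
        lp = d / rp.name.replace("raw_", "label_")
        if not lp.exists():
            raise ValueError(f"missing label for patch {rp.name}")
        raw = tifffile.imread(rp)
        lab = tifffile.imread(lp)
        if raw.shape != lab.shape:
            raise ValueError(f"shape mismatch in pair {rp.name}")
        pairs.append((raw, (lab > 0).astype(np.uint8)))
    return pairs


def run_training(cfg: TrainConfig) -> TrainedModel:
    """Train from scratch or fine-tune; writes checkpoint, loss log and a
    held-out evaluation report."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    pairs = load_patch_pairs(cfg.patch_dir)
    test = pairs[len(pairs) - cfg.n_test:] if cfg.n_test else []
    trainset = pairs[: len(pairs) - cfg.n_test] if cfg.n_test else pairs

    if cfg.start_checkpoint:
        model = load_checkpoint(cfg.start_checkpoint)
        ucfg = model.config
        ucfg.epochs = cfg.epochs
        ucfg.lr = cfg.lr
        ucfg.batch_size = cfg.batch_size
        ucfg.seed = cfg.seed
    else:
        ucfg = UNetConfig(base_features=cfg.base_features, depth=cfg.depth,
                          epochs=cfg.epochs, lr=cfg.lr,
                          batch_size=cfg.batch_size, seed=cfg.seed)
        model = build_unet(ucfg)
    if cfg.epochs > 0:
        train(model, trainset, ucfg)
    save_checkpoint(model, out / "model.npz")
    (out / "training_log.json").write_text(json.dumps(model.training_log))

    if test:
        from .segmentation import normalize_intensity
        counts = []
        for raw, lab in test:
            p = model.predict_proba(normalize_intensity(raw))
            counts.append(evaluate_patch((p >= 0.5).astype(np.uint8), lab,
                                         cfg.connectivity))
        vol, inst, total = aggregate_and_score(counts)
        (out / "evaluation.json").write_text(json.dumps({
            "volumetric": {"dice": vol.dice, "sensitivity": vol.sensitivity,
                           "precision": vol.precision},
            "instance": {"f1": inst.f1, "sensitivity": inst.sensitivity,
                         "precision": inst.precision},
            "counts": asdict(total),
        }, indent=1))
    return model
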