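"""Ventricle masking pre-processing.

The brain's fluid-filled ventricles accumulate antibody label and produce
bright lumens that confound cell detection.  This module reproduces the
standard pre-processing chain: downsample the stack to an isotropic working
resolution (default 25 µm), classify ventricle vs. parenchyma voxels with a
random-forest pixel classifier over multi-scale image features, upsample
the binary mask back to the original dimensions with smooth (bicubic
per-plane) interpolation, and zero the masked voxels in the raw stack.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
from scipy import ndimage
from skimage.transform import resize
from sklearn.ensemble import RandomForestClassifier

from .types import ImageStack, MaskStack

DEFAULT_TARGET_UM = 25.0
DEFAULT_FEATURE_SCALES_UM = (25.0, 50.0, 100.0)
#: per-class cap on training voxels fed to the forest
_MAX_TRAIN_VOXELS = 200_000


# ------------------------------------------------------------- downsampling

def downsample_iso(stack: ImageStack, target_um: float = DEFAULT_TARGET_UM) -> ImageStack:
    """Anti-aliased downsampling to an isotropic grid.

    Output dims are ``ceil(dim * spacing / target)`` per axis; intensities
    come from Gaussian-prefiltered linear resampling (local averaging).
    """
    if target_um < max(stack.spacing_um) - 1e-9:
        raise ValueError(
            f"target {target_um} µm is finer than input spacing "
            f"{stack.spacing_um}; this op only downsamples")
    factors = [target_um / s for s in stack.spacing_um]
    out_shape = tuple(int(np.ceil(d * s / target_um))
                      for d, s in zip(stack.shape, stack.spacing_um))
    vol = stack.voxels.astype(np.float32)
    sigmas = [max(0.0, (f ** 2 - 1.0) ** 0.5 / 2.0) for f in factors]
    if any(s > 0 for s in sigmas):
        vol = ndimage.gaussian_filter(vol, sigmas)
    out = resize(vol, out_shape, order=1, mode="edge",
                 anti_aliasing=False, preserve_range=True)
    return ImageStack(np.clip(np.round(out), 0, 65535).astype(np.uint16),
                      spacing_um=(target_um,) * 3)


# ----------------------------------------------------------------- features

def _voxel_features(vol: np.ndarray, spacing_um: float,
                    scales_um) -> np.ndarray:
    """Per-voxel feature stack: Gaussian-smoothed intensity, gradient
    magnitude and Laplacian-of-Gaussian at each physical scale."""
    v = vol.astype(np.float32)
    feats = [v]
    for s in scales_um:
        sig = s / spacing_um
        feats.append(ndimage.gaussian_filter(v, sig))
        feats.append(ndimage.gaussian_gradient_magnitude(v, sig))
        feats.append(ndimage.gaussian_laplace(v, sig))
    return np.stack([f.ravel() for f in feats], axis=1)


@dataclass
class VoxelClassifier:
    """Two-class (ventricle vs. parenchyma) random-forest pixel classifier."""

    feature_spec: list  # [(feature name, scale µm), ...]
    model: RandomForestClassifier
    target_spacing_um: float

    def save(self, path) -> None:
        path = Path(path)
        joblib.dump(self.model, path)
        sidecar = {
            "feature_spec": [[n, s] for n, s in self.feature_spec],
            "target_spacing_um": self.target_spacing_um,
            "format_version": 1,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path) -> "VoxelClassifier":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(feature_spec=[tuple(fs) for fs in meta["feature_spec"]],
                   model=joblib.load(path),
                   target_spacing_um=float(meta["target_spacing_um"]))


def train_voxel_classifier(stacks: list[ImageStack],
                           ventricle_labels: list[MaskStack],
                           feature_scales_um=DEFAULT_FEATURE_SCALES_UM,
                           seed: int = 0,
                           n_estimators: int = 50) -> VoxelClassifier:
    """Fit the ventricle/parenchyma forest on labeled downsampled stacks.

    Labels are binary masks aligned voxelwise with the stacks (1 =
    ventricle).  Training subsamples at most 200k voxels per class,
    deterministically for a fixed seed.
    """
    if not stacks or len(stacks) != len(ventricle_labels):
        raise ValueError("need equally many stacks and label masks")
    spacing = stacks[0].spacing_um[0]
    X_parts, y_parts = [], []
    for st, lab in zip(stacks, ventricle_labels):
        if st.shape != lab.shape:
            raise ValueError("stack/label shape mismatch")
        X_parts.append(_voxel_features(st.voxels, spacing, feature_scales_um))
        y_parts.append(lab.mask.ravel())
    X = np.concatenate(X_parts)
    y = np.concatenate(y_parts)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class; need both "
                         "ventricle and parenchyma voxels")
    rng = np.random.default_rng(seed)
    keep = []
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        if len(idx) > _MAX_TRAIN_VOXELS:
            idx = rng.choice(idx, _MAX_TRAIN_VOXELS, replace=False)
        keep.append(idx)
    keep = np.concatenate(keep)
    model = RandomForestClassifier(n_estimators=n_estimators, n_jobs=1,
                                   random_state=seed)
    model.fit(X[keep], y[keep])
    spec = [("intensity", 0.0)]
    for s in feature_scales_um:
        spec += [("gaussian", s), ("gradient_magnitude", s), ("laplacian", s)]
    return VoxelClassifier(feature_spec=spec, model=model,
                           target_spacing_um=spacing)


def predict_mask(clf: VoxelClassifier, stack: ImageStack,
                 largest_component_only: bool = False) -> MaskStack:
    """Classify every voxel of an isotropic stack at the classifier's
    working resolution."""
    sp = stack.spacing_um[0]
    if not stack.is_isotropic or abs(sp - clf.target_spacing_um) > 0.01 * clf.target_spacing_um:
        raise ValueError(
            f"stack spacing {stack.spacing_um} does not match classifier "
            f"target {clf.target_spacing_um} µm")
    scales = sorted({s for _, s in clf.feature_spec if s > 0})
    X = _voxel_features(stack.voxels, sp, scales)
    pred = clf.model.predict(X).reshape(stack.shape).astype(np.uint8)
    if largest_component_only and pred.any():
        lab, n = ndimage.label(pred)
        sizes = ndimage.sum_labels(pred, lab, np.arange(1, n + 1))
        pred = (lab == (1 + int(np.argmax(sizes)))).astype(np.uint8)
    return MaskStack(pred, stack.spacing_um)


# ------------------------------------------------------------- mask up/apply

def upsample_mask(mask: MaskStack, target_shape, threshold: float = 0.5,
                  target_spacing_um=None, dilate_vox: int = 0) -> MaskStack:
    """Upsample a binary mask to ``target_shape`` and re-binarize.

    Interpolation is cubic within each output z-plane (bicubic, avoiding
    staircase aliasing at ventricle edges) and nearest-neighbour across z.
    ``dilate_vox`` grows the result by that many binary dilations — a
    safety margin against the quantization fringe a coarse mask leaves at
    full resolution.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0,1)")
    target_shape = tuple(int(t) for t in target_shape)
    if any(t < s for t, s in zip(target_shape, mask.shape)):
        raise ValueError("target_shape must be >= mask shape on every axis")
    src = mask.mask.astype(np.float32)
    d_src = mask.shape[0]
    d_tgt = target_shape[0]
    z_src = np.minimum((np.arange(d_tgt) * d_src) // max(1, d_tgt), d_src - 1)
    out = np.empty(target_shape, dtype=np.uint8)
    plane_cache: dict[int, np.ndarray] = {}
    for zt, zs in enumerate(z_src):
        zs = int(zs)
        if zs not in plane_cache:
            plane = resize(src[zs], target_shape[1:], order=3, mode="edge",
                           anti_aliasing=False, preserve_range=True)
            plane_cache[zs] = (plane >= threshold).astype(np.uint8)
        out[zt] = plane_cache[zs]
    if dilate_vox > 0:
        out = ndimage.binary_dilation(out, iterations=dilate_vox).astype(np.uint8)
    if target_spacing_um is None:
        target_spacing_um = tuple(
            s * m / t for s, m, t in zip(mask.spacing_um, mask.shape, target_shape))
    return MaskStack(out, target_spacing_um)


def apply_mask(stack: ImageStack, mask: MaskStack, pad_to=None) -> ImageStack:
    """Zero out masked voxels (mask == 1); optionally pad symmetrically with
    zeros to ``pad_to``.  Output stays 16-bit."""
    if stack.shape != mask.shape:
        raise ValueError(f"shape mismatch: stack {stack.shape} vs mask {mask.shape}")
    out = stack.voxels.copy()
    out[mask.mask == 1] = 0
    if pad_to is not None:
        pad_to = tuple(int(p) for p in pad_to)
        if any(p < s for p, s in zip(pad_to, stack.shape)):
            raise ValueError("pad_to smaller than stack")
        pads = []
        for p, s in zip(pad_to, stack.shape):
            lo = (p - s) // 2
            pads.append((lo, p - s - lo))
        out = np.pad(out, pads)
    return ImageStack(out, stack.spacing_um)
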