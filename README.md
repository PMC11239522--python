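# somamap

Whole-brain cell mapping for cleared-tissue light-sheet microscopy, at desk
scale.  `somamap` takes a raw 3D image stack of immunolabeled somata (e.g.
c-Fos⁺ nuclei as markers of neuronal activity), masks the brain's
ventricles, segments cells with a 3D UNet, extracts cell instances by
connected-component analysis, registers the brain to a reference atlas,
assigns every cell a region of a hierarchical ontology, and compares groups
of brains region by region with level-aware multiple-testing correction.

Because acquired whole-brain data is terabyte-scale and wet-lab-bound, the
package ships a first-class synthetic generator: toy atlases with a
hierarchical region ontology (including a ventricle and a fiber-tract
leaf), and image stacks of Gaussian-blob somata over noisy, unevenly
illuminated backgrounds with bright ventricle lumens — with exact ground
truth (cell list, label mask, stack→atlas affine) for every stage.

## The model and metrics

**Segmentation** is a symmetric 3D encoder–decoder ("BasicUNet"-style):
two 3×3×3 convolutions with Mish activation per resolution level, 2× max
pooling down, nearest-neighbour upsampling with skip concatenation up, and
a 1×1×1 logit head trained with binary cross-entropy (lr 10⁻³, batch 4,
Adam with warmup/decay, *no* model selection — the last checkpoint is the
model).  Whole stacks are processed by a sliding-window inferer with
Gaussian blending of overlapping windows.  The network and its backward
pass are implemented in numpy/numba; no GPU or deep-learning framework is
required.

**Evaluation** is two-track. Voxelwise (volumetric) and instance-wise
counts are aggregated over all test patches first, then scored once:

    Dice = 2TP / (2TP + FP + FN)   Sensitivity = TP / (TP + FN)
    Precision = TP / (TP + FP)

At the instance level a predicted cell overlapping ≥ 1 voxel of any
reference cell is a TP, a prediction with no overlap is an FP, and an
undetected reference cell is an FN (TPs are counted on predictions, FNs on
references — the instance Dice equals the F1 score, the harmonic mean of
precision and sensitivity).

**Statistics**: per-region cell densities (cells/mm³) are compared between
groups with two-sided unpaired t-tests (Welch by default) at each level of
the region hierarchy, with Benjamini–Hochberg FDR control at q = 0.1
applied within each level; fiber tracts are excluded.

## Worked example

```python
import dataclasses
import numpy as np
from somamap.synthetic import (generate_toy_atlas, generate_scene,
                               sample_patches, stratified_split)
from somamap.segmentation import UNetConfig, build_unet, train, normalize_intensity
from somamap.evaluation import evaluate_patch, aggregate_and_score
from somamap.types import MaskStack
from somamap.ventricle import apply_mask

atlas = generate_toy_atlas((48, 48, 48), levels=3, seed=7)
scene = generate_scene(atlas, upscale=4, cells_per_mm3=30.0, snr=4.0, seed=21)
print(len(scene.cells))                     # 415 ground-truth cells

# annotate/train on the ventricle-masked stack, as in the wet-lab protocol
premasked = apply_mask(scene.stack,
                       MaskStack(scene.ventricle_mask, scene.stack.spacing_um))
pairs = sample_patches(dataclasses.replace(scene, stack=premasked),
                       20, (64, 64, 64), stratify_by_signal=True, seed=5)
trainset, test = stratified_split(pairs, 4, seed=5)

cfg = UNetConfig(base_features=8, depth=3, epochs=50, seed=1)
model = build_unet(cfg)
train(model, trainset, cfg)                 # ~10 min on one CPU core

counts = [evaluate_patch(
              (model.predict_proba(normalize_intensity(r)) >= 0.5).astype(np.uint8), l)
          for r, l in test]
vol, inst, _ = aggregate_and_score(counts)
print(round(inst.f1, 3), round(vol.dice, 3))   # 0.911 0.774
```

The two printed scores are the global instance F1 (how reliably individual
cells are found) and the volumetric Dice (how well cell *shapes* are
delineated) on the four held-out patches.  Instance F1 is much higher than
volumetric Dice, as expected for blob-like objects whose exact boundary is
ambiguous while their presence is not.

The same steps are available from the shell:

```sh
somamap simulate --shape 48,48,48 --levels 3 --seed 7 --out scene/
somamap train --patches patches/ --epochs 50 --out model/
somamap run --config config.json
```

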