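# Methods

This note documents the models, parameters and numerical choices behind
`somamap`, and what the synthetic benchmark does and does not demonstrate.

## Synthetic cleared-brain scenes

The generator stands in for antibody-labeled, cleared, light-sheet-imaged
brains.  A **toy atlas** is a recursive rectangular partition of an
isotropic 50 µm/voxel grid: each box splits along its longest axis into
`regions_per_split` slabs at slightly randomized positions, `levels` deep,
yielding a rooted ontology in the style of the Allen structure graph (ids,
acronyms, parent links, structure levels, RGB colors).  Two special leaves
are carved in as children of the root: a cylindrical **ventricle** lumen
and a thin **fiber-tract** slab; their flags propagate to descendants.

A **scene** renders the atlas at `upscale`× resolution (default 4×, i.e.
12.5 µm voxels over a 2.4 mm toy brain):

- Cell centers follow a homogeneous Poisson point process per region
  (default 30 cells/mm³ in gray-matter leaves, none in ventricles/fiber
  tracts).  Placements clipped at the border or overlapping an existing
  cell are resampled, so per-region counts stay Poisson(ρ·V).
- Each soma is an isotropic-in-µm Gaussian blob (σ = r/1.5) added to the
  background; its binary ground-truth support is the sphere of radius r.
  Radii are truncated-normal, default 25 ± 4 µm.  This is *scaled up*
  relative to real nuclei (5–10 µm) exactly as the voxels are scaled up
  relative to a real acquisition (1.6 µm): what is preserved is the
  voxels-per-soma regime (~2 voxels radius), which is what the detector
  sees.
- Background 200 counts, ventricle lumens 3× brighter (label accumulates
  in the cerebrospinal fluid) with a smooth falloff (Gaussian σ = 2 voxels
  — scattering and label diffusion, not a razor edge), a multiplicative
  linear illumination field (±15% by default) across the field of view,
  additive Gaussian noise of σ = 25 counts.  Peak blob amplitude is
  `snr`·σ, so `snr` is the peak-to-background signal-to-noise ratio
  (default 4).
- The stack→atlas transform is stored exactly (identity in µm; the stack
  is the upscaled atlas grid).

Not emulated: stripe/shadow artifacts, refraction, stitching seams,
anisotropic z-blur, labeled processes (dendrites/axons), intensity
variation between somata beyond the illumination field, and touching cell
clumps.  Consequently, passing the synthetic benchmark shows the
*machinery* (training loop, inference, instance extraction, mapping,
statistics) recovers known ground truth under realistic noise and
illumination inhomogeneity — it does not certify performance on any real
acquisition.

Patch sampling mirrors annotated-patch training: random 64³–100³ patches;
"stratified by signal" ranks patches by foreground voxel count and the
train/test split draws the test set systematically across that ranking, so
both splits span the signal range (the quantitative stratification rule is
our choice; the practice it mimics is stated only qualitatively in the
field).

## Ventricle masking

Downsample to isotropic 25 µm (anti-aliased: Gaussian prefilter at
σ = √(f²−1)/2 per axis, then linear resampling; output dims
`ceil(dim·spacing/target)`), classify voxels with a random forest (50
trees) over per-voxel features — raw intensity plus Gaussian-smoothed
intensity, gradient magnitude and Laplacian-of-Gaussian at 25/50/100 µm —
upsample the binary mask to the original dimensions (cubic interpolation
within each z-plane to avoid staircase aliasing at lumen edges,
nearest-neighbour across z, threshold 0.5, then a 2-voxel binary dilation
as a margin against the quantization fringe a 25 µm mask leaves at full
resolution), and zero the masked voxels.  Masked voxels are set to 0
rather than NaN so the 16-bit contract holds.
Per-plane (rather than full-3D) interpolation matches the plane-wise
masking of the original stacks; the choice is interchangeable at the mask
smoothness this pipeline produces.

## Segmentation network

A symmetric 3D encoder–decoder with two 3×3×3 convolutions + Mish per
level, 2× max-pool encoder, nearest-neighbour-upsample + skip-concat
decoder, 1×1×1 logit head.  Feature widths follow the BasicUNet
convention — `(f, f, 2f, 4f, …)`: doubling starts at the second level.
Defaults: depth 5, base 16; the synthetic benchmark uses depth 3, base 8
(88 k parameters), which is ample for blob detection.

Training: binary cross-entropy on voxel labels, batch 4, initial lr 10⁻³,
500 epochs by default (50 in the benchmark), augmentation by random flips
and xy 90° rotations, per-volume intensity normalization to the 1st–99th
percentile range (clipped to [−0.5, 1.5]; percentiles are computed over
nonzero voxels, so ventricle-masked and padded regions do not shift the
scaling between training patches and masked whole-stack inference).
Benchmark training patches are drawn from the ventricle-masked stack, as
in the protocol this mirrors (annotation after manual ventricle masking),
which also makes zeroed regions an in-distribution feature rather than an
inference-time surprise.  The logit head's bias is
initialized to logit(0.01), the standard rare-foreground detection
initialization: somata occupy well under 1% of a stack, and starting from
a 0.5 prior makes plain BCE spend most of a short training budget
unlearning it (with zero-bias init and the benchmark's 200 optimization
steps the network reproducibly collapses to the base-rate predictor).
**No model selection**: the
checkpoint after the last epoch is the model.  The optimizer is Adam with
linear warmup over the first 10% of steps and cosine decay to 10% of the
peak rate — a deliberately plain stand-in for the flat-and-anneal
optimizers fashionable in this niche; on the synthetic benchmark the
optimizer is not the bottleneck.

The network and its backward pass are hand-written (numpy + numba): direct
register-blocked convolution kernels, explicit chain rule, float32
throughout.  Gradients are verified against central differences in the
test suite.  Checkpoints are plain `.npz` files with an embedded JSON
config.

Sliding-window inference tiles the normalized stack (window 64³ default,
overlap 0.25), blends overlapping windows by Gaussian-weighted averaging
(σ = window/8, floor 10⁻³; uniform blending available), reflect-pads
stacks smaller than the window, and binarizes at 0.5 (`≥` counts as
foreground).

## Instances

Connected components of the binary segmentation (26-connectivity by
default, 6/18 available), labeled in deterministic lexicographic-first-
voxel order; unweighted centroids; half-open bounding boxes; 0-based
(z, y, x) everywhere.  The size filter keeps volumes in [min, max]
inclusive (defaults 4–5000 voxels) and is applied before atlas mapping.
Touching cells are not split — the method counts *components*, as is
standard for this class of pipeline.

## Atlas mapping

Registration estimates a 12-parameter affine from a downsampled brain to
an isotropic template: moments initialization (center of mass + per-axis
second moments), then a staged, bounded Powell refinement.  The
first stage captures translation with NCC over the *full* template
domain — resampling zeros pair against template structure, so transforms
that slide content out of the frame are penalized and gross translation
failures are excluded.  The remaining stages free scale, rotation and
shear and switch to NCC over the moving image's *support*, which is
sub-voxel sharp, inside a ±3-voxel translation trust region around the
captured translation (support-restricted similarity metrics are
otherwise exploitable by shrinking the evaluation pool).  Histogram NMI
is available via ``metric="nmi"`` for multi-modal pairs, but for the
mono-modal alignments this package performs NCC is the default: NMI
rewards transforms that degenerate the intensity histogram and its
optimum can sit several voxels from the true affine at these volume
sizes.  Bounds (±35% of the image span in translation, ±0.25 log-scale,
±0.2 rad, ±0.1 shear) keep the derivative-free search inside the capture
range, and a stage's result is rejected if it does not improve on the
stage's starting value (bounded Powell can walk off a sharp optimum and
return a worse point).  Deformable registration
is out of scope; externally computed affines can be imported from JSON and
used identically.

Cell centers map: stack voxel → µm → affine → atlas µm → atlas voxel
(floor — labels are categorical, no interpolation) → region id.  Cells
landing outside the atlas or on background get region 0 and are reported,
never dropped.  Region volumes come from atlas voxel counts × spacing³.
Counts aggregate to any structure level by adding each leaf to its unique
ancestor at that level; totals are conserved by construction and asserted
in tests.

## Region statistics

Densities are cells/mm³ (optionally additionally divided by the sample's
total detected cells; the total includes fiber-tract and unassigned cells).
Fiber tracts are excluded from every comparison.  Per level: two-sided
unpaired t-tests — Welch by default, pooled-variance Student's behind a
flag, since the field convention states only "unpaired" — then BH at
q = 0.1 within the level's tested set ("level-aware"; a global-across-
levels option exists).  Zero-variance degenerate cases are defined
explicitly: identical data → t = 0, p = 1; a clean mean difference with
zero variance → p = 0.  log₂ fold changes use the group-mean ratio; a zero
mean is floored at half the smallest nonzero mean so empty regions stay
finite while nonzero ratios are exact.  The q = 0.1 threshold is FDR
control (the literature of this pipeline family sometimes calls it an
FWER; it is not one).

## Evaluation

Voxel confusion is exact.  Instance matching uses the ≥1-voxel overlap
rule: TPs counted on predictions, FNs on references.  The asymmetry is
preserved faithfully — two predictions hitting one reference cell are two
TPs and no FN, so TP+FN can exceed the reference count.  A stricter
IoU-threshold mode exists but is off by default.  Counts are aggregated
across patches before scores are computed (global scores, not averages of
per-patch scores).  Zero-denominator metrics return NaN with a warning,
never a silent 0.

## Problem sizes

The shipped benchmark uses a 48³ toy atlas rendered at 192³ (~13.8 mm³,
~400 cells), 16 training + 4 held-out patches of 64³, 50 epochs, and
registration recovery over simulated affines with shifts ≤ 6 voxels on a
32³ grid and scales 0.9–1.1.  These sizes make the full suite a
minutes-scale, single-core exercise while keeping every stage's statistics
(Poisson counts, instance scores, FDR behavior) in a regime where the
acceptance thresholds are meaningful.

## Known limitations

- The UNet is CPU-bound and desk-scale; real whole-brain stacks need the
  same architecture on accelerator hardware.
- Affine-only registration cannot express the nonlinear deformations of
  real clearing; the import path exists precisely for external deformable
  tools.
- The instance-matching rule rewards over-segmentation in principle (each
  fragment of a split cell counts as a TP); the size filter is the only
  guard.
- Synthetic somata are isolated by construction; performance on touching
  cells is untested by design (components would merge).
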