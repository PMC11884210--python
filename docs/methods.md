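# Methods

This note records the modelling assumptions behind `triseg`, the parameters
that matter, and the numerical choices made where the design was genuinely
open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The tri-planar model

The core assumption is that a 3D segmentation task over CT/MR volumes can be
solved by a single 2D network if 3D context is supplied *implicitly*: every
voxel is classified three times — in its transversal, sagittal and coronal
slice — and the class posteriors are averaged. A voxel that is ambiguous in
one plane (e.g. a vessel seen in cross-section) is usually unambiguous in
another. The fusion is an unweighted arithmetic mean; no learned fusion
weights and no Gaussian overlap windows are used, which keeps inference a
pure deterministic composition.

This works when classes are separable from local intensity, texture and
short-range shape — bone vs soft tissue, contrast-filled blood pool vs
parenchyma. It deliberately does **not** learn long-range anatomical layout
(the augmentation policy destroys most of it), which is an advantage for
grossly abnormal anatomy but means applications whose only discriminative
signal is relative position need special handling: for the mandible/cranium
case the transversal plane carries no signal and mirroring/transposition
would erase the left/right and up/down cues, so that preset restricts
training and inference to the sagittal and coronal stacks and disables
mirror/transpose augmentation. `orientation_set` is stored in the model
checkpoint so inference always matches training.

Patches rather than whole slices bound memory and make the network
resolution-agnostic. Patches overlap (inference stride defaults to half the
patch size) so each region is segmented multiple times and patch borders
never become prediction borders; overlapping predictions are averaged and
the per-pixel vectors renormalised (a no-op up to floating-point drift,
since means of simplex vectors stay on the simplex).

### Geometry conventions

Grids are indexed `(z, y, x)`, spacing is mm per axis in the same order, and
the world position of a voxel centre is `index * spacing`. DICOM series are
validated (single series, uniform slice gap within 1%), sorted along the
slice normal, rescaled to HU, and reoriented into this canonical frame —
axis-aligned acquisitions by permutation/flips, oblique ones by resampling —
so that stack extraction is deterministic. Isotropic resampling targets the
*minimum* spacing component (no axis loses resolution); images are
interpolated linearly, label maps nearest-neighbour (the interpolation was
an open choice; linear/nearest is standard practice and nearest guarantees
labels never invent classes). Output label maps are resampled back to the
native input lattice by default so they overlay the source file; metrics
are computed on the isotropic working lattice.

### Intensity handling

CT volumes stay on their calibrated HU scale. Volumes in arbitrary units
(MR, phantoms) are min-max scaled to [0, 1] per volume, since their absolute
scale is meaningless. This is a documented default, not a claim that no
better normalisation exists.

## The network and training recipe

The segmentation network is the standard 2D U-Net: per encoder level two
3×3 'same' convolutions + ReLU then 2×2 max pooling; a two-convolution
bottleneck; per decoder level a 2×2 stride-2 transposed convolution, skip
concatenation and two more convolutions; a 1×1 convolution and channel-wise
softmax head emitting C+1 probabilities per pixel. Feature widths double
from `base_filters` (64 by default; 8–16 in desk-scale tests). The same
parameter set serves all orientations.

It is implemented directly in numpy (`_nnops.py`): im2col convolutions,
hand-written backward passes (verified against central differences in the
test suite), and an Adam optimiser with decay rates (0.9, 0.999). The
patch-based design keeps tensors small enough that CPU matmuls suffice.

Training defaults (all in `TrainingConfig`):

| parameter | default | notes |
|---|---|---|
| patch size | 128 px | 32 in desk-scale tests; must divide by 2^depth |
| learning rate | 1e-3 | dropped by `lr_drop_factor` each `lr_drop_period` |
| lr drop period / factor | 5 epochs / 0.85 | midpoints of the 4–6 / 0.8–0.9 recipe ranges |
| encoder depth | 4 | 2 in desk-scale tests |
| L2 strength | 1e-4 | weights only, not biases |
| gradient clipping | global L2 norm, threshold 10 | the recipe fixes the method but not the threshold; 10 is this package's choice |
| epochs / batch | 100 / 30 | scaled down for tests |

The loss is unweighted cross entropy including background: the framework is
expected to tolerate severe class imbalance (an airway at ~2% of the lung
volume) without re-weighting, and the phantom imbalance preset exists to
exercise exactly that. Patch sampling is uniform over the tiled patches (no
foreground balancing — an open choice, configurable upstream by tiling
strategy). Every epoch re-draws the augmentation of every patch from the
policy, so the network never sees a bit-identical patch twice; the base
tiling itself is fixed. There is no early stopping. Given a seed, training
is bit-reproducible.

## Augmentation policy

Each transform has an activation probability and a U(a, b) parameter range.
Geometric transforms (2D rotation, scaling about the centre, horizontal and
vertical mirroring, transposition) apply identically to image and label
patches (labels nearest-neighbour); intensity transforms (white noise,
streak noise, brightness, contrast about the patch mean, 3-px Gaussian
blur, unsharp-mask sharpening) apply to the image only. An optional global
3D rotation (axis drawn uniformly on the sphere — no axis convention is
canonical) applies to the whole volume before patch extraction.

Published recipes for this family of methods print probability and
parameter *ranges* across applications without a per-application mapping;
the policy therefore stores one concrete value per transform and ships
presets: `generic` (lower bound of each probability range, widest parameter
range), `mandible` (no mirror/transpose), `fetal` (MR: no
mirror/transpose/streaks, sharpening enabled) and `phantom` (geometric
transforms at generic settings, intensity jitter narrowed to the [0, 1]
normalised scale so class-mean contrast is perturbed rather than erased —
brightness ±0.05, contrast 0.95–1.05). Two interpretations are deliberate
and documented rather than canonical: white noise is an additive per-pixel
U(−A, A) draw with A a fraction of the patch intensity range (the
uniform-vs-Gaussian question is unstated in the recipes we follow), and
streak noise — undefined anywhere — is implemented as constant offsets on
1–4 whole rows/columns, mimicking CT streak artifacts. A corollary of the
range-relative amplitude: on a constant patch both noises are exact
identities.

## Post-processing

Per class, in order: probability threshold → hole filling → removal of
objects < 0.1 ml → n-largest selection → touch constraint. The order is a
documented choice (published pipelines show it only graphically): filling
first means a filled hole cannot resurrect an object the volume cut
removed, and n-largest ranks final candidate sizes. Classes with a
`must_touch` reference are processed after their target class (cycles are a
configuration error).

Details that needed a decision: thresholding assigns a voxel to the
highest-probability class among those *strictly* exceeding their threshold
(background if none passes — so sub-50% thresholds let thin structures win
against a background plurality); exact ties go to the lower class index;
"smaller than 0.1 ml" is a strict inequality (an object of exactly 0.1 ml
is kept); object connectivity is 26 everywhere, but hole filling floods the
background with 6-connectivity so cavities cannot leak out through diagonal
gaps; equal-size ties in n-largest go to scan order. When per-class masks
are merged back into one label map, threshold assignments are already
disjoint and hole-filled additions only claim unassigned voxels, so classes
never overwrite each other and the whole procedure is idempotent.

## Metrics

Dice and Jaccard come from one-vs-rest voxel counts; empty-vs-empty scores
1.0 by convention (a correctly absent class is a perfect prediction), and
an empty prediction against a non-empty truth scores 0 with surface metrics
reported as missing, not infinite.

Surfaces are triangulated by marching cubes at the 0.5 level of the binary
mask, padded so border-touching objects close, with vertices in world mm
and outward normals (orientation fixed via signed mesh volume). The binary
field is pre-smoothed with a Gaussian of sigma 0.5 voxels before the level
set: the raw voxel staircase otherwise inflates the area of smooth objects
by ~10–15%, while 0.5 voxels keeps flat faces, watertightness and thin
structures intact (and extraction falls back to the raw field if smoothing
would drop a sub-voxel object below the level). Distances are measured from
every ground-truth *vertex* to the nearest point on any predicted
*triangle* — an exact KD-tree-pruned point-to-triangle search, cross-checked
against a brute-force scan in the tests. The sign is positive when the
nearest predicted point lies along the ground-truth outward normal
(over-segmentation). Reported summaries: 95th percentile of signed and of
absolute distances, and the median absolute distance ("median distance" is
interpreted as the median of absolute values — the signed median is near
zero whenever errors are balanced, which would make it uninformative).

## Phantoms: what they emulate and what they do not

A phantom is a set of analytic solids (sphere, ellipsoid, box, tube, hollow
shell) rasterised into a label map on a possibly anisotropic grid, with
per-class Gaussian intensities plus global Gaussian noise. The default
study condition is a 32 mm cube sampled at (2, 1, 1) mm — through-plane
twice as coarse as in-plane, as clinical CT stacks typically are — with a
6 mm-radius class-1 object and an 8 mm class-2 box; class means 100 and 200
against background 0 with all SDs at 5–8, i.e. classes separated by many
noise SDs, as bone/contrast/air are on CT. Cohorts jitter sizes (±15%),
centres (±2 mm) and class means (±10 units — emulating contrast
variability), and draw object shapes from per-class alternatives. The
held-out-shape flag removes one shape type from every training phantom
while forcing it into the test set, emulating zero-shot inference on
unseen anatomy. The imbalance preset places a thin tube (~2% of its
companion slab's volume) against the slab, exercising both class imbalance
and the touch rule.

Analytic solids mean every geometric assertion has a closed form, which is
why the generator is first-class, tested code. What phantoms do *not*
emulate: partial-volume effects, CT physics (beam hardening, metal
artifacts), anatomical texture, or inter-class intensity overlap. Passing
the phantom study therefore demonstrates that the pipeline's machinery —
resampling, tri-planar fusion, training, post-processing, metrics — is
correct and data-efficient on intensity-separable structure; it does not
certify clinical-grade accuracy on real scans.

## Scaled-down study sizes

The end-to-end study run by `tests/test_acceptance.py` and
`scripts/acceptance.py` uses a depth-2 U-Net with 8 base filters on
32-pixel patches, trained 10 epochs on 20 phantoms (≈1900 patches/epoch
over three orientations) and evaluated on 5 held-out phantoms; these sizes
were chosen so the whole study is a few minutes of CPU work while still
exercising every pipeline stage, including resampling from anisotropic
input and zero-shot shape transfer. The full-scale defaults (depth 4,
64 filters, 128-pixel patches, 100 epochs) are the shipped configuration
for real data.

## Known limitations

- The numpy network is CPU-bound; at the full-scale defaults training is
  orders of magnitude slower than a GPU implementation. The architecture
  and recipe are faithful, the throughput is not the point.
- Orientation canonicalisation trusts DICOM direction cosines; gantry-tilt
  series and multi-frame (enhanced) DICOM are not handled.
- Surface distances are sampled at ground-truth vertices; vertex density is
  tied to the voxel grid, so the summaries are controlled approximations of
  the continuous surface integrals.
- The probability-threshold / n-largest / touch rules assume roughly
  blob-like anatomy; sheet-like structures below voxel resolution can still
  be lost before post-processing can help.
- Phantom realism is deliberately limited (see above); conclusions about
  real cohorts require real data.
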