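# triseg

Tri-planar 2D U-Net segmentation of 3D medical images, built for the
limited-training-data regime of clinical 3D printing and surgical-planning
work: tens of labelled subjects, consumer-grade hardware, and anatomy that
varies too much to memorise.

## The approach

Instead of a 3D network, a **single 2D U-Net** segments the volume three
times — once per orthogonal slicing direction — and the results are fused:

1. Resample the input volume (NIfTI or DICOM series) to isotropic
   resolution, using the finest spacing present in-plane or through-plane.
2. Split it into three stacks of 2D slices: transversal (fixing z), coronal
   (fixing y) and sagittal (fixing x).
3. Tile every slice into fixed-size overlapping patches (default P = 128,
   stride P/2) and run each patch through the shared U-Net (encoder depth 4,
   3×3 convolutions with 'same' padding, softmax head over C+1 channels).
4. Stitch patch probabilities back into slices (overlap pixels averaged) and
   average the three orientation probability volumes voxel-wise:
   p(c | x) = (1/3) Σ_o p_o(c | x).
5. Convert probabilities to labels with rule-based anatomical
   post-processing: per-class probability threshold (50/25/12.5%), hole
   filling, removal of objects < 0.1 ml, keeping the n largest 26-connected
   objects, and optional "must touch another class" constraints.

Evaluation follows the field's standard metrics. With TP/FP/FN counted
voxel-wise one class against the rest:

    Dice = 2TP / (2TP + FP + FN)        Jaccard (IoU) = TP / (TP + FP + FN)

plus surface-based metrics: the 95th percentile of signed and absolute
distances from every ground-truth surface vertex to the nearest point on
the predicted surface (sign from the ground-truth outward normal), and the
median absolute distance, all in mm.

Training uses unweighted cross entropy with Adam, a step learning-rate
schedule, L2 regularisation, gradient clipping, and a per-epoch stochastic
augmentation policy (rotations, scaling, mirroring, transposition, white
and streak noise, brightness/contrast, blur, sharpening) with
per-application presets. The network is implemented directly in numpy with
hand-written backpropagation — patch-based 2D inputs keep it small enough
that no GPU runtime is required.

Because clinical volumes cannot be redistributed, the package ships a
phantom generator (`triseg.phantom`) producing image/label pairs with the
statistical structure the framework assumes — class-distinct Gaussian
intensities, anisotropic spacing, noise, multi-object and hollow topologies,
class imbalance — so the entire pipeline is testable end to end.

## Worked example

Generate a small phantom cohort, train a desk-scale model (depth-2 U-Net on
32-pixel patches), segment a held-out phantom and score it:

```bash
triseg phantom generate --n 12 --n-test 2 --seed 5 --output-dir work/
triseg train --data-dir work/ --seed 1 --epochs 10 --output work/model.npz
triseg infer --model work/model.npz --input work/case010_image.nii.gz \
             --output work/case010_seg.nii.gz
triseg evaluate --prediction work/case010_seg.nii.gz \
                --truth work/case010_labels.nii.gz
```

The evaluate step prints one row per class:

```
 class_id class_name     dice  jaccard  p95_signed_mm  p95_abs_mm  median_abs_mm  present_in_gt  present_in_pred
        1    class_1 0.981439 0.963554       0.029397    0.517626       0.001546           True             True
        2    class_2 1.000000 1.000000       0.000000    0.000000       0.000000           True             True
```

Dice/Jaccard near 1 mean the predicted voxel set almost coincides with the
truth; a 95th-percentile surface distance of 0.5 mm means 95% of the
ground-truth surface lies within half a voxel of the predicted surface.

A training-set-size sweep (how little data is enough?) over nested subsets
evaluated on one fixed test set:

```bash
triseg sweep --data-dir work/ --sizes 3,5,10 --seed 1 --output work/sweep.csv
```

## Layout

| module | contents |
|---|---|
| `triseg.volumes` / `triseg.io` | volume containers, isotropic resampling, NIfTI + DICOM I/O |
| `triseg.triplanar` | slice stacks, patch tiling/stitching, probability fusion |
| `triseg.augment` | stochastic augmentation policy and presets |
| `triseg.network` | numpy 2D U-Net, training loop, checkpoints |
| `triseg.postprocess` | thresholds, n-largest, touch rules, hole filling |
| `triseg.metrics` | Dice/Jaccard, surface meshes and distances |
| `triseg.phantom` | synthetic phantom and cohort generation |
| `triseg.pipeline` / `triseg.cli` | end-to-end orchestration and CLI |

See `docs/methods.md` for the modelling assumptions, parameter choices and
known limitations.
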