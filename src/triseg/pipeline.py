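"""End-to-end orchestration: inference, evaluation and training-set-size sweeps.

The inference workflow is a deterministic composition: resample the input
volume to isotropic resolution, split it into the model's orientation
stacks, tile each slice into overlapping patches, predict per-patch class
probabilities with the single shared 2D U-Net, stitch patches back into
slices, fuse the orientation probability volumes by voxel-wise averaging,
apply the rule-based post-processing, and finally resample the label map
back to the native input lattice so it overlays the source file.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .augment import AugmentationPolicy
from .metrics import MetricsReport, evaluate_case
from .network import (
    SegmentationModel,
    TrainingConfig,
    extract_training_patches,
    train_model,
)
from .phantom import CohortCase
from .postprocess import PostProcessSpec, apply_postprocess
from .triplanar import (
    PatchGrid,
    ProbabilityVolume,
    extract_slices,
    restack_slices,
    tile_slice,
    stitch_slice,
    fuse_orientations,
)
from .volumes import (
    ImageVolume,
    LabelVolume,
    ValidationError,
    normalize_intensities,
    resample_isotropic,
    resample_labels_to_shape,
)


class StageError(RuntimeError):
    """Wraps an error raised inside a pipeline stage with the stage name."""

    def __init__(self, stage: str, original: BaseException):
        super().__init__(f"[{stage}] {original}")
        self.stage = stage
        self.original = original


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - deliberately annotated and re-raised
                raise StageError(name, exc) from exc

        return wrapper

    return deco


@dataclass
class RunLogEntry:
    stage: str
    seconds: float
    detail: str = ""


@dataclass
class RunLog:
    """Structured record of pipeline stages for reproducibility audits."""

    entries: list[RunLogEntry] = field(default_factory=list)

    def add(self, stage: str, seconds: float, detail: str = "") -> None:
        self.entries.append(RunLogEntry(stage, seconds, detail))


def predict_probabilities(
    model: SegmentationModel,
    vol: ImageVolume,
    stride: int | None = None,
) -> ProbabilityVolume:
    """Tri-planar patch inference on an isotropic, normalised volume.

    The default inference stride is half the patch size (50% overlap), so
    interior regions are segmented multiple times per orientation and
    boundary areas are never missed.
    """
    stride = stride or max(1, model.patch_size // 2)
    per_orientation = []
    for orientation in model.orientation_set:
        stack = extract_slices(vol.data, orientation)
        grid = PatchGrid(model.patch_size, stride, stack.shape[1:])
        n_slices = stack.shape[0]
        anchors = grid.offsets
        # batch all patches of the stack through the network at once
        patches = np.stack(
            [p for s in stack for p, _ in tile_slice(s, grid)]
        )
        probs = model.predict_probs(patches)
        per_patch = probs.transpose(0, 2, 3, 1)  # (n, P, P, K)
        k = len(anchors)
        slices_out = [
            stitch_slice(
                list(zip(per_patch[i * k : (i + 1) * k], anchors)), stack.shape[1:]
            )
            for i in range(n_slices)
        ]
        stack_probs = np.stack(slices_out)  # (S, H, W, K)
        vol_probs = restack_slices(stack_probs, orientation)
        per_orientation.append(
            ProbabilityVolume(
                np.moveaxis(vol_probs, -1, 0), vol.spacing, model.class_names
            )
        )
    return fuse_orientations(per_orientation)


def segment_volume(
    model: SegmentationModel,
    vol: ImageVolume,
    spec: PostProcessSpec,
    stride: int | None = None,
    output_lattice: str = "native",
    run_log: RunLog | None = None,
) -> LabelVolume:
    """Full inference workflow from raw volume to post-processed label map.

    Parameters
    ----------
    output_lattice : {"native", "isotropic"}
        "native" resamples the result back onto the input grid
        (nearest-neighbour); "isotropic" keeps the working grid, which is
        the default lattice for metric evaluation.
    """
    if set(spec.class_names) != set(model.class_names):
        raise StageError(
            "postprocess",
            ValidationError(
                f"post-processing classes {spec.class_names} do not match model "
                f"classes {model.class_names}"
            ),
        )
    log = run_log if run_log is not None else RunLog()

    t0 = time.perf_counter()
    iso = _stage("resample")(resample_isotropic)(vol)
    norm = _stage("normalize")(normalize_intensities)(iso)
    log.add("resample", time.perf_counter() - t0, f"{vol.shape} -> {iso.shape}")

    t0 = time.perf_counter()
    fused = _stage("inference")(predict_probabilities)(model, norm, stride)
    log.add("inference", time.perf_counter() - t0, f"orientations={len(model.orientation_set)}")

    t0 = time.perf_counter()
    labels = _stage("postprocess")(apply_postprocess)(fused, spec)
    log.add("postprocess", time.perf_counter() - t0)

    if output_lattice == "native":
        labels = _stage("resample_back")(resample_labels_to_shape)(
            labels, vol.shape, vol.spacing
        )
    elif output_lattice != "isotropic":
        raise StageError("output", ValidationError(f"unknown lattice {output_lattice!r}"))
    return labels


# ---------------------------------------------------------------------------
# Phantom-cohort training harness


def train_on_cohort(
    cases: Sequence[CohortCase],
    config: TrainingConfig,
    policy: AugmentationPolicy | None = None,
    orientations=None,
    stride: int | None = None,
    verbose: bool = False,
):
    """Resample/normalise the training cases, tile them, and train one model."""
    from .triplanar import ALL_ORIENTATIONS
    from .volumes import resample_labels

    orientations = tuple(orientations or ALL_ORIENTATIONS)
    stride = stride or config.patch_size
    train_cases = [c for c in cases if not c.is_test]
    if not train_cases:
        raise ValidationError("cohort contains no training cases")
    dataset = []
    class_names = train_cases[0].labels.class_names
    for c in train_cases:
        iso = normalize_intensities(resample_isotropic(c.image))
        lab = resample_labels(c.labels, iso.spacing)
        dataset.extend(
            extract_training_patches(iso, lab, config.patch_size, stride, orientations)
        )
    return train_model(
        dataset,
        config,
        policy,
        class_names=class_names,
        orientations=orientations,
        verbose=verbose,
    )


def evaluate_on_cases(
    model: SegmentationModel,
    cases: Sequence[CohortCase],
    spec: PostProcessSpec,
    stride: int | None = None,
    surface: bool = True,
) -> list[tuple[CohortCase, MetricsReport]]:
    """Segment each case and score it against its ground truth.

    Metrics are computed on the isotropic working lattice (the prediction's
    native grid), with the ground truth resampled onto it.
    """
    from .volumes import resample_labels

    out = []
    for case in cases:
        pred = segment_volume(model, case.image, spec, stride=stride, output_lattice="isotropic")
        gt = resample_labels(case.labels, pred.spacing)
        out.append((case, evaluate_case(gt, pred, surface=surface)))
    return out


@dataclass
class ExperimentManifest:
    """Bookkeeping for a training-set-size sweep.

    Train and test case ids are disjoint by construction; training subsets
    are nested (every smaller training set is a prefix of the larger ones),
    mirroring how data-efficiency studies grow their training pools.
    """

    train_ids: list[int]
    test_ids: list[int]
    sizes: list[int]
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValidationError("train and test case ids overlap")
        if self.sizes and max(self.sizes) > len(self.train_ids):
            raise ValidationError(
                f"largest sweep size {max(self.sizes)} exceeds training pool "
                f"({len(self.train_ids)} cases)"
            )

    def subset(self, size: int) -> list[int]:
        return self.train_ids[:size]


def run_size_sweep(
    cases: Sequence[CohortCase],
    sizes: Sequence[int],
    config: TrainingConfig,
    spec: PostProcessSpec,
    policy: AugmentationPolicy | None = None,
    seed: int = 0,
    surface: bool = False,
):
    """Train one model per training-set size; evaluate all on the same test set.

    Returns ``(table, manifest)`` where the table has one row per
    (size, test case, class) with Dice/Jaccard (and surface metrics when
    requested) plus the per-case delta of each size against the smallest.
    """
    import pandas as pd
    from dataclasses import replace as dc_replace

    train_ids = [c.case_id for c in cases if not c.is_test]
    test_ids = [c.case_id for c in cases if c.is_test]
    manifest = ExperimentManifest(train_ids, test_ids, sorted(sizes), seed)
    by_id = {c.case_id: c for c in cases}
    test_cases = [by_id[i] for i in test_ids]
    rows = []
    for size in manifest.sizes:
        subset_ids = manifest.subset(size)
        subset = [by_id[i] for i in subset_ids]
        cfg = dc_replace(config, seed=seed)
        model, _ = train_on_cohort(subset, cfg, policy)
        for case, report in evaluate_on_cases(model, test_cases, spec, surface=surface):
            for m in report.per_class:
                rows.append(
                    {
                        "size": size,
                        "case_id": case.case_id,
                        "class_id": m.class_id,
                        "class_name": m.class_name,
                        "dice": m.dice,
                        "jaccard": m.jaccard,
                        "p95_abs_mm": m.p95_abs_mm,
                    }
                )
    table = pd.DataFrame(rows)
    base = table[table["size"] == manifest.sizes[0]].set_index(["case_id", "class_id"])["dice"]
    table["dice_delta_vs_smallest"] = table.apply(
        lambda r: r["dice"] - base.loc[(r["case_id"], r["class_id"])], axis=1
    )
    return table, manifest


__all__ = [
    "StageError",
    "RunLog",
    "ExperimentManifest",
    "predict_probabilities",
    "segment_volume",
    "train_on_cohort",
    "evaluate_on_cases",
    "run_size_sweep",
]
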