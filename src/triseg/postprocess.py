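"""Rule-based anatomical post-processing of fused probability volumes.

The framework converts class probabilities into final label maps with a
small set of configurable, anatomy-driven rules:

* a per-class probability threshold (50%, 25% or 12.5% in the shipped
  presets) — lowering it below 50% lets a class win even when background
  holds the majority, which recovers thin structures such as the orbital
  floor;
* hole filling (segmented objects are solid, e.g. bones include the
  spongious interior);
* removal of objects smaller than 0.1 ml;
* keeping only the n largest 26-connected objects of a class (anatomical
  prior: at most two eyes, one mandible, ...);
* requiring a class's objects to touch another class's objects (the trachea
  must touch the lung parenchyma).

All object logic uses standard 26-connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass
from graphlib import CycleError, TopologicalSorter
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .triplanar import ProbabilityVolume
from .volumes import LabelVolume, ValidationError

STRUCT_26 = np.ones((3, 3, 3), bool)


class ConfigurationError(ValueError):
    """Raised for inconsistent post-processing specifications."""


@dataclass(frozen=True)
class ClassRule:
    """Post-processing rule for one class (one row of the settings table)."""

    threshold: float = 0.5
    n_largest: int | None = None
    must_touch: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold <= 1.0:
            raise ConfigurationError(f"threshold must be in (0, 1], got {self.threshold}")
        if self.n_largest is not None and self.n_largest < 1:
            raise ConfigurationError("n_largest must be >= 1")


@dataclass
class PostProcessSpec:
    """Per-class rules plus the global fill-holes and minimum-volume settings."""

    rules: dict[str, ClassRule]
    fill_holes: bool = True
    min_volume_ml: float = 0.1

    def __post_init__(self) -> None:
        for name, rule in self.rules.items():
            if rule.must_touch is not None and rule.must_touch not in self.rules:
                raise ConfigurationError(
                    f"class {name!r} must touch unknown class {rule.must_touch!r}"
                )

    @property
    def class_names(self) -> list[str]:
        return list(self.rules)

    def processing_order(self) -> list[str]:
        """Classes ordered so every must_touch target is processed first."""
        ts = TopologicalSorter(
            {n: ([r.must_touch] if r.must_touch else []) for n, r in self.rules.items()}
        )
        try:
            return list(ts.static_order())
        except CycleError as exc:
            raise ConfigurationError(f"circular must_touch references: {exc}") from exc

    def to_dict(self) -> dict:
        return {
            "fill_holes": self.fill_holes,
            "min_volume_ml": self.min_volume_ml,
            "classes": {
                n: {
                    "threshold": r.threshold,
                    "n_largest": r.n_largest,
                    "must_touch": r.must_touch,
                }
                for n, r in self.rules.items()
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PostProcessSpec":
        rules = {
            str(n): ClassRule(
                threshold=float(r.get("threshold", 0.5)),
                n_largest=r.get("n_largest"),
                must_touch=r.get("must_touch"),
            )
            for n, r in d["classes"].items()
        }
        return cls(
            rules,
            fill_holes=bool(d.get("fill_holes", True)),
            min_volume_ml=float(d.get("min_volume_ml", 0.1)),
        )


#: Shipped per-application presets (probability threshold, n-largest, touch).
TABLE_PRESETS: dict[str, PostProcessSpec] = {
    "skeletal": PostProcessSpec({"bone": ClassRule(0.5)}),
    "oculo_cranial": PostProcessSpec(
        {"orbita": ClassRule(0.125, 1), "eyes": ClassRule(0.125, 2)}
    ),
    "mandibulo_cranial": PostProcessSpec(
        {"mandible": ClassRule(0.5, 1), "cranium": ClassRule(0.5, 1)}
    ),
    "congenital": PostProcessSpec({"blood_pool": ClassRule(0.25, 1), "bone": ClassRule(0.25, 1)}),
    "fetal": PostProcessSpec({"fetus": ClassRule(0.5, 1)}),
    "pulmonary_tracheal": PostProcessSpec(
        {
            "parenchyma": ClassRule(0.5, 2),
            "trachea": ClassRule(0.5, 1, must_touch="parenchyma"),
        }
    ),
}


# ---------------------------------------------------------------------------
# Primitive operations


def threshold_probabilities(
    prob: ProbabilityVolume, spec: PostProcessSpec
) -> LabelVolume:
    """Assign voxels to classes by thresholded maximum probability.

    A voxel belongs to the foreground class with the highest probability
    among the classes whose probability strictly exceeds their threshold;
    if no class passes, the voxel is background. With thresholds below 50%
    a foreground class can claim a voxel even when the background holds the
    plurality. Exact probability ties go to the lower class index.
    """
    names = spec.class_names
    if len(names) != prob.num_classes:
        raise ConfigurationError(
            f"spec has {len(names)} classes but probabilities have {prob.num_classes}"
        )
    fg = prob.channels[1:].astype(np.float64)  # (C, Z, Y, X)
    thresholds = np.array([spec.rules[n].threshold for n in names])
    passes = fg > thresholds[:, None, None, None]
    masked = np.where(passes, fg, -np.inf)
    best = np.argmax(masked, axis=0)  # argmax returns first (lowest) index on ties
    any_pass = passes.any(axis=0)
    labels = np.where(any_pass, best + 1, 0).astype(np.int16)
    return LabelVolume(labels, prob.spacing, names)


def label_components(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """26-connected component labelling.

    Returns the component-id grid (0 = background, ids 1..n in scan order)
    and the per-component voxel counts (index i = component i + 1).
    """
    comp, n = ndimage.label(mask.astype(bool), structure=STRUCT_26)
    counts = np.bincount(comp.ravel(), minlength=n + 1)[1:]
    return comp, counts


def select_n_largest(mask: np.ndarray, n: int) -> np.ndarray:
    """Keep the n largest 26-connected components by voxel count.

    Size ties are broken by component id (scan order), so the result is
    deterministic.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    comp, counts = label_components(mask)
    if counts.size <= n:
        return mask.astype(bool).copy()
    # stable sort descending on counts -> scan-order tie-break
    order = np.argsort(-counts, kind="stable")[:n]
    keep = np.zeros(counts.size + 1, bool)
    keep[order + 1] = True
    return keep[comp]


def remove_small_objects(
    mask: np.ndarray, spacing: Sequence[float], min_volume_ml: float = 0.1
) -> np.ndarray:
    """Drop 26-connected components with physical volume < ``min_volume_ml``.

    Volume is voxel count x voxel volume; the cut is strict, so an object of
    exactly the minimum volume is kept. 0.1 ml corresponds to 100 voxels at
    1 mm isotropic spacing.
    """
    spacing = tuple(float(s) for s in spacing)
    if any(s <= 0 for s in spacing):
        raise ValidationError("spacing must be positive")
    voxel_ml = float(np.prod(spacing)) / 1000.0
    comp, counts = label_components(mask)
    keep = np.zeros(counts.size + 1, bool)
    keep[1:] = counts * voxel_ml >= min_volume_ml
    return keep[comp]


def enforce_touch(mask: np.ndarray, other: np.ndarray) -> np.ndarray:
    """Keep components of ``mask`` that are 26-adjacent to (or overlap) ``other``."""
    mask = np.asarray(mask, bool)
    other = np.asarray(other, bool)
    if mask.shape != other.shape:
        raise ValidationError("mask and other must share a shape")
    if not other.any():
        return np.zeros_like(mask)
    reach = ndimage.binary_dilation(other, structure=STRUCT_26)
    comp, counts = label_components(mask)
    touching = np.unique(comp[reach & (comp > 0)])
    keep = np.zeros(counts.size + 1, bool)
    keep[touching] = True
    return keep[comp]


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill internal cavities of a binary mask.

    Background components that do not reach the volume border under
    6-connectivity (face adjacency, so filling cannot leak through diagonal
    gaps) become foreground. Monotone (output is a superset of the input)
    and idempotent.
    """
    return ndimage.binary_fill_holes(np.asarray(mask, bool))


# ---------------------------------------------------------------------------
# Full procedure


def apply_postprocess(prob: ProbabilityVolume, spec: PostProcessSpec) -> LabelVolume:
    """Run the full post-processing chain on a fused probability volume.

    Per class, in order: threshold -> fill holes -> remove objects below the
    minimum volume -> keep the n largest -> enforce the touch constraint.
    Filling before removal/selection means holes cannot resurrect discarded
    objects and n-largest ranks final candidate sizes. Classes with a
    ``must_touch`` reference are processed after the class they must touch.

    Voxels a class loses become background; voxels hole-filling adds are
    claimed only if currently unassigned, so classes never overwrite each
    other. The procedure is deterministic and idempotent.
    """
    thresholded = threshold_probabilities(prob, spec)
    out = np.zeros_like(thresholded.data)
    names = spec.class_names
    final_masks: dict[str, np.ndarray] = {}
    for name in spec.processing_order():
        rule = spec.rules[name]
        class_id = names.index(name) + 1
        m = thresholded.data == class_id
        if spec.fill_holes:
            m = fill_holes(m)
        if spec.min_volume_ml > 0:
            m = remove_small_objects(m, prob.spacing, spec.min_volume_ml)
        if rule.n_largest is not None:
            m = select_n_largest(m, rule.n_largest)
        if rule.must_touch is not None:
            m = enforce_touch(m, final_masks[rule.must_touch])
        final_masks[name] = m
    for name in names:  # write in class-index order; first writer wins
        class_id = names.index(name) + 1
        out[(final_masks[name]) & (out == 0)] = class_id
    return LabelVolume(out, prob.spacing, names)


__all__ = [
    "ClassRule",
    "PostProcessSpec",
    "ConfigurationError",
    "TABLE_PRESETS",
    "STRUCT_26",
    "threshold_probabilities",
    "label_components",
    "select_n_largest",
    "remove_small_objects",
    "enforce_touch",
    "fill_holes",
    "apply_postprocess",
]
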