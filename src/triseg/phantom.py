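"""Synthetic phantom volumes for exercising the full segmentation pipeline.

Real training data for this kind of framework are clinical CT/MR volumes
with tissue classes that differ in intensity distribution, anisotropic
voxel spacing (coarser through-plane than in-plane), noise, multiple
disjoint objects per class and hollow structures. The phantoms emulate that
statistical structure with analytic solids — spheres, ellipsoids, boxes,
tubes and hollow shells — rasterised into a label map, plus Gaussian
per-class intensities and global Gaussian noise. Analytic shapes mean every
geometric assertion (volumes, topology, surface areas) has a closed form.

Cohorts jitter object size, pose and intensity across members, emulating
patient-to-patient variability and contrast differences. A held-out-shape
flag excludes one shape type from all training phantoms while guaranteeing
it appears in the test phantoms, emulating zero-shot inference on an
anatomy the model has never seen.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .volumes import ImageVolume, IntensityUnits, LabelVolume, ValidationError

SHAPES = ("sphere", "ellipsoid", "box", "tube", "hollow_shell")


@dataclass(frozen=True)
class PhantomObject:
    """One analytic solid.

    ``size_mm`` semantics by shape:
      sphere        — (radius,)
      ellipsoid     — (rz, ry, rx) semi-axes
      box           — (hz, hy, hx) half-extents
      tube          — (radius, half_length); axis along z
      hollow_shell  — (outer_radius, inner_radius)
    ``center_mm`` is (z, y, x) in world mm.
    """

    shape: str
    class_id: int
    center_mm: tuple[float, ...]
    size_mm: tuple[float, ...]
    intensity_mean: float
    intensity_sd: float

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ValidationError(f"unknown shape {self.shape!r}")
        if self.class_id < 1:
            raise ValidationError("class_id must be >= 1")

    def bounds_mm(self) -> tuple[np.ndarray, np.ndarray]:
        c = np.asarray(self.center_mm, float)
        s = np.asarray(self.size_mm, float)
        if self.shape == "sphere":
            half = np.full(3, s[0])
        elif self.shape == "ellipsoid":
            half = s
        elif self.shape == "box":
            half = s
        elif self.shape == "tube":
            half = np.array([s[1], s[0], s[0]])
        else:  # hollow_shell
            half = np.full(3, s[0])
        return c - half, c + half

    def mask(self, zz: np.ndarray, yy: np.ndarray, xx: np.ndarray) -> np.ndarray:
        cz, cy, cx = self.center_mm
        s = self.size_mm
        dz, dy, dx = zz - cz, yy - cy, xx - cx
        if self.shape == "sphere":
            return dz**2 + dy**2 + dx**2 <= s[0] ** 2
        if self.shape == "ellipsoid":
            return (dz / s[0]) ** 2 + (dy / s[1]) ** 2 + (dx / s[2]) ** 2 <= 1.0
        if self.shape == "box":
            return (np.abs(dz) <= s[0]) & (np.abs(dy) <= s[1]) & (np.abs(dx) <= s[2])
        if self.shape == "tube":
            return (dy**2 + dx**2 <= s[0] ** 2) & (np.abs(dz) <= s[1])
        # hollow_shell
        r2 = dz**2 + dy**2 + dx**2
        return (r2 <= s[0] ** 2) & (r2 > s[1] ** 2)


@dataclass
class PhantomSpec:
    """Full description of one phantom volume."""

    volume_shape: tuple[int, int, int] = (16, 32, 32)
    spacing: tuple[float, float, float] = (2.0, 1.0, 1.0)
    objects: list[PhantomObject] = field(default_factory=list)
    background_mean: float = 0.0
    background_sd: float = 5.0
    noise_sd: float = 5.0
    seed: int = 0

    @property
    def num_classes(self) -> int:
        return max((o.class_id for o in self.objects), default=0)

    def validate(self) -> None:
        ids = sorted({o.class_id for o in self.objects})
        if ids and ids != list(range(1, len(ids) + 1)):
            raise ValidationError(f"class ids must be contiguous from 1, got {ids}")
        extent = np.array(self.volume_shape) * np.array(self.spacing)
        for obj in self.objects:
            lo, hi = obj.bounds_mm()
            if np.any(lo < 0) or np.any(hi > extent):
                raise ValidationError(
                    f"{obj.shape} (class {obj.class_id}) at {obj.center_mm} exceeds "
                    f"the volume extent {tuple(extent)}"
                )


def generate_phantom(spec: PhantomSpec) -> tuple[ImageVolume, LabelVolume]:
    """Rasterise a phantom spec into an image/label pair.

    Later objects overwrite earlier ones where they overlap. The image is a
    per-class Gaussian intensity draw plus global Gaussian noise; everything
    is deterministic given ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.volume_shape)
    spacing = np.asarray(spec.spacing, float)
    zz, yy, xx = np.meshgrid(
        *(np.arange(n) * s for n, s in zip(shape, spacing)), indexing="ij"
    )
    labels = np.zeros(shape, np.int16)
    image = rng.normal(spec.background_mean, spec.background_sd, shape).astype(np.float32)
    for obj in spec.objects:
        m = obj.mask(zz, yy, xx)
        labels[m] = obj.class_id
        image[m] = rng.normal(obj.intensity_mean, obj.intensity_sd, int(m.sum()))
    image += rng.normal(0.0, spec.noise_sd, shape).astype(np.float32)
    class_names = [f"class_{i}" for i in range(1, spec.num_classes + 1)]
    return (
        ImageVolume(image, tuple(spacing), IntensityUnits.ARBITRARY),
        LabelVolume(labels, tuple(spacing), class_names),
    )


# ---------------------------------------------------------------------------
# Templates


def two_class_template(seed: int = 0) -> PhantomSpec:
    """The default study condition: two foreground classes on an anisotropic grid.

    A 32 mm cube sampled at (2, 1, 1) mm spacing — twice as coarse through-
    plane as in-plane, as CT stacks typically are. Class 1 is a 6 mm-radius
    sphere, class 2 an 8 mm box; class means (100, 200) sit 12 noise-SDs
    apart on an arbitrary-unit scale (think soft tissue vs bone on CT),
    against background 0 with SD 5 plus global noise SD 5.
    """
    return PhantomSpec(
        volume_shape=(16, 32, 32),
        spacing=(2.0, 1.0, 1.0),
        objects=[
            PhantomObject("sphere", 1, (16.0, 11.0, 11.0), (6.0,), 100.0, 8.0),
            PhantomObject("box", 2, (16.0, 23.0, 23.0), (4.0, 4.0, 4.0), 200.0, 8.0),
        ],
        background_mean=0.0,
        background_sd=5.0,
        noise_sd=5.0,
        seed=seed,
    )


def imbalanced_template(seed: int = 0) -> PhantomSpec:
    """Severe class imbalance: a thin tube beside a large slab.

    The tube occupies roughly 1-3% of the slab's volume, emulating airway-
    versus-lung class imbalance, and touches the slab so the touch
    constraint is exercised.
    """
    return PhantomSpec(
        volume_shape=(16, 32, 32),
        spacing=(2.0, 1.0, 1.0),
        objects=[
            PhantomObject("box", 1, (16.0, 13.0, 16.0), (10.0, 9.0, 12.0), 100.0, 8.0),
            PhantomObject("tube", 2, (16.0, 24.0, 16.0), (1.8, 9.0), 200.0, 8.0),
        ],
        seed=seed,
    )


@dataclass(frozen=True)
class CohortJitter:
    """Per-case random perturbations emulating cohort diversity.

    size_frac: multiplicative size jitter U(1-f, 1+f);
    center_shift_mm: each centre coordinate shifted U(-d, d);
    intensity_shift: class mean shifted U(-s, s) (contrast variability).
    """

    size_frac: float = 0.15
    center_shift_mm: float = 2.0
    intensity_shift: float = 10.0


@dataclass
class CohortCase:
    case_id: int
    seed: int
    is_test: bool
    image: ImageVolume
    labels: LabelVolume
    shapes: dict[int, str]  # class id -> shape used


#: alternative shapes per class for cohort diversity (first entry = fallback)
_SHAPE_CHOICES: dict[int, tuple[str, ...]] = {1: ("sphere", "ellipsoid"), 2: ("box", "tube")}


def _jittered_spec(
    template: PhantomSpec,
    jitter: CohortJitter,
    rng: np.random.Generator,
    case_seed: int,
    shape_overrides: dict[int, str],
) -> PhantomSpec:
    objects = []
    for obj in template.objects:
        size = np.asarray(obj.size_mm, float)
        centre = np.asarray(obj.center_mm, float)
        shape = shape_overrides.get(obj.class_id, obj.shape)
        f = rng.uniform(1 - jitter.size_frac, 1 + jitter.size_frac)
        shift = rng.uniform(-jitter.center_shift_mm, jitter.center_shift_mm, 3)
        dmean = rng.uniform(-jitter.intensity_shift, jitter.intensity_shift)
        if shape != obj.shape:
            # re-parameterise the size for the substituted shape, matching scale
            base = float(size[0])
            if shape == "ellipsoid":
                size = np.array([base, base * 0.8, base * 1.2])
            elif shape == "sphere":
                size = np.array([base])
            elif shape == "box":
                size = np.array([base, base, base])
            elif shape == "tube":
                size = np.array([base * 0.5, base * 1.5])
        objects.append(
            replace(
                obj,
                shape=shape,
                size_mm=tuple(size * f),
                center_mm=tuple(centre + shift),
                intensity_mean=obj.intensity_mean + dmean,
            )
        )
    return replace(template, objects=objects, seed=case_seed)


def generate_cohort(
    n: int,
    spec_template: PhantomSpec | None = None,
    jitter: CohortJitter | None = None,
    seed: int = 0,
    n_test: int = 0,
    held_out_shape: str | None = None,
) -> list[CohortCase]:
    """Generate ``n`` independent, jittered phantoms.

    The first ``n - n_test`` cases are the training pool, the rest the test
    set. With ``held_out_shape`` set, that shape type never appears in a
    training phantom but is forced into at least one test phantom —
    emulating inference on unseen anatomy (zero-shot).
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if not 0 <= n_test < n or (n_test == 0 and held_out_shape):
        if held_out_shape and n_test == 0:
            raise ValidationError("held_out_shape requires n_test >= 1")
        raise ValidationError("n_test must satisfy 0 <= n_test < n")
    if held_out_shape is not None and held_out_shape not in SHAPES:
        raise ValidationError(f"unknown shape {held_out_shape!r}")
    template = spec_template or two_class_template()
    jitter = jitter or CohortJitter()
    rng = np.random.default_rng(seed)
    cases: list[CohortCase] = []
    n_train = n - n_test
    for i in range(n):
        is_test = i >= n_train
        overrides: dict[int, str] = {}
        for obj in template.objects:
            choices = list(_SHAPE_CHOICES.get(obj.class_id, (obj.shape,)))
            if obj.shape not in choices:
                choices.insert(0, obj.shape)
            if not is_test and held_out_shape in choices:
                choices = [c for c in choices if c != held_out_shape]
            overrides[obj.class_id] = choices[int(rng.integers(0, len(choices)))]
        if is_test and held_out_shape is not None and i == n_train:
            # guarantee at least one test exposure of the held-out shape
            for obj in template.objects:
                if held_out_shape in _SHAPE_CHOICES.get(obj.class_id, ()):
                    overrides[obj.class_id] = held_out_shape
                    break
        case_seed = int(rng.integers(0, 2**31 - 1))
        spec = _jittered_spec(template, jitter, rng, case_seed, overrides)
        img, lab = generate_phantom(spec)
        cases.append(CohortCase(i, case_seed, is_test, img, lab, overrides))
    return cases


def cohort_manifest(cases: Sequence[CohortCase]):
    """Tabular cohort summary (case id, seed, split, shape inventory)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "case_id": c.case_id,
                "seed": c.seed,
                "split": "test" if c.is_test else "train",
                **{f"class_{k}_shape": v for k, v in sorted(c.shapes.items())},
            }
            for c in cases
        ]
    )


__all__ = [
    "SHAPES",
    "PhantomObject",
    "PhantomSpec",
    "CohortJitter",
    "CohortCase",
    "generate_phantom",
    "generate_cohort",
    "cohort_manifest",
    "two_class_template",
    "imbalanced_template",
]
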