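"""Volume containers and isotropic resampling.

Conventions used throughout the package:

* Grids are indexed ``(z, y, x)``, 0-based.
* ``spacing`` is the per-axis voxel size in millimetres, ordered ``(z, y, x)``
  to match the index order.
* The world position of a voxel centre is ``index * spacing`` (canonical
  axis-aligned frame; oblique acquisitions are resampled into it on load).

The first step of the segmentation framework is resampling every volume to
isotropic resolution, where the target spacing is the finest resolution of
the acquisition (the minimum spacing component, in-plane or through-plane).
Images are interpolated linearly, label maps with nearest neighbour so that
class indices stay discrete.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import ndimage


class IntensityUnits(str, Enum):
    """Intensity scale of an image volume."""

    HU = "HU"  # calibrated CT Hounsfield units (water = 0, air ~ -1000)
    ARBITRARY = "arbitrary"  # e.g. MR magnitude images


class ValidationError(ValueError):
    """Raised when a volume or argument violates a documented invariant."""


def _check_spacing(spacing: Sequence[float]) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3:
        raise ValidationError(f"spacing must have 3 components, got {len(spacing)}")
    if any(not np.isfinite(s) or s <= 0 for s in spacing):
        raise ValidationError(f"spacing components must be positive, got {spacing}")
    return spacing


@dataclass
class ImageVolume:
    """A 3D scalar image on a regular grid.

    Parameters
    ----------
    data : ndarray, shape (Z, Y, X)
        Scalar intensities.
    spacing : (float, float, float)
        Voxel size in mm, ordered (z, y, x).
    units : IntensityUnits
        ``HU`` for CT, ``arbitrary`` otherwise.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    units: IntensityUnits = IntensityUnits.ARBITRARY

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or any(s < 1 for s in self.data.shape):
            raise ValidationError(
                f"image data must be 3D with each axis >= 1, got shape {self.data.shape}"
            )
        self.spacing = _check_spacing(self.spacing)
        self.units = IntensityUnits(self.units)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def is_isotropic(self) -> bool:
        s = self.spacing
        return bool(np.allclose(s, s[0], rtol=1e-5, atol=1e-8))

    def voxel_volume_ml(self) -> float:
        """Physical volume of one voxel in millilitres (1 ml = 1000 mm^3)."""
        return float(np.prod(self.spacing)) / 1000.0


@dataclass
class LabelVolume:
    """An integer class map on a regular grid; 0 is background, 1..C are classes."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or any(s < 1 for s in self.data.shape):
            raise ValidationError(
                f"label data must be 3D with each axis >= 1, got shape {self.data.shape}"
            )
        if not np.issubdtype(self.data.dtype, np.integer):
            if np.issubdtype(self.data.dtype, np.floating) and np.all(
                self.data == np.round(self.data)
            ):
                self.data = self.data.astype(np.int16)
            else:
                raise ValidationError("label data must be an integer grid")
        if self.data.min() < 0:
            raise ValidationError("label values must be >= 0")
        self.spacing = _check_spacing(self.spacing)
        if self.class_names:
            self.class_names = list(self.class_names)
            if int(self.data.max()) > len(self.class_names):
                raise ValidationError(
                    f"label map contains class {int(self.data.max())} but only "
                    f"{len(self.class_names)} class names were given"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def num_classes(self) -> int:
        """Number of foreground classes C (class indices run 1..C)."""
        if self.class_names:
            return len(self.class_names)
        return int(self.data.max())

    def class_mask(self, class_id: int) -> np.ndarray:
        return self.data == class_id


def _resample_grid(
    data: np.ndarray,
    spacing: tuple[float, float, float],
    target_spacing: tuple[float, float, float],
    order: int,
) -> np.ndarray:
    """Resample onto a new grid with the same physical extent.

    Output size per axis is ``round(extent / target)`` so the physical extent
    is preserved to within one output voxel.
    """
    out_shape = tuple(
        max(1, int(round(n * s / t)))
        for n, s, t in zip(data.shape, spacing, target_spacing)
    )
    if out_shape == data.shape and np.allclose(spacing, target_spacing):
        return data.copy()
    # Map output index -> input index: world-extent preserving affine.
    scale = [data.shape[i] / out_shape[i] for i in range(3)]
    # Align voxel centres: in_index = (out_index + 0.5) * scale - 0.5
    offset = [0.5 * s - 0.5 for s in scale]
    out = ndimage.affine_transform(
        data.astype(np.float32 if order > 0 else data.dtype),
        np.diag(scale),
        offset=offset,
        output_shape=out_shape,
        order=order,
        mode="nearest",
    )
    return out


def resample_isotropic(
    vol: ImageVolume, interpolation: str = "linear"
) -> ImageVolume:
    """Resample an image volume to isotropic spacing.

    The target spacing is the minimum of the input spacing components — the
    highest resolution present in-plane or through-plane — so no axis loses
    resolution.

    Parameters
    ----------
    vol : ImageVolume
    interpolation : {"linear", "nearest"}

    Returns
    -------
    ImageVolume with spacing (s, s, s), s = min(input spacing).
    """
    if interpolation not in ("linear", "nearest"):
        raise ValidationError(f"unknown interpolation {interpolation!r}")
    s = min(vol.spacing)
    target = (s, s, s)
    if vol.is_isotropic:
        return ImageVolume(vol.data.copy(), target, vol.units)
    order = 1 if interpolation == "linear" else 0
    out = _resample_grid(vol.data, vol.spacing, target, order)
    return ImageVolume(out, target, vol.units)


def resample_labels(
    lab: LabelVolume, target_spacing: Sequence[float]
) -> LabelVolume:
    """Resample a label volume with nearest-neighbour interpolation.

    Nearest neighbour guarantees the output label set is a subset of the
    input label set — no fractional classes are invented.
    """
    target = _check_spacing(target_spacing)
    if np.allclose(lab.spacing, target):
        return LabelVolume(lab.data.copy(), target, lab.class_names)
    out = _resample_grid(lab.data, lab.spacing, target, order=0)
    return LabelVolume(out, target, lab.class_names)


def resample_labels_to_shape(
    lab: LabelVolume,
    target_shape: tuple[int, int, int],
    target_spacing: Sequence[float],
) -> LabelVolume:
    """Nearest-neighbour resample onto an explicit target lattice.

    Used at the end of inference to bring a prediction back to the native
    lattice of the input scan so outputs overlay the source file exactly.
    """
    target = _check_spacing(target_spacing)
    if lab.shape == tuple(target_shape) and np.allclose(lab.spacing, target):
        return LabelVolume(lab.data.copy(), target, lab.class_names)
    scale = [lab.shape[i] / target_shape[i] for i in range(3)]
    offset = [0.5 * s - 0.5 for s in scale]
    out = ndimage.affine_transform(
        lab.data,
        np.diag(scale),
        offset=offset,
        output_shape=tuple(target_shape),
        order=0,
        mode="nearest",
    )
    return LabelVolume(out, target, lab.class_names)


def normalize_intensities(vol: ImageVolume) -> ImageVolume:
    """Network-input intensity normalisation.

    CT volumes (Hounsfield units) are left on their calibrated scale; volumes
    in arbitrary units (MR, phantoms) are min-max scaled per volume to [0, 1]
    because their absolute scale carries no information.
    """
    if vol.units == IntensityUnits.HU:
        return vol
    lo = float(vol.data.min())
    hi = float(vol.data.max())
    if hi - lo <= 0:
        return ImageVolume(np.zeros_like(vol.data, dtype=np.float32), vol.spacing, vol.units)
    out = (vol.data.astype(np.float32) - lo) / (hi - lo)
    return ImageVolume(out, vol.spacing, vol.units)


def one_hot_probabilities(lab: LabelVolume, num_classes: int | None = None) -> np.ndarray:
    """Encode a label map as a (C+1, Z, Y, X) one-hot probability array."""
    C = num_classes if num_classes is not None else lab.num_classes
    out = np.zeros((C + 1, *lab.shape), dtype=np.float32)
    for k in range(C + 1):
        out[k] = lab.data == k
    return out


__all__ = [
    "ImageVolume",
    "LabelVolume",
    "IntensityUnits",
    "ValidationError",
    "resample_isotropic",
    "resample_labels",
    "resample_labels_to_shape",
    "normalize_intensities",
    "one_hot_probabilities",
]
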