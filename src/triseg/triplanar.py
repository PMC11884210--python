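"""Tri-planar decomposition, patch tiling/stitching and probability fusion.

The framework turns a 3D segmentation task into 2D ones: the isotropic
volume is split into three stacks of slices (transversal fixing z, coronal
fixing y, sagittal fixing x), each slice is subdivided into fixed-size
overlapping square patches, a single 2D network predicts per-pixel class
probabilities per patch, patches are stitched back into slices (overlap
pixels averaged), and the three orientation probability volumes are fused by
a voxel-wise arithmetic mean. Because patches overlap, every region is
segmented multiple times and boundary areas are not missed.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .volumes import ImageVolume, ValidationError

SIMPLEX_TOL = 1e-5


class Orientation(str, Enum):
    """Slicing plane; the value names the anatomical direction.

    transversal slices fix the z index, coronal fix y, sagittal fix x.
    """

    TRANSVERSAL = "transversal"
    CORONAL = "coronal"
    SAGITTAL = "sagittal"

    @property
    def axis(self) -> int:
        return {"transversal": 0, "coronal": 1, "sagittal": 2}[self.value]


ALL_ORIENTATIONS = (Orientation.TRANSVERSAL, Orientation.CORONAL, Orientation.SAGITTAL)


def parse_orientations(names: Iterable[str]) -> tuple[Orientation, ...]:
    out = tuple(Orientation(n) for n in names)
    if not out:
        raise ValidationError("at least one orientation is required")
    if len(set(out)) != len(out):
        raise ValidationError("duplicate orientations")
    return out


# ---------------------------------------------------------------------------
# Slice stacks


def extract_slices(data: np.ndarray | ImageVolume, orientation: Orientation) -> np.ndarray:
    """Split a volume into an ordered stack of 2D slices.

    Slice ``k`` of the stack corresponds to fixed-axis index ``k`` in the
    volume, so ``restack_slices`` is an exact inverse.

    An :class:`ImageVolume` input must be isotropic — slices from an
    anisotropic grid would have non-square pixels and orientation-dependent
    geometry.
    """
    if isinstance(data, ImageVolume):
        if not data.is_isotropic:
            raise ValidationError(
                "extract_slices requires an isotropic volume; resample first"
            )
        data = data.data
    return np.moveaxis(data, orientation.axis, 0)


def restack_slices(stack: np.ndarray, orientation: Orientation) -> np.ndarray:
    """Inverse of :func:`extract_slices` (stack axis moved back into place)."""
    return np.moveaxis(stack, 0, orientation.axis)


# ---------------------------------------------------------------------------
# Patch grids


@dataclass(frozen=True)
class PatchGrid:
    """Anchor layout covering a 2D slice with P x P patches.

    Anchors are (row, col) top-left corners. Along an axis of length
    ``L >= P`` there are ``ceil((L - P) / stride) + 1`` anchors, the last one
    clamped so its patch ends exactly at the boundary. Axes shorter than P
    get a single anchor at 0 and the patch is padded by edge replication
    (the padding is discarded on stitching).
    """

    patch_size: int
    stride: int
    slice_shape: tuple[int, int]

    def __post_init__(self) -> None:
        if self.patch_size < 1:
            raise ValidationError("patch_size must be >= 1")
        if not (1 <= self.stride <= self.patch_size):
            raise ValidationError("stride must satisfy 1 <= stride <= patch_size")

    @staticmethod
    def _axis_anchors(length: int, P: int, stride: int) -> list[int]:
        if length <= P:
            return [0]
        n = int(np.ceil((length - P) / stride)) + 1
        anchors = [min(i * stride, length - P) for i in range(n)]
        # clamping can duplicate the final anchor; keep unique, ordered
        out: list[int] = []
        for a in anchors:
            if not out or a != out[-1]:
                out.append(a)
        return out

    @property
    def offsets(self) -> list[tuple[int, int]]:
        rows = self._axis_anchors(self.slice_shape[0], self.patch_size, self.stride)
        cols = self._axis_anchors(self.slice_shape[1], self.patch_size, self.stride)
        return [(r, c) for r in rows for c in cols]


def tile_slice(slice2d: np.ndarray, grid: PatchGrid) -> list[tuple[np.ndarray, tuple[int, int]]]:
    """Cut a slice into P x P patches according to a :class:`PatchGrid`.

    Returns a list of ``(patch, anchor)``; patches along short axes are
    edge-padded to exactly P x P.
    """
    P = grid.patch_size
    H, W = slice2d.shape[:2]
    if (H, W) != grid.slice_shape:
        raise ValidationError(
            f"slice shape {(H, W)} does not match grid {grid.slice_shape}"
        )
    pad_h, pad_w = max(0, P - H), max(0, P - W)
    padded = slice2d
    if pad_h or pad_w:
        # trailing dims (e.g. a channel axis) are never padded
        pad_width = ((0, pad_h), (0, pad_w)) + ((0, 0),) * (slice2d.ndim - 2)
        padded = np.pad(slice2d, pad_width, mode="edge")
    out = []
    for r, c in grid.offsets:
        out.append((padded[r : r + P, c : c + P], (r, c)))
    return out


def stitch_slice(
    patch_probs: Sequence[tuple[np.ndarray, tuple[int, int]]],
    slice_shape: tuple[int, int],
) -> np.ndarray:
    """Reassemble per-patch probability maps into one slice-level map.

    Each pixel's class vector is the arithmetic mean over all patches that
    cover it; pad regions beyond the slice boundary are discarded. The
    result is re-normalised to the probability simplex (means of simplex
    vectors already sum to 1; renormalisation only removes accumulated
    floating-point drift).

    Raises
    ------
    ValidationError
        If any pixel of the slice is covered by no patch.
    """
    if not patch_probs:
        raise ValidationError("no patches to stitch")
    K = patch_probs[0][0].shape[-1]
    H, W = slice_shape
    acc = np.zeros((H, W, K), dtype=np.float64)
    count = np.zeros((H, W), dtype=np.int32)
    for patch, (r, c) in patch_probs:
        P = patch.shape[0]
        h = min(P, H - r)
        w = min(P, W - c)
        if h <= 0 or w <= 0:
            raise ValidationError(f"anchor {(r, c)} outside slice {slice_shape}")
        acc[r : r + h, c : c + w] += patch[:h, :w]
        count[r : r + h, c : c + w] += 1
    if np.any(count == 0):
        raise ValidationError("patch grid does not cover the slice")
    out = acc / count[..., None]
    total = out.sum(axis=-1, keepdims=True)
    out = out / np.where(total > 0, total, 1.0)
    return out


# ---------------------------------------------------------------------------
# Probability volumes and fusion


@dataclass
class ProbabilityVolume:
    """Per-voxel class probabilities: channels (C+1, Z, Y, X), background first."""

    channels: np.ndarray
    spacing: tuple[float, float, float]
    class_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.float32)
        if self.channels.ndim != 4:
            raise ValidationError("channels must be a 4D (C+1, Z, Y, X) array")

    @property
    def num_classes(self) -> int:
        return self.channels.shape[0] - 1

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.channels.shape[1:]

    def validate_simplex(self, tol: float = SIMPLEX_TOL) -> None:
        if self.channels.min() < -tol or self.channels.max() > 1 + tol:
            raise ValidationError("probabilities outside [0, 1]")
        sums = self.channels.sum(axis=0)
        if np.abs(sums - 1.0).max() > tol:
            raise ValidationError(
                f"probabilities do not sum to 1 (max deviation {np.abs(sums - 1).max():.2e})"
            )

    def argmax_labels(self) -> np.ndarray:
        return np.argmax(self.channels, axis=0).astype(np.int16)


def fuse_orientations(per_orientation: Sequence[ProbabilityVolume]) -> ProbabilityVolume:
    """Fuse orientation-wise probability volumes by voxel-wise averaging.

    The final voxel-wise classification of the framework is obtained from
    the unweighted mean of the probabilities predicted along each slicing
    direction. Accepts 1-3 volumes: some applications use only two
    orientations (e.g. sagittal + coronal for mandible/cranium separation,
    where transversal patches are uninformative), and one orientation
    degenerates to plain 2D stack segmentation.
    """
    vols = list(per_orientation)
    if not 1 <= len(vols) <= 3:
        raise ValidationError("fuse_orientations expects 1-3 probability volumes")
    ref = vols[0]
    for v in vols[1:]:
        if v.channels.shape != ref.channels.shape:
            raise ValidationError(
                f"shape mismatch: {v.channels.shape} vs {ref.channels.shape}"
            )
        if not np.allclose(v.spacing, ref.spacing):
            raise ValidationError("spacing mismatch between orientation volumes")
    mean = np.mean([v.channels.astype(np.float64) for v in vols], axis=0)
    return ProbabilityVolume(mean.astype(np.float32), ref.spacing, ref.class_names)


__all__ = [
    "Orientation",
    "ALL_ORIENTATIONS",
    "parse_orientations",
    "PatchGrid",
    "ProbabilityVolume",
    "extract_slices",
    "restack_slices",
    "tile_slice",
    "stitch_slice",
    "fuse_orientations",
    "SIMPLEX_TOL",
]
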