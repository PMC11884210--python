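"""Reading and writing volumes: NIfTI files and DICOM series directories.

NIfTI stores grids in (x, y, z) order; this package uses (z, y, x), so data
is transposed on the way in and out. Spacing is carried in the NIfTI affine
(diagonal, canonical axis-aligned frame) and the intensity units in the
header ``descrip`` field. Probability volumes are stored as 4D NIfTI with
one channel per class, background first.

DICOM series are read with pydicom: the directory must contain exactly one
series; slices are sorted by their position along the slice normal and the
slice gap must be uniform. Axis-aligned acquisitions are permuted/flipped
into the canonical frame; oblique acquisitions are resampled into it so that
stack extraction downstream is deterministic.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import nibabel as nib

from .volumes import ImageVolume, IntensityUnits, LabelVolume, ValidationError

_SLICE_GAP_RTOL = 1e-2  # relative tolerance on uniformity of DICOM slice gaps


class FormatError(ValueError):
    """Raised when a file or series cannot be interpreted as a single volume."""


class GeometryError(ValueError):
    """Raised when series geometry is inconsistent (e.g. non-uniform slice gap)."""


# ---------------------------------------------------------------------------
# NIfTI


def _affine_from_spacing(spacing: tuple[float, float, float]) -> np.ndarray:
    # spacing is (z, y, x); NIfTI axes are (x, y, z)
    sz, sy, sx = spacing
    return np.diag([sx, sy, sz, 1.0])


def save_nifti(vol: ImageVolume | LabelVolume, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI (.nii or .nii.gz), preserving spacing and units."""
    data = vol.data
    img = nib.Nifti1Image(np.asanyarray(data).T, _affine_from_spacing(vol.spacing))
    if isinstance(vol, ImageVolume):
        img.header["descrip"] = f"triseg units={vol.units.value}".encode()
    else:
        names = ",".join(vol.class_names) if vol.class_names else ""
        img.header["descrip"] = f"triseg labels={names}"[:79].encode()
    nib.save(img, str(path))


def load_nifti_image(path: str | os.PathLike) -> ImageVolume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).T
    if data.ndim != 3:
        raise FormatError(f"expected a 3D NIfTI image, got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]  # (x, y, z)
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    descrip = bytes(img.header["descrip"].tobytes()).decode(errors="ignore")
    units = IntensityUnits.HU if "units=HU" in descrip else IntensityUnits.ARBITRARY
    return ImageVolume(data, spacing, units)


def load_nifti_labels(path: str | os.PathLike) -> LabelVolume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).T
    if data.ndim != 3:
        raise FormatError(f"expected a 3D NIfTI label map, got {data.ndim}D")
    if not np.all(data == np.round(data)):
        raise FormatError("label NIfTI contains non-integer values")
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    descrip = bytes(img.header["descrip"].tobytes()).decode(errors="ignore")
    names: list[str] = []
    if "labels=" in descrip:
        tail = descrip.split("labels=", 1)[1].strip("\x00 ")
        names = [n for n in tail.split(",") if n]
    return LabelVolume(data.astype(np.int16), spacing, names)


def save_probabilities(
    channels: np.ndarray, spacing: tuple[float, float, float], path: str | os.PathLike,
    class_names: list[str] | None = None,
) -> None:
    """Write a (C+1, Z, Y, X) probability array as 4D NIfTI (channel last on disk).

    Channel 0 is the background; the channel order is recorded in the header
    description field.
    """
    channels = np.asarray(channels, dtype=np.float32)
    if channels.ndim != 4:
        raise ValidationError("probability array must be (C+1, Z, Y, X)")
    on_disk = np.moveaxis(channels, 0, -1).transpose(2, 1, 0, 3)  # (x, y, z, c)
    img = nib.Nifti1Image(on_disk, _affine_from_spacing(spacing))
    order = "background," + ",".join(class_names or [])
    img.header["descrip"] = f"triseg channels={order}"[:79].encode()
    nib.save(img, str(path))


def load_probabilities(path: str | os.PathLike) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise FormatError(f"expected 4D probability NIfTI, got {data.ndim}D")
    channels = np.moveaxis(data.transpose(2, 1, 0, 3), -1, 0).astype(np.float32)
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return channels, spacing


# ---------------------------------------------------------------------------
# DICOM series


def _read_series(path: Path):
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file())
    datasets = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            datasets.append(ds)
    if not datasets:
        raise FormatError(f"no DICOM image files found in {path}")
    uids = {ds.SeriesInstanceUID for ds in datasets}
    if len(uids) != 1:
        raise FormatError(
            f"directory contains {len(uids)} DICOM series; expected exactly one"
        )
    return datasets


def load_dicom_series(path: str | os.PathLike) -> ImageVolume:
    """Read one DICOM series directory into an ImageVolume.

    Slices are ordered by position along the slice normal (the cross product
    of the row and column direction cosines). The through-plane spacing is
    the gap between consecutive slices, which must be uniform within 1%.
    CT series (Modality == "CT") are rescaled to Hounsfield units via
    RescaleSlope/RescaleIntercept and flagged ``units=HU``.
    """
    path = Path(path)
    if not path.is_dir():
        raise FormatError(f"{path} is not a directory")
    datasets = _read_series(path)

    ref = datasets[0]
    iop = np.array(getattr(ref, "ImageOrientationPatient", [1, 0, 0, 0, 1, 0]), float)
    row_dir, col_dir = iop[:3], iop[3:]
    normal = np.cross(row_dir, col_dir)

    def position(ds):
        return float(np.dot(np.array(ds.ImagePositionPatient, float), normal))

    datasets.sort(key=position)
    positions = np.array([position(ds) for ds in datasets])
    if len(datasets) < 2:
        gap = float(getattr(ref, "SliceThickness", 1.0) or 1.0)
    else:
        gaps = np.diff(positions)
        gap = float(np.mean(gaps))
        if gap <= 0 or np.any(np.abs(gaps - gap) > _SLICE_GAP_RTOL * abs(gap)):
            raise GeometryError(
                f"non-uniform slice gap in series (gaps {gaps.min():.4f}..{gaps.max():.4f})"
            )

    rows_sp, cols_sp = (float(v) for v in ref.PixelSpacing)  # (row, col) = (y, x)
    slope = float(getattr(ref, "RescaleSlope", 1.0) or 1.0)
    intercept = float(getattr(ref, "RescaleIntercept", 0.0) or 0.0)
    stack = np.stack([ds.pixel_array for ds in datasets]).astype(np.float32)
    if slope != 1.0 or intercept != 0.0:
        stack = stack * slope + intercept

    units = (
        IntensityUnits.HU
        if getattr(ref, "Modality", "") == "CT"
        else IntensityUnits.ARBITRARY
    )
    vol = ImageVolume(stack, (gap, rows_sp, cols_sp), units)
    return _canonicalize(vol, row_dir, col_dir, normal)


def _canonicalize(
    vol: ImageVolume, row_dir: np.ndarray, col_dir: np.ndarray, normal: np.ndarray
) -> ImageVolume:
    """Bring an acquisition into the canonical axis-aligned frame.

    Axis-aligned direction cosines (within tolerance) are handled by axis
    permutation and flips; anything oblique is resampled onto an axis-aligned
    grid of the same spacing with linear interpolation.
    """
    # grid axes (z, y, x) as world-space unit vectors; pixel rows (grid y)
    # run along the IOP column direction, pixel columns (grid x) along the
    # IOP row direction
    dirs = np.stack([normal, col_dir, row_dir])
    snapped = np.round(dirs)
    if np.allclose(dirs, snapped, atol=1e-3) and np.allclose(
        np.abs(snapped).sum(axis=1), 1
    ):
        world_axis = np.argmax(np.abs(snapped), axis=1)  # which world axis each grid axis runs along
        if len(set(world_axis.tolist())) != 3:
            raise GeometryError("degenerate direction cosines")
        signs = snapped[np.arange(3), world_axis]
        data = vol.data
        for ax in range(3):
            if signs[ax] < 0:
                data = np.flip(data, axis=ax)
        # world axes are (x, y, z); canonical grid order is (z, y, x)
        order = [int(np.where(world_axis == w)[0][0]) for w in (2, 1, 0)]
        data = np.transpose(data, order)
        spacing = tuple(vol.spacing[o] for o in order)
        return ImageVolume(np.ascontiguousarray(data), spacing, vol.units)
    # Oblique: resample into the axis-aligned frame at the finest spacing.
    # world(in_idx) = (in_idx * spacing) @ dirs, i.e. in_idx @ A with
    # A = diag(spacing) @ dirs; the output grid is axis-aligned with
    # world(out_idx) = lo + out_idx @ B, B = diag(s_out) @ [[0,0,1],[0,1,0],[1,0,0]].
    from scipy import ndimage

    shape = np.array(vol.shape)
    spacing = np.array(vol.spacing)
    corners = np.array(
        [[i, j, k] for i in (0, shape[0] - 1) for j in (0, shape[1] - 1) for k in (0, shape[2] - 1)],
        float,
    )
    world = (corners * spacing) @ dirs
    lo, hi = world.min(axis=0), world.max(axis=0)
    s_out = float(spacing.min())
    out_shape = np.maximum(1, np.floor((hi - lo) / s_out).astype(int) + 1)
    A = np.diag(spacing) @ dirs
    Ainv = np.linalg.inv(A)
    B = s_out * np.array([[0.0, 0.0, 1.0], [0.0, 1.0, 0.0], [1.0, 0.0, 0.0]])
    # affine_transform: in_idx = matrix @ out_idx + offset
    matrix = (B @ Ainv).T
    offset = lo @ Ainv
    out = ndimage.affine_transform(
        vol.data.astype(np.float32),
        matrix,
        offset=offset,
        output_shape=tuple(int(n) for n in out_shape),
        order=1,
        mode="nearest",
    )
    return ImageVolume(out, (s_out, s_out, s_out), vol.units)


def load_volume(path: str | os.PathLike, format: str | None = None) -> ImageVolume:
    """Load a volume from a NIfTI file or a DICOM series directory.

    Parameters
    ----------
    path : file or directory
    format : {"nifti", "dicom_series"}, optional
        Inferred from the path when omitted.
    """
    p = Path(path)
    if format is None:
        format = "dicom_series" if p.is_dir() else "nifti"
    if format == "nifti":
        return load_nifti_image(p)
    if format == "dicom_series":
        return load_dicom_series(p)
    raise FormatError(f"unknown format {format!r}")


__all__ = [
    "FormatError",
    "GeometryError",
    "load_volume",
    "load_dicom_series",
    "load_nifti_image",
    "load_nifti_labels",
    "save_nifti",
    "save_probabilities",
    "load_probabilities",
]
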