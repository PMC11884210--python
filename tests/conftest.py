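"""Shared fixtures: small synthetic volumes and a programmatic DICOM writer."""

from __future__ import annotations

import os

import numpy as np
import pytest

from triseg.volumes import ImageVolume, LabelVolume


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_volume(rng):
    return ImageVolume(rng.normal(size=(8, 8, 8)).astype(np.float32), (1.0, 1.0, 1.0))


@pytest.fixture
def sphere_pair():
    """16^3 isotropic volume with a centred radius-5 sphere of class 1."""
    zz, yy, xx = np.meshgrid(*[np.arange(16)] * 3, indexing="ij")
    mask = (zz - 7.5) ** 2 + (yy - 7.5) ** 2 + (xx - 7.5) ** 2 <= 25
    img = np.where(mask, 100.0, 0.0).astype(np.float32)
    return (
        ImageVolume(img, (1.0, 1.0, 1.0)),
        LabelVolume(mask.astype(np.int16), (1.0, 1.0, 1.0), ["sphere"]),
    )


def write_dicom_series(
    dirpath,
    n_slices=4,
    shape=(8, 8),
    series_uid=None,
    gap=2.0,
    start=0.0,
    pixel_spacing=(0.5, 0.75),
    positions=None,
    orientation=(1, 0, 0, 0, 1, 0),
    modality="CT",
    pixels=None,
    prefix="s",
):
    """Write a minimal synthetic CT series with pydicom; returns the series UID."""
    import pydicom
    from pydicom.dataset import Dataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    series_uid = series_uid or generate_uid()
    study_uid = generate_uid()
    for i in range(n_slices):
        ds = Dataset()
        ds.SOPClassUID = "1.2.840.10008.5.1.4.1.1.2"
        ds.SOPInstanceUID = generate_uid()
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.Modality = modality
        ds.Rows, ds.Columns = shape
        ds.PixelSpacing = list(pixel_spacing)
        ds.ImageOrientationPatient = list(orientation)
        z = positions[i] if positions is not None else start + i * gap
        ds.ImagePositionPatient = [0, 0, z]
        ds.SliceThickness = gap
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = -1024.0
        ds.BitsAllocated = ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        if pixels is not None:
            arr = pixels[i].astype(np.uint16)
        else:
            arr = (np.arange(shape[0] * shape[1]).reshape(shape) % 2000 + i).astype(
                np.uint16
            )
        ds.PixelData = arr.tobytes()
        ds.file_meta = pydicom.dataset.FileMetaDataset()
        ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta.MediaStorageSOPClassUID = ds.SOPClassUID
        ds.file_meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        pydicom.dcmwrite(
            os.path.join(dirpath, f"{prefix}{i:03d}.dcm"), ds, enforce_file_format=True
        )
    return series_uid
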