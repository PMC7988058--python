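"""Imaging and tabular I/O.

Volumes are held as 3D arrays of Hounsfield Units with axis order
``slice x row x column`` and a physical voxel spacing in mm for each axis.
NIfTI files (via nibabel) and single-series DICOM directories (via pydicom)
are supported for volumes; NIfTI for lesion masks; CSV for feature and
survival tables.

The internal array convention is fixed so that axis 0 iterates over axial
slices: in-plane filtration operates on ``voxels[k]`` with pixel spacing
``(row, column)``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

from .errors import FormatError, GeometryError, ValidationError

FEATURE_COLUMNS = ["mean", "sd", "entropy", "kurtosis", "skewness", "mpp"]
FEATURE_TABLE_COLUMNS = ["patient_id", "ssf"] + FEATURE_COLUMNS
SURVIVAL_COLUMNS = [
    "patient_id",
    "os_days",
    "os_event",
    "pfs_days",
    "pfs_event",
    "progressor",
]


@dataclass(frozen=True)
class CTVolume:
    """A 3D CT grid in Hounsfield Units.

    Parameters
    ----------
    voxels
        3D float array, axis order (slice, row, column).
    spacing_mm
        (slice thickness, row spacing, column spacing) in mm, all > 0.
    patient_id
        Opaque identifier used to key feature/survival tables.
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    patient_id: str = ""

    def __post_init__(self):
        vox = np.asarray(self.voxels, dtype=np.float64)
        if vox.ndim != 3 or vox.size == 0:
            raise ValidationError("volume must be a non-empty 3D grid")
        if not np.all(np.isfinite(vox)):
            raise ValidationError("volume intensities must be finite")
        spacing = tuple(float(s) for s in self.spacing_mm)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValidationError(f"voxel spacings must be > 0, got {spacing}")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing_mm", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def in_plane_spacing_mm(self) -> tuple[float, float]:
        """(row, column) pixel spacing of the axial plane."""
        return self.spacing_mm[1], self.spacing_mm[2]


@dataclass(frozen=True)
class LesionMask:
    """Binary volume of interest aligned to a :class:`CTVolume`."""

    voxels: np.ndarray
    reference: str = ""

    def __post_init__(self):
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise ValidationError("mask must be a 3D grid")
        if vox.dtype != bool:
            uniq = np.unique(vox)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValidationError("mask values must be strictly binary")
            vox = vox.astype(bool)
        if not vox.any():
            raise ValidationError("mask has no foreground voxels")
        object.__setattr__(self, "voxels", vox)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_foreground(self) -> int:
        return int(self.voxels.sum())


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------

def _nifti_affine(spacing_mm) -> np.ndarray:
    sz, sr, sc = spacing_mm
    return np.diag([sc, sr, sz, 1.0])


def write_volume_nifti(volume: CTVolume, path) -> None:
    """Write a volume as NIfTI with on-disk axes (column, row, slice)."""
    data = np.transpose(volume.voxels, (2, 1, 0))
    img = nib.Nifti1Image(data.astype(np.float64), _nifti_affine(volume.spacing_mm))
    nib.save(img, os.fspath(path))


def write_mask_nifti(mask: LesionMask, spacing_mm, path) -> None:
    data = np.transpose(mask.voxels.astype(np.uint8), (2, 1, 0))
    img = nib.Nifti1Image(data, _nifti_affine(spacing_mm))
    nib.save(img, os.fspath(path))


def _read_nifti_grid(path):
    try:
        img = nib.load(os.fspath(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # nibabel raises several parse errors
        raise FormatError(f"could not parse NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D NIfTI image, got ndim={data.ndim}")
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise FormatError(f"{path}: non-positive voxel spacing in header: {zooms}")
    # on-disk (column, row, slice) -> internal (slice, row, column)
    grid = np.transpose(np.asarray(data, dtype=np.float64), (2, 1, 0))
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return grid, spacing


# ---------------------------------------------------------------------------
# DICOM
# ---------------------------------------------------------------------------

def _read_dicom_series(directory) -> tuple[np.ndarray, tuple[float, float, float]]:
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = []
    for p in files:
        try:
            ds = pydicom.dcmread(os.fspath(p))
        except Exception:
            continue  # non-DICOM clutter in the directory is skipped
        if hasattr(ds, "PixelData"):
            datasets.append(ds)
    if not datasets:
        raise FormatError(f"{directory}: no DICOM image files found")

    uids = {str(getattr(ds, "SeriesInstanceUID", "")) for ds in datasets}
    if len(uids) != 1:
        raise FormatError(
            f"{directory}: mixed SeriesInstanceUIDs in one directory ({len(uids)} series)"
        )

    for ds in datasets:
        if "PixelSpacing" not in ds:
            raise FormatError(f"{directory}: DICOM slice without PixelSpacing")

    # sort along the slice axis
    if all("ImagePositionPatient" in ds for ds in datasets):
        datasets.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
        zs = np.array([float(ds.ImagePositionPatient[2]) for ds in datasets])
        if len(zs) > 1:
            slice_spacing = float(np.median(np.diff(zs)))
        else:
            slice_spacing = float(getattr(datasets[0], "SliceThickness", 0) or 0)
    else:
        datasets.sort(key=lambda ds: int(getattr(ds, "InstanceNumber", 0)))
        slice_spacing = float(getattr(datasets[0], "SliceThickness", 0) or 0)
    if slice_spacing <= 0:
        raise FormatError(f"{directory}: cannot determine a positive slice spacing")

    ps = datasets[0].PixelSpacing  # (row, column)
    spacing = (slice_spacing, float(ps[0]), float(ps[1]))
    if spacing[1] <= 0 or spacing[2] <= 0:
        raise FormatError(f"{directory}: non-positive PixelSpacing {ps}")

    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
    shapes = {s.shape for s in slices}
    if len(shapes) != 1:
        raise FormatError(f"{directory}: inconsistent slice shapes {shapes}")
    return np.stack(slices, axis=0), spacing


def write_volume_dicom(volume: CTVolume, directory, prefix: str = "slice") -> None:
    """Write a volume as one CT DICOM series (one file per axial slice).

    HU values are stored as int16 with RescaleIntercept -1024 so that
    typical CT ranges fit the unsigned stored representation.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    study_uid = generate_uid()
    intercept = -1024.0
    sz, sr, sc = volume.spacing_mm
    for k in range(volume.shape[0]):
        stored = np.round(volume.voxels[k] - intercept).astype(np.int16)
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.PatientID = volume.patient_id or "ANON"
        ds.PatientName = volume.patient_id or "ANON"
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.InstanceNumber = k + 1
        ds.ImagePositionPatient = [0.0, 0.0, float(k) * sz]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [sr, sc]
        ds.SliceThickness = sz
        ds.Rows, ds.Columns = stored.shape
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = intercept
        ds.PixelData = stored.tobytes()
        ds.save_as(os.fspath(directory / f"{prefix}_{k:04d}.dcm"), enforce_file_format=True)


# ---------------------------------------------------------------------------
# Public readers
# ---------------------------------------------------------------------------

def read_volume(path, patient_id: str | None = None) -> CTVolume:
    """Read a CT volume from a NIfTI file or a directory holding one DICOM series.

    Intensities are returned in HU (DICOM rescale slope/intercept applied);
    spacing is taken from the header and never defaulted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file or directory: {path}")
    if path.is_dir():
        grid, spacing = _read_dicom_series(path)
    elif path.name.endswith((".nii", ".nii.gz")):
        grid, spacing = _read_nifti_grid(path)
    else:
        raise FormatError(f"{path}: expected a .nii/.nii.gz file or a DICOM directory")
    if patient_id is None:
        patient_id = path.name.split(".")[0]
    return CTVolume(voxels=grid, spacing_mm=spacing, patient_id=patient_id)


def read_mask(path, reference: CTVolume) -> LesionMask:
    """Read a lesion mask (NIfTI) and check congruence with its reference volume.

    Values > 0.5 map to foreground, tolerating interpolated mask exports.
    """
    grid, _ = _read_nifti_grid(path)
    if grid.shape != reference.shape:
        raise GeometryError(
            f"mask shape {grid.shape} does not match volume shape {reference.shape}"
        )
    binary = grid > 0.5
    if not binary.any():
        raise ValidationError(f"{path}: mask has no foreground voxels")
    return LesionMask(voxels=binary, reference=reference.patient_id)


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def _check_feature_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in FEATURE_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"feature table missing columns: {missing}")
    return table[FEATURE_TABLE_COLUMNS]


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write a feature table as CSV; missing values become empty fields."""
    _check_feature_table(table).to_csv(os.fspath(path), index=False)


def read_feature_table(path) -> pd.DataFrame:
    table = pd.read_csv(os.fspath(path), dtype={"patient_id": str})
    return _check_feature_table(table)


def write_survival_table(table: pd.DataFrame, path) -> None:
    validate_survival_table(table).to_csv(os.fspath(path), index=False)


def read_survival_table(path) -> pd.DataFrame:
    table = pd.read_csv(os.fspath(path), dtype={"patient_id": str})
    return validate_survival_table(table)


def validate_survival_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the per-patient survival table invariants.

    Times must be non-negative, event flags binary, and progression-free
    survival cannot exceed overall survival on the same clock.
    """
    missing = [c for c in SURVIVAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"survival table missing columns: {missing}")
    table = table[SURVIVAL_COLUMNS].copy()
    if (table["os_days"] < 0).any() or (table["pfs_days"] < 0).any():
        raise ValidationError("survival times must be non-negative")
    for col in ("os_event", "pfs_event", "progressor"):
        if not table[col].isin((0, 1)).all():
            raise ValidationError(f"{col} must be binary 0/1")
    if (table["pfs_days"] > table["os_days"] + 1e-9).any():
        raise ValidationError("pfs_days must not exceed os_days")
    if table["patient_id"].duplicated().any():
        raise ValidationError("duplicate patient_id in survival table")
    return table
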