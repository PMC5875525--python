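"""Read and write axial CT/CBCT series in DICOM, rescaled to HU.

The in-memory container is :class:`PhantomImageSeries`: a float HU
voxel array plus the geometry metadata the analysis needs.  Physical
in-plane coordinates are mm, with pixel (row r, col c) at
``(origin_x + c * col_spacing, origin_y + r * row_spacing)``; z is the
DICOM slice position, ascending.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

__all__ = ["PhantomImageSeries", "read_series", "write_series"]

_CT_STORAGE = "1.2.840.10008.5.1.4.1.1.2"
_AXIAL_ORIENTATION = [1.0, 0.0, 0.0, 0.0, 1.0, 0.0]


@dataclass
class PhantomImageSeries:
    """An axial HU volume of the phantom with physical geometry metadata."""

    hu: np.ndarray  # (slices, rows, cols), HU
    pixel_spacing: tuple[float, float]  # (row, col) mm/pixel
    slice_thickness: float  # mm
    z_positions: np.ndarray  # mm, ascending, one per slice
    modality: str = "CT"  # CT | CBCT (stored as CT with a label)
    protocol: str = ""
    machine: str = ""
    acquisition_date: str = ""  # ISO yyyy-mm-dd
    origin: tuple[float, float] = (0.0, 0.0)  # mm of pixel (0, 0) center

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu, dtype=np.float64)
        self.z_positions = np.asarray(self.z_positions, dtype=np.float64)
        if self.hu.ndim != 3:
            raise ValueError("hu must be (slices, rows, cols)")
        if len(self.z_positions) != self.hu.shape[0]:
            raise ValueError("one z position per slice required")
        if len(self.z_positions) > 1 and not np.all(np.diff(self.z_positions) > 0):
            raise ValueError("slice z positions must be strictly increasing")
        if min(self.pixel_spacing) <= 0:
            raise ValueError("pixel spacing must be positive")
        if not np.all(np.isfinite(self.hu)):
            raise ValueError("HU values must be finite")

    @property
    def n_slices(self) -> int:
        return self.hu.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.hu.shape

    def pixel_area_mm2(self) -> float:
        return self.pixel_spacing[0] * self.pixel_spacing[1]

    def slice_index_at(self, z: float) -> int:
        """Index of the slice whose center is nearest z (mm)."""
        return int(np.argmin(np.abs(self.z_positions - z)))

    def pixel_coords_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) mm coordinate grids of pixel centers, each (rows, cols)."""
        nr, nc = self.hu.shape[1:]
        x = self.origin[0] + np.arange(nc)[None, :] * self.pixel_spacing[1]
        y = self.origin[1] + np.arange(nr)[:, None] * self.pixel_spacing[0]
        return np.broadcast_to(x, (nr, nc)), np.broadcast_to(y, (nr, nc))


def _require(ds: Dataset, attr: str, path: str):
    value = getattr(ds, attr, None)
    if value is None:
        raise ValueError(f"{path}: missing required DICOM attribute {attr}")
    return value


def read_series(directory_path) -> PhantomImageSeries:
    """Read a single axial DICOM series from a directory.

    Stored values are mapped to HU with RescaleSlope/RescaleIntercept and
    slices are sorted by z ascending.  Mixed series, missing geometry or
    rescale metadata and non-axial orientations are rejected with an
    error that names the offending attribute or file.
    """
    directory = Path(directory_path)
    files = sorted(p for p in directory.glob("*.dcm"))
    if not files:
        files = sorted(p for p in directory.iterdir() if p.is_file())
    if not files:
        raise ValueError(f"{directory}: no DICOM files found")
    slices = []
    for path in files:
        try:
            ds = pydicom.dcmread(path)
        except Exception as exc:  # unreadable file in the directory
            raise ValueError(f"{path}: not a readable DICOM file ({exc})") from exc
        slices.append((path, ds))

    first = slices[0][1]
    series_uid = getattr(first, "SeriesInstanceUID", None)
    shape = (int(first.Rows), int(first.Columns))
    spacing = _require(first, "PixelSpacing", str(slices[0][0]))
    records = []
    for path, ds in slices:
        if getattr(ds, "SeriesInstanceUID", None) != series_uid:
            raise ValueError(f"{path}: mixed series (SeriesInstanceUID differs)")
        if (int(ds.Rows), int(ds.Columns)) != shape:
            raise ValueError(f"{path}: matrix size differs within the series (Rows/Columns)")
        ps = _require(ds, "PixelSpacing", str(path))
        if not np.allclose([float(v) for v in ps], [float(v) for v in spacing]):
            raise ValueError(f"{path}: PixelSpacing differs within the series")
        orient = _require(ds, "ImageOrientationPatient", str(path))
        if not np.allclose([float(v) for v in orient], _AXIAL_ORIENTATION, atol=1e-4):
            raise ValueError(f"{path}: non-axial ImageOrientationPatient")
        ipp = _require(ds, "ImagePositionPatient", str(path))
        slope = getattr(ds, "RescaleSlope", None)
        intercept = getattr(ds, "RescaleIntercept", None)
        if slope is None or intercept is None:
            raise ValueError(f"{path}: missing RescaleSlope/RescaleIntercept")
        hu = ds.pixel_array.astype(np.float64) * float(slope) + float(intercept)
        records.append((float(ipp[2]), (float(ipp[0]), float(ipp[1])), hu, ds))

    records.sort(key=lambda r: r[0])
    z = np.array([r[0] for r in records])
    if len(z) > 1 and np.any(np.diff(z) <= 0):
        raise ValueError(f"{directory}: duplicate ImagePositionPatient z values")
    first_ds = records[0][3]
    thickness = float(getattr(first_ds, "SliceThickness", 0.0) or 0.0)
    if thickness <= 0 and len(z) > 1:
        thickness = float(np.median(np.diff(z)))
    if thickness <= 0:
        raise ValueError(f"{directory}: missing SliceThickness")
    date = getattr(first_ds, "AcquisitionDate", "") or ""
    if len(date) == 8:
        date = f"{date[:4]}-{date[4:6]}-{date[6:]}"
    return PhantomImageSeries(
        hu=np.stack([r[2] for r in records]),
        pixel_spacing=(float(spacing[0]), float(spacing[1])),
        slice_thickness=thickness,
        z_positions=z,
        modality=getattr(first_ds, "ImageComments", "") or "CT",
        protocol=getattr(first_ds, "SeriesDescription", "") or "",
        machine=getattr(first_ds, "StationName", "") or "",
        acquisition_date=date,
        origin=records[0][1],
    )


def write_series(series: PhantomImageSeries, directory_path) -> list[Path]:
    """Write one DICOM CT file per slice such that read_series inverts it.

    HU values are stored as signed 16-bit with slope 1 / intercept 0,
    which is lossless for integral HU in [-32768, 32767]; non-integral
    HU is rounded to the nearest unit (scanner exports are integral).
    """
    directory = Path(directory_path)
    directory.mkdir(parents=True, exist_ok=True)
    study_uid = generate_uid()
    series_uid = generate_uid()
    frame_uid = generate_uid()
    date = (series.acquisition_date or "").replace("-", "") or _dt.date.today().strftime(
        "%Y%m%d"
    )
    paths = []
    for i in range(series.n_slices):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = _CT_STORAGE
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian

        ds = Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = _CT_STORAGE
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.Modality = "CT"
        ds.ImageComments = series.modality
        ds.SeriesDescription = series.protocol
        ds.StationName = series.machine
        ds.PatientName = "QA^Phantom"
        ds.PatientID = "ACR464"
        ds.AcquisitionDate = date
        ds.ContentDate = date
        ds.InstanceNumber = i + 1
        ds.ImageOrientationPatient = list(_AXIAL_ORIENTATION)
        ds.ImagePositionPatient = [
            float(series.origin[0]),
            float(series.origin[1]),
            float(series.z_positions[i]),
        ]
        ds.SliceThickness = float(series.slice_thickness)
        ds.PixelSpacing = [float(series.pixel_spacing[0]), float(series.pixel_spacing[1])]
        ds.Rows, ds.Columns = series.hu.shape[1:]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = 1
        ds.RescaleIntercept = 0
        stored = np.clip(np.rint(series.hu[i]), -32768, 32767).astype(np.int16)
        ds.PixelData = stored.tobytes()
        path = directory / f"slice_{i:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths
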