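"""Reading and writing axial CT series in DICOM, with Hounsfield conversion.

A CT series is one directory of single-slice DICOM files. Stored pixel
values relate to radiodensity through the per-slice rescale affine
``HU = slope * stored + intercept``; scanners conventionally store air at
-1024 with slope 1. Slice geometry (ImagePositionPatient, PixelSpacing,
SliceThickness) is repaired where possible: a missing thickness is inferred
from the median inter-slice position step.

Axis convention throughout the package: arrays are indexed ``(z, y, x)``
with ``z`` the slice-stacking axis, and spacings are quoted in the same
order, so a femur voxel of shape 112x128x128 has 112 slices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

__all__ = [
    "SliceStack",
    "CTVolume",
    "DicomIOError",
    "NoSeriesError",
    "MixedSeriesError",
    "DegenerateGeometryError",
    "InvalidRescaleError",
    "read_series",
    "to_hounsfield",
    "write_series",
]

DEFAULT_RESCALE_SLOPE = 1.0
DEFAULT_RESCALE_INTERCEPT = -1024.0
#: maximum relative deviation of inter-slice steps from their median
MAX_SPACING_DEVIATION = 0.05


class DicomIOError(Exception):
    """Base class for CT series I/O failures."""


class NoSeriesError(DicomIOError):
    """Directory holds no readable series (or fewer than two slices)."""


class MixedSeriesError(DicomIOError):
    """Directory mixes slices from more than one SeriesInstanceUID."""


class DegenerateGeometryError(DicomIOError):
    """Slice positions are duplicated, non-monotone or grossly non-uniform."""


class InvalidRescaleError(DicomIOError):
    """Rescale slope of zero: the stored-value affine is not invertible."""


@dataclass
class SliceStack:
    """A sorted stack of co-registered axial slices, still in stored values.

    ``pixels`` has shape ``(n_slices, rows, cols)``; ``positions`` holds the
    ImagePositionPatient of each slice (mm); ``pixel_spacing`` is the
    in-plane (row, col) spacing in mm.
    """

    pixels: np.ndarray
    positions: np.ndarray
    pixel_spacing: tuple[float, float]
    slope: float
    intercept: float
    slice_thickness: float
    series_uid: str = ""

    @property
    def n_slices(self) -> int:
        return self.pixels.shape[0]


@dataclass
class CTVolume:
    """A rank-3 scalar grid in Hounsfield units with physical geometry.

    ``spacing`` and ``origin`` are (z, y, x) in mm.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError("CT volume must be a rank-3 grid with nonempty axes")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("CT volume spacing components must be strictly positive")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


def _read_datasets(directory: Path) -> list[pydicom.Dataset]:
    datasets = []
    for path in sorted(directory.iterdir()):
        if not path.is_file():
            continue
        try:
            datasets.append(pydicom.dcmread(path))
        except Exception:  # not a DICOM file; tolerated, like stray sidecars
            continue
    return datasets


def read_series(directory: str | Path) -> SliceStack:
    """Read one axial CT series from ``directory`` and sort it spatially.

    Slices are ordered by position along the stacking axis. A missing
    SliceThickness is repaired as the median inter-slice position step.

    Raises
    ------
    NoSeriesError
        Empty directory, or fewer than two readable slices.
    MixedSeriesError
        Slices from more than one series.
    DegenerateGeometryError
        Duplicate slice positions or non-uniform spacing beyond 5%.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise NoSeriesError(f"no series: {directory} is not a directory")
    datasets = _read_datasets(directory)
    if len(datasets) < 2:
        raise NoSeriesError(f"no series: found {len(datasets)} readable slices in {directory}")

    uids = {str(getattr(ds, "SeriesInstanceUID", "")) for ds in datasets}
    if len(uids) > 1:
        raise MixedSeriesError(f"mixed series: {sorted(uids)}")

    shapes = {(int(ds.Rows), int(ds.Columns)) for ds in datasets}
    if len(shapes) > 1:
        raise DicomIOError(f"heterogeneous in-plane shapes: {sorted(shapes)}")

    positions = np.array(
        [[float(v) for v in ds.ImagePositionPatient] for ds in datasets], dtype=float
    )
    order = np.argsort(positions[:, 2], kind="stable")
    datasets = [datasets[i] for i in order]
    positions = positions[order]

    z = positions[:, 2]
    steps = np.diff(z)
    if np.any(steps <= 0):
        raise DegenerateGeometryError("degenerate geometry: duplicate or non-monotone slice positions")
    median_step = float(np.median(steps))
    if np.max(np.abs(steps - median_step)) > MAX_SPACING_DEVIATION * median_step:
        raise DegenerateGeometryError(
            f"degenerate geometry: slice spacing varies more than "
            f"{MAX_SPACING_DEVIATION:.0%} around the median of {median_step:g} mm"
        )

    first = datasets[0]
    thickness = getattr(first, "SliceThickness", None)
    if thickness is None or float(thickness) <= 0:
        thickness = median_step

    slope = getattr(first, "RescaleSlope", None)
    intercept = getattr(first, "RescaleIntercept", None)
    if slope is None or intercept is None:
        warnings.warn(
            "rescale tags missing; assuming CT convention slope=1, intercept=-1024",
            stacklevel=2,
        )
        slope = DEFAULT_RESCALE_SLOPE if slope is None else slope
        intercept = DEFAULT_RESCALE_INTERCEPT if intercept is None else intercept

    pixel_spacing = tuple(float(v) for v in first.PixelSpacing)
    pixels = np.stack([ds.pixel_array for ds in datasets])
    return SliceStack(
        pixels=pixels,
        positions=positions,
        pixel_spacing=pixel_spacing,  # type: ignore[arg-type]
        slope=float(slope),
        intercept=float(intercept),
        slice_thickness=float(thickness),
        series_uid=uids.pop(),
    )


def to_hounsfield(stack: SliceStack) -> CTVolume:
    """Apply the rescale affine ``HU = slope * stored + intercept``.

    The resulting volume carries spacing (slice thickness, row spacing,
    col spacing) and the position of the first slice as its origin.
    """
    if stack.slope == 0:
        raise InvalidRescaleError("invalid rescale: slope must be nonzero")
    values = stack.slope * stack.pixels.astype(np.float32) + stack.intercept
    x0, y0, z0 = stack.positions[0]
    return CTVolume(
        values=values.astype(np.float32),
        spacing=(stack.slice_thickness, stack.pixel_spacing[0], stack.pixel_spacing[1]),
        origin=(float(z0), float(y0), float(x0)),
    )


def write_series(
    volume: CTVolume,
    directory: str | Path,
    subject_id: str | None = None,
    slope: float = DEFAULT_RESCALE_SLOPE,
    intercept: float = DEFAULT_RESCALE_INTERCEPT,
) -> list[Path]:
    """Write ``volume`` as one DICOM file per axial slice; return the paths.

    HU values are quantized through the inverse rescale affine into signed
    16-bit stored values, so a read-back reproduces HU within ``|slope|``.
    Out-of-range HU are clipped with a warning.
    """
    if slope == 0:
        raise InvalidRescaleError("invalid rescale: slope must be nonzero")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    subject_id = subject_id or volume.subject_id or "anon"

    stored = np.rint((volume.values.astype(np.float64) - intercept) / slope)
    if stored.min() < -32768 or stored.max() > 32767:
        warnings.warn("HU out of signed 16-bit stored range; clipping", stacklevel=2)
        stored = np.clip(stored, -32768, 32767)
    stored = stored.astype(np.int16)

    series_uid = generate_uid()
    study_uid = generate_uid()
    dz, dy, dx = volume.spacing
    z0, y0, x0 = volume.origin
    paths: list[Path] = []
    for k in range(volume.shape[0]):
        ds = Dataset()
        ds.file_meta = FileMetaDataset()
        ds.file_meta.MediaStorageSOPClassUID = CTImageStorage
        ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
        ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.Modality = "CT"
        ds.PatientID = subject_id
        ds.InstanceNumber = k + 1
        ds.Rows, ds.Columns = stored.shape[1:]
        ds.PixelSpacing = [f"{dy:g}", f"{dx:g}"]
        ds.SliceThickness = f"{dz:g}"
        ds.ImagePositionPatient = [f"{x0:g}", f"{y0:g}", f"{z0 + k * dz:.6f}"]
        ds.ImageOrientationPatient = ["1", "0", "0", "0", "1", "0"]
        ds.RescaleSlope = f"{slope:g}"
        ds.RescaleIntercept = f"{intercept:g}"
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed
        ds.PixelData = stored[k].tobytes()
        path = directory / f"slice_{k:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths
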