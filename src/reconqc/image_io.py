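"""DICOM series reading, AI/standard slice pairing, and ROI extraction.

A monitored exam consists of two single-frame DICOM series acquired
consecutively at matched table positions: the AI-based reconstruction and
the standard reconstruction.  This module loads each series, matches slices
across arms by out-of-plane position, and crops the central region of
interest on which every metric is computed.
"""

from __future__ import annotations

import os
from datetime import datetime
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, MRImageStorage, generate_uid

from .errors import PairingError, ValidationError
from .types import Arm, ImageSlice, RoiSpec, SeriesPair

DEFAULT_PAIRING_TOL_MM = 0.5


def _slice_position(ds: Dataset) -> float:
    """Out-of-plane coordinate of a single-frame dataset.

    Prefers the third component of ImagePositionPatient; falls back to
    SliceLocation, then InstanceNumber.
    """
    ipp = getattr(ds, "ImagePositionPatient", None)
    if ipp is not None and len(ipp) == 3:
        return float(ipp[2])
    loc = getattr(ds, "SliceLocation", None)
    if loc is not None:
        return float(loc)
    inst = getattr(ds, "InstanceNumber", None)
    if inst is not None:
        return float(inst)
    raise ValidationError("dataset carries no slice position information")


def _acquired_at(ds: Dataset) -> datetime | None:
    date = getattr(ds, "AcquisitionDate", "") or getattr(ds, "StudyDate", "")
    time = getattr(ds, "AcquisitionTime", "") or getattr(ds, "StudyTime", "")
    if not date:
        return None
    time = (str(time).split(".")[0] or "000000").ljust(6, "0")
    try:
        return datetime.strptime(str(date) + time, "%Y%m%d%H%M%S")
    except ValueError:
        return None


def load_series(
    directory_path: str | os.PathLike,
    arm_mapping: dict[str, Arm | str] | None = None,
    default_arm: Arm | str | None = None,
) -> list[ImageSlice]:
    """Load one single-frame DICOM series from a directory.

    Parameters
    ----------
    directory_path
        Directory holding the files of exactly one series.
    arm_mapping
        SeriesDescription -> arm.  Which series description denotes the
        AI-based arm is site-specific, so the caller supplies the mapping
        explicitly rather than the loader guessing.
    default_arm
        Arm to assign when the description is not in the mapping.

    Returns
    -------
    list of ImageSlice sorted ascending by slice position, with any stored
    rescale slope/intercept applied to the pixel data.

    Raises
    ------
    IOError
        If a file cannot be parsed as DICOM; the message names the file.
    ValidationError
        If the directory mixes more than one SeriesInstanceUID.
    """
    directory = Path(directory_path)
    if not directory.is_dir():
        raise IOError(f"not a directory: {directory}")
    files = sorted(p for p in directory.iterdir() if p.is_file())
    if not files:
        raise IOError(f"no files in {directory}")

    arm_mapping = {k: Arm(v) for k, v in (arm_mapping or {}).items()}
    slices: list[ImageSlice] = []
    series_uid: str | None = None
    for path in files:
        try:
            ds = pydicom.dcmread(path)
            pixels = ds.pixel_array.astype(np.float64)
        except Exception as exc:  # noqa: BLE001 - rewrap with the file name
            raise IOError(f"unreadable DICOM file: {path}") from exc
        uid = str(getattr(ds, "SeriesInstanceUID", ""))
        if series_uid is None:
            series_uid = uid
        elif uid != series_uid:
            raise ValidationError(
                f"mixed series in {directory}: {series_uid} vs {uid} ({path.name})"
            )
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        if slope != 1.0 or intercept != 0.0:
            pixels = pixels * slope + intercept
        desc = str(getattr(ds, "SeriesDescription", ""))
        arm = arm_mapping.get(desc, default_arm)
        if arm is None:
            raise ValidationError(
                f"series description {desc!r} not in arm mapping and no default arm"
            )
        slices.append(
            ImageSlice(
                pixels=pixels,
                slice_position_mm=_slice_position(ds),
                exam_id=str(getattr(ds, "StudyID", "") or getattr(ds, "PatientID", "")),
                scanner_id=str(getattr(ds, "StationName", "")),
                arm=Arm(arm),
                acquired_at=_acquired_at(ds),
            )
        )
    slices.sort(key=lambda s: s.slice_position_mm)
    return slices


def write_series(
    slices: list[ImageSlice],
    directory_path: str | os.PathLike,
    series_description: str = "",
) -> list[Path]:
    """Write slices as a minimal valid single-frame MR DICOM series.

    Intended for fixtures and for exporting synthetic cohorts so the DICOM
    reading path is exercised end to end.  Pixel values are stored as
    uint16, so intensities must be integral and within [0, 65535] for an
    exact round trip.
    """
    directory = Path(directory_path)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    study_uid = generate_uid()
    paths = []
    for i, sl in enumerate(slices):
        px = np.round(sl.pixels)
        if np.any(px < 0) or np.any(px > 65535):
            raise ValidationError("pixel values must fit uint16 for DICOM export")
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = MRImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = MRImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "MR"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.SeriesDescription = series_description or sl.arm.value
        ds.PatientID = sl.exam_id
        ds.StudyID = sl.exam_id
        ds.StationName = sl.scanner_id
        ds.InstanceNumber = i + 1
        ds.ImagePositionPatient = [0.0, 0.0, float(sl.slice_position_mm)]
        ds.SliceLocation = float(sl.slice_position_mm)
        if sl.acquired_at is not None:
            ds.AcquisitionDate = sl.acquired_at.strftime("%Y%m%d")
            ds.AcquisitionTime = sl.acquired_at.strftime("%H%M%S")
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.Rows, ds.Columns = px.shape
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.PixelData = px.astype(np.uint16).tobytes()
        path = directory / f"slice_{i:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths


def pair_series(
    ai_slices: list[ImageSlice],
    standard_slices: list[ImageSlice],
    tol_mm: float = DEFAULT_PAIRING_TOL_MM,
) -> SeriesPair:
    """Match AI and standard slices by out-of-plane position.

    Greedy nearest-neighbour matching: candidate (ai, standard) pairs are
    taken in order of increasing position difference, each slice used at
    most once, and a pair is accepted only if the difference is within
    ``tol_mm``.  Unmatched slices are reported on the returned pair, never
    silently dropped.

    Raises
    ------
    ValidationError
        Empty inputs, mismatched exam/scanner identity, or duplicate
        positions within one arm.
    PairingError
        If no pair at all is within tolerance.
    """
    if not ai_slices or not standard_slices:
        raise ValidationError("both arms must contain at least one slice")
    exam_ids = {s.exam_id for s in ai_slices} | {s.exam_id for s in standard_slices}
    scanner_ids = {s.scanner_id for s in ai_slices} | {
        s.scanner_id for s in standard_slices
    }
    if len(exam_ids) != 1 or len(scanner_ids) != 1:
        raise ValidationError(
            f"slices mix exams {exam_ids} or scanners {scanner_ids}"
        )
    for arm_slices, name in ((ai_slices, "ai"), (standard_slices, "standard")):
        pos = [s.slice_position_mm for s in arm_slices]
        if len(pos) != len(set(pos)):
            raise ValidationError(f"duplicate slice positions in {name} arm")

    candidates = sorted(
        (
            (abs(a.slice_position_mm - s.slice_position_mm), i, j)
            for i, a in enumerate(ai_slices)
            for j, s in enumerate(standard_slices)
        ),
        key=lambda t: (t[0], t[1], t[2]),
    )
    used_ai: set[int] = set()
    used_std: set[int] = set()
    matched: list[tuple[ImageSlice, ImageSlice]] = []
    for dist, i, j in candidates:
        if dist > tol_mm:
            break
        if i in used_ai or j in used_std:
            continue
        used_ai.add(i)
        used_std.add(j)
        matched.append((ai_slices[i], standard_slices[j]))
    if not matched:
        raise PairingError(
            f"no slice pairs within {tol_mm} mm for exam {next(iter(exam_ids))}"
        )
    matched.sort(key=lambda p: p[0].slice_position_mm)
    acquired = min(
        (s.acquired_at for s in ai_slices + standard_slices if s.acquired_at),
        default=None,
    )
    return SeriesPair(
        exam_id=next(iter(exam_ids)),
        scanner_id=next(iter(scanner_ids)),
        pairs=matched,
        unmatched_ai=[a for i, a in enumerate(ai_slices) if i not in used_ai],
        unmatched_standard=[
            s for j, s in enumerate(standard_slices) if j not in used_std
        ],
        acquired_at=acquired,
    )


def extract_central_roi(
    image: ImageSlice | np.ndarray, roi: RoiSpec = RoiSpec()
) -> np.ndarray:
    """Centred crop of ``roi.height_px`` x ``roi.width_px`` pixels.

    The top-left offset is floor((dim - roi) / 2) in each dimension, so for
    odd margins the extra pixel falls on the bottom/right.  This convention
    is fixed for bit-reproducibility.
    """
    pixels = image.pixels if isinstance(image, ImageSlice) else np.asarray(image)
    rows, cols = pixels.shape
    if roi.height_px > rows or roi.width_px > cols:
        raise ValidationError(
            f"ROI {roi.height_px}x{roi.width_px} exceeds image {rows}x{cols}"
        )
    r0 = (rows - roi.height_px) // 2
    c0 = (cols - roi.width_px) // 2
    return pixels[r0 : r0 + roi.height_px, c0 : c0 + roi.width_px]
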