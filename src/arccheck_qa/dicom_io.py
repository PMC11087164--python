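"""DICOM serialization: pseudo-CT series, RT Structure Set and RT Dose grids.

Axis mapping is a single convention: the phantom cylinder axis maps to DICOM z
(slice stacking) and the beam-anterior direction to DICOM -y in a
head-first-supine frame, so phantom coordinates ARE patient coordinates.
Internally everything is 0-based and in mm; DICOM tags use 1-based instance
numbering.  Dose is stored as 16-bit unsigned integers with
``DoseGridScaling = max_dose / (2**16 - 1)``.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import (
    CTImageStorage,
    ExplicitVRLittleEndian,
    RTDoseStorage,
    RTStructureSetStorage,
    generate_uid,
)

from .errors import ConfigurationError, FormatError
from .grids import DoseGrid, Grid3D
from .phantom_builder import PseudoCT, StructureSet

__all__ = [
    "write_ct_series",
    "read_ct_series",
    "write_rtstruct",
    "read_rtstruct",
    "write_rtdose",
    "read_rtdose",
]


def _base_dataset(path: Path, sop_class, sop_uid) -> FileDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = sop_uid
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = sop_class
    ds.SOPInstanceUID = sop_uid
    ds.PatientName = "ArcCHECK^Virtual"
    ds.PatientID = "ARCCHECK-QA"
    ds.PatientPosition = "HFS"
    return ds


def write_ct_series(ct: PseudoCT, out_dir: str | os.PathLike) -> dict:
    """Write one CT file per slice; returns series metadata (UIDs, file list).

    Stored pixel values carry the CT numbers directly (RescaleSlope 1,
    RescaleIntercept 0); every slice shares one FrameOfReferenceUID so the
    structure set and dose can reference the same frame.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec, grid = ct.spec, ct.grid
    study_uid, series_uid, frame_uid = generate_uid(), generate_uid(), generate_uid()
    paths, sop_uids = [], []
    pixels = np.asarray(ct.values)
    if pixels.min() < 0:
        raise ConfigurationError("pseudo-CT stored pixels must be non-negative")
    for k, z in enumerate(grid.zs):
        sop_uid = generate_uid()
        path = out / f"CT.{k + 1:03d}.dcm"
        ds = _base_dataset(path, CTImageStorage, sop_uid)
        ds.Modality = "CT"
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.InstanceNumber = k + 1
        ds.ImagePositionPatient = [grid.origin[0], grid.origin[1], float(z)]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [spec.pixel_spacing, spec.pixel_spacing]
        ds.SliceThickness = spec.slice_thickness
        ds.SliceLocation = float(z)
        ds.Rows = spec.matrix
        ds.Columns = spec.matrix
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.RescaleSlope = 1
        ds.RescaleIntercept = 0
        ds.PixelData = pixels[k].astype(np.uint16).tobytes()
        try:
            ds.save_as(str(path), enforce_file_format=True)
        except OSError as exc:  # pragma: no cover - environment dependent
            raise FormatError(f"failed to write CT slice {path}: {exc}") from exc
        paths.append(path)
        sop_uids.append(sop_uid)
    return {
        "paths": paths,
        "sop_uids": sop_uids,
        "series_uid": series_uid,
        "study_uid": study_uid,
        "frame_of_reference_uid": frame_uid,
        "slice_positions": [float(z) for z in grid.zs],
    }


def read_ct_series(ct_dir: str | os.PathLike) -> tuple[Grid3D, np.ndarray, dict]:
    """Read a CT series back into (grid, stored values, metadata)."""
    files = sorted(Path(ct_dir).glob("*.dcm"))
    slices = [pydicom.dcmread(str(f)) for f in files]
    slices = [s for s in slices if getattr(s, "Modality", "") == "CT"]
    if not slices:
        raise FormatError(f"no CT slices found in {ct_dir}")
    slices.sort(key=lambda s: float(s.ImagePositionPatient[2]))
    first = slices[0]
    zs = np.array([float(s.ImagePositionPatient[2]) for s in slices])
    dz = float(np.diff(zs).mean()) if len(zs) > 1 else float(first.SliceThickness)
    grid = Grid3D(
        origin=(
            float(first.ImagePositionPatient[0]),
            float(first.ImagePositionPatient[1]),
            float(zs[0]),
        ),
        spacing=(float(first.PixelSpacing[1]), float(first.PixelSpacing[0]), dz),
        shape=(int(first.Columns), int(first.Rows), len(slices)),
    )
    values = np.stack([s.pixel_array for s in slices]).astype(np.int32)
    meta = {
        "frame_of_reference_uid": str(first.FrameOfReferenceUID),
        "sop_uids": [str(s.SOPInstanceUID) for s in slices],
        "series_uid": str(first.SeriesInstanceUID),
    }
    return grid, values, meta


def write_rtstruct(
    structures: StructureSet,
    ct_meta: dict,
    path: str | os.PathLike,
) -> Path:
    """Write the structure set referencing an existing CT series.

    Each structure becomes one ROI whose contours are closed planar polylines
    attached to the CT slice at their z position; structure names are
    preserved verbatim.
    """
    path = Path(path)
    slice_z = np.asarray(ct_meta["slice_positions"], dtype=float)
    sop_uids = ct_meta["sop_uids"]
    sop_class = CTImageStorage

    ds = _base_dataset(path, RTStructureSetStorage, generate_uid())
    ds.Modality = "RTSTRUCT"
    ds.StudyInstanceUID = ct_meta["study_uid"]
    ds.SeriesInstanceUID = generate_uid()
    ds.StructureSetLabel = "ArcCHECK-MR QA"

    ref_frame = Dataset()
    ref_frame.FrameOfReferenceUID = ct_meta["frame_of_reference_uid"]
    ds.ReferencedFrameOfReferenceSequence = [ref_frame]

    roi_seq, contour_seq, obs_seq = [], [], []
    for number, struct in enumerate(structures.structures, start=1):
        roi = Dataset()
        roi.ROINumber = number
        roi.ROIName = struct.name
        roi.ReferencedFrameOfReferenceUID = ct_meta["frame_of_reference_uid"]
        roi.ROIGenerationAlgorithm = "AUTOMATIC"
        roi_seq.append(roi)

        rc = Dataset()
        rc.ReferencedROINumber = number
        contours = []
        for z, verts in struct.contours:
            hit = np.flatnonzero(np.abs(slice_z - z) < 1e-6)
            if hit.size != 1:
                raise FormatError(
                    f"structure {struct.name}: contour at z={z} has no matching CT slice"
                )
            image = Dataset()
            image.ReferencedSOPClassUID = sop_class
            image.ReferencedSOPInstanceUID = sop_uids[int(hit[0])]
            c = Dataset()
            c.ContourImageSequence = [image]
            c.ContourGeometricType = "CLOSED_PLANAR"
            c.NumberOfContourPoints = len(verts)
            data = np.column_stack([verts, np.full(len(verts), z)])
            c.ContourData = [float(v) for v in data.ravel()]
            contours.append(c)
        rc.ContourSequence = contours
        contour_seq.append(rc)

        obs = Dataset()
        obs.ObservationNumber = number
        obs.ReferencedROINumber = number
        obs.RTROIInterpretedType = ""
        obs.ROIInterpreter = ""
        obs_seq.append(obs)

    ds.StructureSetROISequence = roi_seq
    ds.ROIContourSequence = contour_seq
    ds.RTROIObservationsSequence = obs_seq
    ds.save_as(str(path), enforce_file_format=True)
    return path


def read_rtstruct(path: str | os.PathLike) -> dict[str, list[tuple[float, np.ndarray]]]:
    """Read ROI contours back as {name: [(z, (M, 2) vertices), ...]}."""
    ds = pydicom.dcmread(str(path))
    if getattr(ds, "Modality", "") != "RTSTRUCT":
        raise FormatError(f"{path} is not an RT Structure Set")
    names = {int(r.ROINumber): str(r.ROIName) for r in ds.StructureSetROISequence}
    out: dict[str, list[tuple[float, np.ndarray]]] = {}
    for rc in ds.ROIContourSequence:
        name = names[int(rc.ReferencedROINumber)]
        contours = []
        for c in getattr(rc, "ContourSequence", []):
            data = np.asarray(c.ContourData, dtype=float).reshape(-1, 3)
            contours.append((float(data[0, 2]), data[:, :2]))
        out[name] = contours
    return out


def write_rtdose(dose: DoseGrid, path: str | os.PathLike, frame_uid: str | None = None) -> Path:
    """Write a grid-type RT Dose file (16-bit storage, Gy)."""
    path = Path(path)
    if dose.values.size == 0 or dose.max_dose <= 0:
        raise FormatError("refusing to write an empty/zero dose grid")
    scaling = dose.max_dose / (2**16 - 1)
    stored = np.round(dose.values / scaling).astype(np.uint16)

    ds = _base_dataset(path, RTDoseStorage, generate_uid())
    ds.Modality = "RTDOSE"
    ds.StudyInstanceUID = generate_uid()
    ds.SeriesInstanceUID = generate_uid()
    ds.FrameOfReferenceUID = frame_uid or generate_uid()
    nz, ny, nx = stored.shape
    ds.Rows = ny
    ds.Columns = nx
    ds.NumberOfFrames = nz
    ds.FrameIncrementPointer = pydicom.tag.Tag(0x3004, 0x000C)
    ds.GridFrameOffsetVector = [float(k * dose.grid.spacing[2]) for k in range(nz)]
    ds.ImagePositionPatient = [dose.grid.origin[0], dose.grid.origin[1], dose.grid.origin[2]]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.PixelSpacing = [dose.grid.spacing[1], dose.grid.spacing[0]]  # [row, col]
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.DoseGridScaling = scaling
    ds.PixelData = stored.tobytes()
    ds.save_as(str(path), enforce_file_format=True)
    return path


def read_rtdose(path: str | os.PathLike) -> DoseGrid:
    """Read a grid-type RT Dose file; values = stored integers x DoseGridScaling."""
    ds = pydicom.dcmread(str(path))
    if getattr(ds, "Modality", "") != "RTDOSE":
        raise FormatError(f"{path} is not an RT Dose object")
    if "DoseGridScaling" not in ds:
        raise FormatError(f"{path}: missing DoseGridScaling tag")
    stored = ds.pixel_array
    if stored.ndim == 2:
        stored = stored[None]
    if stored.size == 0:
        raise FormatError(f"{path}: empty dose grid")
    offsets = np.asarray(ds.GridFrameOffsetVector, dtype=float)
    dz = float(np.diff(offsets).mean()) if offsets.size > 1 else 1.0
    grid = Grid3D(
        origin=(
            float(ds.ImagePositionPatient[0]),
            float(ds.ImagePositionPatient[1]),
            float(ds.ImagePositionPatient[2]) + float(offsets[0]),
        ),
        spacing=(float(ds.PixelSpacing[1]), float(ds.PixelSpacing[0]), dz),
        shape=(int(ds.Columns), int(ds.Rows), stored.shape[0]),
    )
    values = stored.astype(np.float64) * float(ds.DoseGridScaling)
    return DoseGrid(grid, values, meta={"frame_of_reference_uid": str(ds.FrameOfReferenceUID)})
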