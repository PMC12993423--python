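"""Reading and writing of the DICOM-RT objects the workflow touches.

Covers RT Dose, RT Structure Set, CT Image series, DICOM Spatial
Registration objects, a plain-text 4x4 matrix dialect (row-major,
whitespace-separated, four lines) and a YAML course manifest that ties a
planning set and per-fraction files together.

All geometry handed to the rest of the package is in the DICOM patient
coordinate system (x right->left, y anterior->posterior, z
inferior->superior), millimetres.  Only axial orientations are accepted;
dose slice order follows the stored grid-offset vector (a descending
vector is normalised to ascending with an explicit warning, never
silently).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pydicom
import yaml
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import (
    CTImageStorage,
    ExplicitVRLittleEndian,
    RTDoseStorage,
    RTStructureSetStorage,
    generate_uid,
)

from .core import (
    DoseGrid,
    FractionRecord,
    ImageGeometry,
    RegistrationMatrix,
    Roi,
    StructureSet,
    TreatmentCourse,
)
from .errors import (
    CourseError,
    EmptyStructureError,
    FormatError,
    NonUniformGridError,
    UnsupportedUnitsError,
)

__all__ = [
    "read_dose",
    "write_dose",
    "read_structure_set",
    "write_structure_set",
    "read_registration",
    "write_registration_text",
    "write_registration_dicom",
    "write_ct_series",
    "load_course",
    "write_manifest",
]

SPATIAL_REGISTRATION_STORAGE = "1.2.840.10008.5.1.4.1.1.66.1"
_SLICE_TOL_MM = 1e-3
_DOSE_SCALING = 1e-3  # Gy per stored integer unit (1 mGy quantum)
_FIXED_DATE = "20260101"  # constant metadata dates keep output byte-stable
_FIXED_TIME = "120000"


def _file_meta(sop_class, sop_instance) -> FileMetaDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = sop_instance
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    return meta


def _base_dataset(sop_class, entropy: list[str], modality: str) -> Dataset:
    sop_instance = generate_uid(entropy_srcs=entropy)
    ds = Dataset()
    ds.file_meta = _file_meta(sop_class, sop_instance)
    ds.SOPClassUID = sop_class
    ds.SOPInstanceUID = sop_instance
    ds.Modality = modality
    ds.PatientName = "PHANTOM^DOSEACCUM"
    ds.PatientID = "PHANTOM"
    ds.StudyInstanceUID = generate_uid(entropy_srcs=entropy + ["study"])
    ds.SeriesInstanceUID = generate_uid(entropy_srcs=entropy + ["series"])
    ds.StudyDate = ds.SeriesDate = _FIXED_DATE
    ds.StudyTime = ds.SeriesTime = _FIXED_TIME
    ds.Manufacturer = "doseaccum"
    return ds


# ---------------------------------------------------------------------------
# RT Dose


def read_dose(path) -> DoseGrid:
    """Read a DICOM RT Dose object into a :class:`DoseGrid` (values in Gy).

    Stored integers are multiplied by the dose-grid scaling factor.  A
    missing scaling factor, non-Gy units or a nonuniform grid-offset vector
    raise; the orientation must be axial.
    """
    ds = pydicom.dcmread(path)
    if getattr(ds, "Modality", "") != "RTDOSE":
        raise FormatError(f"{path}: not an RT Dose object")
    if "DoseGridScaling" not in ds:
        raise FormatError(f"{path}: missing DoseGridScaling")
    units = str(getattr(ds, "DoseUnits", "")).upper()
    if units != "GY":
        raise UnsupportedUnitsError(f"{path}: dose units {units!r}, want GY")

    iop = np.array(ds.ImageOrientationPatient, dtype=float)
    orientation = np.column_stack([iop[:3], iop[3:], np.cross(iop[:3], iop[3:])])
    if not np.allclose(orientation, np.eye(3), atol=1e-3):
        raise FormatError(f"{path}: non-axial dose grid orientation")

    offsets = np.array(ds.GridFrameOffsetVector, dtype=float)
    if len(offsets) < 1:
        raise FormatError(f"{path}: empty GridFrameOffsetVector")
    values = ds.pixel_array.astype(float) * float(ds.DoseGridScaling)
    if values.ndim == 2:
        values = values[None]
    if len(offsets) != values.shape[0]:
        raise FormatError(f"{path}: offset vector length != number of frames")

    if len(offsets) > 1:
        diffs = np.diff(offsets)
        if np.all(diffs < 0):
            warnings.warn(f"{path}: descending grid offsets; normalising to "
                          "ascending slice order", stacklevel=2)
            offsets = offsets[::-1]
            values = values[::-1]
            diffs = np.diff(offsets)
        if np.any(diffs <= 0) or np.ptp(diffs) > _SLICE_TOL_MM:
            raise NonUniformGridError(
                f"{path}: nonuniform grid offsets {ds.GridFrameOffsetVector}")
        dz = float(np.mean(diffs))
    else:
        dz = float(getattr(ds, "SliceThickness", 1.0) or 1.0)

    ipp = np.array(ds.ImagePositionPatient, dtype=float)
    origin = ipp + orientation[:, 2] * offsets[0]
    row_mm, col_mm = (float(v) for v in ds.PixelSpacing)
    geom = ImageGeometry(
        origin=tuple(origin),
        spacing=(col_mm, row_mm, dz),
        dims=(values.shape[2], values.shape[1], values.shape[0]),
        frame_of_reference_id=str(getattr(ds, "FrameOfReferenceUID", "")),
    )
    return DoseGrid(geometry=geom, values=values.transpose(2, 1, 0),
                    dose_units="GY",
                    summation_type=str(getattr(ds, "DoseSummationType", "PLAN")))


def write_dose(dose: DoseGrid, path, *, scaling: float = _DOSE_SCALING,
               entropy: list[str] | None = None) -> None:
    """Write a :class:`DoseGrid` as a DICOM RT Dose object.

    Dose is stored as 32-bit unsigned integers at ``scaling`` Gy per unit
    (default 1 mGy), so a write/read round trip is exact to one quantum.
    """
    g = dose.geometry
    entropy = entropy or [g.frame_of_reference_id, "rtdose"]
    ds = _base_dataset(RTDoseStorage, entropy, "RTDOSE")
    ds.FrameOfReferenceUID = g.frame_of_reference_id or generate_uid(
        entropy_srcs=entropy + ["for"])
    nx, ny, nz = g.dims
    ds.Rows, ds.Columns, ds.NumberOfFrames = ny, nx, nz
    ds.PixelSpacing = [f"{g.spacing[1]:.6f}", f"{g.spacing[0]:.6f}"]
    ds.ImagePositionPatient = [f"{v:.6f}" for v in g.origin]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.GridFrameOffsetVector = [f"{i * g.spacing[2]:.6f}" for i in range(nz)]
    ds.SliceThickness = f"{g.spacing[2]:.6f}"
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = dose.summation_type
    ds.DoseGridScaling = f"{scaling:.10g}"
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    stored = np.round(dose.values.transpose(2, 1, 0) / scaling)
    if stored.max() > np.iinfo(np.uint32).max:
        raise FormatError("dose exceeds 32-bit storage at this scaling")
    ds.PixelData = np.ascontiguousarray(stored.astype(np.uint32)).tobytes()
    ds.save_as(path, enforce_file_format=True)


# ---------------------------------------------------------------------------
# RT Structure Set


def read_structure_set(path) -> StructureSet:
    """Read a DICOM RT Structure Set into named planar-contour ROIs.

    Non-CLOSED_PLANAR contour items are skipped and contours with fewer
    than three points dropped, each with a warning; a set with zero usable
    ROIs raises.
    """
    ds = pydicom.dcmread(path)
    if getattr(ds, "Modality", "") != "RTSTRUCT":
        raise FormatError(f"{path}: not an RT Structure Set")
    names = {}
    colors_default = (255, 0, 0)
    for item in getattr(ds, "StructureSetROISequence", []):
        names[int(item.ROINumber)] = str(item.ROIName)

    frame_id = ""
    for item in getattr(ds, "StructureSetROISequence", []):
        frame_id = str(getattr(item, "ReferencedFrameOfReferenceUID", "")) or frame_id
    if not frame_id:
        for item in getattr(ds, "ReferencedFrameOfReferenceSequence", []):
            frame_id = str(getattr(item, "FrameOfReferenceUID", "")) or frame_id

    rois: dict[str, Roi] = {}
    n_dropped = 0
    n_skipped = 0
    for rc in getattr(ds, "ROIContourSequence", []):
        number = int(rc.ReferencedROINumber)
        name = names.get(number, f"ROI_{number}")
        color = tuple(int(c) for c in getattr(rc, "ROIDisplayColor",
                                              colors_default))
        per_z: dict[float, list[np.ndarray]] = {}
        for c in getattr(rc, "ContourSequence", []):
            gtype = str(getattr(c, "ContourGeometricType", "CLOSED_PLANAR"))
            if gtype != "CLOSED_PLANAR":
                n_skipped += 1
                continue
            data = np.array(c.ContourData, dtype=float).reshape(-1, 3)
            if len(data) < 3:
                n_dropped += 1
                continue
            z = float(np.mean(data[:, 2]))
            per_z.setdefault(round(z, 3), []).append(data[:, :2])
        slices = [(z, polys) for z, polys in per_z.items()]
        roi = Roi(name=name, slices=slices, color=color)
        if not roi.is_empty:
            rois[name] = roi
    if n_skipped:
        warnings.warn(f"{path}: skipped {n_skipped} non-CLOSED_PLANAR "
                      "contour item(s)", stacklevel=2)
    if n_dropped:
        warnings.warn(f"{path}: dropped {n_dropped} degenerate contour(s) "
                      "with < 3 points", stacklevel=2)
    if not rois:
        raise EmptyStructureError(f"{path}: no usable ROIs")
    return StructureSet(rois=rois, frame_of_reference_id=frame_id,
                        source_image_id=str(getattr(ds, "SeriesInstanceUID", "")))


def write_structure_set(ss: StructureSet, path, *,
                        entropy: list[str] | None = None) -> None:
    """Write a :class:`StructureSet` as a DICOM RT Structure Set.

    Vertex coordinates are written with 3 decimals (micrometre precision),
    the round-trip tolerance of the readers.
    """
    entropy = entropy or [ss.frame_of_reference_id, "rtstruct",
                          ",".join(sorted(ss.rois))]
    ds = _base_dataset(RTStructureSetStorage, entropy, "RTSTRUCT")
    ds.StructureSetLabel = "doseaccum"
    ds.StructureSetDate = _FIXED_DATE
    ds.StructureSetTime = _FIXED_TIME

    ref_frame = Dataset()
    ref_frame.FrameOfReferenceUID = ss.frame_of_reference_id
    ds.ReferencedFrameOfReferenceSequence = [ref_frame]

    ssroi_seq = []
    contour_seq = []
    for i, (name, roi) in enumerate(ss.rois.items(), start=1):
        ssroi = Dataset()
        ssroi.ROINumber = i
        ssroi.ReferencedFrameOfReferenceUID = ss.frame_of_reference_id
        ssroi.ROIName = name
        ssroi.ROIGenerationAlgorithm = "AUTOMATIC"
        ssroi_seq.append(ssroi)

        rc = Dataset()
        rc.ReferencedROINumber = i
        rc.ROIDisplayColor = list(roi.color)
        items = []
        for z, polys in roi.slices:
            for poly in polys:
                c = Dataset()
                c.ContourGeometricType = "CLOSED_PLANAR"
                c.NumberOfContourPoints = len(poly)
                flat = []
                for x, y in poly:
                    flat.extend([f"{x:.3f}", f"{y:.3f}", f"{z:.3f}"])
                c.ContourData = flat
                items.append(c)
        rc.ContourSequence = items
        contour_seq.append(rc)
    ds.StructureSetROISequence = ssroi_seq
    ds.ROIContourSequence = contour_seq
    ds.save_as(path, enforce_file_format=True)


# ---------------------------------------------------------------------------
# Registration matrices


def read_registration(path) -> RegistrationMatrix:
    """Read a rigid 4x4 registration from a DICOM Spatial Registration
    object or from the plain-text dialect (four whitespace-separated rows).

    Rigidity of the upper-left 3x3 block is enforced at tolerance 1e-4;
    the text dialect carries no frame identifiers (both empty).
    """
    path = Path(path)
    try:
        ds = pydicom.dcmread(path)
        is_dicom = True
    except Exception:
        is_dicom = False
    if not is_dicom:
        m = np.loadtxt(path, dtype=float)
        if m.shape != (4, 4):
            raise FormatError(f"{path}: text matrix shape {m.shape}, want 4x4")
        return RegistrationMatrix(m)

    fixed = str(getattr(ds, "FrameOfReferenceUID", ""))
    moving = ""
    matrix = None
    for item in getattr(ds, "RegistrationSequence", []):
        item_frame = str(getattr(item, "FrameOfReferenceUID", ""))
        for mr in getattr(item, "MatrixRegistrationSequence", []):
            for mi in getattr(mr, "MatrixSequence", []):
                m = np.array(mi.FrameOfReferenceTransformationMatrix,
                             dtype=float).reshape(4, 4)
                if item_frame == fixed and np.allclose(m, np.eye(4)):
                    continue  # the fixed frame's identity entry
                matrix = m
                moving = item_frame
    if matrix is None:
        raise FormatError(f"{path}: no transformation matrix found")
    return RegistrationMatrix(matrix, moving_frame_id=moving,
                              fixed_frame_id=fixed)


def write_registration_text(reg: RegistrationMatrix, path) -> None:
    """Write the 4x4 matrix in the row-major plain-text dialect."""
    with open(path, "w") as fh:
        for row in reg.matrix:
            fh.write(" ".join(f"{v:.9g}" for v in row) + "\n")


def write_registration_dicom(reg: RegistrationMatrix, path, *,
                             entropy: list[str] | None = None) -> None:
    """Write a DICOM Spatial Registration object (moving -> fixed)."""
    entropy = entropy or [reg.fixed_frame_id, reg.moving_frame_id, "reg"]
    ds = _base_dataset(SPATIAL_REGISTRATION_STORAGE, entropy, "REG")
    ds.FrameOfReferenceUID = reg.fixed_frame_id
    ds.ContentDate = _FIXED_DATE
    ds.ContentTime = _FIXED_TIME

    def _reg_item(frame_uid, matrix):
        mi = Dataset()
        mi.FrameOfReferenceTransformationMatrixType = "RIGID"
        mi.FrameOfReferenceTransformationMatrix = [
            f"{v:.10g}" for v in np.asarray(matrix).ravel()]
        mr = Dataset()
        mr.MatrixSequence = [mi]
        item = Dataset()
        item.FrameOfReferenceUID = frame_uid
        item.MatrixRegistrationSequence = [mr]
        return item

    ds.RegistrationSequence = [
        _reg_item(reg.fixed_frame_id, np.eye(4)),
        _reg_item(reg.moving_frame_id, reg.matrix),
    ]
    ds.save_as(path, enforce_file_format=True)


# ---------------------------------------------------------------------------
# CT image series


def write_ct_series(geometry: ImageGeometry, hu: np.ndarray, out_dir, *,
                    entropy: list[str] | None = None) -> list[Path]:
    """Write an axial CT series, one file per slice (HU int16).

    The CT voxel data are not consumed by the dose pipeline; the series
    completes the on-disk course layout.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entropy = entropy or [geometry.frame_of_reference_id, "ct"]
    nx, ny, nz = geometry.dims
    series_uid = generate_uid(entropy_srcs=entropy + ["series"])
    study_uid = generate_uid(entropy_srcs=entropy + ["study"])
    paths = []
    for iz in range(nz):
        ds = _base_dataset(CTImageStorage, entropy + [f"slice{iz}"], "CT")
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.FrameOfReferenceUID = geometry.frame_of_reference_id
        ds.Rows, ds.Columns = ny, nx
        ds.PixelSpacing = [f"{geometry.spacing[1]:.6f}",
                           f"{geometry.spacing[0]:.6f}"]
        z = geometry.origin[2] + iz * geometry.spacing[2]
        ds.ImagePositionPatient = [f"{geometry.origin[0]:.6f}",
                                   f"{geometry.origin[1]:.6f}", f"{z:.6f}"]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.SliceThickness = f"{geometry.spacing[2]:.6f}"
        ds.InstanceNumber = iz + 1
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.RescaleSlope = "1"
        ds.RescaleIntercept = "0"
        ds.PixelData = np.ascontiguousarray(
            hu[:, :, iz].T.astype(np.int16)).tobytes()
        p = out_dir / f"ct_{iz + 1:03d}.dcm"
        ds.save_as(p, enforce_file_format=True)
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# Course manifest


def write_manifest(path, *, plan_structures: str, plan_dose: str,
                   fractions: list[dict], n_fractions_planned: int,
                   matrix_maps: str = "moving_to_fixed",
                   ct_dir: str | None = None) -> None:
    """Write the YAML manifest naming every file of a course.

    ``fractions`` items carry ``index``, ``structures``, ``registration``
    and optional ``label``; paths are relative to the manifest directory.
    ``matrix_maps`` records the direction of the stored matrices
    (``moving_to_fixed`` maps daily coordinates into the planning frame).
    """
    doc = {
        "plan": {"structures": plan_structures, "dose": plan_dose},
        "n_fractions_planned": int(n_fractions_planned),
        "matrix_maps": matrix_maps,
        "fractions": fractions,
    }
    if ct_dir:
        doc["plan"]["ct_dir"] = ct_dir
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_course(manifest_path) -> TreatmentCourse:
    """Assemble a validated :class:`TreatmentCourse` from a YAML manifest.

    Missing files are collected and reported in one aggregate error;
    duplicate fraction indices raise; fractions are returned sorted by
    index.  If the manifest declares ``matrix_maps: fixed_to_moving`` the
    matrices are inverted on load, so downstream code always applies them
    moving (daily) -> fixed (planning).
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        doc = yaml.safe_load(fh)
    base = manifest_path.parent

    direction = str(doc.get("matrix_maps", "moving_to_fixed"))
    if direction not in ("moving_to_fixed", "fixed_to_moving"):
        raise CourseError(f"unknown matrix_maps value {direction!r}")

    missing = []
    for key in ("structures", "dose"):
        if not (base / doc["plan"][key]).exists():
            missing.append(str(doc["plan"][key]))
    frac_entries = doc.get("fractions", [])
    for entry in frac_entries:
        for key in ("structures", "registration"):
            if not (base / entry[key]).exists():
                missing.append(str(entry[key]))
    if missing:
        raise CourseError("missing course files: " + ", ".join(missing))

    indices = [int(e["index"]) for e in frac_entries]
    if len(set(indices)) != len(indices):
        dupes = sorted({i for i in indices if indices.count(i) > 1})
        raise CourseError(f"duplicate fraction index(es) {dupes}")

    plan_ss = read_structure_set(base / doc["plan"]["structures"])
    plan_dose = read_dose(base / doc["plan"]["dose"])

    fractions = []
    for entry in frac_entries:
        reg = read_registration(base / entry["registration"])
        if direction == "fixed_to_moving":
            reg = reg.inverse()
        fractions.append(FractionRecord(
            index=int(entry["index"]),
            structure_set=read_structure_set(base / entry["structures"]),
            registration=reg,
            acquisition_label=str(entry.get("label", f"fx{entry['index']:03d}")),
        ))
    return TreatmentCourse(
        planning_structures=plan_ss,
        plan_dose=plan_dose,
        fractions=fractions,
        n_fractions_planned=int(doc.get("n_fractions_planned",
                                        len(fractions))),
    )
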