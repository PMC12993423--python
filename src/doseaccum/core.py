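"""Internal data model: image geometry, dose grids, contoured structures,
rigid registrations and treatment courses.

Coordinate convention
---------------------
Everything outside the DICOM readers/writers lives in the DICOM patient
coordinate system: x runs right->left, y anterior->posterior, z
inferior->superior, all in millimetres.  Dose arrays are indexed ``[ix, iy,
iz]`` so that axis order matches the (x, y, z) coordinate order; conversion
to the DICOM on-disk frame/row/column layout happens only at I/O time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, FrameMismatchError, RigidityError

__all__ = [
    "ImageGeometry",
    "DoseGrid",
    "Roi",
    "StructureSet",
    "RegistrationMatrix",
    "FractionRecord",
    "TreatmentCourse",
    "polygon_area",
]

_AXIAL_TOL = 1e-3


def polygon_area(poly: np.ndarray) -> float:
    """Unsigned area (mm^2) of a closed 2-D polygon via the shoelace formula.

    The polygon is treated as closed: the first vertex follows the last.
    """
    p = np.asarray(poly, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


@dataclass(frozen=True)
class ImageGeometry:
    """Placement of a regular 3-D grid in the patient coordinate system.

    ``origin`` is the centre of voxel (0, 0, 0) in mm; ``spacing`` is mm per
    voxel along (x, y, z); ``orientation`` maps voxel-index axes to patient
    axes (identity for axial grids).
    """

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    dims: tuple[int, int, int]
    orientation: np.ndarray = field(
        default_factory=lambda: np.eye(3))
    frame_of_reference_id: str = ""

    def __post_init__(self):
        if any(s <= 0 for s in self.spacing):
            raise ConfigError(f"non-positive spacing {self.spacing}")
        if any(d < 1 for d in self.dims):
            raise ConfigError(f"invalid dims {self.dims}")
        o = np.asarray(self.orientation, dtype=float)
        if not np.allclose(o @ o.T, np.eye(3), atol=1e-6):
            raise ConfigError("orientation matrix is not orthonormal")
        object.__setattr__(self, "orientation", o)
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "spacing", tuple(float(v) for v in self.spacing))
        object.__setattr__(self, "dims", tuple(int(v) for v in self.dims))

    @property
    def is_axial(self) -> bool:
        return bool(np.allclose(self.orientation, np.eye(3), atol=_AXIAL_TOL))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        """Patient-space coordinates of voxel centres along one axis (axial)."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.dims[axis])

    def extent(self) -> tuple[np.ndarray, np.ndarray]:
        """(lo, hi) patient coordinates of the first/last voxel centres."""
        lo = np.asarray(self.origin, dtype=float)
        hi = lo + (np.asarray(self.dims) - 1) * np.asarray(self.spacing)
        return lo, hi


@dataclass
class DoseGrid:
    """A 3-D absorbed-dose distribution in Gy on a placed grid."""

    geometry: ImageGeometry
    values: np.ndarray  # shape = geometry.dims, Gy
    dose_units: str = "GY"
    summation_type: str = "PLAN"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != tuple(self.geometry.dims):
            raise ConfigError(
                f"dose array shape {self.values.shape} != dims {self.geometry.dims}")
        if np.any(self.values < 0):
            raise ConfigError("negative dose values")
        if self.dose_units.upper() != "GY":
            raise ConfigError(f"unsupported dose units {self.dose_units!r}")


@dataclass
class Roi:
    """One contoured structure: a stack of closed planar polygons.

    ``slices`` maps slice position to in-plane polygons: a list of
    ``(z_mm, [poly, ...])`` where each ``poly`` is an (n>=3, 2) array of
    (x, y) vertices in mm.  Polygons are closed implicitly (first vertex
    follows the last).  Nested polygons on one slice create holes via the
    even-odd rule at rasterization time.
    """

    name: str
    slices: list[tuple[float, list[np.ndarray]]]
    color: tuple[int, int, int] = (255, 0, 0)

    def __post_init__(self):
        cleaned = []
        for z, polys in self.slices:
            kept = [np.asarray(p, dtype=float).reshape(-1, 2)
                    for p in polys
                    if len(p) >= 3 and polygon_area(np.asarray(p)) > 0]
            if kept:
                cleaned.append((float(z), kept))
        cleaned.sort(key=lambda t: t[0])
        self.slices = cleaned

    @property
    def is_empty(self) -> bool:
        return not self.slices

    @property
    def n_polygons(self) -> int:
        return sum(len(p) for _, p in self.slices)

    def plane_zs(self) -> np.ndarray:
        return np.array([z for z, _ in self.slices], dtype=float)

    def plane_spacing(self) -> float:
        """Median spacing between consecutive contour planes (mm).

        Falls back to 0 for single-plane ROIs; callers substitute the grid
        spacing in that case.
        """
        zs = self.plane_zs()
        if len(zs) < 2:
            return 0.0
        return float(np.median(np.diff(zs)))

    def all_vertices(self) -> np.ndarray:
        """All vertices as an (n, 3) array of (x, y, z) mm."""
        out = []
        for z, polys in self.slices:
            for p in polys:
                out.append(np.column_stack([p, np.full(len(p), z)]))
        if not out:
            return np.empty((0, 3))
        return np.vstack(out)


@dataclass
class StructureSet:
    """Named ROIs sharing a frame of reference."""

    rois: dict[str, Roi]
    frame_of_reference_id: str = ""
    source_image_id: str = ""

    def __post_init__(self):
        lowered = [n.lower() for n in self.rois]
        if len(set(lowered)) != len(lowered):
            raise ConfigError("ROI names are not unique (case-insensitive)")

    def get(self, name: str) -> Roi:
        for key, roi in self.rois.items():
            if key.lower() == name.lower():
                return roi
        from .errors import LookupError_
        raise LookupError_(
            f"structure {name!r} not found; available: {sorted(self.rois)}")

    def __contains__(self, name: str) -> bool:
        return any(key.lower() == name.lower() for key in self.rois)


@dataclass(frozen=True)
class RegistrationMatrix:
    """4x4 homogeneous rigid transform, moving-frame -> fixed-frame, mm."""

    matrix: np.ndarray
    moving_frame_id: str = ""
    fixed_frame_id: str = ""
    rigidity_tol: float = 1e-4

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ConfigError(f"registration matrix shape {m.shape}, want 4x4")
        if not np.allclose(m[3], [0, 0, 0, 1], atol=1e-9):
            raise RigidityError(f"last row {m[3]} != (0,0,0,1)")
        r = m[:3, :3]
        if not np.allclose(r @ r.T, np.eye(3), atol=self.rigidity_tol):
            raise RigidityError(
                "upper-left 3x3 block is not orthogonal within "
                f"{self.rigidity_tol:g} (not a rigid transform)")
        object.__setattr__(self, "matrix", m)

    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    @property
    def is_pure_translation(self) -> bool:
        return bool(np.allclose(self.rotation, np.eye(3), atol=1e-6))

    def inverse(self) -> "RegistrationMatrix":
        inv = np.eye(4)
        inv[:3, :3] = self.rotation.T
        inv[:3, 3] = -self.rotation.T @ self.translation
        return RegistrationMatrix(inv, moving_frame_id=self.fixed_frame_id,
                                  fixed_frame_id=self.moving_frame_id)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (n, 3) points from the moving to the fixed frame."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    @staticmethod
    def identity(frame_id: str = "") -> "RegistrationMatrix":
        return RegistrationMatrix(np.eye(4), moving_frame_id=frame_id,
                                  fixed_frame_id=frame_id)

    @staticmethod
    def from_translation(t, moving_frame_id: str = "",
                         fixed_frame_id: str = "") -> "RegistrationMatrix":
        m = np.eye(4)
        m[:3, 3] = np.asarray(t, dtype=float)
        return RegistrationMatrix(m, moving_frame_id=moving_frame_id,
                                  fixed_frame_id=fixed_frame_id)


@dataclass
class FractionRecord:
    """One treatment session: its daily contours and online registration."""

    index: int
    structure_set: StructureSet
    registration: RegistrationMatrix
    acquisition_label: str = ""


@dataclass
class TreatmentCourse:
    """A planning set plus the ordered daily fraction records."""

    planning_structures: StructureSet
    plan_dose: DoseGrid
    fractions: list[FractionRecord]
    n_fractions_planned: int = 20

    def __post_init__(self):
        ps_for = self.planning_structures.frame_of_reference_id
        dose_for = self.plan_dose.geometry.frame_of_reference_id
        if ps_for and dose_for and ps_for != dose_for:
            raise FrameMismatchError(
                "plan dose and planning structures have different frames of "
                f"reference: {dose_for!r} vs {ps_for!r}")
        idx = [f.index for f in self.fractions]
        if len(set(idx)) != len(idx):
            dupes = sorted({i for i in idx if idx.count(i) > 1})
            raise ConfigError(f"duplicate fraction indices {dupes}")
        self.fractions = sorted(self.fractions, key=lambda f: f.index)
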