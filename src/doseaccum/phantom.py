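"""Synthetic treatment-course generator with analytic ground truth.

Emulates, for a hypofractionated prostate course (60 Gy in 20 fractions),
the data the workflow consumes in the clinic: a planning set (CT series,
structure set, planned dose grid) plus one structure set and one online
rigid registration matrix per daily session.  It stands in for the
planning-system export, the daily cone-beam imaging and the AI contouring.

The pelvis is modelled with convex analytic shapes — prostate ellipsoid,
bladder sphere, rectum cylinder, elliptical body cylinder — whose volumes,
centroids and point-membership are known in closed form, so every pipeline
estimate can be checked against ground truth.  Interfractional change is
modelled as:

* per-organ volume scaling by log-normal factors calibrated to target
  coefficients of variation (bladder >> rectum >> prostate, defaults
  35 / 21 / 10 %, the magnitudes reported for clinical cohorts);
* a 3-D Gaussian anatomical displacement of the prostate (default SD
  2.13 mm per axis, giving a mean 3-D displacement of about 3.4 mm);
* bladder filling drifting the bladder superiorly, coupled to its scale;
* a rigid setup error applied to *all* structures and recorded inversely
  in the emitted registration matrix, so that applying the matrix restores
  everything except the true anatomical change — exactly the situation
  after online couch correction.

The planned dose is a smooth plateau over the prostate plus margin with a
sigmoidal falloff (about 4-5 mm gradient scale), not a beam-model
calculation: only the structure-on-dose evaluation is under test, and the
workflow itself reuses the baseline dose by design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import qmc

from .core import (
    DoseGrid,
    ImageGeometry,
    RegistrationMatrix,
    Roi,
    StructureSet,
)
from .dvh import DoseMetrics, DoseSamples, compute_metrics
from .errors import ConfigError, DoseAccumError
from . import io as rtio

__all__ = [
    "PhantomConfig",
    "Shape",
    "Ellipsoid",
    "ZCylinder",
    "EllipticalCylinder",
    "FractionTruth",
    "GroundTruth",
    "generate_planning_set",
    "generate_fraction",
    "generate_course",
    "oracle_dvh",
]


# ---------------------------------------------------------------------------
# Analytic shapes (convex, axis-aligned before translation/scaling)


class Shape:
    """Convex analytic shape: closed-form volume, centroid, membership and
    axial contours."""

    center: np.ndarray

    def volume_mm3(self) -> float:
        raise NotImplementedError

    def contains(self, points: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def contour_at(self, z: float, n_vertices: int) -> np.ndarray | None:
        """(n, 2) polygon of the cross-section at height z, or None."""
        raise NotImplementedError

    def z_range(self) -> tuple[float, float]:
        raise NotImplementedError

    def bbox(self) -> tuple[np.ndarray, np.ndarray]:
        raise NotImplementedError

    def support(self, u: np.ndarray) -> float:
        """Support function: max over the shape of <p - center, u>."""
        raise NotImplementedError

    def translated(self, t) -> "Shape":
        raise NotImplementedError

    def scaled(self, s: float) -> "Shape":
        """Isotropic scaling by volume factor ``s`` about the centroid."""
        raise NotImplementedError

    def contours(self, z_positions, n_vertices: int = 64) -> Roi:
        """Planar contours on the given slice positions as a :class:`Roi`."""
        slices = []
        for z in z_positions:
            poly = self.contour_at(float(z), n_vertices)
            if poly is not None:
                slices.append((float(z), [poly]))
        return Roi(name="", slices=slices)


def _circle(cx, cy, r, n) -> np.ndarray:
    th = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    return np.column_stack([cx + r * np.cos(th), cy + r * np.sin(th)])


@dataclass(frozen=True)
class Ellipsoid(Shape):
    """Axis-aligned ellipsoid.  ``radial`` switches volume scaling from
    isotropic to in-plane-only (fixed cranio-caudal extent), the model for
    tubular organs whose distension is radial."""

    center: np.ndarray
    semiaxes: np.ndarray  # (a, b, c) mm along (x, y, z)
    radial: bool = False

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, float))
        object.__setattr__(self, "semiaxes", np.asarray(self.semiaxes, float))

    def volume_mm3(self) -> float:
        return 4.0 / 3.0 * math.pi * float(np.prod(self.semiaxes))

    def contains(self, points) -> np.ndarray:
        q = (np.asarray(points, float) - self.center) / self.semiaxes
        return (q ** 2).sum(axis=-1) <= 1.0

    def contour_at(self, z, n_vertices):
        c, ax = self.center, self.semiaxes
        t = (z - c[2]) / ax[2]
        if abs(t) >= 1.0:
            return None
        shrink = math.sqrt(1.0 - t * t)
        th = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
        return np.column_stack([c[0] + ax[0] * shrink * np.cos(th),
                                c[1] + ax[1] * shrink * np.sin(th)])

    def z_range(self):
        return (self.center[2] - self.semiaxes[2],
                self.center[2] + self.semiaxes[2])

    def bbox(self):
        return self.center - self.semiaxes, self.center + self.semiaxes

    def support(self, u):
        return float(np.linalg.norm(self.semiaxes * np.asarray(u, float)))

    def translated(self, t):
        return Ellipsoid(self.center + np.asarray(t, float), self.semiaxes,
                         self.radial)

    def scaled(self, s):
        if self.radial:
            k = np.array([s ** 0.5, s ** 0.5, 1.0])
        else:
            k = s ** (1.0 / 3.0)
        return Ellipsoid(self.center, self.semiaxes * k, self.radial)


@dataclass(frozen=True)
class ZCylinder(Shape):
    center: np.ndarray
    radius: float
    half_length: float

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, float))

    def volume_mm3(self) -> float:
        return math.pi * self.radius ** 2 * 2.0 * self.half_length

    def contains(self, points) -> np.ndarray:
        p = np.asarray(points, float) - self.center
        return ((p[..., 0] ** 2 + p[..., 1] ** 2 <= self.radius ** 2)
                & (np.abs(p[..., 2]) <= self.half_length))

    def contour_at(self, z, n_vertices):
        if abs(z - self.center[2]) > self.half_length:
            return None
        return _circle(self.center[0], self.center[1], self.radius,
                       n_vertices)

    def z_range(self):
        return (self.center[2] - self.half_length,
                self.center[2] + self.half_length)

    def bbox(self):
        r = np.array([self.radius, self.radius, self.half_length])
        return self.center - r, self.center + r

    def support(self, u):
        u = np.asarray(u, float)
        return float(self.radius * np.hypot(u[0], u[1])
                     + self.half_length * abs(u[2]))

    def translated(self, t):
        return ZCylinder(self.center + np.asarray(t, float), self.radius,
                         self.half_length)

    def scaled(self, s):
        # tubular organs distend radially; length is anatomically fixed
        return ZCylinder(self.center, self.radius * s ** 0.5,
                         self.half_length)


@dataclass(frozen=True)
class EllipticalCylinder(Shape):
    center: np.ndarray
    semiaxes_xy: np.ndarray  # (a, b) mm
    half_length: float

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, float))
        object.__setattr__(self, "semiaxes_xy",
                           np.asarray(self.semiaxes_xy, float))

    def volume_mm3(self) -> float:
        return (math.pi * float(np.prod(self.semiaxes_xy))
                * 2.0 * self.half_length)

    def contains(self, points) -> np.ndarray:
        p = np.asarray(points, float) - self.center
        q = p[..., :2] / self.semiaxes_xy
        return (((q ** 2).sum(axis=-1) <= 1.0)
                & (np.abs(p[..., 2]) <= self.half_length))

    def contour_at(self, z, n_vertices):
        if abs(z - self.center[2]) > self.half_length:
            return None
        th = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
        return np.column_stack([
            self.center[0] + self.semiaxes_xy[0] * np.cos(th),
            self.center[1] + self.semiaxes_xy[1] * np.sin(th)])

    def z_range(self):
        return (self.center[2] - self.half_length,
                self.center[2] + self.half_length)

    def bbox(self):
        r = np.array([self.semiaxes_xy[0], self.semiaxes_xy[1],
                      self.half_length])
        return self.center - r, self.center + r

    def support(self, u):
        u = np.asarray(u, float)
        return float(np.linalg.norm(self.semiaxes_xy * u[:2])
                     + self.half_length * abs(u[2]))

    def translated(self, t):
        return EllipticalCylinder(self.center + np.asarray(t, float),
                                  self.semiaxes_xy, self.half_length)

    def scaled(self, s):
        # cross-sectional change only; the scan length is fixed
        return EllipticalCylinder(self.center, self.semiaxes_xy * s ** 0.5,
                                  self.half_length)


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class PhantomConfig:
    """Geometry and variability of the synthetic course.

    Volume CV targets and the prostate displacement scale default to the
    interfractional variability magnitudes reported for prostate cohorts
    (bladder ~35 %, rectum ~21 %, prostate ~10 %, mean 3-D prostate
    displacement ~3.4 mm).  All lengths in mm, volumes in the shapes'
    natural units, CVs as fractions.
    """

    seed: int = 0
    n_fractions: int = 20
    plan_dose_gy: float = 60.0
    dose_spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    ct_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 3.0)
    # field of view (mm, symmetric about the origin)
    fov_x_mm: float = 240.0
    fov_y_mm: float = 200.0
    fov_z_mm: float = 260.0
    # baseline organ geometry
    prostate_semiaxes_mm: tuple[float, float, float] = (25.0, 20.0, 20.0)
    prostate_center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    bladder_radius_mm: float = 36.0
    bladder_center_mm: tuple[float, float, float] = (0.0, -25.0, 55.0)
    rectum_radius_mm: float = 16.0
    rectum_half_length_mm: float = 68.0
    rectum_center_mm: tuple[float, float, float] = (0.0, 45.0, 0.0)
    body_semiaxes_mm: tuple[float, float] = (115.0, 85.0)
    # dose model (normalised ellipsoidal radius units; see _dose_field)
    dose_plateau_rho: float = 2.0
    dose_falloff_rho: float = 0.2
    # interfractional variability
    bladder_volume_cv: float = 0.35
    rectum_volume_cv: float = 0.21
    prostate_volume_cv: float = 0.10
    body_volume_cv: float = 0.02
    prostate_shift_sd_mm: float = 2.13
    setup_error_sd_mm: float = 2.0
    # 1.0 anchors the bladder base / rectum anterior wall while the organ
    # inflates, reproducing the inverse volume-dose mechanism; 0 scales
    # purely about the centroid
    bladder_drift_coupling: float = 1.0
    rectum_drift_coupling: float = 1.0
    contour_vertices: int = 64

    def __post_init__(self):
        for name in ("bladder_radius_mm", "rectum_radius_mm",
                     "rectum_half_length_mm"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0, got "
                                  f"{getattr(self, name)}")
        if any(a <= 0 for a in self.prostate_semiaxes_mm):
            raise ConfigError("prostate semi-axes must be > 0")
        if any(a <= 0 for a in self.body_semiaxes_mm):
            raise ConfigError("body semi-axes must be > 0")
        for name in ("prostate_shift_sd_mm", "setup_error_sd_mm",
                     "bladder_volume_cv", "rectum_volume_cv",
                     "prostate_volume_cv", "body_volume_cv"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        self._validate_layout()

    # -- baseline shapes ----------------------------------------------------

    def baseline_shapes(self) -> dict[str, Shape]:
        return {
            "body": EllipticalCylinder(
                (0.0, 0.0, 0.0), self.body_semiaxes_mm,
                self.fov_z_mm / 2.0),
            "bladder": Ellipsoid(self.bladder_center_mm,
                                 (self.bladder_radius_mm,) * 3),
            # elongated ellipsoid: tapering ends keep end-slice partial
            # volumes graceful on 3 mm slices; radial volume scaling
            "rectum": Ellipsoid(self.rectum_center_mm,
                                (self.rectum_radius_mm, self.rectum_radius_mm,
                                 self.rectum_half_length_mm), radial=True),
            "prostate": Ellipsoid(self.prostate_center_mm,
                                  self.prostate_semiaxes_mm),
        }

    def _validate_layout(self):
        shapes = self.baseline_shapes()
        organs = ["bladder", "rectum", "prostate"]
        for i, a in enumerate(organs):
            for b in organs[i + 1:]:
                sa, sb = shapes[a], shapes[b]
                d = sb.center - sa.center
                dist = float(np.linalg.norm(d))
                u = d / dist
                if sa.support(u) + sb.support(-u) >= dist:
                    raise ConfigError(
                        f"organs {a!r} and {b!r} overlap at baseline")
        # prostate inside the dose plateau
        p = shapes["prostate"]
        surf = p.center + p.semiaxes * np.array([1.0, 0, 0])
        if self._dose_at(surf[None, :])[0] < 0.95 * self.plan_dose_gy:
            raise ConfigError("prostate is not inside the dose plateau")

    # -- grids --------------------------------------------------------------

    def _grid(self, spacing) -> ImageGeometry:
        half = np.array([self.fov_x_mm, self.fov_y_mm, self.fov_z_mm]) / 2.0
        sp = np.asarray(spacing, float)
        dims = (np.floor(2 * half / sp)).astype(int) + 1
        origin = -((dims - 1) * sp) / 2.0
        return ImageGeometry(origin=tuple(origin), spacing=tuple(sp),
                             dims=tuple(int(d) for d in dims))

    def dose_geometry(self, frame_id: str = "") -> ImageGeometry:
        g = self._grid(self.dose_spacing_mm)
        return replace_frame(g, frame_id)

    def ct_geometry(self, frame_id: str = "") -> ImageGeometry:
        g = self._grid(self.ct_spacing_mm)
        return replace_frame(g, frame_id)

    # -- dose model ---------------------------------------------------------

    def _rho(self, points: np.ndarray) -> np.ndarray:
        """Normalised ellipsoidal radius about the baseline prostate."""
        c = np.asarray(self.prostate_center_mm)
        ax = np.asarray(self.prostate_semiaxes_mm)
        q = (np.asarray(points, float) - c) / ax
        return np.sqrt((q ** 2).sum(axis=-1))

    def _dose_at(self, points: np.ndarray) -> np.ndarray:
        """Continuous planned-dose field: plateau with sigmoidal falloff."""
        x = (self.dose_plateau_rho - self._rho(points)) / self.dose_falloff_rho
        return self.plan_dose_gy / (1.0 + np.exp(-x))


def replace_frame(g: ImageGeometry, frame_id: str) -> ImageGeometry:
    return ImageGeometry(origin=g.origin, spacing=g.spacing, dims=g.dims,
                         orientation=g.orientation,
                         frame_of_reference_id=frame_id)


# ---------------------------------------------------------------------------
# Ground truth containers


@dataclass
class FractionTruth:
    """Per-fraction, per-organ truth in the *planning* frame."""

    index: int
    shapes: dict[str, Shape]  # anatomy after registration (planning frame)
    scales: dict[str, float]  # volume scale factors vs baseline
    displacement_mm: dict[str, np.ndarray]  # anatomical COM shift
    setup_error_mm: np.ndarray  # applied to all structures, corrected by reg

    def true_volume_cm3(self, organ: str) -> float:
        return self.shapes[organ].volume_mm3() / 1000.0

    def true_displacement_norm(self, organ: str) -> float:
        return float(np.linalg.norm(self.displacement_mm[organ]))


@dataclass
class GroundTruth:
    """Truth for a whole generated course."""

    baseline_shapes: dict[str, Shape]
    fractions: list[FractionTruth] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        rows = []
        for ft in self.fractions:
            for organ, shape in ft.shapes.items():
                d = ft.displacement_mm[organ]
                rows.append({
                    "fraction": ft.index, "organ": organ,
                    "scale": ft.scales[organ],
                    "true_volume_cm3": ft.true_volume_cm3(organ),
                    "dx_mm": d[0], "dy_mm": d[1], "dz_mm": d[2],
                    "displacement_mm": ft.true_displacement_norm(organ),
                    "setup_x_mm": ft.setup_error_mm[0],
                    "setup_y_mm": ft.setup_error_mm[1],
                    "setup_z_mm": ft.setup_error_mm[2],
                })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Generation


def _lognormal_scale(rng, cv: float) -> float:
    """Unit-mean log-normal volume factor with the requested CV.

    CV of a log-normal is sqrt(exp(sigma^2) - 1), so sigma =
    sqrt(ln(1 + cv^2)); mu = -sigma^2/2 centres the mean at 1.
    """
    if cv == 0:
        return 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return float(rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma))


def _frame_uid(config: PhantomConfig, label: str) -> str:
    from pydicom.uid import generate_uid

    return str(generate_uid(
        entropy_srcs=[f"doseaccum-phantom-{config.seed}", label]))


def _structure_set(shapes: dict[str, Shape], config: PhantomConfig,
                   frame_id: str) -> StructureSet:
    colors = {"body": (0, 255, 0), "bladder": (0, 0, 255),
              "rectum": (0, 128, 0), "prostate": (255, 0, 0)}
    ct = config.ct_geometry()
    zs = ct.axis_coords(2)
    rois = {}
    for name, shape in shapes.items():
        roi = shape.contours(zs, config.contour_vertices)
        roi.name = name
        roi.color = colors.get(name, (255, 255, 0))
        rois[name] = roi
    return StructureSet(rois=rois, frame_of_reference_id=frame_id)


def generate_planning_set(config: PhantomConfig
                          ) -> tuple[ImageGeometry, np.ndarray, StructureSet,
                                     DoseGrid, GroundTruth]:
    """The planning phase: CT geometry + HU volume, baseline structures,
    planned dose grid and the ground-truth record.

    The CT volume is a water-equivalent body with fixed HU offsets per
    organ; its voxel data are not used by the dose pipeline.  The dose is
    the analytic plateau field evaluated at the dose-grid voxel centres.
    """
    frame = _frame_uid(config, "planning")
    shapes = config.baseline_shapes()

    ct_geom = config.ct_geometry(frame)
    xs, ys, zs = (ct_geom.axis_coords(i) for i in range(3))
    hu = np.full(ct_geom.dims, -1000.0, dtype=np.float32)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    organ_hu = {"body": 0.0, "bladder": 30.0, "rectum": -50.0,
                "prostate": 40.0}
    for iz, z in enumerate(zs):
        pts = np.column_stack([gx.ravel(), gy.ravel(),
                               np.full(gx.size, z)])
        plane = np.full(gx.size, -1000.0, dtype=np.float32)
        for name in ("body", "bladder", "rectum", "prostate"):
            inside = shapes[name].contains(pts)
            plane[inside] = organ_hu[name]
        hu[:, :, iz] = plane.reshape(gx.shape)

    ss = _structure_set(shapes, config, frame)

    dgeom = config.dose_geometry(frame)
    dx, dy, dz = (dgeom.axis_coords(i) for i in range(3))
    gx3, gy3, gz3 = np.meshgrid(dx, dy, dz, indexing="ij")
    pts = np.column_stack([gx3.ravel(), gy3.ravel(), gz3.ravel()])
    dose_values = config._dose_at(pts).reshape(dgeom.dims)
    dose = DoseGrid(geometry=dgeom, values=dose_values)

    return ct_geom, hu, ss, dose, GroundTruth(baseline_shapes=shapes)


def generate_fraction(config: PhantomConfig, index: int,
                      rng: np.random.Generator | None = None
                      ) -> tuple[StructureSet, RegistrationMatrix,
                                 FractionTruth]:
    """One daily session: scaled/shifted anatomy in its own (daily) frame
    plus the online registration matrix mapping it back to planning.

    With all variability parameters zero the output anatomy equals the
    planning anatomy and the matrix is the identity.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, index])
    base = config.baseline_shapes()

    scales = {
        "body": _lognormal_scale(rng, config.body_volume_cv),
        "bladder": _lognormal_scale(rng, config.bladder_volume_cv),
        "rectum": _lognormal_scale(rng, config.rectum_volume_cv),
        "prostate": _lognormal_scale(rng, config.prostate_volume_cv),
    }
    prostate_shift = (rng.normal(0.0, config.prostate_shift_sd_mm, size=3)
                      if config.prostate_shift_sd_mm > 0 else np.zeros(3))
    setup = (rng.normal(0.0, config.setup_error_sd_mm, size=3)
             if config.setup_error_sd_mm > 0 else np.zeros(3))

    # anatomy in the planning frame (what a perfect registration recovers)
    anatomy: dict[str, Shape] = {}
    displacement: dict[str, np.ndarray] = {}
    for name, shape in base.items():
        s = shape.scaled(scales[name])
        shift = np.zeros(3)
        if name == "prostate":
            shift = prostate_shift
        elif name == "bladder":
            # filling expands superiorly from an (approximately) fixed base
            k = scales[name] ** (1.0 / 3.0) - 1.0
            shift = np.array([0.0, 0.0, config.bladder_drift_coupling
                              * k * config.bladder_radius_mm])
        elif name == "rectum":
            # radial distension moves the lumen centre posteriorly; the
            # anterior wall facing the prostate stays (approximately) fixed
            k = scales[name] ** 0.5 - 1.0
            shift = np.array([0.0, config.rectum_drift_coupling
                              * k * config.rectum_radius_mm, 0.0])
        anatomy[name] = s.translated(shift)
        displacement[name] = shift

    # the daily frame differs from planning by the setup error; the online
    # matrix (moving -> fixed) undoes it
    daily_frame = _frame_uid(config, f"fx{index:03d}")
    planning_frame = _frame_uid(config, "planning")
    daily_shapes = {name: s.translated(setup) for name, s in anatomy.items()}
    ss = _structure_set(daily_shapes, config, daily_frame)
    reg = RegistrationMatrix.from_translation(
        -setup, moving_frame_id=daily_frame, fixed_frame_id=planning_frame)

    truth = FractionTruth(index=index, shapes=anatomy, scales=scales,
                          displacement_mm=displacement,
                          setup_error_mm=setup)
    return ss, reg, truth


def generate_course(config: PhantomConfig, out_dir,
                    write_ct: bool = True) -> tuple[Path, GroundTruth]:
    """Write a complete on-disk course loadable by
    :func:`doseaccum.io.load_course`.

    Layout: ``manifest.yaml``, ``plan/`` (CT slices, structures, dose),
    ``fx<NNN>/`` per fraction (structures + text matrix) and
    ``ground_truth.csv``.  Byte-deterministic for a fixed seed and config.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    plan_dir = out_dir / "plan"
    plan_dir.mkdir(exist_ok=True)

    ct_geom, hu, plan_ss, dose, truth = generate_planning_set(config)
    entropy = [f"doseaccum-phantom-{config.seed}"]
    rtio.write_structure_set(plan_ss, plan_dir / "structures.dcm",
                             entropy=entropy + ["plan-ss"])
    rtio.write_dose(dose, plan_dir / "dose.dcm", entropy=entropy + ["dose"])
    if write_ct:
        rtio.write_ct_series(ct_geom, hu, plan_dir / "ct",
                             entropy=entropy + ["ct"])

    fractions = []
    for i in range(1, config.n_fractions + 1):
        ss, reg, ft = generate_fraction(config, i)
        fx_dir = out_dir / f"fx{i:03d}"
        fx_dir.mkdir(exist_ok=True)
        rtio.write_structure_set(ss, fx_dir / "structures.dcm",
                                 entropy=entropy + [f"fx{i:03d}-ss"])
        rtio.write_registration_text(reg, fx_dir / "registration.txt")
        truth.fractions.append(ft)
        fractions.append({"index": i,
                          "structures": f"fx{i:03d}/structures.dcm",
                          "registration": f"fx{i:03d}/registration.txt",
                          "label": f"fx{i:03d}"})

    manifest = out_dir / "manifest.yaml"
    rtio.write_manifest(manifest, plan_structures="plan/structures.dcm",
                        plan_dose="plan/dose.dcm", fractions=fractions,
                        n_fractions_planned=config.n_fractions,
                        matrix_maps="moving_to_fixed",
                        ct_dir="plan/ct" if write_ct else None)
    truth.to_frame().to_csv(out_dir / "ground_truth.csv", index=False)
    return manifest, truth


# ---------------------------------------------------------------------------
# Rasterization-free oracle


def oracle_samples(shape: Shape, dose: DoseGrid, n_points: int = 100_000,
                   seed: int = 0) -> DoseSamples:
    """Dose samples at quasi-random points inside an analytic shape.

    Scrambled Sobol points in the shape's bounding box are
    rejection-filtered with the exact membership test, then the dose grid
    is interpolated trilinearly at the survivors — no rasterization
    anywhere, which makes this an independent reference for the
    mask-based pipeline.
    """
    from .dvh import _dose_interpolator

    lo, hi = shape.bbox()
    vol_frac = shape.volume_mm3() / float(np.prod(hi - lo))
    if vol_frac <= 0:
        raise DoseAccumError("degenerate shape: zero volume")
    sampler = qmc.Sobol(d=3, scramble=True, seed=seed)
    pts_in: list[np.ndarray] = []
    n_have = 0
    # draw in powers of two (Sobol balance), reject outside points
    batch = int(2 ** math.ceil(math.log2(max(n_points / vol_frac, 256))))
    while n_have < n_points:
        u = sampler.random(batch)
        p = lo + u * (hi - lo)
        keep = p[shape.contains(p)]
        pts_in.append(keep)
        n_have += len(keep)
        batch = max(batch // 2, 4096)
    pts = np.vstack(pts_in)[:n_points]
    interp = _dose_interpolator(dose, method="linear")
    vals = interp(pts)
    inside = ~np.isnan(vals)
    return DoseSamples(values=vals[inside], voxel_volume_cm3=0.0,
                       n_outside_grid=int((~inside).sum()))


def oracle_dvh(shape: Shape, dose: DoseGrid, n_points: int = 100_000,
               seed: int = 0) -> DoseMetrics:
    """ICRU-83 metrics from the analytic-shape quasi-random oracle."""
    return compute_metrics(oracle_samples(shape, dose, n_points, seed))
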