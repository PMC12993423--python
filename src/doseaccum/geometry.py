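"""Rigid contour transformation, polygon rasterization and the geometric
change metrics used to characterise interfractional anatomy: structure
volume, centre-of-mass distance (CMD), Dice similarity coefficient (DSC)
and uniform margin expansion.

Masks live on an explicit :class:`~doseaccum.core.ImageGeometry`; metrics
that compare two masks require the geometries to match, which in the
pipeline is guaranteed by evaluating everything on one common grid in the
planning frame (by default the dose grid resampled to isotropic 1 mm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
from matplotlib.path import Path as MplPath
from scipy import ndimage

from .core import ImageGeometry, RegistrationMatrix, Roi
from .errors import EmptyStructureError, FrameMismatchError, UndefinedMetricError

__all__ = [
    "BinaryMask",
    "GeometrySummary",
    "Direction",
    "transform_roi",
    "rasterize",
    "mask_volume",
    "center_of_mass",
    "cmd",
    "dice",
    "expand_margin",
    "isotropic_geometry",
    "summarize_geometry",
]


class Direction(str, Enum):
    """Which way a registration matrix is applied to contour points."""

    MOVING_TO_FIXED = "moving_to_fixed"
    FIXED_TO_MOVING = "fixed_to_moving"


@dataclass
class BinaryMask:
    """Boolean occupancy of a structure on a placed grid."""

    geometry: ImageGeometry
    voxels: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.shape != tuple(self.geometry.dims):
            raise ValueError(
                f"mask shape {self.voxels.shape} != dims {self.geometry.dims}")

    @property
    def n_set(self) -> int:
        return int(self.voxels.sum())

    @property
    def is_empty(self) -> bool:
        return not self.voxels.any()


@dataclass
class GeometrySummary:
    """Per-structure geometric comparison of a daily mask against baseline.

    ``volume_dev_pct`` is (V_daily - V_plan) / V_plan * 100 and is ``None``
    when the baseline volume is zero (undefined rather than 0).
    """

    volume_cm3: float
    volume_dev_pct: float | None
    com: tuple[float, float, float]
    cmd_mm: float
    dsc: float


def isotropic_geometry(geometry: ImageGeometry,
                       spacing_mm: float = 1.0) -> ImageGeometry:
    """A grid covering the same physical extent at isotropic spacing.

    Used to evaluate geometry and DVH metrics on a common fine grid
    independent of the (typically coarser) dose-grid resolution.
    """
    lo, hi = geometry.extent()
    dims = tuple(int(np.floor((hi[i] - lo[i]) / spacing_mm)) + 1
                 for i in range(3))
    return ImageGeometry(
        origin=tuple(lo), spacing=(spacing_mm,) * 3, dims=dims,
        frame_of_reference_id=geometry.frame_of_reference_id)


def transform_roi(roi: Roi, reg: RegistrationMatrix,
                  direction: Direction | str = Direction.MOVING_TO_FIXED) -> Roi:
    """Map a contour stack through a rigid registration.

    Pure translations keep the planar structure and simply shift every
    vertex.  Transforms with a non-identity rotation block tilt the contour
    planes, so the ROI is re-sliced: the input is rasterized on a fine
    temporary grid, the mask is rigidly resampled, and new axial polygons
    are traced from the transformed mask.
    """
    if roi.is_empty:
        raise EmptyStructureError(f"ROI {roi.name!r} has no contours")
    direction = Direction(direction)
    m = reg if direction is Direction.MOVING_TO_FIXED else reg.inverse()
    if m.is_pure_translation:
        t = m.translation
        slices = [(z + t[2], [p + t[:2] for p in polys])
                  for z, polys in roi.slices]
        return Roi(name=roi.name, slices=slices, color=roi.color)
    return _transform_roi_resample(roi, m)


def _transform_roi_resample(roi: Roi, m: RegistrationMatrix,
                            spacing: float = 1.0) -> Roi:
    """Rotation path: rasterize, rigidly resample the mask, re-trace contours."""
    from skimage import measure

    verts = roi.all_vertices()
    pad = 4.0 * spacing
    lo = verts.min(axis=0) - pad
    hi = verts.max(axis=0) + pad
    src_geom = ImageGeometry(
        origin=tuple(lo), spacing=(spacing,) * 3,
        dims=tuple(int(np.ceil((hi[i] - lo[i]) / spacing)) + 1 for i in range(3)))
    src = rasterize(roi, src_geom, supersample=4)

    # output grid: axis-aligned bounding box of the transformed corners
    corners = np.array([[x, y, z]
                        for x in (lo[0], hi[0])
                        for y in (lo[1], hi[1])
                        for z in (lo[2], hi[2])])
    tc = m.apply(corners)
    tlo, thi = tc.min(axis=0), tc.max(axis=0)
    out_geom = ImageGeometry(
        origin=tuple(tlo), spacing=(spacing,) * 3,
        dims=tuple(int(np.ceil((thi[i] - tlo[i]) / spacing)) + 1 for i in range(3)))

    # inverse map: output voxel centre -> input voxel index (spacing cancels
    # because both grids are isotropic at the same spacing)
    inv = m.inverse()
    offset = (inv.rotation @ np.asarray(out_geom.origin) + inv.translation
              - np.asarray(src_geom.origin)) / spacing
    resampled = ndimage.affine_transform(
        src.voxels.astype(np.float32), inv.rotation, offset=offset,
        output_shape=out_geom.dims, order=1, mode="constant", cval=0.0)
    mask = resampled >= 0.5

    slices: list[tuple[float, list[np.ndarray]]] = []
    zs = out_geom.axis_coords(2)
    for iz in range(out_geom.dims[2]):
        plane = mask[:, :, iz]
        if not plane.any():
            continue
        polys = []
        for contour in measure.find_contours(plane.astype(float), 0.5):
            # find_contours returns (row=x-index, col=y-index) pairs here
            xy = np.column_stack([
                out_geom.origin[0] + contour[:, 0] * spacing,
                out_geom.origin[1] + contour[:, 1] * spacing])
            if len(xy) >= 3:
                polys.append(xy)
        if polys:
            slices.append((float(zs[iz]), polys))
    return Roi(name=roi.name, slices=slices, color=roi.color)


def _rasterize_plane(polys: list[np.ndarray], geometry: ImageGeometry,
                     supersample: int) -> tuple[slice, slice, np.ndarray]:
    """Even-odd rasterization of one slice's polygons onto the in-plane grid.

    Returns the bounding index windows and the boolean sub-mask.  A voxel is
    set when the majority of its supersample x supersample sub-centres fall
    inside an odd number of polygons (ties count as inside).
    """
    ox, oy = geometry.origin[0], geometry.origin[1]
    dx, dy = geometry.spacing[0], geometry.spacing[1]
    nx, ny = geometry.dims[0], geometry.dims[1]

    allv = np.vstack(polys)
    ix0 = max(int(np.floor((allv[:, 0].min() - ox) / dx)) - 1, 0)
    ix1 = min(int(np.ceil((allv[:, 0].max() - ox) / dx)) + 1, nx - 1)
    iy0 = max(int(np.floor((allv[:, 1].min() - oy) / dy)) - 1, 0)
    iy1 = min(int(np.ceil((allv[:, 1].max() - oy) / dy)) + 1, ny - 1)
    if ix1 < ix0 or iy1 < iy0:
        return slice(0, 0), slice(0, 0), np.zeros((0, 0), dtype=bool)

    s = int(supersample)
    sub = (np.arange(s) + 0.5) / s - 0.5  # sub-centre offsets in voxel units
    xs = ox + dx * (np.arange(ix0, ix1 + 1)[:, None] + sub[None, :])
    ys = oy + dy * (np.arange(iy0, iy1 + 1)[:, None] + sub[None, :])
    xs = xs.ravel()
    ys = ys.ravel()
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])

    parity = np.zeros(len(pts), dtype=np.uint8)
    for poly in polys:
        # Path(..., closed=True) treats the *last* vertex as the CLOSEPOLY
        # marker, so the first vertex must be repeated explicitly
        path = MplPath(np.vstack([poly, poly[:1]]), closed=True)
        parity ^= path.contains_points(pts)
    inside = parity.reshape(ix1 - ix0 + 1, s, iy1 - iy0 + 1, s)
    votes = inside.sum(axis=(1, 3))
    mask2d = votes * 2 >= s * s
    return slice(ix0, ix1 + 1), slice(iy0, iy1 + 1), mask2d


def rasterize(roi: Roi, geometry: ImageGeometry,
              supersample: int = 4) -> BinaryMask:
    """Voxelize a planar contour stack onto a grid (slab model).

    Each evaluation slice takes the polygons of the nearest contour plane,
    provided that plane lies within half a slab of the slice centre, where
    the slab thickness is the contour-plane spacing (or the grid slice
    spacing for single-plane ROIs).  In-plane membership uses voxel centres
    on a ``supersample``-refined grid with the even-odd rule, so nested
    contours create holes; majority vote maps back to native voxels.
    Contour planes outside the grid z-range (beyond half a slab) are
    dropped with a warning; if all planes are out of range an all-false
    mask is returned with a warning.
    """
    if roi.is_empty:
        return BinaryMask(geometry, np.zeros(geometry.dims, dtype=bool),
                          label=roi.name)
    voxels = np.zeros(geometry.dims, dtype=bool)
    gz = geometry.axis_coords(2)
    dz = geometry.spacing[2]
    slab = max(roi.plane_spacing(), dz)
    half = slab / 2 + 1e-6

    plane_zs = roi.plane_zs()
    n_dropped = 0
    # assign every grid slice to its nearest contour plane
    assignment: dict[int, list[int]] = {}
    for iz, z in enumerate(gz):
        j = int(np.argmin(np.abs(plane_zs - z)))
        if abs(plane_zs[j] - z) <= half:
            assignment.setdefault(j, []).append(iz)
    used_planes = set(assignment)
    for j, z in enumerate(plane_zs):
        if j not in used_planes and (z < gz[0] - half or z > gz[-1] + half):
            n_dropped += 1
    if n_dropped:
        warnings.warn(
            f"ROI {roi.name!r}: {n_dropped} contour plane(s) outside grid "
            "z-range dropped", stacklevel=2)
    if not assignment:
        warnings.warn(
            f"ROI {roi.name!r}: all contour planes outside grid; empty mask",
            stacklevel=2)
        return BinaryMask(geometry, voxels, label=roi.name)

    # identical polygon stacks (e.g. a cylinder contoured on every slice)
    # rasterize once and are reused via a content-keyed cache
    cache: dict = {}
    for j, iz_list in assignment.items():
        polys = roi.slices[j][1]
        key = tuple(p.tobytes() for p in polys)
        if key not in cache:
            cache[key] = _rasterize_plane(polys, geometry, supersample)
        sx, sy, mask2d = cache[key]
        if mask2d.size == 0:
            continue
        for iz in iz_list:
            voxels[sx, sy, iz] |= mask2d
    return BinaryMask(geometry, voxels, label=roi.name)


def mask_volume(mask: BinaryMask) -> float:
    """Structure volume in cm^3: set-voxel count times voxel volume."""
    return mask.n_set * mask.geometry.voxel_volume_mm3 / 1000.0


def center_of_mass(mask: BinaryMask) -> np.ndarray:
    """Unweighted centroid of set-voxel centres, patient mm."""
    if mask.is_empty:
        raise EmptyStructureError(f"mask {mask.label!r} is empty")
    idx = np.argwhere(mask.voxels)
    mean_idx = idx.mean(axis=0)
    return np.asarray(mask.geometry.origin) + mean_idx * np.asarray(
        mask.geometry.spacing)


def _check_same_geometry(a: BinaryMask, b: BinaryMask) -> None:
    ga, gb = a.geometry, b.geometry
    if (ga.dims != gb.dims or not np.allclose(ga.origin, gb.origin)
            or not np.allclose(ga.spacing, gb.spacing)):
        raise FrameMismatchError("masks are on different grids")


def cmd(mask_daily: BinaryMask, mask_plan: BinaryMask) -> float:
    """Centre-of-mass distance between two masks on the same grid, mm."""
    _check_same_geometry(mask_daily, mask_plan)
    return float(np.linalg.norm(center_of_mass(mask_daily)
                                - center_of_mass(mask_plan)))


def dice(mask_a: BinaryMask, mask_b: BinaryMask) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|) on voxel counts.

    1 means perfect overlap, 0 none.  Both masks empty is treated as a
    pipeline fault (undefined), one empty gives 0.
    """
    _check_same_geometry(mask_a, mask_b)
    na, nb = mask_a.n_set, mask_b.n_set
    if na == 0 and nb == 0:
        raise UndefinedMetricError("DSC undefined: both masks empty")
    inter = int(np.logical_and(mask_a.voxels, mask_b.voxels).sum())
    return 2.0 * inter / (na + nb)


def expand_margin(mask: BinaryMask, margin_mm: float) -> BinaryMask:
    """Uniform Euclidean expansion: voxels within ``margin_mm`` of the input.

    Uses an anisotropic-spacing-aware distance transform, so the margin is
    isotropic in mm even on non-cubic voxels.  Used to build the
    prostate + 1 cm planning-target surrogate.
    """
    if mask.is_empty:
        raise EmptyStructureError(f"mask {mask.label!r} is empty")
    if margin_mm <= 0:
        raise ValueError("margin must be > 0")
    # restrict the distance transform to the dilated bounding box; outside
    # it the distance exceeds the margin by construction
    spacing = np.asarray(mask.geometry.spacing)
    idx = np.argwhere(mask.voxels)
    grow = np.ceil(margin_mm / spacing).astype(int) + 1
    lo = np.maximum(idx.min(axis=0) - grow, 0)
    hi = np.minimum(idx.max(axis=0) + grow + 1, mask.geometry.dims)
    window = tuple(slice(lo[i], hi[i]) for i in range(3))
    dist = ndimage.distance_transform_edt(
        ~mask.voxels[window], sampling=spacing)
    out = np.zeros(mask.geometry.dims, dtype=bool)
    out[window] = dist <= margin_mm
    return BinaryMask(mask.geometry, out, label=f"{mask.label}+{margin_mm:g}mm")


def summarize_geometry(mask_daily: BinaryMask,
                       mask_plan: BinaryMask) -> GeometrySummary:
    """Volume, deviation vs baseline, COM, CMD and DSC in one record."""
    v_daily = mask_volume(mask_daily)
    v_plan = mask_volume(mask_plan)
    dev = None if v_plan == 0 else (v_daily - v_plan) / v_plan * 100.0
    return GeometrySummary(
        volume_cm3=v_daily,
        volume_dev_pct=dev,
        com=tuple(center_of_mass(mask_daily)),
        cmd_mm=cmd(mask_daily, mask_plan),
        dsc=dice(mask_daily, mask_plan),
    )
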