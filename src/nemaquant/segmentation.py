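"""VOI definition: fixed-fraction threshold, background-adapted threshold
and CT-based ROI transfer.

Threshold VOIs are grown as the 26-connected component, above the absolute
level, that contains the hottest voxel of a search box around the nominal
sphere centre.  The search box (side twice the sphere diameter) prevents
background flooding at low sphere-to-background ratios; a grown mask that
reaches the box boundary is reported as infeasible rather than returned as
a bogus volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import (
    GeometryError,
    InvalidArgumentError,
    SegmentationInfeasibleError,
)
from .geometry import GridSpec, PhantomGeometry, VOIMask, ct_reference_mask
from .simulator import ImageVolume

__all__ = [
    "MaxEstimate",
    "BackgroundEstimate",
    "SearchRegion",
    "sphere_search_region",
    "find_max",
    "background_roi_boxes",
    "estimate_background",
    "plain_threshold",
    "adapted_threshold",
    "grow_voi",
    "segment",
    "METHODS",
    "DEFAULT_T_GRID",
]

METHODS = ("threshold", "adapted", "ct", "ct3d")

#: The threshold grid used throughout: 10% to 90% in steps of 10.
DEFAULT_T_GRID = tuple(np.round(np.arange(0.1, 0.91, 0.1), 2))

#: Background box ROIs: edge length (mm), radial position (mm) and angular
#: offset from the first sphere (deg).  Chosen to keep every box >= 15 mm
#: from sphere surfaces, lung insert and body wall.
BG_BOX_SIZE_MM = 16.0
BG_BOX_RADIUS_MM = 90.0
BG_BOX_ANGLES_DEG = (30.0, 150.0, 270.0)


@dataclass(frozen=True)
class MaxEstimate:
    """Maximum image value within a search region and where it occurs."""

    value: float
    location: tuple[int, int, int]  # voxel index


@dataclass(frozen=True)
class BackgroundEstimate:
    """Mean background level from three box ROIs between spheres and wall."""

    value: float
    roi_means: tuple[float, ...]
    roi_boxes: tuple[tuple[tuple[int, int], ...], ...]  # index ranges per ROI
    roi_std: float = 0.0  # pooled voxel SD, used as a noise proxy


@dataclass(frozen=True)
class SearchRegion:
    """Half-open voxel-index box ``[start, stop)`` per axis."""

    start: tuple[int, int, int]
    stop: tuple[int, int, int]

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(a, b) for a, b in zip(self.start, self.stop))

    @property
    def is_empty(self) -> bool:
        return any(b <= a for a, b in zip(self.start, self.stop))


def _box_region(grid: GridSpec, center_mm, half_extent_mm) -> SearchRegion:
    """Voxels whose centres lie within center +- half_extent, clipped to grid."""
    c = np.asarray(center_mm, dtype=float)
    h = np.asarray(half_extent_mm, dtype=float)
    lo = grid.world_to_index(c - h)
    hi = grid.world_to_index(c + h)
    start = tuple(int(max(0, np.ceil(l - 1e-9))) for l in lo)
    stop = tuple(int(min(n, np.floor(h_ + 1e-9) + 1)) for n, h_ in zip(grid.dims, hi))
    return SearchRegion(start, stop)


def sphere_search_region(grid: GridSpec, geometry: PhantomGeometry, sphere_id: str) -> SearchRegion:
    """Cube of side twice the sphere diameter, centred on the nominal centre."""
    sphere = geometry.sphere(sphere_id)
    region = _box_region(grid, sphere.center, (sphere.inner_diameter,) * 3)
    if region.is_empty:
        raise InvalidArgumentError(f"search region for {sphere_id} is empty on this grid")
    return region


def find_max(image: ImageVolume, region: SearchRegion) -> MaxEstimate:
    """Maximum value and its voxel location within a search region."""
    if region.is_empty:
        raise InvalidArgumentError("empty search region")
    sub = image.values[region.slices()]
    flat = int(np.argmax(sub))
    local = np.unravel_index(flat, sub.shape)
    location = tuple(int(s + l) for s, l in zip(region.start, local))
    return MaxEstimate(value=float(sub.max()), location=location)


def background_roi_boxes(
    geometry: PhantomGeometry,
    grid: GridSpec,
    box_size_mm: float = BG_BOX_SIZE_MM,
    radius_mm: float = BG_BOX_RADIUS_MM,
    clearance_mm: float = 15.0,
) -> list[SearchRegion]:
    """Deterministic placement of the three background box ROIs.

    Boxes sit in the sphere plane at 120-degree spacing, midway between
    sphere positions, and are verified to clear spheres, lung and wall.
    """
    half = box_size_mm / 2.0
    boxes = []
    for ang_deg in BG_BOX_ANGLES_DEG:
        ang = np.deg2rad(ang_deg)
        center = np.array(
            [radius_mm * np.cos(ang), radius_mm * np.sin(ang), geometry.sphere_plane_z]
        )
        # clearance check against the whole box, via its corners
        corners = center + half * np.array(
            [(sx, sy, sz) for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]
        )
        for p in corners:
            for s in geometry.spheres:
                if np.linalg.norm(p - s.center) < s.radius + clearance_mm:
                    raise GeometryError("background ROI too close to a sphere")
            if geometry.lung is not None and np.hypot(p[0], p[1]) < geometry.lung.radius + clearance_mm:
                raise GeometryError("background ROI too close to the lung insert")
            body = geometry.body
            xc = np.clip(p[0], -body.half_straight, body.half_straight)
            if body.cap_radius - np.hypot(p[0] - xc, p[1]) < clearance_mm:
                raise GeometryError("background ROI too close to the body wall")
        region = _box_region(grid, center, (half,) * 3)
        if region.is_empty:
            raise GeometryError("background ROI contains no voxels on this grid")
        boxes.append(region)
    return boxes


def estimate_background(
    image: ImageVolume, geometry: PhantomGeometry, grid: GridSpec | None = None
) -> BackgroundEstimate:
    """BG of the adapted threshold: mean of the three box-ROI means."""
    grid = grid or image.grid
    boxes = background_roi_boxes(geometry, grid)
    means, sds, index_ranges = [], [], []
    for box in boxes:
        vals = image.values[box.slices()]
        means.append(float(vals.mean()))
        sds.append(float(vals.std(ddof=1)) if vals.size > 1 else 0.0)
        index_ranges.append(tuple(zip(box.start, box.stop)))
    # noise can push the estimate below zero on cold backgrounds; clamp,
    # concentrations are non-negative by definition
    return BackgroundEstimate(
        value=max(float(np.mean(means)), 0.0),
        roi_means=tuple(means),
        roi_boxes=tuple(index_ranges),
        roi_std=float(np.sqrt(np.mean(np.square(sds)))),
    )


def _check_T(T: float) -> float:
    if not 0.0 < T <= 1.0:
        raise InvalidArgumentError(f"threshold fraction must be in (0, 1], got {T}")
    return float(T)


def plain_threshold(T: float, ac_max: MaxEstimate | float) -> float:
    """Absolute level T * AC_max of the fixed-fraction method."""
    T = _check_T(T)
    value = ac_max.value if isinstance(ac_max, MaxEstimate) else float(ac_max)
    if value <= 0:
        raise SegmentationInfeasibleError("AC_max <= 0: nothing to segment")
    return T * value


def adapted_threshold(
    T: float, ac_max: MaxEstimate | float, bg: BackgroundEstimate | float
) -> float:
    """Background-adapted absolute level: T * (AC_max - BG) + BG."""
    T = _check_T(T)
    a = ac_max.value if isinstance(ac_max, MaxEstimate) else float(ac_max)
    b = bg.value if isinstance(bg, BackgroundEstimate) else float(bg)
    if b < 0:
        raise InvalidArgumentError("BG must be >= 0")
    if a < b:
        raise SegmentationInfeasibleError("AC_max below background: sphere not segmentable")
    return T * (a - b) + b


_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def grow_voi(
    image: ImageVolume,
    level: float,
    seed_location: tuple[int, int, int],
    region: SearchRegion,
    method: str = "threshold",
    sphere_id: str = "",
    threshold: float | None = None,
    reject_boundary: bool = False,
) -> VOIMask:
    """26-connected component >= level containing the seed, within a region.

    With ``reject_boundary`` (used by :func:`segment`), a component touching
    a region face that is not a grid edge means the segmentation merged with
    the surroundings (flooding) and is reported infeasible.
    """
    sl = region.slices()
    sub = image.values[sl]
    seed_local = tuple(s - a for s, a in zip(seed_location, region.start))
    if any(not 0 <= i < n for i, n in zip(seed_local, sub.shape)):
        raise InvalidArgumentError("seed location outside the search region")
    if image.values[seed_location] < level:
        raise SegmentationInfeasibleError("seed voxel below threshold level: empty VOI")
    above = sub >= level
    labels, _ = ndimage.label(above, structure=_STRUCT_26)
    component = labels == labels[seed_local]
    if reject_boundary and _touches_interior_boundary(component, region, image.grid):
        raise SegmentationInfeasibleError(
            "VOI reached the search-region boundary (background flooding)"
        )
    mask = np.zeros(image.grid.dims, dtype=bool)
    mask[sl] = component
    return VOIMask(
        mask=mask,
        grid=image.grid,
        method=method,
        sphere_id=sphere_id,
        threshold=threshold,
        absolute_level=float(level),
    )


def _touches_interior_boundary(component: np.ndarray, region: SearchRegion, grid: GridSpec) -> bool:
    """True if the component touches a region face that is not a grid edge."""
    for axis in range(3):
        if region.start[axis] > 0 and np.any(np.take(component, 0, axis=axis)):
            return True
        if region.stop[axis] < grid.dims[axis] and np.any(np.take(component, -1, axis=axis)):
            return True
    return False


def segment(
    image: ImageVolume,
    geometry: PhantomGeometry,
    sphere_id: str,
    method: str,
    T: float | None = None,
    grid: GridSpec | None = None,
) -> VOIMask:
    """Dispatch to one of the three VOI-definition methods.

    ``threshold`` and ``adapted`` need a threshold fraction ``T``; ``ct``
    (single-slice disk) and ``ct3d`` ignore it.  AC_max is taken within the
    search box before mask growth; the seed is the voxel attaining it.

    Raises
    ------
    SegmentationInfeasibleError
        When no meaningful VOI exists (e.g. AC_max below background, or the
        grown component floods into the surroundings).  Batch drivers catch
        this per sphere.
    """
    grid = grid or image.grid
    if method not in METHODS:
        raise InvalidArgumentError(f"unknown method {method!r}; expected one of {METHODS}")
    if method in ("ct", "ct3d"):
        return ct_reference_mask(geometry, grid, sphere_id, three_dimensional=method == "ct3d")
    if T is None:
        raise InvalidArgumentError("threshold methods require a threshold fraction T")
    region = sphere_search_region(grid, geometry, sphere_id)
    ac_max = find_max(image, region)
    if method == "threshold":
        level = plain_threshold(T, ac_max)
    else:  # adapted
        bg = estimate_background(image, geometry, grid)
        level = adapted_threshold(T, ac_max, bg)
    return grow_voi(
        image,
        level,
        ac_max.location,
        region,
        method=method,
        sphere_id=sphere_id,
        threshold=float(T),
        reject_boundary=True,
    )
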