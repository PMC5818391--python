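"""Analytic NEMA IEC body-phantom model and rasterization.

World coordinates are right-handed, in millimetres, with the origin at the
phantom centre.  A voxel's coordinate is the coordinate of its centre; voxel
indices are 0-based and axial slices are constant-z planes.  Arrays are
indexed ``[ix, iy, iz]``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator

import numpy as np
import yaml

from .errors import CoverageError, GeometryError, InvalidArgumentError

__all__ = [
    "SphereSpec",
    "CylinderSpec",
    "BodyOutline",
    "PhantomGeometry",
    "GridSpec",
    "FractionMap",
    "VOIMask",
    "sphere_volume",
    "default_nema_geometry",
    "uniform_geometry",
    "voxelize",
    "ct_reference_mask",
]

#: Diameter (mm) of the circle on which the six sphere centres sit.
SPHERE_CIRCLE_DIAMETER_MM = 114.4

#: Inner diameters (mm) of the six fillable spheres, largest first.
SPHERE_DIAMETERS_MM = (37.0, 28.0, 22.0, 17.0, 13.0, 10.0)


def sphere_volume(diameter_mm: float) -> float:
    """Volume in cm^3 of a sphere with the given inner diameter in mm.

    Parameters
    ----------
    diameter_mm : float
        Inner diameter, millimetres.  Must be positive.

    Returns
    -------
    float
        (pi/6) * d^3 with d in cm.
    """
    if diameter_mm <= 0:
        raise InvalidArgumentError(f"diameter must be positive, got {diameter_mm}")
    d_cm = diameter_mm / 10.0
    return (np.pi / 6.0) * d_cm**3


@dataclass(frozen=True)
class SphereSpec:
    """One fillable sphere: label, inner diameter and centre position."""

    id: str
    inner_diameter: float  # mm
    center: tuple[float, float, float]  # mm

    def __post_init__(self):
        if self.inner_diameter <= 0:
            raise InvalidArgumentError("sphere diameter must be positive")

    @property
    def radius(self) -> float:
        return self.inner_diameter / 2.0

    @property
    def true_volume(self) -> float:
        """Analytic volume in cm^3."""
        return sphere_volume(self.inner_diameter)

    def contains(self, x, y, z):
        cx, cy, cz = self.center
        return (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= self.radius**2


@dataclass(frozen=True)
class CylinderSpec:
    """Cylindrical insert, axis along z through the phantom centre."""

    outer_diameter: float = 51.0  # mm
    length: float = 180.0  # mm

    def __post_init__(self):
        if self.outer_diameter <= 0 or self.length <= 0:
            raise InvalidArgumentError("cylinder dimensions must be positive")

    @property
    def radius(self) -> float:
        return self.outer_diameter / 2.0

    def contains(self, x, y, z):
        return (x**2 + y**2 <= self.radius**2) & (np.abs(z) <= self.length / 2.0)


@dataclass(frozen=True)
class BodyOutline:
    """Torso cross-section approximated as a stadium, extruded in z.

    The stadium is a ``(width - height)``-long rectangle in x capped by two
    half-discs of radius ``height/2``; the exact engineering outline of the
    commercial phantom is not reproduced.
    """

    width: float = 300.0  # mm, full extent in x
    height: float = 230.0  # mm, full extent in y
    length: float = 180.0  # mm, full extent in z

    def __post_init__(self):
        if self.height > self.width:
            raise InvalidArgumentError("stadium requires width >= height")

    @property
    def cap_radius(self) -> float:
        return self.height / 2.0

    @property
    def half_straight(self) -> float:
        """Half-length of the straight section in x."""
        return (self.width - self.height) / 2.0

    def contains(self, x, y, z):
        xc = np.clip(x, -self.half_straight, self.half_straight)
        in_plane = (x - xc) ** 2 + y**2 <= self.cap_radius**2
        return in_plane & (np.abs(z) <= self.length / 2.0)

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([-self.width / 2, -self.height / 2, -self.length / 2])
        return lo, -lo


@dataclass(frozen=True)
class PhantomGeometry:
    """Spheres + lung insert + body outline, with disjoint compartments.

    Compartment labels are ``outside``, ``background``, ``lung`` and one
    ``sphere_<d>mm`` per sphere; background is body minus lung minus spheres.
    """

    spheres: tuple[SphereSpec, ...]
    lung: CylinderSpec | None = CylinderSpec()
    body: BodyOutline = field(default_factory=BodyOutline)
    sphere_plane_z: float = 0.0

    def __post_init__(self):
        self.validate()

    @property
    def compartments(self) -> tuple[str, ...]:
        names = ["outside", "background"]
        if self.lung is not None:
            names.append("lung")
        names.extend(s.id for s in self.spheres)
        return tuple(names)

    def sphere(self, sphere_id: str) -> SphereSpec:
        for s in self.spheres:
            if s.id == sphere_id:
                return s
        raise InvalidArgumentError(f"unknown sphere id {sphere_id!r}")

    def validate(self) -> None:
        """Check pairwise disjointness and body containment."""
        for s in self.spheres:
            cx, cy, cz = s.center
            # containment: the whole ball must sit inside the outline
            xc = np.clip(cx, -self.body.half_straight, self.body.half_straight)
            wall = self.body.cap_radius - np.hypot(cx - xc, cy)
            if wall < s.radius or abs(cz) + s.radius > self.body.length / 2:
                raise GeometryError(f"{s.id} extends outside the body outline")
            if self.lung is not None:
                if np.hypot(cx, cy) < self.lung.radius + s.radius:
                    raise GeometryError(f"{s.id} intersects the lung insert")
        for i, a in enumerate(self.spheres):
            for b in self.spheres[i + 1 :]:
                d = np.linalg.norm(np.subtract(a.center, b.center))
                if d < a.radius + b.radius:
                    raise GeometryError(f"{a.id} and {b.id} overlap")

    def label_points(self, x, y, z) -> np.ndarray:
        """Classify points into compartment indices (into ``compartments``)."""
        names = self.compartments
        labels = np.zeros(np.broadcast(x, y, z).shape, dtype=np.uint8)
        labels[self.body.contains(x, y, z)] = names.index("background")
        if self.lung is not None:
            labels[self.lung.contains(x, y, z)] = names.index("lung")
        for s in self.spheres:
            labels[s.contains(x, y, z)] = names.index(s.id)
        return labels

    # --- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "units": "mm",
            "spheres": [
                {
                    "id": s.id,
                    "inner_diameter": float(s.inner_diameter),
                    "center": [float(v) for v in s.center],
                }
                for s in self.spheres
            ],
            "lung": asdict(self.lung) if self.lung is not None else None,
            "body": asdict(self.body),
            "sphere_plane_z": self.sphere_plane_z,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomGeometry":
        spheres = tuple(
            SphereSpec(s["id"], s["inner_diameter"], tuple(s["center"]))
            for s in d["spheres"]
        )
        lung = CylinderSpec(**d["lung"]) if d.get("lung") else None
        body = BodyOutline(**d.get("body", {}))
        return cls(spheres, lung, body, d.get("sphere_plane_z", 0.0))

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict())
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "PhantomGeometry":
        path = Path(path)
        if path.suffix == ".json":
            return cls.from_dict(json.loads(path.read_text()))
        return cls.from_dict(yaml.safe_load(path.read_text()))


def default_nema_geometry(sphere_plane_z: float = 0.0) -> PhantomGeometry:
    """Six-sphere NEMA IEC layout: centres coplanar on a 114.4-mm circle.

    The largest sphere sits at angle 0 (positive x); diameters decrease
    counter-clockwise in 60-degree steps, so the 37- and 17-mm spheres are
    diametrically opposite.
    """
    r = SPHERE_CIRCLE_DIAMETER_MM / 2.0
    spheres = []
    for k, d in enumerate(SPHERE_DIAMETERS_MM):
        ang = np.deg2rad(60.0 * k)
        spheres.append(
            SphereSpec(
                id=f"sphere_{d:.0f}mm",
                inner_diameter=d,
                center=(r * np.cos(ang), r * np.sin(ang), sphere_plane_z),
            )
        )
    return PhantomGeometry(tuple(spheres), CylinderSpec(), BodyOutline(), sphere_plane_z)


def uniform_geometry() -> PhantomGeometry:
    """Phantom body without spheres or lung insert (calibration fill)."""
    return PhantomGeometry((), None, BodyOutline(), 0.0)


@dataclass(frozen=True)
class GridSpec:
    """Regular 3-D sampling grid; ``origin`` is the centre of voxel (0,0,0)."""

    dims: tuple[int, int, int]
    spacing: tuple[float, float, float]  # mm
    origin: tuple[float, float, float]  # mm

    def __post_init__(self):
        if any(n <= 0 for n in self.dims):
            raise InvalidArgumentError("grid dims must be positive")
        if any(s <= 0 for s in self.spacing):
            raise InvalidArgumentError("grid spacing must be positive")

    @classmethod
    def centered(cls, dims, spacing) -> "GridSpec":
        origin = tuple(-(n - 1) / 2.0 * s for n, s in zip(dims, spacing))
        return cls(tuple(dims), tuple(spacing), origin)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_ml(self) -> float:
        """Voxel volume in mL (= cm^3)."""
        return self.voxel_volume_mm3 / 1000.0

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.spacing[axis] * np.arange(self.dims[axis])

    def world_to_index(self, point) -> np.ndarray:
        """Continuous voxel index of a world point (mm)."""
        p = np.asarray(point, dtype=float)
        return (p - np.asarray(self.origin)) / np.asarray(self.spacing)

    def index_to_world(self, index) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(index) * np.asarray(self.spacing)

    def extent(self) -> tuple[np.ndarray, np.ndarray]:
        """(lo, hi) outer corners of the grid in mm (voxel faces)."""
        lo = np.asarray(self.origin) - np.asarray(self.spacing) / 2.0
        hi = lo + np.asarray(self.dims) * np.asarray(self.spacing)
        return lo, hi

    def covers(self, lo, hi) -> bool:
        glo, ghi = self.extent()
        return bool(np.all(glo <= np.asarray(lo)) and np.all(ghi >= np.asarray(hi)))

    def contains_point(self, point) -> bool:
        lo, hi = self.extent()
        p = np.asarray(point, dtype=float)
        return bool(np.all(p >= lo) and np.all(p <= hi))


@dataclass
class FractionMap:
    """Per-compartment occupancy fractions on a grid (partition of unity)."""

    grid: GridSpec
    fractions: dict[str, np.ndarray]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.fractions[name]

    def compartment_volume_ml(self, name: str) -> float:
        """Rasterized volume of a compartment in cm^3."""
        return float(self.fractions[name].sum()) * self.grid.voxel_volume_ml

    def items(self) -> Iterator[tuple[str, np.ndarray]]:
        return self.fractions.items()


@dataclass
class VOIMask:
    """Boolean voxel mask plus provenance of how it was produced."""

    mask: np.ndarray  # bool, full-grid shape
    grid: GridSpec
    method: str  # threshold | adapted | ct | ct3d
    sphere_id: str
    threshold: float | None = None  # fraction T, None for ct methods
    absolute_level: float | None = None  # image-value level actually applied

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_ml(self) -> float:
        return self.voxel_count * self.grid.voxel_volume_ml


def _subsample_offsets(subsampling: int) -> np.ndarray:
    """Centred sub-voxel offsets in units of voxel spacing, shape (s^3, 3)."""
    u = (np.arange(subsampling) + 0.5) / subsampling - 0.5
    return np.array(np.meshgrid(u, u, u, indexing="ij")).reshape(3, -1).T


def voxelize(
    geometry: PhantomGeometry,
    grid: GridSpec,
    subsampling: int = 2,
    allow_partial: bool = False,
) -> FractionMap:
    """Rasterize the phantom onto a grid as per-compartment fractions.

    Each voxel is probed at ``subsampling**3`` regularly spaced interior
    points; a compartment's fraction is the share of points landing in it,
    so fractions sum to 1 at every voxel by construction.

    Raises
    ------
    CoverageError
        If the grid extent does not contain the phantom bounding box and
        ``allow_partial`` is False.
    """
    if subsampling < 1:
        raise InvalidArgumentError("subsampling must be >= 1")
    lo, hi = geometry.body.bounding_box()
    if not allow_partial and not grid.covers(lo, hi):
        raise CoverageError("grid does not cover the phantom; pass allow_partial=True to override")

    names = geometry.compartments
    counts = np.zeros((len(names), *grid.dims), dtype=np.uint32)
    x0 = grid.axis_coords(0)
    y0 = grid.axis_coords(1)
    z0 = grid.axis_coords(2)
    for off in _subsample_offsets(subsampling):
        x = (x0 + off[0] * grid.spacing[0])[:, None, None]
        y = (y0 + off[1] * grid.spacing[1])[None, :, None]
        z = (z0 + off[2] * grid.spacing[2])[None, None, :]
        labels = geometry.label_points(x, y, z)
        for idx in range(len(names)):
            counts[idx] += labels == idx
    total = subsampling**3
    fractions = {name: counts[i] / total for i, name in enumerate(names)}
    return FractionMap(grid=grid, fractions=fractions)


def _central_slice_index(grid: GridSpec, z_mm: float) -> int:
    """Index of the axial slice nearest z_mm; ties resolve to the lower slice."""
    zc = grid.axis_coords(2)
    d = np.abs(zc - z_mm)
    # np.argmin already returns the first (lower) index on exact ties
    k = int(np.argmin(d))
    if k < 0 or k >= grid.dims[2]:  # pragma: no cover - argmin is always in range
        raise CoverageError("sphere centre outside grid")
    return k


def ct_reference_mask(
    geometry: PhantomGeometry,
    grid: GridSpec,
    sphere_id: str,
    three_dimensional: bool = False,
) -> VOIMask:
    """Ground-truth ROI transferred from the anatomical image.

    Default is a single-slice disk in the axial slice nearest the sphere
    centre: voxels whose in-plane centre distance to the sphere centre is at
    most the inner radius.  With ``three_dimensional=True`` a full spherical
    mask is produced instead (method label ``ct3d``).
    """
    sphere = geometry.sphere(sphere_id)
    if not grid.contains_point(sphere.center):
        raise CoverageError(f"{sphere_id} centre lies outside the grid")
    cx, cy, cz = sphere.center
    x = grid.axis_coords(0)[:, None, None]
    y = grid.axis_coords(1)[None, :, None]
    mask = np.zeros(grid.dims, dtype=bool)
    if three_dimensional:
        z = grid.axis_coords(2)[None, None, :]
        mask[:] = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= sphere.radius**2
        method = "ct3d"
    else:
        k = _central_slice_index(grid, cz)
        disk = ((x - cx) ** 2 + (y - cy) ** 2 <= sphere.radius**2)[:, :, 0]
        mask[:, :, k] = disk
        method = "ct"
    return VOIMask(mask=mask, grid=grid, method=method, sphere_id=sphere_id)
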