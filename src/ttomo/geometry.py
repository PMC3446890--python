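"""Voxel grids, tissue masks and slab-sectioning geometry.

The coordinate space is a regular isotropic voxel grid measured in
micrometres.  A *sectioning series* cuts the space into parallel slabs
("fractions") of fixed width along a unit normal; a *fraction template*
records, per voxel, which fraction of a series the voxel belongs to.
The volume assigned a fraction in every series of a design is the
*coverage* volume on which reconstructed maps are defined.

Axis convention: x = left->right (sagittal normal), y = posterior->anterior
(coronal normal), z = ventral->dorsal (horizontal normal).  Voxel indices
are 0-based; slab intervals are half-open [k*width, (k+1)*width) after the
offset shift; a voxel belongs to the slab containing its center (no
partial-volume weighting).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Sentinel fraction index for voxels outside a series' slab span (or outside
#: the tissue mask).
OUTSIDE = -1

_UNIT_TOL = 1e-9


@dataclass(frozen=True)
class VoxelGrid:
    """Regular isotropic 3D voxel lattice.

    Parameters
    ----------
    shape
        Number of voxels along (x, y, z).
    voxel_size
        Edge length of a voxel in micrometres (isotropic).
    origin
        Physical coordinate (µm) of the *corner* of voxel (0, 0, 0); the
        center of that voxel sits at ``origin + 0.5 * voxel_size``.
    """

    shape: tuple[int, int, int]
    voxel_size: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"grid shape must be three positive integers, got {self.shape!r}")
        if not (float(self.voxel_size) > 0):
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size!r}")
        origin = tuple(float(o) for o in self.origin)
        if len(origin) != 3:
            raise ValueError("origin must be a 3-vector")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size", float(self.voxel_size))
        object.__setattr__(self, "origin", origin)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical edge lengths of the grid box in µm."""
        return tuple(s * self.voxel_size for s in self.shape)

    def axis_centers(self, axis: int) -> np.ndarray:
        """Physical coordinates of voxel centers along one axis."""
        return self.origin[axis] + (np.arange(self.shape[axis]) + 0.5) * self.voxel_size

    def center_projections(self, normal) -> np.ndarray:
        """Dot product of every voxel center with ``normal`` (shape = grid shape)."""
        n = np.asarray(normal, dtype=float)
        cx, cy, cz = (self.axis_centers(a) for a in range(3))
        return (
            cx[:, None, None] * n[0]
            + cy[None, :, None] * n[1]
            + cz[None, None, :] * n[2]
        )

    def voxel_center(self, index) -> np.ndarray:
        """Physical center (µm) of the voxel at an integer index triple."""
        idx = np.asarray(index, dtype=float)
        return np.asarray(self.origin) + (idx + 0.5) * self.voxel_size

    def same_lattice(self, other: "VoxelGrid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.voxel_size, other.voxel_size)
            and np.allclose(self.origin, other.origin)
        )


@dataclass
class BrainMask:
    """Boolean tissue support on a grid."""

    grid: VoxelGrid
    inside: np.ndarray

    def __post_init__(self) -> None:
        self.inside = np.asarray(self.inside, dtype=bool)
        if self.inside.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid shape")
        if not self.inside.any():
            raise ValueError("mask has no inside voxels")

    @property
    def n_inside(self) -> int:
        return int(self.inside.sum())

    @property
    def volume_um3(self) -> float:
        return self.n_inside * self.grid.voxel_size**3

    def bounding_box_um(self) -> np.ndarray:
        """(2, 3) array of [min, max] in-mask voxel-center coordinates per axis."""
        idx = np.argwhere(self.inside)
        lo = self.grid.voxel_center(idx.min(axis=0))
        hi = self.grid.voxel_center(idx.max(axis=0))
        return np.stack([lo, hi])


@dataclass(frozen=True)
class SectioningSeries:
    """One complete slab sectioning of the space along a fixed direction.

    ``offset`` is the position (µm, along the normal) of the first slab
    boundary; slab k occupies [offset + k*width, offset + (k+1)*width).
    """

    series_id: str
    normal: tuple[float, float, float]
    width: float
    offset: float
    n_fractions: int

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        if n.shape != (3,):
            raise ValueError("normal must be a 3-vector")
        if abs(np.linalg.norm(n) - 1.0) > _UNIT_TOL:
            raise ValueError(f"series {self.series_id!r}: normal must be a unit vector")
        if not (float(self.width) > 0):
            raise ValueError("slab width must be positive")
        if int(self.n_fractions) < 1:
            raise ValueError("n_fractions must be >= 1")
        object.__setattr__(self, "normal", tuple(float(x) for x in n))
        object.__setattr__(self, "width", float(self.width))
        object.__setattr__(self, "offset", float(self.offset))
        object.__setattr__(self, "n_fractions", int(self.n_fractions))

    @property
    def span_um(self) -> float:
        return self.n_fractions * self.width

    @property
    def fraction_ids(self) -> list[str]:
        return [f"{self.series_id}{k + 1}" for k in range(self.n_fractions)]

    def to_dict(self) -> dict:
        return {
            "series_id": self.series_id,
            "normal": list(self.normal),
            "width_um": self.width,
            "offset_um": self.offset,
            "n_fractions": self.n_fractions,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SectioningSeries":
        return cls(
            series_id=d["series_id"],
            normal=tuple(d["normal"]),
            width=d["width_um"],
            offset=d["offset_um"],
            n_fractions=d["n_fractions"],
        )


def slab_index(point, series: SectioningSeries) -> int:
    """Fraction index of a physical point, or :data:`OUTSIDE`.

    The point belongs to fraction k = floor((p.n - offset) / width) when that
    value lies in [0, n_fractions); the right edge of the span is exclusive.
    """
    p = np.asarray(point, dtype=float)
    proj = float(p @ np.asarray(series.normal))
    k = int(np.floor((proj - series.offset) / series.width))
    if 0 <= k < series.n_fractions:
        return k
    return OUTSIDE


@dataclass
class FractionTemplate:
    """Per-voxel fraction membership of one series, restricted to a mask.

    ``fraction_of_voxel`` holds the fraction index for in-mask voxels whose
    center falls in the series' span and :data:`OUTSIDE` (-1) everywhere else.
    """

    series: SectioningSeries
    grid: VoxelGrid
    fraction_of_voxel: np.ndarray
    fraction_volumes: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.fraction_of_voxel = np.asarray(self.fraction_of_voxel, dtype=np.int32)
        if self.fraction_of_voxel.shape != self.grid.shape:
            raise ValueError("fraction_of_voxel shape does not match grid")
        if self.fraction_volumes is None:
            assigned = self.fraction_of_voxel[self.fraction_of_voxel >= 0]
            self.fraction_volumes = np.bincount(assigned, minlength=self.series.n_fractions)
        self.fraction_volumes = np.asarray(self.fraction_volumes, dtype=np.int64)

    @property
    def assigned(self) -> np.ndarray:
        """Boolean volume of voxels carrying a fraction index."""
        return self.fraction_of_voxel >= 0

    @property
    def n_assigned(self) -> int:
        return int(self.fraction_volumes.sum())


def build_fraction_template(
    grid: VoxelGrid, mask: BrainMask, series: SectioningSeries
) -> FractionTemplate:
    """Assign every in-mask voxel center to a fraction of ``series``."""
    if grid.shape != mask.grid.shape:
        raise ValueError("grid and mask shapes differ")
    proj = grid.center_projections(series.normal)
    idx = np.floor((proj - series.offset) / series.width).astype(np.int64)
    valid = mask.inside & (idx >= 0) & (idx < series.n_fractions)
    if not valid.any():
        raise ValueError(f"empty template: series {series.series_id!r} covers no in-mask voxels")
    fov = np.where(valid, idx, OUTSIDE).astype(np.int32)
    volumes = np.bincount(fov[valid], minlength=series.n_fractions).astype(np.int64)
    return FractionTemplate(series=series, grid=grid, fraction_of_voxel=fov, fraction_volumes=volumes)


@dataclass
class CoverageMask:
    """Voxels assigned a fraction in *every* series of a design."""

    grid: VoxelGrid
    covered: np.ndarray

    def __post_init__(self) -> None:
        self.covered = np.asarray(self.covered, dtype=bool)
        if self.covered.shape != self.grid.shape:
            raise ValueError("coverage shape does not match grid")

    @property
    def n_covered(self) -> int:
        return int(self.covered.sum())


def coverage(templates: list[FractionTemplate]) -> CoverageMask:
    """Intersection of per-series covered sets (the common mapping volume)."""
    if not templates:
        raise ValueError("coverage requires at least one fraction template")
    grid = templates[0].grid
    covered = np.ones(grid.shape, dtype=bool)
    for t in templates:
        if t.grid.shape != grid.shape:
            raise ValueError("templates are defined on different grids")
        covered &= t.assigned
    return CoverageMask(grid=grid, covered=covered)


def _rotate(vec, axis: int, angle_deg: float) -> tuple[float, float, float]:
    """Rotate a 3-vector about one coordinate axis."""
    th = np.deg2rad(angle_deg)
    c, s = np.cos(th), np.sin(th)
    v = np.asarray(vec, dtype=float)
    if axis == 0:
        rot = np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
    elif axis == 1:
        rot = np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])
    else:
        rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
    out = rot @ v
    out /= np.linalg.norm(out)
    return tuple(out)

# Reference design: orthogonal sagittal/coronal/horizontal series and their
# slightly oblique counterparts, 61 fractions of 1,000 µm in total.
_DESIGN_FRACTIONS = {"S": 9, "C": 13, "H": 6, "So": 10, "Co": 16, "Ho": 7}
_AXIS_NORMALS = {"S": (1.0, 0.0, 0.0), "C": (0.0, 1.0, 0.0), "H": (0.0, 0.0, 1.0)}
# Oblique normals tilt each orthogonal normal about a fixed perpendicular axis.
_OBLIQUE_ROT_AXIS = {"So": 2, "Co": 2, "Ho": 0}


def _centered_series(
    series_id: str,
    normal,
    n_fractions: int,
    width: float,
    mask: BrainMask,
) -> SectioningSeries:
    proj = mask.grid.center_projections(normal)[mask.inside]
    pmin, pmax = float(proj.min()), float(proj.max())
    span = n_fractions * width
    if pmax - pmin >= span:
        raise ValueError(
            f"mask larger than the fraction span for series {series_id!r}: "
            f"extent {pmax - pmin:.1f} µm >= span {span:.1f} µm"
        )
    offset = 0.5 * (pmin + pmax) - 0.5 * span
    return SectioningSeries(
        series_id=series_id, normal=tuple(normal), width=width,
        offset=offset, n_fractions=n_fractions,
    )


def default_design(
    grid: VoxelGrid,
    mask: BrainMask,
    oblique_angle_deg: float | dict = 10.0,
    width_um: float = 1000.0,
) -> list[SectioningSeries]:
    """The 6-series / 61-fraction reference design.

    S/C/H are axis-aligned with 9/13/6 fractions; So/Co/Ho are tilted by
    ``oblique_angle_deg`` (a single angle, or a {series_id: angle} mapping
    for per-series tilts) with 10/16/7 fractions.  Each series' slab span
    is centered on the mask along its normal; a mask wider than a span
    raises.
    """
    series = []
    for sid in ("S", "C", "H", "So", "Co", "Ho"):
        base = sid.rstrip("o")
        normal = _AXIS_NORMALS[base]
        if sid.endswith("o"):
            angle = (
                oblique_angle_deg.get(sid, 10.0)
                if isinstance(oblique_angle_deg, dict)
                else oblique_angle_deg
            )
            normal = _rotate(normal, _OBLIQUE_ROT_AXIS[sid], angle)
        series.append(
            _centered_series(sid, normal, _DESIGN_FRACTIONS[sid], width_um, mask)
        )
    return series


def sphere_voxel_mask(grid: VoxelGrid, center_um, diameter_um: float) -> np.ndarray:
    """Boolean volume of voxels whose center lies within a physical sphere.

    The sphere is clipped to the grid; portions outside the box are simply
    not represented.
    """
    if not (diameter_um > 0):
        raise ValueError("sphere diameter must be positive")
    c = np.asarray(center_um, dtype=float)
    r = diameter_um / 2.0
    out = np.zeros(grid.shape, dtype=bool)
    lo, hi, axes = [], [], []
    for a in range(3):
        centers = grid.axis_centers(a)
        i0 = int(np.searchsorted(centers, c[a] - r, side="left"))
        i1 = int(np.searchsorted(centers, c[a] + r, side="right"))
        if i0 >= i1:
            return out
        lo.append(i0)
        hi.append(i1)
        axes.append(centers[i0:i1] - c[a])
    dx, dy, dz = axes
    d2 = (
        dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2
    )
    out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = d2 <= r * r
    return out
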