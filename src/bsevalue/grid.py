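"""Site grid, planar projection, and exclusion masks.

A *site* is deliberately scale-flexible in this framework; here it is realized
as one cell of a regular grid in a local planar frame.  Cells are half-open
``[x, x + cell) x [y, y + cell)`` with the origin at the lower-left corner, so
every in-extent point belongs to exactly one cell.  Site ids are ``"ix_iy"``.

Longitude/latitude I/O is converted to the planar frame with an
equirectangular projection about a local anchor; intended extents are
local-to-regional, where the approximation error is negligible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point, Polygon

EARTH_RADIUS_M = 6_371_000.0


class OutOfExtentError(ValueError):
    """A point falls outside the grid extent."""


@dataclass(frozen=True)
class EquirectangularProjection:
    """Local equirectangular (plate carree) projection about an anchor.

    ``x = R cos(lat0) (lon - lon0)``, ``y = R (lat - lat0)`` with angles in
    radians; adequate for the local-to-regional extents this package targets.
    """

    lon0: float
    lat0: float

    def to_xy(self, lon, lat):
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        k = EARTH_RADIUS_M * np.pi / 180.0
        x = k * np.cos(np.deg2rad(self.lat0)) * (lon - self.lon0)
        y = k * (lat - self.lat0)
        return x, y

    def to_lonlat(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        k = EARTH_RADIUS_M * np.pi / 180.0
        lon = self.lon0 + x / (k * np.cos(np.deg2rad(self.lat0)))
        lat = self.lat0 + y / k
        return lon, lat


@dataclass(frozen=True)
class SiteGrid:
    """Regular grid of half-open square cells in a projected planar frame."""

    origin_x: float
    origin_y: float
    cell_size: float
    n_x: int
    n_y: int
    crs_note: str = "local equirectangular meters"
    projection: EquirectangularProjection = field(
        default_factory=lambda: EquirectangularProjection(151.0, -33.8)
    )

    def __post_init__(self):
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if self.n_x < 1 or self.n_y < 1:
            raise ValueError("grid dimensions must be positive")

    @property
    def n_sites(self) -> int:
        return self.n_x * self.n_y

    @property
    def extent(self):
        """(xmin, ymin, xmax, ymax) of the grid."""
        return (
            self.origin_x,
            self.origin_y,
            self.origin_x + self.n_x * self.cell_size,
            self.origin_y + self.n_y * self.cell_size,
        )

    @property
    def diagonal(self) -> float:
        return float(np.hypot(self.n_x * self.cell_size, self.n_y * self.cell_size))

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Return (ix, iy) of the half-open cell containing a planar point."""
        ix = int(np.floor((x - self.origin_x) / self.cell_size))
        iy = int(np.floor((y - self.origin_y) / self.cell_size))
        if not (0 <= ix < self.n_x and 0 <= iy < self.n_y):
            raise OutOfExtentError(
                f"point ({x}, {y}) outside grid extent {self.extent}"
            )
        return ix, iy

    def site_id(self, ix: int, iy: int) -> str:
        return f"{ix}_{iy}"

    def parse_site_id(self, site_id: str) -> tuple[int, int]:
        ix_s, iy_s = site_id.split("_")
        ix, iy = int(ix_s), int(iy_s)
        if not (0 <= ix < self.n_x and 0 <= iy < self.n_y):
            raise ValueError(f"site id {site_id!r} outside grid")
        return ix, iy

    def site_index(self, site_id: str) -> int:
        ix, iy = self.parse_site_id(site_id)
        return iy * self.n_x + ix

    def all_site_ids(self) -> list[str]:
        """Site ids in canonical order (row-major, ix fastest)."""
        return [
            self.site_id(ix, iy)
            for iy in range(self.n_y)
            for ix in range(self.n_x)
        ]

    def centers(self) -> np.ndarray:
        """(n_sites, 2) array of cell centers, canonical order."""
        xs = self.origin_x + (np.arange(self.n_x) + 0.5) * self.cell_size
        ys = self.origin_y + (np.arange(self.n_y) + 0.5) * self.cell_size
        gx, gy = np.meshgrid(xs, ys)
        return np.column_stack([gx.ravel(), gy.ravel()])

    def cell_polygon(self, ix: int, iy: int) -> list[tuple[float, float]]:
        """Closed ring of the cell's corners in planar coordinates."""
        x0 = self.origin_x + ix * self.cell_size
        y0 = self.origin_y + iy * self.cell_size
        d = self.cell_size
        return [(x0, y0), (x0 + d, y0), (x0 + d, y0 + d), (x0, y0 + d), (x0, y0)]


@dataclass
class ExclusionMask:
    """Polygons (private land, sensitive habitat) whose sites must never be
    recommended.  Containment is tested against site *centers* — deterministic
    and unambiguous at grid scale."""

    polygons: list[Polygon]
    labels: list[str]

    def __post_init__(self):
        if len(self.polygons) != len(self.labels):
            raise ValueError("one label per polygon required")
        for poly, label in zip(self.polygons, self.labels):
            if not poly.is_valid:
                raise ValueError(f"exclusion polygon {label!r} is not a valid simple polygon")

    @classmethod
    def empty(cls) -> "ExclusionMask":
        return cls(polygons=[], labels=[])

    def contains_point(self, x: float, y: float) -> bool:
        if not self.polygons:
            return False
        pt = Point(x, y)
        return any(poly.covers(pt) for poly in self.polygons)

    def excluded_sites(self, grid: SiteGrid) -> set[str]:
        """Site ids whose centers fall inside any exclusion polygon."""
        out: set[str] = set()
        centers = grid.centers()
        ids = grid.all_site_ids()
        for sid, (cx, cy) in zip(ids, centers):
            if self.contains_point(cx, cy):
                out.add(sid)
        return out
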