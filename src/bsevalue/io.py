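"""Records and file I/O: BSE tables (CSV), priority maps and exclusion masks (GeoJSON).

The atomic data unit is the *biodiversity sampling event* (BSE): one
observation of a taxon with coordinates and a timestamp.  BSE tables are plain
CSV with the exact ordered columns::

    observation_id, lon, lat, timestamp, species_code, observer_id

Rows that fail validation are rejected with a reason and reported — never
silently dropped and never repaired.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .grid import ExclusionMask, SiteGrid

logger = logging.getLogger(__name__)

BSE_COLUMNS = ["observation_id", "lon", "lat", "timestamp", "species_code", "observer_id"]

#: species code used for a checklist event in which the focal species was not recorded
NO_DETECTION = "NONE"


class MissingColumnError(ValueError):
    """A required CSV column is absent."""


@dataclass(frozen=True)
class BSERecord:
    """One biodiversity sampling event."""

    observation_id: str
    lon: float
    lat: float
    timestamp: pd.Timestamp  # tz-aware UTC
    species_code: str
    observer_id: str
    site_id: str | None = None

    @property
    def day(self) -> int:
        """UTC day as a proleptic-Gregorian ordinal (interval arithmetic unit)."""
        return self.timestamp.tz_convert("UTC").date().toordinal()

    def detected(self) -> bool:
        return self.species_code != NO_DETECTION


@dataclass
class BSEReadResult:
    """Accepted records plus a per-row rejection report."""

    records: list[BSERecord]
    rejected: pd.DataFrame  # columns: row, observation_id, reason

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def read_bse_csv(path: str | Path) -> BSEReadResult:
    """Read a BSE table, validating each row.

    Raises :class:`MissingColumnError` if a required column is absent.  Rows
    with out-of-range coordinates, unparseable timestamps, or duplicate
    observation ids are rejected row-wise with a reason.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in BSE_COLUMNS:
        if col not in df.columns:
            raise MissingColumnError(f"required column {col!r} missing from {path}")

    records: list[BSERecord] = []
    rejects: list[tuple[int, str, str]] = []
    seen_ids: set[str] = set()
    for row_number, row in enumerate(df.itertuples(index=False), start=2):
        reason = None
        lon = lat = np.nan
        ts = None
        try:
            lon = float(row.lon)
            lat = float(row.lat)
        except ValueError:
            reason = "unparseable coordinate"
        if reason is None and not (-180.0 <= lon <= 180.0):
            reason = "longitude out of range"
        if reason is None and not (-90.0 <= lat <= 90.0):
            reason = "latitude out of range"
        if reason is None:
            try:
                ts = pd.Timestamp(row.timestamp)
                ts = ts.tz_localize("UTC") if ts.tzinfo is None else ts.tz_convert("UTC")
            except (ValueError, TypeError):
                reason = "unparseable timestamp"
        if reason is None and not row.observation_id:
            reason = "empty observation_id"
        if reason is None and row.observation_id in seen_ids:
            reason = "duplicate observation_id"

        if reason is not None:
            rejects.append((row_number, row.observation_id, reason))
            logger.warning("rejected row %d (%s): %s", row_number, row.observation_id, reason)
            continue
        seen_ids.add(row.observation_id)
        records.append(
            BSERecord(
                observation_id=row.observation_id,
                lon=lon,
                lat=lat,
                timestamp=ts,
                species_code=row.species_code,
                observer_id=row.observer_id,
            )
        )
    rejected = pd.DataFrame(rejects, columns=["row", "observation_id", "reason"])
    return BSEReadResult(records=records, rejected=rejected)


def write_bse_csv(records: list[BSERecord], path: str | Path) -> None:
    """Write records in the canonical column order (lossless round-trip)."""
    rows = [
        {
            "observation_id": r.observation_id,
            "lon": repr(r.lon),
            "lat": repr(r.lat),
            "timestamp": r.timestamp.tz_convert("UTC").isoformat(),
            "species_code": r.species_code,
            "observer_id": r.observer_id,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=BSE_COLUMNS).to_csv(path, index=False)


def attach_sites(records: list[BSERecord], grid: SiteGrid) -> list[BSERecord]:
    """Project lon/lat into the grid frame and assign each record its site id."""
    out = []
    for r in records:
        out.append(replace(r, site_id=assign_site(r, grid)))
    return out


def assign_site(record: BSERecord, grid: SiteGrid) -> str:
    """Site id of the unique half-open cell containing the record's location.

    Raises :class:`~bsevalue.grid.OutOfExtentError` for points outside the grid.
    """
    x, y = grid.projection.to_xy(record.lon, record.lat)
    ix, iy = grid.cell_of(float(x), float(y))
    return grid.site_id(ix, iy)


# ---------------------------------------------------------------------------
# GeoJSON (RFC 7946)
# ---------------------------------------------------------------------------

def write_priority_geojson(surface, grid: SiteGrid, path: str | Path) -> None:
    """Write a marginal-value surface as a GeoJSON FeatureCollection.

    One polygon feature per site with properties
    ``{site_id, raw_value, normalized_value, rank}``.  Raises ``ValueError``
    on an empty surface rather than writing an empty file.
    """
    frame = surface.frame
    if frame.empty:
        raise ValueError("refusing to write an empty priority surface")
    features = []
    for row in frame.itertuples(index=False):
        ix, iy = grid.parse_site_id(row.site_id)
        ring = [
            list(grid.projection.to_lonlat(x, y))
            for x, y in grid.cell_polygon(ix, iy)
        ]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {
                    "site_id": row.site_id,
                    "raw_value": float(row.raw_value),
                    "normalized_value": float(row.normalized_value),
                    "rank": int(row.rank),
                },
            }
        )
    collection = {
        "type": "FeatureCollection",
        "as_of_date": str(surface.as_of_date),
        "features": features,
    }
    Path(path).write_text(json.dumps(collection))


def read_priority_geojson(path: str | Path) -> pd.DataFrame:
    """Read back a priority GeoJSON as a frame of per-site properties."""
    collection = json.loads(Path(path).read_text())
    if collection.get("type") != "FeatureCollection":
        raise ValueError("not a GeoJSON FeatureCollection")
    rows = [f["properties"] for f in collection["features"]]
    return pd.DataFrame(rows, columns=["site_id", "raw_value", "normalized_value", "rank"])


def read_exclusion_geojson(path: str | Path, grid: SiteGrid) -> ExclusionMask:
    """Read exclusion polygons (lon/lat rings) into grid coordinates."""
    collection = json.loads(Path(path).read_text())
    polygons, labels = [], []
    for i, feature in enumerate(collection.get("features", [])):
        geom = feature["geometry"]
        if geom["type"] != "Polygon":
            raise ValueError(f"exclusion feature {i} is not a Polygon")
        ring = geom["coordinates"][0]
        xy = [grid.projection.to_xy(lon, lat) for lon, lat in ring]
        polygons.append(Polygon([(float(x), float(y)) for x, y in xy]))
        labels.append(str(feature.get("properties", {}).get("label", f"exclusion_{i}")))
    return ExclusionMask(polygons=polygons, labels=labels)


def write_exclusion_geojson(mask: ExclusionMask, grid: SiteGrid, path: str | Path) -> None:
    features = []
    for poly, label in zip(mask.polygons, mask.labels):
        ring = [
            list(grid.projection.to_lonlat(x, y))
            for x, y in poly.exterior.coords
        ]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {"label": label},
            }
        )
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))
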