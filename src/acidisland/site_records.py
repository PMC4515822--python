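"""Data model and I/O for site tables, city registries and region polygons.

The site CSV dialect is UTF-8, comma-separated, "." decimal, header
mandatory. One row is one (site, medium) pair: a site measured in both
bulk precipitation and throughfall appears as two rows sharing ``site_id``.
Validation is strict-reject per row — literature-compiled tables are
ragged, so a bad row is dropped with a row-indexed diagnostic rather than
aborting the whole file.

Columns: site_id, latitude, longitude, precipitation_mm, medium, ph,
conc_so4_ueq_l, conc_no3_ueq_l, conc_nh4_ueq_l, obs_years, distance_km
(the last seven optional / nullable). City CSV columns: name, latitude,
longitude, nonag_population. Regions are GeoJSON Polygon/MultiPolygon in
WGS84 lon/lat.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping, shape

from . import geodesy
from .errors import DomainError, RowError, SchemaError

logger = logging.getLogger(__name__)

SITE_COLUMNS = [
    "site_id",
    "latitude",
    "longitude",
    "precipitation_mm",
    "medium",
    "ph",
    "conc_so4_ueq_l",
    "conc_no3_ueq_l",
    "conc_nh4_ueq_l",
    "obs_years",
    "distance_km",
]
REQUIRED_SITE_COLUMNS = ["site_id", "latitude", "longitude", "precipitation_mm", "medium"]
CITY_COLUMNS = ["name", "latitude", "longitude", "nonag_population"]

#: Default inclusion threshold for "large" cities (persons, strict >).
LARGE_CITY_POPULATION = 500_000


class Medium(str, Enum):
    BULK = "bulk"
    THROUGHFALL = "throughfall"


@dataclass(frozen=True)
class SiteRecord:
    """One monitoring site's location, precipitation and VWM chemistry.

    Concentration fields are nullable: a record contributes to the
    analysis of ion i only if conc_i is non-null, so per-ion sample sizes
    may differ.
    """

    site_id: str
    latitude: float
    longitude: float
    precipitation: float  # mm yr-1
    medium: Medium
    ph: float | None = None
    conc_so4: float | None = None  # ueq L-1
    conc_no3: float | None = None
    conc_nh4: float | None = None
    obs_years: str = ""
    distance_km: float | None = None

    def __post_init__(self) -> None:
        if not self.site_id:
            raise RowError("site_id must be non-empty")
        if not -90.0 <= self.latitude <= 90.0:
            raise RowError(f"latitude {self.latitude} outside [-90, 90]")
        if not -180.0 <= self.longitude <= 180.0:
            raise RowError(f"longitude {self.longitude} outside [-180, 180]")
        if not self.precipitation > 0:
            raise RowError("precipitation must be > 0 mm yr-1")
        if self.ph is not None and not (0.0 < self.ph < 14.0):
            raise RowError(f"ph {self.ph} outside (0, 14)")
        for name in ("conc_so4", "conc_no3", "conc_nh4"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise RowError(f"{name} must be >= 0")
        if self.distance_km is not None and not self.distance_km > 0:
            raise RowError("distance_km must be > 0 when provided")


@dataclass(frozen=True)
class CityRecord:
    """A large-city center: coordinates plus nonagricultural population."""

    name: str
    latitude: float
    longitude: float
    nonag_population: float

    def __post_init__(self) -> None:
        if not self.name:
            raise RowError("city name must be non-empty")
        if not -90.0 <= self.latitude <= 90.0:
            raise RowError(f"latitude {self.latitude} outside [-90, 90]")
        if not -180.0 <= self.longitude <= 180.0:
            raise RowError(f"longitude {self.longitude} outside [-180, 180]")
        if self.nonag_population < 0:
            raise RowError("nonag_population must be >= 0")


class RegionPolygon:
    """A study-region boundary in WGS84 lon/lat with a spherical area.

    Wraps a shapely Polygon/MultiPolygon whose edges are straight in
    lon/lat space. The area is computed by densifying edges and projecting
    to a Lambert azimuthal equal-area plane centered on the region.
    """

    def __init__(self, geometry) -> None:
        geometry = shape(geometry) if isinstance(geometry, dict) else geometry
        if geometry.geom_type not in ("Polygon", "MultiPolygon"):
            raise DomainError(f"region must be Polygon/MultiPolygon, got {geometry.geom_type}")
        if not geometry.is_valid:
            raise DomainError("region polygon is invalid (self-intersecting?)")
        if geometry.is_empty:
            raise DomainError("region polygon is empty")
        self.geometry = geometry
        c = geometry.centroid
        self.center_lon = float(c.x)
        self.center_lat = float(c.y)
        self._area_km2: float | None = None

    @classmethod
    def rectangle(cls, lon_min: float, lat_min: float, lon_max: float, lat_max: float) -> "RegionPolygon":
        return cls(shapely.box(lon_min, lat_min, lon_max, lat_max))

    @classmethod
    def from_geojson(cls, path: str | Path) -> "RegionPolygon":
        with open(path, encoding="utf-8") as fh:
            gj = json.load(fh)
        if gj.get("type") == "FeatureCollection":
            gj = gj["features"][0]["geometry"]
        elif gj.get("type") == "Feature":
            gj = gj["geometry"]
        return cls(gj)

    def to_geojson(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(mapping(self.geometry), fh)

    def projected(self, max_segment_deg: float = 0.05):
        """The region projected to the LAEA plane (km), edges densified so
        that lon/lat-straight edges stay straight after projection."""
        dense = shapely.segmentize(self.geometry, max_segment_deg)
        return shapely.transform(
            dense,
            lambda coords: np.column_stack(
                geodesy.laea_forward(coords[:, 1], coords[:, 0], self.center_lat, self.center_lon)
            ),
        )

    @property
    def area_km2(self) -> float:
        if self._area_km2 is None:
            a = float(self.projected().area)
            if not a > 0:
                raise DomainError("region area must be > 0")
            self._area_km2 = a
        return self._area_km2

    def contains_points(self, lons, lats):
        return shapely.contains_xy(self.geometry, lons, lats)


# ---------------------------------------------------------------------------
# CSV readers


def _to_float(cell: Any, column: str, allow_null: bool) -> float | None:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell).strip() == "":
        if allow_null:
            return None
        raise RowError(f"missing value in required column {column!r}")
    try:
        return float(cell)
    except (TypeError, ValueError):
        raise RowError(f"non-numeric value {cell!r} in column {column!r}") from None


def read_sites(
    path: str | Path,
    medium_filter: Medium | str | None = None,
    *,
    return_diagnostics: bool = False,
):
    """Read and validate a site table.

    Rows violating record invariants are rejected individually; each
    rejection is logged with its 0-based data-row index and reason. With
    ``return_diagnostics=True`` the list of (row_index, message) pairs is
    returned alongside the records.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_SITE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"site table {path} missing required column(s): {', '.join(missing)}")
    if medium_filter is not None:
        medium_filter = Medium(medium_filter)

    records: list[SiteRecord] = []
    diagnostics: list[tuple[int, str]] = []
    for idx, row in df.iterrows():
        try:
            medium = Medium(str(row["medium"]).strip().lower())
            rec = SiteRecord(
                site_id=str(row["site_id"]).strip(),
                latitude=_to_float(row["latitude"], "latitude", False),
                longitude=_to_float(row["longitude"], "longitude", False),
                precipitation=_to_float(row["precipitation_mm"], "precipitation_mm", False),
                medium=medium,
                ph=_to_float(row.get("ph"), "ph", True),
                conc_so4=_to_float(row.get("conc_so4_ueq_l"), "conc_so4_ueq_l", True),
                conc_no3=_to_float(row.get("conc_no3_ueq_l"), "conc_no3_ueq_l", True),
                conc_nh4=_to_float(row.get("conc_nh4_ueq_l"), "conc_nh4_ueq_l", True),
                obs_years=str(row.get("obs_years", "") or ""),
                distance_km=_to_float(row.get("distance_km"), "distance_km", True),
            )
        except (RowError, ValueError) as exc:
            logger.warning("rejecting site row %d: %s", idx, exc)
            diagnostics.append((int(idx), str(exc)))
            continue
        if medium_filter is None or rec.medium is medium_filter:
            records.append(rec)
    if return_diagnostics:
        return records, diagnostics
    return records


def write_sites(records: Iterable[SiteRecord], path: str | Path) -> None:
    """Write site records in the package CSV dialect (round-trips exactly)."""
    rows = []
    for r in records:
        rows.append(
            {
                "site_id": r.site_id,
                "latitude": repr(r.latitude),
                "longitude": repr(r.longitude),
                "precipitation_mm": repr(r.precipitation),
                "medium": r.medium.value,
                "ph": "" if r.ph is None else repr(r.ph),
                "conc_so4_ueq_l": "" if r.conc_so4 is None else repr(r.conc_so4),
                "conc_no3_ueq_l": "" if r.conc_no3 is None else repr(r.conc_no3),
                "conc_nh4_ueq_l": "" if r.conc_nh4 is None else repr(r.conc_nh4),
                "obs_years": r.obs_years,
                "distance_km": "" if r.distance_km is None else repr(r.distance_km),
            }
        )
    pd.DataFrame(rows, columns=SITE_COLUMNS).to_csv(path, index=False)


def read_cities(
    path: str | Path, min_population: float = LARGE_CITY_POPULATION
) -> list[CityRecord]:
    """Read a city registry, keeping cities with nonag_population strictly
    greater than ``min_population``.

    An empty result is a warning, not an error: downstream distances are
    then undefined. Duplicate names at distinct coordinates are kept with
    a warning.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CITY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"city registry {path} missing required column(s): {', '.join(missing)}")
    cities: list[CityRecord] = []
    for idx, row in df.iterrows():
        try:
            rec = CityRecord(
                name=str(row["name"]).strip(),
                latitude=_to_float(row["latitude"], "latitude", False),
                longitude=_to_float(row["longitude"], "longitude", False),
                nonag_population=_to_float(row["nonag_population"], "nonag_population", False),
            )
        except RowError as exc:
            logger.warning("rejecting city row %d: %s", idx, exc)
            continue
        if rec.nonag_population > min_population:
            cities.append(rec)
    names = [c.name for c in cities]
    for name in sorted(set(n for n in names if names.count(n) > 1)):
        logger.warning("duplicate city name %r at distinct rows; all retained", name)
    if not cities:
        logger.warning("city registry %s yielded no cities above %g", path, min_population)
    return cities


def write_cities(cities: Iterable[CityRecord], path: str | Path) -> None:
    rows = [
        {
            "name": c.name,
            "latitude": repr(c.latitude),
            "longitude": repr(c.longitude),
            "nonag_population": repr(c.nonag_population),
        }
        for c in cities
    ]
    pd.DataFrame(rows, columns=CITY_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Report bundle


def write_report(result_bundle: dict, out_dir: str | Path) -> dict[str, Path]:
    """Serialize a completed pipeline bundle.

    Writes ``report.json`` (fits, radius, area, summaries, resolved
    config) and ``sites_derived.csv`` (per-site fluxes and distances) into
    ``out_dir``. Numeric fields round-trip at full double precision.
    Missing sections are written as explicit nulls.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle = dict(result_bundle)
    table = bundle.pop("site_table", None)
    report_path = out_dir / "report.json"
    with open(report_path, "w", encoding="utf-8") as fh:
        json.dump(bundle, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")
    paths = {"report": report_path}
    if table is not None:
        csv_path = out_dir / "sites_derived.csv"
        pd.DataFrame(table).to_csv(csv_path, index=False)
        paths["sites"] = csv_path
    return paths


def read_report(out_dir: str | Path) -> dict:
    with open(Path(out_dir) / "report.json", encoding="utf-8") as fh:
        return json.load(fh)
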