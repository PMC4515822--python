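"""Acid-island computations: potential acid load, critical radius, island
area, enrichment ratios and emission-equivalent acidity.

The potential acid load (PAL) at distance r from a city is the proton
load realized after complete nitrification of deposited ammonium,

    PAL(r) = F_H(r) + 2 * F_NH4(r)   [keq ha-1 yr-1],

where F_H and F_NH4 are fitted power-law curves of H+ and NH4+
deposition flux versus distance. Throughfall fluxes are used by default
(throughfall approximates total deposition better than bulk
precipitation); a bulk-based curve is available for sensitivity
analysis. The critical radius r* solves PAL(r*) = CL for a critical
acid load CL (default 2 keq ha-1 yr-1, the regional maximum for
acid-sensitive soils); inside r* the soil's critical load is exceeded,
and the disc of radius r* around each large city is its "acid island".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon

from . import geodesy
from .chem_units import Ion
from .empirical_fits import PowerLawFit
from .errors import BracketError, DomainError, NonMonotoneError
from .site_records import CityRecord, RegionPolygon

logger = logging.getLogger(__name__)

DEFAULT_CRITICAL_LOAD = 2.0  # keq ha-1 yr-1
BISECTION_BRACKET_KM = (1.0, 10_000.0)
BISECTION_LOAD_TOL = 1e-9  # keq ha-1 yr-1
DEFAULT_MC_POINTS = 1_000_000

#: Molar masses (g mol-1) and acid equivalents per mol for precursor gases.
MOLAR_MASS_S = 32.06
MOLAR_MASS_N = 14.007
SO2_EQ_PER_MOL = 2.0  # SO2 -> H2SO4 yields two protons per S


@dataclass(frozen=True)
class AcidLoadCurve:
    """PAL(r) assembled from H+ and NH4+ flux power-law fits."""

    fit_h: PowerLawFit
    fit_nh4: PowerLawFit
    critical_load: float = DEFAULT_CRITICAL_LOAD

    def well_posed(self) -> bool:
        """Both exponents negative, so PAL is strictly decreasing."""
        return self.fit_h.b < 0 and self.fit_nh4.b < 0


@dataclass(frozen=True)
class AcidIslandResult:
    critical_radius_km: float
    islands: list = field(default_factory=list)  # (city_name, radius_km)
    union_area_km2: float | None = None
    region_area_km2: float | None = None
    fraction: float | None = None
    area_method: str | None = None
    mc_se_area_km2: float | None = None
    no_island: bool = False

    def to_dict(self) -> dict:
        return {
            "critical_radius_km": self.critical_radius_km,
            "no_island": self.no_island,
            "islands": [{"city": c, "radius_km": r} for c, r in self.islands],
            "union_area_km2": self.union_area_km2,
            "region_area_km2": self.region_area_km2,
            "fraction": self.fraction,
            "area_method": self.area_method,
            "mc_se_area_km2": self.mc_se_area_km2,
        }


def potential_acid_load(r, curve: AcidLoadCurve):
    """PAL(r) = a_H r**b_H + 2 a_N r**b_N, keq ha-1 yr-1."""
    r = np.asarray(r, dtype=float)
    pal = curve.fit_h.a * r**curve.fit_h.b + 2.0 * curve.fit_nh4.a * r**curve.fit_nh4.b
    if pal.ndim == 0:
        return float(pal)
    return pal


def critical_radius(curve: AcidLoadCurve) -> tuple[float, bool]:
    """Solve PAL(r*) = critical_load by bisection on [1, 10000] km.

    Returns (r*, no_island). The load at r* matches the critical load to
    1e-9 keq ha-1 yr-1. If the load never exceeds the critical load even
    at the inner bracket edge there is no island: (0, True) is returned
    with a warning. A curve whose load still exceeds the critical load at
    10000 km has no meaningful regional radius and raises BracketError;
    a non-decreasing curve raises NonMonotoneError.
    """
    if not curve.well_posed():
        raise NonMonotoneError(
            f"PAL not strictly decreasing: exponents b_H={curve.fit_h.b:.3g}, "
            f"b_NH4={curve.fit_nh4.b:.3g} must both be < 0"
        )
    lo, hi = BISECTION_BRACKET_KM
    cl = curve.critical_load
    if potential_acid_load(lo, curve) < cl:
        logger.warning(
            "PAL(%.0f km) = %.3g <= critical load %.3g: no acid island",
            lo, potential_acid_load(lo, curve), cl,
        )
        return 0.0, True
    if potential_acid_load(hi, curve) >= cl:
        raise BracketError(
            f"PAL({hi:.0f} km) = {potential_acid_load(hi, curve):.3g} still >= "
            f"critical load {cl:.3g}; no crossing inside the bracket"
        )
    # Plain bisection: PAL is monotone, so the crossing is unique. The
    # interval is driven to floating-point convergence, which leaves the
    # load matched far below BISECTION_LOAD_TOL and the radius at the
    # closed form to machine precision.
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mid == lo or mid == hi:
            break
        if potential_acid_load(mid, curve) > cl:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi), False


def single_term_radius(a: float, b: float, critical_load: float) -> float:
    """Closed form r* = (a / CL)**(-1/b) for a one-term power-law load."""
    if b >= 0:
        raise NonMonotoneError("closed form needs b < 0")
    return (a / critical_load) ** (-1.0 / b)


# ---------------------------------------------------------------------------
# Island area


def _disc_polygon_projected(city: CityRecord, radius_km: float, region: RegionPolygon) -> Polygon:
    lats, lons = geodesy.geodesic_circle(city.latitude, city.longitude, radius_km)
    x, y = geodesy.laea_forward(lats, lons, region.center_lat, region.center_lon)
    return Polygon(np.column_stack([x, y]))


def buffer_union_area(
    cities: Sequence[CityRecord],
    radius_km: float,
    region: RegionPolygon,
    method: str = "projected_union",
    mc_points: int = DEFAULT_MC_POINTS,
    seed: int | None = None,
) -> tuple[float, float]:
    """Area (km²) of the union of geodesic discs around the cities,
    clipped to the region, and its fraction of the region area.

    Two methods with a cross-check contract (they must agree within
    ~3 Monte Carlo standard errors):

    * "projected_union": each disc boundary is traced on the sphere and
      projected, with the region, to a Lambert azimuthal equal-area plane
      where shapely takes the union, clips, and measures area.
    * "mc": points are sampled uniformly over the sphere within the
      region (uniform in longitude and in sin latitude, rejected against
      the polygon) and the fraction within ``radius_km`` of any city by
      haversine scales the region area. Requires ``seed``.
    """
    if not radius_km > 0:
        raise DomainError("radius must be > 0")
    region_area = region.area_km2  # raises if degenerate
    if not cities:
        return 0.0, 0.0
    if method == "projected_union":
        discs = [_disc_polygon_projected(c, radius_km, region) for c in cities]
        union = shapely.unary_union(discs).intersection(region.projected())
        area = float(union.area)
        return area, area / region_area
    if method == "mc":
        if mc_points < 10_000:
            logger.warning("mc_points=%d is small; the area estimate will be noisy", mc_points)
        detail = mc_area_detail(cities, radius_km, region, mc_points=mc_points, seed=seed)
        return detail["union_area_km2"], detail["fraction"]
    raise DomainError(f"unknown area method {method!r}")


def mc_standard_error_km2(fraction: float, n_region_points: int, region_area_km2: float) -> float:
    """Binomial standard error of the Monte Carlo area estimate."""
    return region_area_km2 * float(
        np.sqrt(max(fraction * (1.0 - fraction), 0.0) / max(n_region_points, 1))
    )


def mc_area_detail(
    cities: Sequence[CityRecord],
    radius_km: float,
    region: RegionPolygon,
    mc_points: int = DEFAULT_MC_POINTS,
    seed: int | None = None,
) -> dict:
    """Monte Carlo area with its standard error and in-region point count."""
    if seed is None:
        raise DomainError("Monte Carlo area estimation requires a seed")
    rng = np.random.default_rng(seed)
    region_area = region.area_km2
    lon_min, lat_min, lon_max, lat_max = region.geometry.bounds
    z_lo, z_hi = np.sin(np.radians([lat_min, lat_max]))
    lons = rng.uniform(lon_min, lon_max, mc_points)
    lats = np.degrees(np.arcsin(rng.uniform(z_lo, z_hi, mc_points)))
    inside = region.contains_points(lons, lats)
    m = int(inside.sum())
    if m == 0:
        raise DomainError("no Monte Carlo points landed in the region")
    lons_in, lats_in = lons[inside], lats[inside]
    hit = np.zeros(m, dtype=bool)
    for c in cities:
        todo = ~hit
        if not todo.any():
            break
        d = geodesy.haversine_km(
            lats_in[todo], lons_in[todo], c.latitude, c.longitude, validate=False
        )
        hit[todo] |= np.atleast_1d(d) <= radius_km
    frac = float(hit.sum() / m)
    return {
        "union_area_km2": region_area * frac,
        "fraction": frac,
        "se_km2": mc_standard_error_km2(frac, m, region_area),
        "n_region_points": m,
    }


def islands_geojson(cities: Sequence[CityRecord], radius_km: float) -> dict:
    """The acid-island union as a WGS84 GeoJSON geometry (lon/lat discs)."""
    discs = []
    for c in cities:
        lats, lons = geodesy.geodesic_circle(c.latitude, c.longitude, radius_km)
        discs.append(Polygon(np.column_stack([lons, lats])))
    return shapely.geometry.mapping(shapely.unary_union(discs))


# ---------------------------------------------------------------------------
# Budget arithmetic


def enrichment_ratios(summary_bulk: dict, summary_throughfall: dict) -> dict:
    """Per-ion throughfall/bulk ratios of geometric-mean fluxes.

    The ratio reflects canopy-captured dry deposition net of canopy
    exchange; it is invariant to a common rescaling of both media. Ions
    missing from either medium get a null ratio.
    """
    out: dict[str, float | None] = {}
    for ion in (Ion.SO4, Ion.NO3, Ion.NH4):
        b = summary_bulk.get(ion) or summary_bulk.get(ion.value)
        t = summary_throughfall.get(ion) or summary_throughfall.get(ion.value)
        if b is None or t is None:
            out[ion.value] = None
            continue
        b_gm = getattr(b, "geometric_mean", b)
        t_gm = getattr(t, "geometric_mean", t)
        out[ion.value] = float(t_gm) / float(b_gm)
    return out


def emission_acidity(
    so2_TgS: float, nox_TgN: float, nh3_TgN: float | None = None
) -> tuple[float, float | None]:
    """Acidification-capacity ratio and NH3 neutralization fraction from
    national precursor emissions.

    Acid equivalents (Teq yr-1): SO2 contributes 2*(TgS/32.06) (two
    protons per sulfur), NOx and NH3 contribute TgN/14.007 each. Returns
    (eq_SO2/eq_NOx, eq_NH3/(eq_SO2 + eq_NOx)); the second element is None
    when no NH3 emission is given.
    """
    if so2_TgS < 0 or nox_TgN < 0 or (nh3_TgN is not None and nh3_TgN < 0):
        raise DomainError("emissions must be nonnegative")
    if nox_TgN == 0:
        raise DomainError("acidification-capacity ratio undefined for zero NOx")
    eq_so2 = SO2_EQ_PER_MOL * so2_TgS / MOLAR_MASS_S
    eq_nox = nox_TgN / MOLAR_MASS_N
    ratio = eq_so2 / eq_nox
    if nh3_TgN is None:
        return ratio, None
    return ratio, (nh3_TgN / MOLAR_MASS_N) / (eq_so2 + eq_nox)
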