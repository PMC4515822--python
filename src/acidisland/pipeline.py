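"""End-to-end orchestration: site table -> distances -> fluxes ->
summaries -> fit table -> potential acid load -> critical radius ->
island area -> report bundle.

The pipeline is a pure function of (input files, configuration, seed):
re-running with identical inputs reproduces the report bitwise. Every
stage logs what it consumed and decided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import __version__
from .acid_island import (
    AcidIslandResult,
    AcidLoadCurve,
    DEFAULT_CRITICAL_LOAD,
    DEFAULT_MC_POINTS,
    buffer_union_area,
    critical_radius,
    enrichment_ratios,
    mc_area_detail,
)
from .chem_units import Ion, Kind, conc_to_flux, ph_to_h, summarize
from .empirical_fits import FitTable, fit_all
from .errors import ConfigError, DomainError, FitError
from .proximity import assign_distances
from .site_records import (
    LARGE_CITY_POPULATION,
    Medium,
    RegionPolygon,
    read_cities,
    read_sites,
    write_report,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Resolved configuration for one pipeline run.

    ``radius_medium`` selects which medium's flux fits feed the potential
    acid load; throughfall is the default (closer to total deposition),
    bulk is kept for sensitivity analysis. ``ph_mode`` records how
    per-site volume-weighted pH values were aggregated upstream — site
    tables carry already-aggregated values, which are used as reported.
    """

    sites: str
    cities: str
    region: str | None = None
    out_dir: str | None = None
    critical_load: float = DEFAULT_CRITICAL_LOAD
    min_population: float = LARGE_CITY_POPULATION
    distance_policy: str = "recompute"
    fit_method: str = "loglog_ols"
    radius_medium: str = "throughfall"
    area_method: str = "projected_union"
    mc_points: int = DEFAULT_MC_POINTS
    seed: int | None = None
    ph_mode: str = "as_reported"

    def __post_init__(self) -> None:
        for name in ("sites", "cities", "region"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{name} path does not exist: {p}")
        if self.area_method == "mc" and self.seed is None:
            raise ConfigError("area_method=mc requires a seed")


_CONFIG_TYPES = {
    "critical_load": float, "min_population": float, "mc_points": int, "seed": int,
}


def parse_config(path: str | Path, **overrides) -> PipelineConfig:
    """Parse a flat ``key = value`` configuration file, with overrides."""
    values: dict = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            values[key] = _CONFIG_TYPES.get(key, str)(value)
    values.update({k: v for k, v in overrides.items() if v is not None})
    try:
        return PipelineConfig(**values)
    except TypeError as exc:
        raise ConfigError(f"bad configuration key: {exc}") from exc


def _summaries(records) -> dict:
    out: dict = {}
    for medium in Medium:
        med: dict = {"ph": None, "concentration": {}, "flux": {}}
        try:
            s = summarize(records, Ion.H, Kind.CONCENTRATION, medium)
            med["ph"] = {"geometric_mean": s.geometric_mean, "n": s.n}
        except DomainError:
            pass
        for ion in (Ion.SO4, Ion.NO3, Ion.NH4):
            for kind, key in ((Kind.CONCENTRATION, "concentration"), (Kind.FLUX, "flux")):
                try:
                    s = summarize(records, ion, kind, medium)
                    med[key][ion.value] = {"geometric_mean": s.geometric_mean, "n": s.n}
                except DomainError:
                    med[key][ion.value] = None
        # H+ flux (derived from pH) belongs with the flux summaries
        try:
            s = summarize(records, Ion.H, Kind.FLUX, medium)
            med["flux"]["H"] = {"geometric_mean": s.geometric_mean, "n": s.n}
        except DomainError:
            med["flux"]["H"] = None
        out[medium.value] = med
    return out


def _site_table(records, assignment_by_id) -> list[dict]:
    rows = []
    for rec in records:
        assign = assignment_by_id.get(rec.site_id)
        h_conc = None if rec.ph is None else ph_to_h(rec.ph)
        rows.append(
            {
                "site_id": rec.site_id,
                "medium": rec.medium.value,
                "latitude": rec.latitude,
                "longitude": rec.longitude,
                "precipitation_mm": rec.precipitation,
                "nearest_city": assign.city_name if assign else None,
                "distance_km": assign.distance_km if assign else None,
                "ph": rec.ph,
                "conc_h_ueq_l": h_conc,
                "conc_so4_ueq_l": rec.conc_so4,
                "conc_no3_ueq_l": rec.conc_no3,
                "conc_nh4_ueq_l": rec.conc_nh4,
                "flux_h_keq_ha_yr": None if h_conc is None else conc_to_flux(h_conc, rec.precipitation),
                "flux_so4_keq_ha_yr": None if rec.conc_so4 is None else conc_to_flux(rec.conc_so4, rec.precipitation),
                "flux_no3_keq_ha_yr": None if rec.conc_no3 is None else conc_to_flux(rec.conc_no3, rec.precipitation),
                "flux_nh4_keq_ha_yr": None if rec.conc_nh4 is None else conc_to_flux(rec.conc_nh4, rec.precipitation),
            }
        )
    return rows


def acid_island_from_fits(
    table: FitTable, config: PipelineConfig, cities, region: RegionPolygon | None
) -> AcidIslandResult:
    """Critical radius and island area from a fitted table."""
    medium = config.radius_medium
    fit_h = table.get(medium, Ion.H, Kind.FLUX)
    fit_nh4 = table.get(medium, Ion.NH4, Kind.FLUX)
    if fit_h is None or fit_nh4 is None:
        raise FitError(
            f"cannot build the potential acid load: {medium} H+/NH4+ flux fits unavailable"
        )
    curve = AcidLoadCurve(fit_h=fit_h, fit_nh4=fit_nh4, critical_load=config.critical_load)
    radius, no_island = critical_radius(curve)
    if no_island or region is None or not cities:
        return AcidIslandResult(
            critical_radius_km=radius,
            islands=[] if no_island else [(c.name, radius) for c in cities],
            no_island=no_island,
        )
    mc_se = None
    if config.area_method == "mc":
        detail = mc_area_detail(cities, radius, region, mc_points=config.mc_points, seed=config.seed)
        area, fraction = detail["union_area_km2"], detail["fraction"]
        mc_se = detail["se_km2"]
    else:
        area, fraction = buffer_union_area(
            cities, radius, region, method=config.area_method,
            mc_points=config.mc_points, seed=config.seed,
        )
    return AcidIslandResult(
        critical_radius_km=radius,
        islands=[(c.name, radius) for c in cities],
        union_area_km2=area,
        region_area_km2=region.area_km2,
        fraction=fraction,
        area_method=config.area_method,
        mc_se_area_km2=mc_se,
        no_island=False,
    )


def run(config: PipelineConfig) -> dict:
    """Execute the full analysis and return (and optionally write) the
    report bundle."""
    logger.info("[read] sites=%s cities=%s", config.sites, config.cities)
    records, diagnostics = read_sites(config.sites, return_diagnostics=True)
    cities = read_cities(config.cities, min_population=config.min_population)
    region = RegionPolygon.from_geojson(config.region) if config.region else None
    logger.info(
        "[read] %d site rows (%d rejected), %d cities", len(records), len(diagnostics), len(cities)
    )

    assignments = assign_distances(records, cities, override_policy=config.distance_policy)
    by_id = {a.site_id: a for a in assignments}
    logger.info("[distances] assigned %d sites, policy=%s", len(by_id), config.distance_policy)

    summaries = _summaries(records)
    table = fit_all(records, assignments, method=config.fit_method)
    logger.info("[fits] %d fits, %d unavailable", table.n_fits, len(table.unavailable))
    if table.n_fits == 0:
        raise FitError("fit table is empty: no quantity had >= 3 usable sites")

    ratios = enrichment_ratios(
        {k: v["geometric_mean"] for k, v in summaries["bulk"]["flux"].items() if v},
        {k: v["geometric_mean"] for k, v in summaries["throughfall"]["flux"].items() if v},
    )

    island = acid_island_from_fits(table, config, cities, region)
    if island.no_island:
        logger.warning("[radius] potential acid load below the critical load everywhere: no island")
    else:
        logger.info("[radius] critical radius %.2f km", island.critical_radius_km)

    bundle = {
        "package": {"name": "acidisland", "version": __version__},
        "config": asdict(config),
        "inputs": {
            "n_site_rows": len(records),
            "n_rejected_rows": len(diagnostics),
            "n_sites": len({r.site_id for r in records}),
            "n_cities": len(cities),
        },
        "ph_mode": config.ph_mode,
        "summaries": summaries,
        "fits": table.to_dict(),
        "enrichment_ratios": ratios,
        "acid_island": island.to_dict(),
        "site_table": _site_table(records, by_id),
    }
    if config.out_dir:
        paths = write_report(bundle, config.out_dir)
        logger.info("[report] wrote %s", paths["report"])
    return bundle
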