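"""Synthetic study generator with known ground truth.

Emulates the statistical structure the analysis assumes: monitoring
sites scattered around large cities inside a rectangular region, with

* ion concentrations following y = a * x**b times multiplicative
  lognormal noise exp(eps), eps ~ N(0, sigma_log**2), where x is the
  distance (km) to the nearest large city;
* pH following c + d * ln x plus additive Gaussian noise, clipped to
  (3, 9) to stay inside the pH <-> H+ domain (clips are counted);
* throughfall concentrations equal to bulk times a per-ion enrichment
  multiplier applied before the noise, so the enrichment-ratio oracle
  is exact in expectation;
* precipitation uniform over a fixed range, shared by the bulk and
  throughfall rows of a site.

Default ground truth anchors each quantity's geometric mean at the
geometric-mean site distance (sqrt(2*300) ~ 24.5 km of the log-uniform
distance law) to the study region's reported levels: pH 5.5 (bulk) /
5.8 (throughfall); SO4/NO3/NH4 bulk concentrations 101.2/19.1/47.6
ueq L-1; throughfall enrichments 1.82/1.56/1.34. Decay exponents are
not pinned down by those summary levels and are set to moderate values
(-0.40/-0.25/-0.35; pH slope 0.30 per ln km), nitrate flattest since
road traffic blurs its urban gradient. The seed is mandatory: the
generator has no implicit randomness and identical seeds give
byte-identical tables.
"""

from __future__ import annotations

import ast
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import geodesy
from .acid_island import AcidLoadCurve, DEFAULT_CRITICAL_LOAD, critical_radius
from .chem_units import FLUX_FACTOR
from .empirical_fits import PowerLawFit
from .errors import GenerationError
from .proximity import DISTANCE_FLOOR_KM
from .site_records import (
    CityRecord,
    Medium,
    RegionPolygon,
    SiteRecord,
    write_cities,
    write_sites,
)

#: Geometric mean of the default log-uniform distance law on [2, 300] km.
GM_DISTANCE_KM = math.sqrt(2.0 * 300.0)

FIXTURE_SEED = 1234


def _amp(gm_anchor: float, b: float) -> float:
    """Power-law amplitude whose value at the GM distance is gm_anchor."""
    return gm_anchor * GM_DISTANCE_KM ** (-b)


def _default_conc_truth() -> dict:
    return {
        "SO4": (_amp(101.2, -0.40), -0.40),
        "NO3": (_amp(19.1, -0.25), -0.25),
        "NH4": (_amp(47.6, -0.35), -0.35),
    }


def _default_ph_truth() -> dict:
    d = 0.30
    return {
        "bulk": (5.5 - d * math.log(GM_DISTANCE_KM), d),
        "throughfall": (5.8 - d * math.log(GM_DISTANCE_KM), d),
    }


def _default_enrichment() -> dict:
    return {"SO4": 1.82, "NO3": 1.56, "NH4": 1.34}


@dataclass
class SyntheticConfig:
    """Ground-truth parameters for one synthetic study.

    ``conc_truth`` maps ion -> (a, b) for bulk concentration in ueq L-1;
    ``ph_truth`` maps medium -> (c, d). ``n_missing`` optionally blanks a
    quantity at that many randomly chosen sites (both media), emulating
    ragged literature tables with differing per-ion n.
    """

    seed: int
    n_cities: int = 5
    n_sites: int = 33
    region_bounds: tuple[float, float, float, float] = (100.0, 21.0, 121.0, 33.0)
    distance_range_km: tuple[float, float] = (2.0, 300.0)
    conc_truth: dict = field(default_factory=_default_conc_truth)
    ph_truth: dict = field(default_factory=_default_ph_truth)
    enrichment: dict = field(default_factory=_default_enrichment)
    sigma_log: float = 0.3
    sigma_ph: float = 0.25
    precip_range: tuple[float, float] = (1200.0, 2200.0)
    ph_clip: tuple[float, float] = (3.0, 9.0)
    n_missing: dict = field(default_factory=dict)  # e.g. {"ph": 5, "SO4": 3}

    def __post_init__(self) -> None:
        if self.seed is None:
            raise GenerationError("seed is mandatory")
        for ion, (a, _) in self.conc_truth.items():
            if not a > 0:
                raise GenerationError(f"amplitude for {ion} must be > 0")
        if self.sigma_log < 0 or self.sigma_ph < 0:
            raise GenerationError("noise standard deviations must be >= 0")


@dataclass
class SyntheticDataset:
    cities: list
    region: RegionPolygon
    sites: list
    truth: dict
    n_ph_clipped: int = 0


def power_law_samples(x, a: float, b: float, sigma: float, rng) -> np.ndarray:
    """Samples a * x**b * exp(eps), eps ~ N(0, sigma^2) — the noise model
    shared by the generator and parameter-recovery experiments."""
    x = np.asarray(x, dtype=float)
    return a * x**b * np.exp(rng.normal(0.0, sigma, size=x.shape))


def log_uniform(rng, lo: float, hi: float, size=None):
    return np.exp(rng.uniform(math.log(lo), math.log(hi), size=size))


def gm_precip(precip_range: tuple[float, float]) -> float:
    """Geometric mean of Uniform(lo, hi): exp of the mean log."""
    lo, hi = precip_range
    if lo == hi:
        return lo
    return math.exp((hi * (math.log(hi) - 1.0) - lo * (math.log(lo) - 1.0)) / (hi - lo))


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate (cities, region, sites, truth) for one synthetic study.

    Sites are placed at log-uniform distances and uniform bearings from
    randomly chosen cities, resampled until inside the region. Chemistry
    is generated from each site's distance to the *nearest* city (the
    quantity the analysis regresses on), so noise-free data are exactly
    recoverable. The written ``distance_km`` column is left null to make
    the pipeline exercise the proximity stage.
    """
    rng = np.random.default_rng(config.seed)
    lon_min, lat_min, lon_max, lat_max = config.region_bounds
    region = RegionPolygon.rectangle(lon_min, lat_min, lon_max, lat_max)

    margin = min(1.0, (lat_max - lat_min) / 4.0, (lon_max - lon_min) / 4.0)
    cities = []
    for i in range(config.n_cities):
        cities.append(
            CityRecord(
                name=f"City-{chr(ord('A') + i)}" if i < 26 else f"City-{i}",
                latitude=float(rng.uniform(lat_min + margin, lat_max - margin)),
                longitude=float(rng.uniform(lon_min + margin, lon_max - margin)),
                nonag_population=float(rng.uniform(6e5, 9e6)),
            )
        )
    city_lats = np.array([c.latitude for c in cities])
    city_lons = np.array([c.longitude for c in cities])

    d_lo, d_hi = config.distance_range_km
    positions = []
    for _ in range(config.n_sites):
        for _attempt in range(1000):
            j = int(rng.integers(config.n_cities))
            dist = float(log_uniform(rng, d_lo, d_hi))
            bearing = float(rng.uniform(0.0, 360.0))
            lat, lon = geodesy.destination_point(
                cities[j].latitude, cities[j].longitude, bearing, dist
            )
            if region.contains_points(np.array([lon]), np.array([lat]))[0]:
                positions.append((lat, lon))
                break
        else:
            raise GenerationError(
                "region too small to place sites at the requested distances"
            )

    lats = np.array([p[0] for p in positions])
    lons = np.array([p[1] for p in positions])
    # distance to the nearest city drives the chemistry
    dmat = geodesy.haversine_km(
        lats[:, None], lons[:, None], city_lats[None, :], city_lons[None, :],
        validate=False,
    )
    x = np.maximum(dmat.min(axis=1), DISTANCE_FLOOR_KM)

    precip = rng.uniform(*config.precip_range, size=config.n_sites)

    conc = {}  # (medium, ion) -> array
    for ion, (a, b) in config.conc_truth.items():
        conc[("bulk", ion)] = power_law_samples(x, a, b, config.sigma_log, rng)
        conc[("throughfall", ion)] = power_law_samples(
            x, a * config.enrichment[ion], b, config.sigma_log, rng
        )
    ph = {}
    n_clipped = 0
    lo_ph, hi_ph = config.ph_clip
    for medium, (c, d) in config.ph_truth.items():
        raw = c + d * np.log(x) + rng.normal(0.0, config.sigma_ph, size=config.n_sites)
        clipped = np.clip(raw, lo_ph, hi_ph)
        n_clipped += int(np.sum(clipped != raw))
        ph[medium] = clipped

    missing_mask = {}  # quantity -> bool array over sites
    for quantity, k in config.n_missing.items():
        idx = rng.choice(config.n_sites, size=int(k), replace=False)
        mask = np.zeros(config.n_sites, dtype=bool)
        mask[idx] = True
        missing_mask[quantity] = mask

    def _val(quantity: str, medium: str, i: int):
        mask = missing_mask.get(quantity)
        if mask is not None and mask[i]:
            return None
        if quantity == "ph":
            return float(ph[medium][i])
        return float(conc[(medium, quantity)][i])

    sites = []
    for i in range(config.n_sites):
        for medium in ("bulk", "throughfall"):
            sites.append(
                SiteRecord(
                    site_id=f"S{i + 1:03d}",
                    latitude=float(lats[i]),
                    longitude=float(lons[i]),
                    precipitation=float(precip[i]),
                    medium=Medium(medium),
                    ph=_val("ph", medium, i),
                    conc_so4=_val("SO4", medium, i),
                    conc_no3=_val("NO3", medium, i),
                    conc_nh4=_val("NH4", medium, i),
                    obs_years="2000-2009",
                    distance_km=None,
                )
            )

    truth = {
        "seed": config.seed,
        "sigma_log": config.sigma_log,
        "sigma_ph": config.sigma_ph,
        "gm_precip_mm": gm_precip(config.precip_range),
    }
    for ion, (a, b) in config.conc_truth.items():
        truth[f"conc.bulk.{ion}.a"] = a
        truth[f"conc.bulk.{ion}.b"] = b
        truth[f"conc.throughfall.{ion}.a"] = a * config.enrichment[ion]
        truth[f"conc.throughfall.{ion}.b"] = b
        truth[f"enrichment.{ion}"] = config.enrichment[ion]
    for medium, (c, d) in config.ph_truth.items():
        truth[f"ph.{medium}.c"] = c
        truth[f"ph.{medium}.d"] = d

    return SyntheticDataset(
        cities=cities, region=region, sites=sites, truth=truth, n_ph_clipped=n_clipped
    )


def true_acid_load_curve(
    config: SyntheticConfig, critical_load: float = DEFAULT_CRITICAL_LOAD
) -> AcidLoadCurve:
    """The ground-truth PAL curve implied by a config.

    H+ flux follows from the throughfall pH curve (a_H = 10**(6-c) * P̄ *
    1e-5, b_H = -d ln 10, P̄ the geometric-mean precipitation); NH4+ flux
    from the enriched concentration curve. Exact when precipitation is
    degenerate, geometric-mean-exact otherwise.
    """
    p_gm = gm_precip(config.precip_range)
    c, d = config.ph_truth["throughfall"]
    a_h = 10.0 ** (6.0 - c) * p_gm * FLUX_FACTOR
    b_h = -d * math.log(10.0)
    a_n_conc, b_n = config.conc_truth["NH4"]
    a_n = a_n_conc * config.enrichment["NH4"] * p_gm * FLUX_FACTOR
    mk = lambda a, b: PowerLawFit(
        a=a, b=b, n=config.n_sites, r_squared=1.0, p_value=0.0,
        sigma_log=0.0, method="truth",
    )
    return AcidLoadCurve(fit_h=mk(a_h, b_h), fit_nh4=mk(a_n, b_n), critical_load=critical_load)


def true_critical_radius(
    config: SyntheticConfig, critical_load: float = DEFAULT_CRITICAL_LOAD
) -> float:
    r, _ = critical_radius(true_acid_load_curve(config, critical_load))
    return r


# ---------------------------------------------------------------------------
# On-disk datasets


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write sites.csv / cities.csv / region.geojson / truth.txt."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "sites": out_dir / "sites.csv",
        "cities": out_dir / "cities.csv",
        "region": out_dir / "region.geojson",
        "truth": out_dir / "truth.txt",
    }
    write_sites(dataset.sites, paths["sites"])
    write_cities(dataset.cities, paths["cities"])
    dataset.region.to_geojson(paths["region"])
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        for key in sorted(dataset.truth):
            fh.write(f"{key} = {dataset.truth[key]!r}\n")
    return paths


def read_truth(path: str | Path) -> dict:
    truth: dict = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if "=" not in line:
                continue
            key, _, value = line.partition("=")
            truth[key.strip()] = ast.literal_eval(value.strip())
    return truth


def fixture_config() -> SyntheticConfig:
    """The configuration behind the packaged fixture (5 cities, 33 sites)."""
    return SyntheticConfig(seed=FIXTURE_SEED)


def packaged_fixture() -> dict[str, Path]:
    """Paths of the small committed fixture used by end-to-end tests/docs."""
    data_dir = Path(__file__).parent / "data"
    return {
        "sites": data_dir / "fixture_sites.csv",
        "cities": data_dir / "fixture_cities.csv",
        "region": data_dir / "fixture_region.geojson",
        "truth": data_dir / "fixture_truth.txt",
    }
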