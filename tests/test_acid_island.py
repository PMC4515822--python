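"""Potential acid load, critical radius, island areas, enrichment and
emission arithmetic."""

import numpy as np
import pytest

from acidisland import acid_island as isl
from acidisland import geodesy
from acidisland.chem_units import SummaryStats, Ion, Kind
from acidisland.empirical_fits import PowerLawFit
from acidisland.errors import BracketError, DomainError, NonMonotoneError
from acidisland.site_records import CityRecord, RegionPolygon


def _fit(a, b):
    return PowerLawFit(a=a, b=b, n=10, r_squared=1.0, p_value=0.001, sigma_log=0.1)


def _curve(a_h, b_h, a_n, b_n, cl=2.0):
    return isl.AcidLoadCurve(fit_h=_fit(a_h, b_h), fit_nh4=_fit(a_n, b_n), critical_load=cl)


def _city(name, lat, lon):
    return CityRecord(name=name, latitude=lat, longitude=lon, nonag_population=1e6)


class TestPotentialAcidLoad:
    def test_simple_algebra(self):
        curve = _curve(1.0, -1.0, 0.5, -1.0)
        assert isl.potential_acid_load(1.0, curve) == pytest.approx(2.0)
        assert isl.potential_acid_load(4.0, curve) == pytest.approx(0.5)

    def test_reduces_to_h_term_without_ammonium(self):
        curve = _curve(3.0, -0.7, 0.0, -0.5)
        r = np.array([1.0, 10.0, 100.0])
        assert isl.potential_acid_load(r, curve) == pytest.approx(3.0 * r**-0.7)

    def test_matches_independent_term_sum(self):
        rng = np.random.default_rng(3)
        curve = _curve(5.0, -0.9, 2.0, -0.4)
        for r in rng.uniform(1, 500, 20):
            expected = 5.0 * r**-0.9 + 2.0 * (2.0 * r**-0.4)
            assert isl.potential_acid_load(float(r), curve) == pytest.approx(expected, rel=1e-12)

    def test_monotone_decreasing_on_dense_grid(self):
        curve = _curve(4.0, -0.8, 3.0, -0.3)
        r = np.linspace(1, 1000, 5000)
        pal = isl.potential_acid_load(r, curve)
        assert np.all(np.diff(pal) < 0)


class TestCriticalRadius:
    def test_unit_example(self):
        r, no_island = isl.critical_radius(_curve(1.0, -1.0, 0.5, -1.0, cl=2.0))
        assert not no_island
        assert r == pytest.approx(1.0, abs=1e-6)

    def test_closed_form_with_ammonium_only(self):
        # PAL = 2 * 4 * r**-0.5 = 2  =>  r = 16
        r, _ = isl.critical_radius(_curve(0.0, -1.0, 4.0, -0.5, cl=2.0))
        assert r == pytest.approx(16.0, abs=1e-6)

    def test_bisection_agrees_with_closed_form_single_term(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            a = float(rng.uniform(5.0, 200.0))
            b = float(rng.uniform(-1.5, -0.2))
            cl = float(rng.uniform(0.5, 4.0))
            closed = isl.single_term_radius(a, b, cl)
            if not 1.0 < closed < 10_000.0:
                continue
            r, _ = isl.critical_radius(_curve(a, b, 0.0, -1.0, cl=cl))
            assert r == pytest.approx(closed, abs=1e-6)

    def test_load_matched_at_solution(self):
        curve = _curve(8.0, -0.9, 9.0, -0.55, cl=2.0)
        r, _ = isl.critical_radius(curve)
        assert abs(isl.potential_acid_load(r, curve) - 2.0) < 1e-9

    def test_increasing_critical_load_never_increases_radius(self):
        rng = np.random.default_rng(23)
        checked = 0
        while checked < 20:
            curve_lo = _curve(
                float(rng.uniform(5, 50)), float(rng.uniform(-1.2, -0.3)),
                float(rng.uniform(5, 50)), float(rng.uniform(-1.2, -0.3)), cl=1.0,
            )
            curve_hi = isl.AcidLoadCurve(curve_lo.fit_h, curve_lo.fit_nh4, critical_load=2.0)
            try:
                r_lo, _ = isl.critical_radius(curve_lo)
                r_hi, _ = isl.critical_radius(curve_hi)
            except isl.BracketError:
                continue  # crossing outside the regional bracket; redraw
            checked += 1
            assert r_hi <= r_lo + 1e-9

    def test_no_island_when_load_below_critical_everywhere(self):
        r, no_island = isl.critical_radius(_curve(0.1, -0.5, 0.1, -0.5, cl=2.0))
        assert no_island and r == 0.0

    def test_bracket_error_when_load_everywhere_above(self):
        with pytest.raises(BracketError):
            isl.critical_radius(_curve(1e6, -0.1, 1e6, -0.1, cl=2.0))

    def test_nonnegative_exponent_rejected(self):
        with pytest.raises(NonMonotoneError):
            isl.critical_radius(_curve(5.0, 0.2, 5.0, -0.5))


class TestBufferUnionArea:
    region = RegionPolygon.rectangle(100, 20, 120, 35)

    def test_isolated_island_matches_spherical_cap(self):
        city = [_city("X", 27.5, 110.0)]
        cap = geodesy.spherical_cap_area_km2(67.0)
        area, frac = isl.buffer_union_area(city, 67.0, self.region, method="projected_union")
        assert area == pytest.approx(cap, rel=1e-3)
        assert frac == pytest.approx(cap / self.region.area_km2, rel=1e-3)
        # and within 0.1% of the flat-disc area at this radius
        assert area == pytest.approx(np.pi * 67.0**2, rel=1e-3)

    def test_disjoint_cities_double_the_area(self):
        one = isl.buffer_union_area([_city("A", 27.0, 105.0)], 50.0, self.region, "projected_union")[0]
        two = isl.buffer_union_area(
            [_city("A", 27.0, 105.0), _city("B", 27.0, 115.0)], 50.0, self.region, "projected_union"
        )[0]
        assert two == pytest.approx(2 * one, rel=1e-6)

    def test_coincident_cities_are_idempotent(self):
        cities = [_city("A", 27.0, 110.0), _city("B", 27.0, 110.0)]
        one = isl.buffer_union_area(cities[:1], 60.0, self.region, "projected_union")[0]
        both = isl.buffer_union_area(cities, 60.0, self.region, "projected_union")[0]
        assert both == pytest.approx(one, rel=1e-12)

    def test_union_monotone_in_radius(self):
        cities = [_city("A", 26.0, 108.0), _city("B", 28.0, 112.0)]
        areas = [
            isl.buffer_union_area(cities, r, self.region, "projected_union")[0]
            for r in (20.0, 50.0, 90.0, 150.0)
        ]
        assert all(a2 > a1 for a1, a2 in zip(areas, areas[1:]))

    def test_union_bounded_by_sum_and_region(self):
        cities = [_city(f"c{i}", 26.0 + i, 108.0 + i) for i in range(4)]
        area, frac = isl.buffer_union_area(cities, 80.0, self.region, "projected_union")
        assert area <= 4 * geodesy.spherical_cap_area_km2(80.0) * (1 + 1e-9)
        assert area <= self.region.area_km2
        assert 0.0 <= frac <= 1.0

    def test_mc_agrees_with_projection_within_3se(self):
        rng = np.random.default_rng(99)
        for trial in range(3):
            n_cities = int(rng.integers(1, 11))
            cities = [
                _city(f"c{i}", float(rng.uniform(21, 34)), float(rng.uniform(101, 119)))
                for i in range(n_cities)
            ]
            radius = float(rng.uniform(40, 120))
            proj, _ = isl.buffer_union_area(cities, radius, self.region, "projected_union")
            detail = isl.mc_area_detail(cities, radius, self.region, mc_points=200_000, seed=trial)
            assert abs(detail["union_area_km2"] - proj) < 3 * detail["se_km2"]

    def test_mc_requires_seed(self):
        with pytest.raises(DomainError):
            isl.buffer_union_area([_city("A", 27.0, 110.0)], 50.0, self.region, "mc", seed=None)

    def test_bad_radius(self):
        with pytest.raises(DomainError):
            isl.buffer_union_area([_city("A", 27.0, 110.0)], 0.0, self.region, "projected_union")

    def test_islands_export_as_valid_wgs84_geojson(self):
        gj = isl.islands_geojson([_city("A", 27.0, 105.0), _city("B", 27.0, 115.0)], 50.0)
        assert gj["type"] == "MultiPolygon"  # disjoint discs
        from shapely.geometry import shape

        geom = shape(gj)
        assert geom.is_valid
        lon_min, lat_min, lon_max, lat_max = geom.bounds
        assert -180 <= lon_min <= lon_max <= 180
        assert -90 <= lat_min <= lat_max <= 90
        merged = isl.islands_geojson([_city("A", 27.0, 110.0), _city("B", 27.2, 110.2)], 50.0)
        assert merged["type"] == "Polygon"  # overlapping discs union


class TestEnrichmentRatios:
    def test_reported_flux_means_reproduce_reported_ratios(self):
        bulk = {"SO4": 1.55, "NO3": 0.30, "NH4": 0.73}
        tf = {"SO4": 2.83, "NO3": 0.47, "NH4": 0.98}
        ratios = isl.enrichment_ratios(bulk, tf)
        assert ratios["SO4"] == pytest.approx(1.82, abs=0.01)
        assert ratios["NO3"] == pytest.approx(1.56, abs=0.01)
        assert ratios["NH4"] == pytest.approx(1.34, abs=0.01)

    def test_identical_summaries_give_unity(self):
        s = {"SO4": SummaryStats(1.5, 30, Ion.SO4, Kind.FLUX, "bulk")}
        assert isl.enrichment_ratios(s, s)["SO4"] == pytest.approx(1.0)

    def test_missing_ion_yields_null(self):
        ratios = isl.enrichment_ratios({"SO4": 1.5}, {"NO3": 0.4})
        assert ratios["SO4"] is None and ratios["NO3"] is None and ratios["NH4"] is None

    def test_invariant_to_common_rescaling(self):
        bulk = {"SO4": 1.55, "NO3": 0.30, "NH4": 0.73}
        tf = {"SO4": 2.83, "NO3": 0.47, "NH4": 0.98}
        scaled = isl.enrichment_ratios(
            {k: 3.7 * v for k, v in bulk.items()}, {k: 3.7 * v for k, v in tf.items()}
        )
        for ion, r in isl.enrichment_ratios(bulk, tf).items():
            assert scaled[ion] == pytest.approx(r, rel=1e-12)


class TestEmissionAcidity:
    def test_national_emissions_give_reported_ratio_and_fraction(self):
        ratio, frac = isl.emission_acidity(14.4, 5.0, 12.7)
        assert ratio == pytest.approx(2.5, abs=0.1)
        assert frac == pytest.approx(0.72, abs=0.01)

    def test_constructed_equal_capacity(self):
        x = 10.0
        ratio, _ = isl.emission_acidity(x, x * (isl.MOLAR_MASS_N * 2 / isl.MOLAR_MASS_S))
        assert ratio == pytest.approx(1.0, rel=1e-12)

    def test_zero_nox_undefined(self):
        with pytest.raises(DomainError):
            isl.emission_acidity(14.4, 0.0)

    def test_without_nh3_fraction_is_none(self):
        _, frac = isl.emission_acidity(14.4, 5.0)
        assert frac is None
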