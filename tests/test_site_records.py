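"""Site-table and city-registry I/O: validation, per-ion missingness,
round trips, report serialization."""

import json
import logging

import pytest

from acidisland import site_records as sr
from acidisland.errors import DomainError, RowError, SchemaError

WELL_FORMED = """
site_id,latitude,longitude,precipitation_mm,medium,ph,conc_so4_ueq_l,conc_no3_ueq_l,conc_nh4_ueq_l,obs_years,distance_km
s1,25.0,110.0,1500,bulk,5.5,100,20,50,2001-2003,
s2,26.0,111.0,1600,throughfall,5.8,180,30,64,2004,
s3,27.0,112.0,1400,bulk,5.2,90,18,40,2005-2007,
"""

FIVE_ROW_RAGGED = """
site_id,latitude,longitude,precipitation_mm,medium,ph,conc_so4_ueq_l,conc_no3_ueq_l,conc_nh4_ueq_l,obs_years,distance_km
s1,25.0,110.0,1500,bulk,5.5,100,20,50,,
s2,26.0,111.0,1600,bulk,5.8,180,,64,,
s3,27.0,112.0,1400,bulk,5.2,90,18,40,,
s4,24.0,109.0,1550,bulk,,110,,,,
s5,23.0,108.0,1450,bulk,5.0,,25,45,,
"""


class TestReadSites:
    def test_well_formed_round_trip(self, write_csv, tmp_path):
        path = write_csv("sites.csv", WELL_FORMED)
        records = sr.read_sites(path)
        assert len(records) == 3
        out = tmp_path / "again.csv"
        sr.write_sites(records, out)
        assert sr.read_sites(out) == records

    def test_zero_precipitation_rejected_with_diagnostic(self, write_csv):
        path = write_csv(
            "bad.csv",
            """
            site_id,latitude,longitude,precipitation_mm,medium
            s1,25.0,110.0,0,bulk
            s2,26.0,111.0,1600,bulk
            """,
        )
        records, diags = sr.read_sites(path, return_diagnostics=True)
        assert [r.site_id for r in records] == ["s2"]
        assert len(diags) == 1
        assert diags[0][0] == 0 and "precipitation" in diags[0][1]

    def test_blank_cell_becomes_null_and_per_ion_n_differs(self, write_csv):
        records = sr.read_sites(write_csv("ragged.csv", FIVE_ROW_RAGGED))
        assert len(records) == 5
        n = lambda attr: sum(getattr(r, attr) is not None for r in records)
        assert n("ph") == 4
        assert n("conc_so4") == 4
        assert n("conc_no3") == 3
        assert n("conc_nh4") == 4
        by_id = {r.site_id: r for r in records}
        assert by_id["s2"].conc_no3 is None

    def test_missing_required_column_names_it(self, write_csv):
        path = write_csv(
            "noschema.csv",
            """
            site_id,longitude,precipitation_mm,medium
            s1,110.0,1500,bulk
            """,
        )
        with pytest.raises(SchemaError, match="latitude"):
            sr.read_sites(path)

    def test_non_numeric_coordinate_is_row_error(self, write_csv):
        path = write_csv(
            "badcoord.csv",
            """
            site_id,latitude,longitude,precipitation_mm,medium
            s1,north,110.0,1500,bulk
            s2,26.0,111.0,1600,bulk
            """,
        )
        records, diags = sr.read_sites(path, return_diagnostics=True)
        assert len(records) == 1
        assert "latitude" in diags[0][1]

    def test_medium_filter(self, write_csv):
        path = write_csv("sites.csv", WELL_FORMED)
        assert len(sr.read_sites(path, medium_filter="bulk")) == 2
        assert len(sr.read_sites(path, medium_filter=sr.Medium.THROUGHFALL)) == 1

    def test_removing_one_ion_value_only_touches_that_ion(self, write_csv):
        full = sr.read_sites(write_csv("full.csv", WELL_FORMED))
        dropped = sr.read_sites(
            write_csv("drop.csv", WELL_FORMED.replace("5.5,100,20,50", "5.5,,20,50"))
        )
        assert sum(r.conc_so4 is not None for r in dropped) == sum(r.conc_so4 is not None for r in full) - 1
        for attr in ("ph", "conc_no3", "conc_nh4"):
            assert [getattr(r, attr) for r in dropped] == [getattr(r, attr) for r in full]


class TestSiteRecordInvariants:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"precipitation": -10.0},
            {"latitude": 95.0},
            {"longitude": 200.0},
            {"ph": 14.5},
            {"conc_so4": -1.0},
            {"distance_km": 0.0},
        ],
    )
    def test_invalid_field_raises(self, kwargs):
        base = dict(
            site_id="s1", latitude=25.0, longitude=110.0,
            precipitation=1500.0, medium=sr.Medium.BULK,
        )
        base.update(kwargs)
        with pytest.raises(RowError):
            sr.SiteRecord(**base)


class TestReadCities:
    def test_strict_population_threshold(self, write_csv):
        path = write_csv(
            "cities.csv",
            """
            name,latitude,longitude,nonag_population
            Small,25.0,110.0,400000
            AtThreshold,26.0,111.0,500000
            Large,27.0,112.0,600000
            """,
        )
        cities = sr.read_cities(path)
        assert [c.name for c in cities] == ["Large"]
        assert len(sr.read_cities(path, min_population=0)) == 3

    def test_duplicate_names_both_retained_with_warning(self, write_csv, caplog):
        path = write_csv(
            "dup.csv",
            """
            name,latitude,longitude,nonag_population
            Twin,25.0,110.0,800000
            Twin,28.0,113.0,900000
            """,
        )
        with caplog.at_level(logging.WARNING):
            cities = sr.read_cities(path)
        assert len(cities) == 2
        assert any("duplicate" in rec.message for rec in caplog.records)

    def test_empty_result_warns_not_raises(self, write_csv, caplog):
        path = write_csv(
            "none.csv",
            """
            name,latitude,longitude,nonag_population
            Hamlet,25.0,110.0,1000
            """,
        )
        with caplog.at_level(logging.WARNING):
            assert sr.read_cities(path) == []
        assert any("no cities" in rec.message for rec in caplog.records)

    def test_city_round_trip(self, write_csv, tmp_path):
        path = write_csv(
            "cities.csv",
            """
            name,latitude,longitude,nonag_population
            Metro,25.123456789,110.987654321,1234567
            """,
        )
        cities = sr.read_cities(path)
        out = tmp_path / "again.csv"
        sr.write_cities(cities, out)
        assert sr.read_cities(out) == cities


class TestRegionPolygon:
    def test_rectangle_has_positive_area(self):
        region = sr.RegionPolygon.rectangle(100, 20, 120, 35)
        assert region.area_km2 > 0

    def test_geojson_round_trip(self, tmp_path):
        region = sr.RegionPolygon.rectangle(100, 20, 120, 35)
        path = tmp_path / "region.geojson"
        region.to_geojson(path)
        again = sr.RegionPolygon.from_geojson(path)
        assert again.area_km2 == pytest.approx(region.area_km2, rel=1e-12)

    def test_self_intersecting_ring_rejected(self):
        bowtie = {
            "type": "Polygon",
            "coordinates": [[[0, 0], [2, 2], [2, 0], [0, 2], [0, 0]]],
        }
        with pytest.raises(DomainError):
            sr.RegionPolygon(bowtie)


class TestReport:
    def test_write_then_read_preserves_numbers(self, tmp_path):
        bundle = {
            "fits": {"bulk": {"ph": {"c": 4.123456789012345, "d": 0.3}}},
            "acid_island": {"critical_radius_km": 67.89012345678901},
            "site_table": [{"site_id": "s1", "flux_so4_keq_ha_yr": 1.5500000000000003}],
        }
        sr.write_report(bundle, tmp_path / "out")
        again = sr.read_report(tmp_path / "out")
        assert again["acid_island"]["critical_radius_km"] == bundle["acid_island"]["critical_radius_km"]
        assert again["fits"]["bulk"]["ph"]["c"] == 4.123456789012345
        assert (tmp_path / "out" / "sites_derived.csv").exists()

    def test_empty_fit_sections_serialized_as_nulls(self, tmp_path):
        bundle = {"fits": None, "acid_island": None, "summaries": None}
        paths = sr.write_report(bundle, tmp_path / "out")
        data = json.loads(paths["report"].read_text())
        assert data["fits"] is None and data["acid_island"] is None
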