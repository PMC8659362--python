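"""Record parsing, QC, map building and seasonal aggregation."""

import datetime as dt
import json
from dataclasses import replace

import numpy as np
import pytest

import phospad as pp
from phospad.campaign import (
    MapFeature,
    read_geojson,
    records_to_csv,
)
from phospad.synthgen import noiseless

BBOX = (-1.0, 53.5, 1.0, 54.2)
DATES = (dt.date(2020, 1, 1), dt.date(2020, 12, 31))


def _record(**kw):
    base = dict(
        record_id="R0001",
        device_code="0421",
        timestamp=dt.datetime(2020, 6, 1, 12, 0, tzinfo=dt.timezone.utc),
        lat=53.9,
        lon=-0.8,
        waterbody="Pocklington Canal",
        incubation_s=180.0,
        image_path="images/R0001.png",
        user_level=3,
        notes="",
    )
    base.update(kw)
    return pp.SampleRecord(**base)


class TestParseRecords:
    def test_generator_csv_fully_accepted_and_lossless(self, scene_template, tmp_path):
        camp = pp.generate_campaign(6, BBOX, DATES, seed=2, scene_template=scene_template)
        path = tmp_path / "records.csv"
        records_to_csv(camp.records, path)
        parsed = pp.parse_records(path)
        assert parsed.rejected == []
        assert len(parsed.records) == 6
        # lossless: re-serialization reproduces the file byte for byte
        path2 = tmp_path / "records2.csv"
        records_to_csv(parsed.records, path2)
        assert path.read_text() == path2.read_text()

    def test_malformed_rows_rejected_with_reasons(self, tmp_path):
        path = tmp_path / "bad.csv"
        header = "record_id,device_code,timestamp,lat,lon,waterbody,incubation_s,image_path,user_level,notes"
        rows = [
            "R1,0421,2020-06-01T12:00:00+00:00,53.9,-0.8,Canal,180,img.png,3,",
            "R2,0421,2020-06-01T12:00:00+00:00,95.0,-0.8,Canal,180,img.png,3,",  # lat
            "R3,12a4,2020-06-01T12:00:00+00:00,53.9,-0.8,Canal,180,img.png,3,",  # code
            "R4,0421,yesterday,53.9,-0.8,Canal,180,img.png,3,",  # timestamp
        ]
        path.write_text("\n".join([header] + rows) + "\n")
        parsed = pp.parse_records(path)
        assert len(parsed.records) == 1
        assert len(parsed.rejected) == 3
        reasons = {rownum: reason for rownum, _, reason in parsed.rejected}
        assert "lat" in reasons[2]
        assert "device_code" in reasons[3] and "12a4" in reasons[3]
        assert "timestamp" in reasons[4]
        # nothing silently dropped
        assert len(parsed.records) + len(parsed.rejected) == 4

    def test_naive_timestamp_assumed_utc_and_flagged(self, tmp_path):
        path = tmp_path / "naive.csv"
        path.write_text(
            "record_id,device_code,timestamp,lat,lon,waterbody,incubation_s,image_path,user_level,notes\n"
            "R1,0421,2020-06-01T12:00:00,53.9,-0.8,Canal,180,img.png,3,\n"
        )
        parsed = pp.parse_records(path)
        rec = parsed.records[0]
        assert rec.timestamp.tzinfo is not None
        assert "timezone_assumed_utc" in rec.qc_flags

    def test_jsonl_dialect(self, tmp_path):
        path = tmp_path / "records.jsonl"
        row = {
            "record_id": "R1", "device_code": "0421",
            "timestamp": "2020-06-01T12:00:00+00:00", "lat": 53.9, "lon": -0.8,
            "waterbody": "Canal", "incubation_s": 180, "image_path": "i.png",
            "user_level": 3, "notes": "",
        }
        path.write_text(json.dumps(row) + "\n" + "{broken\n")
        parsed = pp.parse_records(path)
        assert len(parsed.records) == 1
        assert len(parsed.rejected) == 1


class TestQC:
    def _reading(self, field_layout, scene_template, **scene_kw):
        scene = pp.SyntheticScene(
            layout=field_layout,
            concentration=scene_kw.pop("concentration", 2.0),
            scene=replace(scene_template, **scene_kw),
        )
        res = pp.render_device_image(scene)
        return pp.quantify_scene(res.image, field_layout, res.truth)

    def test_short_incubation_flagged(self, field_layout, scene_template):
        reading = self._reading(field_layout, scene_template, seed=1)
        flags = pp.qc_record(_record(incubation_s=120.0), reading)
        assert "incubation_short" in flags

    def test_missing_image_flagged(self):
        assert "missing_image" in pp.qc_record(_record(), None)

    def test_strong_water_tint_raises_blank_anomaly(self, field_layout, scene_template):
        reading = self._reading(
            field_layout, scene_template, seed=2, water_tint=(60.0, 80.0, 40.0)
        )
        assert "blank_anomaly" in pp.qc_record(_record(), reading)

    def test_clean_record_has_no_flags(self, field_layout, scene_template):
        reading = self._reading(field_layout, scene_template, seed=3)
        assert pp.qc_record(_record(), reading) == []


@pytest.fixture(scope="module")
def low_noise_model(field_layout, scene_template):
    tmpl = replace(scene_template, zone_noise_sd=0.001, noise_sd=0.5)
    ds = pp.generate_calibration_set(
        range(11), 3, layout=field_layout, scene_template=tmpl, seed=1
    )
    pts = [
        (s.concentration, pp.quantify_scene(r.image, field_layout, r.truth).ari_mean)
        for s, r in ds
    ]
    return pp.fit_calibration(pts)


class TestBuildMap:
    def test_bracket_assignment_end_to_end(self, field_layout, scene_template, low_noise_model):
        """Devices at 0.5/2/5/9 mg/L land in none/low/medium/high."""
        tmpl = replace(scene_template, zone_noise_sd=0.001, noise_sd=0.5)
        records, readings = [], {}
        for i, c in enumerate((0.5, 2.0, 5.0, 9.0)):
            scene = pp.SyntheticScene(
                layout=field_layout, concentration=c, scene=replace(tmpl, seed=50 + i)
            )
            res = pp.render_device_image(scene)
            rec = _record(record_id=f"R{i}")
            records.append(rec)
            readings[rec.record_id] = pp.quantify_scene(res.image, field_layout, res.truth)
        result = pp.build_map(records, readings, low_noise_model)
        assert [f.category.label for f in result.features] == [
            "none", "low", "medium", "high",
        ]

    def test_empty_records(self, low_noise_model):
        result = pp.build_map([], {}, low_noise_model)
        assert result.features == [] and result.skipped == []

    def test_feature_plus_skipped_partitions_records(self, low_noise_model, field_layout, scene_template):
        scene = pp.SyntheticScene(
            layout=field_layout, concentration=2.0, scene=replace(scene_template, seed=9)
        )
        res = pp.render_device_image(scene)
        records = [_record(record_id="A"), _record(record_id="B")]
        readings = {"A": pp.quantify_scene(res.image, field_layout, res.truth)}
        result = pp.build_map(records, readings, low_noise_model)
        assert len(result.features) + len(result.skipped) == len(records)
        assert result.skipped[0][0] == "B"

    def test_category_consistent_with_stored_concentration(
        self, low_noise_model, field_layout, scene_template
    ):
        camp = pp.generate_campaign(8, BBOX, DATES, seed=4, scene_template=scene_template)
        readings = {
            rec.record_id: pp.quantify_scene(r.image, s.layout, r.truth)
            for rec, s, r in zip(camp.records, camp.scenes, camp.renders)
        }
        result = pp.build_map(camp.records, readings, low_noise_model)
        for f in result.features:
            assert f.category == pp.classify_level(f.concentration)


class TestGeoJson:
    def _features(self):
        return [
            MapFeature(
                lon=-0.8 + i, lat=53.9, category=pp.classify_level(float(c)),
                concentration=float(c), record_id=f"R{i}",
                date=dt.datetime(2020, 3 + i, 1, tzinfo=dt.timezone.utc),
                properties={"waterbody": "Canal", "user_level": c, "notes": ""},
            )
            for i, c in enumerate((0, 2, 8))
        ]

    def test_roundtrip_preserves_structure_and_properties(self, tmp_path):
        feats = self._features()
        path = tmp_path / "map.geojson"
        pp.export_geojson(feats, path)
        doc = read_geojson(path)
        assert doc["type"] == "FeatureCollection"
        assert len(doc["features"]) == 3
        for f, orig in zip(doc["features"], feats):
            assert f["geometry"]["coordinates"] == [orig.lon, orig.lat]  # lon, lat order
            props = f["properties"]
            assert props["level"] == orig.category.label
            assert props["concentration_mg_per_L"] == orig.concentration
            assert props["record_id"] == orig.record_id
            assert props["waterbody"] == "Canal"
            assert "marker-color" in props

    def test_marker_colours_follow_brackets(self, tmp_path):
        path = tmp_path / "map.geojson"
        pp.export_geojson(self._features(), path)
        doc = read_geojson(path)
        levels = [f["properties"]["level"] for f in doc["features"]]
        colors = [f["properties"]["marker-color"] for f in doc["features"]]
        assert levels == ["none", "low", "high"]
        assert len(set(colors)) == 3


class TestSeasonalSummary:
    def _truth_features(self, camp):
        return [
            MapFeature(
                lon=rec.lon, lat=rec.lat, category=pp.classify_level(c),
                concentration=c, record_id=rec.record_id, date=rec.timestamp,
                properties={"user_level": rec.user_level},
            )
            for rec, c in zip(camp.records, camp.true_concentrations)
        ]

    def test_counts_sum_to_feature_count(self, scene_template):
        camp = pp.generate_campaign(30, BBOX, DATES, seed=7, scene_template=scene_template)
        table = pp.seasonal_summary(self._truth_features(camp), grouping="month")
        assert table["n"].sum() == 30
        assert list(table["month"]) == list(range(1, 13))
        cat_cols = ["n_none", "n_low", "n_medium", "n_high"]
        assert table[cat_cols].to_numpy().sum() == 30

    def test_summer_exceeds_winter_with_positive_amplitude(self, scene_template):
        camp = pp.generate_campaign(
            150, BBOX, DATES, seasonal_amplitude=0.6, seed=11,
            scene_template=noiseless(scene_template),
        )
        table = pp.seasonal_summary(self._truth_features(camp), grouping="quarter")
        summer = table.loc[table["quarter"] == 3, "mean_concentration"].iloc[0]
        winter = table.loc[table["quarter"] == 1, "mean_concentration"].iloc[0]
        assert summer > winter

    def test_unknown_grouping(self):
        with pytest.raises(ValueError):
            pp.seasonal_summary([], grouping="week")
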