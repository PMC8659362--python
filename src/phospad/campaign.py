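"""Citizen sampling records: parsing, QC, map export and seasonal summaries.

A campaign record is one volunteer observation: device code, GPS point,
timestamp, waterbody, incubation time, the user's own slider reading, and a
photo of the device.  This module parses record files (CSV or JSON-lines)
without ever silently dropping a row, attaches calibrated concentrations and
bracket categories to quantified records, exports an RFC 7946 GeoJSON
FeatureCollection of coloured map pins, and aggregates features into
monthly/quarterly summaries.  QC flags annotate records (short incubation,
pigmented water detected via the blank zones, saturated exposure, missing
image); they never block a record.
"""

from __future__ import annotations

import csv
import datetime as _dt
import json
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calibrate import CalibrationModel, LevelCategory, classify_level, invert
from .errors import OutOfRangeError

_CODE_RE = re.compile(r"^[0-9]{4}$")

CSV_COLUMNS = [
    "record_id",
    "device_code",
    "timestamp",
    "lat",
    "lon",
    "waterbody",
    "incubation_s",
    "image_path",
    "user_level",
    "notes",
]

#: Map pin colours per bracket (config-overridable at export time).
MARKER_COLORS = {
    LevelCategory.NONE: "#2ecc40",  # green
    LevelCategory.LOW: "#ffdc00",  # yellow
    LevelCategory.MEDIUM: "#ff851b",  # orange
    LevelCategory.HIGH: "#ff4136",  # red
}


@dataclass
class SampleRecord:
    record_id: str
    device_code: str | None
    timestamp: _dt.datetime
    lat: float
    lon: float
    waterbody: str = ""
    incubation_s: float = 180.0
    image_path: str = ""
    user_level: int | None = None
    notes: str = ""
    qc_flags: list[str] = field(default_factory=list)


@dataclass
class ParseResult:
    records: list[SampleRecord]
    rejected: list[tuple[int, dict, str]]  # (row number, raw row, reason)


def _parse_row(row: dict, rownum: int) -> SampleRecord:
    rid = (row.get("record_id") or "").strip()
    if not rid:
        raise ValueError("record_id: missing")
    code = (row.get("device_code") or "").strip() or None
    if code is not None and not _CODE_RE.match(code):
        raise ValueError(f"device_code: {code!r} does not match the four-digit pattern")
    ts_raw = (row.get("timestamp") or "").strip()
    try:
        ts = _dt.datetime.fromisoformat(ts_raw)
    except ValueError:
        raise ValueError(f"timestamp: {ts_raw!r} is not ISO 8601")
    flags = []
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=_dt.timezone.utc)
        flags.append("timezone_assumed_utc")
    try:
        lat = float(row.get("lat", ""))
        lon = float(row.get("lon", ""))
    except (TypeError, ValueError):
        raise ValueError("lat/lon: not numeric")
    if not -90.0 <= lat <= 90.0:
        raise ValueError(f"lat: {lat} outside [-90, 90]")
    if not -180.0 <= lon <= 180.0:
        raise ValueError(f"lon: {lon} outside [-180, 180]")
    inc_raw = (str(row.get("incubation_s", "")) or "").strip()
    try:
        incubation = float(inc_raw) if inc_raw else 0.0
    except ValueError:
        raise ValueError(f"incubation_s: {inc_raw!r} not numeric")
    if incubation < 0:
        raise ValueError(f"incubation_s: {incubation} is negative")
    ul_raw = str(row.get("user_level", "") or "").strip()
    user_level = None
    if ul_raw:
        try:
            user_level = int(ul_raw)
        except ValueError:
            raise ValueError(f"user_level: {ul_raw!r} not an integer")
    return SampleRecord(
        record_id=rid,
        device_code=code,
        timestamp=ts,
        lat=lat,
        lon=lon,
        waterbody=(row.get("waterbody") or "").strip(),
        incubation_s=incubation,
        image_path=(row.get("image_path") or "").strip(),
        user_level=user_level,
        notes=(row.get("notes") or ""),
        qc_flags=flags,
    )


def parse_records(path) -> ParseResult:
    """Parse a records file (CSV, or JSON-lines when the name ends .jsonl).

    Every well-formed row becomes a :class:`SampleRecord`; malformed rows are
    returned with their row number and reason, never dropped.  Unknown
    columns are ignored.
    """
    records: list[SampleRecord] = []
    rejected: list[tuple[int, dict, str]] = []
    rows: list[dict]
    if str(path).endswith((".jsonl", ".ndjson")):
        rows = []
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    rows.append(json.loads(line))
                except json.JSONDecodeError as exc:
                    rejected.append((i, {"raw": line}, f"invalid JSON: {exc}"))
    else:
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
    for i, row in enumerate(rows, start=1):
        try:
            records.append(_parse_row({k: v for k, v in row.items()}, i))
        except ValueError as exc:
            rejected.append((i, dict(row), str(exc)))
    return ParseResult(records=records, rejected=rejected)


def records_to_csv(records, path) -> None:
    """Serialize records in the canonical CSV dialect (lossless round-trip)."""
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=CSV_COLUMNS)
        writer.writeheader()
        for r in records:
            writer.writerow(
                {
                    "record_id": r.record_id,
                    "device_code": r.device_code or "",
                    "timestamp": r.timestamp.isoformat(),
                    "lat": repr(r.lat),
                    "lon": repr(r.lon),
                    "waterbody": r.waterbody,
                    "incubation_s": repr(r.incubation_s),
                    "image_path": r.image_path,
                    "user_level": "" if r.user_level is None else r.user_level,
                    "notes": r.notes,
                }
            )


# ---------------------------------------------------------------------------
# QC


def qc_record(
    record: SampleRecord,
    device_reading=None,
    min_incubation_s: float = 180.0,
    blank_excess_threshold: float = 0.1,
) -> list[str]:
    """QC flags for one record (annotations, never blocking).

    blank_anomaly fires when the blank zones read darker than the plain
    laminate by more than ``blank_excess_threshold`` in units of the
    reference-square intensity — the illumination-invariant signature of
    pigmented or turbid water that could fake a positive.
    """
    flags = list(record.qc_flags)
    if record.incubation_s < min_incubation_s:
        flags.append("incubation_short")
    if device_reading is None:
        flags.append("missing_image")
        return flags
    blank_ai = [z.ai for z in device_reading.zone_readings if z.role == "blank"]
    if blank_ai and device_reading.ai_ref > 0:
        excess = (
            float(np.mean(blank_ai)) - device_reading.ai_background
        ) / device_reading.ai_ref
        if excess > blank_excess_threshold:
            flags.append("blank_anomaly")
    if any(z.saturated for z in device_reading.zone_readings):
        flags.append("saturated")
    return flags


# ---------------------------------------------------------------------------
# mapping


@dataclass
class MapFeature:
    lon: float
    lat: float
    category: LevelCategory
    concentration: float
    record_id: str
    date: _dt.datetime
    below_lod: bool = False
    properties: dict = field(default_factory=dict)


@dataclass
class MapResult:
    features: list[MapFeature]
    skipped: list[tuple[str, str]]  # (record_id, reason)


def build_map(records, readings: dict, model: CalibrationModel) -> MapResult:
    """Attach calibrated concentrations and brackets to quantified records.

    ``readings`` maps record_id to a :class:`phospad.quantify.DeviceReading`.
    Records without a reading, or whose reading cannot be inverted, go to the
    skipped list with a reason; features + skipped always partition the input.
    """
    if not model.accepted:
        raise ValueError("calibration model not accepted (non-positive slope)")
    features: list[MapFeature] = []
    skipped: list[tuple[str, str]] = []
    for rec in records:
        reading = readings.get(rec.record_id)
        if reading is None:
            skipped.append((rec.record_id, "no quantifiable image"))
            continue
        try:
            est = invert(
                model,
                reading.ari_mean,
                reading.ari_sd,
                n=max(len(reading.ari_per_zone), 1),
            )
        except OutOfRangeError as exc:
            skipped.append((rec.record_id, str(exc)))
            continue
        conc = max(est.value, 0.0)  # censored negatives classify as zero
        features.append(
            MapFeature(
                lon=rec.lon,
                lat=rec.lat,
                category=classify_level(conc),
                concentration=conc,
                record_id=rec.record_id,
                date=rec.timestamp,
                below_lod=est.below_lod,
                properties={
                    "waterbody": rec.waterbody,
                    "user_level": rec.user_level,
                    "notes": rec.notes,
                    "qc_flags": qc_record(rec, reading),
                },
            )
        )
    return MapResult(features=features, skipped=skipped)


def export_geojson(features, path, marker_colors: dict | None = None) -> None:
    """Write an RFC 7946 FeatureCollection (coordinates ordered lon, lat)."""
    colors = marker_colors or MARKER_COLORS
    collection = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": {
                    "type": "Point",
                    "coordinates": [f.lon, f.lat],
                },
                "properties": {
                    "record_id": f.record_id,
                    "level": f.category.label,
                    "marker-color": colors[f.category],
                    "concentration_mg_per_L": f.concentration,
                    "below_lod": f.below_lod,
                    "date": f.date.isoformat(),
                    **f.properties,
                },
            }
            for f in features
        ],
    }
    with open(path, "w") as fh:
        json.dump(collection, fh, indent=1)


def read_geojson(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# seasonal aggregation


def seasonal_summary(features, grouping: str = "month") -> pd.DataFrame:
    """Period table of counts, mean concentration and category counts.

    ``grouping`` is "month" (1-12) or "quarter" (1-4); periods with no data
    appear with n = 0.  Output order is deterministic (by period).
    """
    if grouping == "month":
        periods = list(range(1, 13))
        key = lambda f: f.date.month  # noqa: E731
    elif grouping == "quarter":
        periods = list(range(1, 5))
        key = lambda f: (f.date.month - 1) // 3 + 1  # noqa: E731
    else:
        raise ValueError(f"grouping must be 'month' or 'quarter', got {grouping!r}")

    rows = []
    feats = list(features)
    for p in periods:
        sel = [f for f in feats if key(f) == p]
        row = {
            grouping: p,
            "n": len(sel),
            "mean_concentration": (
                float(np.mean([f.concentration for f in sel])) if sel else float("nan")
            ),
        }
        for cat in LevelCategory:
            row[f"n_{cat.label}"] = sum(1 for f in sel if f.category == cat)
        with_user = [
            f
            for f in sel
            if f.properties.get("user_level") is not None
        ]
        if with_user:
            row["user_agreement"] = float(
                np.mean(
                    [
                        classify_level(max(float(f.properties["user_level"]), 0.0))
                        == f.category
                        for f in with_user
                    ]
                )
            )
        else:
            row["user_agreement"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
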