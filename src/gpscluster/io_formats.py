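"""Reading and writing the study's file formats.

Fixes come in as delimited text (comma, semicolon or tab) or as GeoJSON
point layers; cluster layers go out as GeoJSON polygons with a plain-text
``key = value`` settings sidecar next to them, so a subsequent analysis can
restore the exact parameters of the previous one.  Waypoint export is GPX
1.1 for hand-held units; tables export as CSV or XLSX.

Conventions:

* CSV coordinates are assumed to already be in the study CRS
  (``config.crs_epsg``, a projected meter-unit CRS); GeoJSON geometries are
  WGS84 per RFC 7946 and are projected at read time.
* Timestamps are UTC throughout and rendered ISO 8601.
* Cluster layers are named ``<label>_clusters_<YYYYMMDDHHMMSS>.geojson``;
  the sidecar replaces ``.geojson`` with ``.settings.txt``.  "Latest" is
  decided by the sidecar's ``analysis_time``, never by filesystem mtime, so
  copying outputs between field laptops cannot reorder history.
"""

from __future__ import annotations

import csv
import json
import logging
from datetime import datetime
from pathlib import Path
from typing import Callable, List, Optional, Sequence, Union
from xml.etree import ElementTree as ET

import pandas as pd
from shapely.geometry import mapping, shape

from . import crs
from .errors import ConfigError, InputError
from .model import (
    AnalysisResult,
    Cluster,
    GpsFix,
    PreviousAnalysis,
    SettingsSidecar,
    StudyConfig,
    format_timestamp,
    parse_timestamp,
)

__all__ = [
    "read_fixes",
    "write_settings",
    "parse_settings",
    "write_cluster_file",
    "read_cluster_file",
    "discover_previous",
    "write_gpx",
    "write_tables",
    "cluster_table",
    "fix_table",
    "NO_LATEST_CLUSTER_FILE",
]

log = logging.getLogger("gpscluster")

#: literal notice logged when a subsequent analysis finds no prior cluster file
NO_LATEST_CLUSTER_FILE = "No latest cluster file"

_DELIMITERS = ",;\t"

GPX_NS = "http://www.topografix.com/GPX/1/1"

#: documented, fixed column orders of the two export tables
CLUSTER_TABLE_COLUMNS = [
    "animal_id",
    "cluster_id",
    "first_time",
    "last_time",
    "mean_x",
    "mean_y",
    "n_inside",
    "n_outside",
    "percent_time",
    "state",
    "event",
    "date_done",
    "technician",
    "notes",
]
#: the optional overview columns controlled by config.add_summary_columns
SUMMARY_COLUMNS = ["n_inside", "n_outside", "percent_time"]

FIX_TABLE_COLUMNS = [
    "animal_id",
    "point_id",
    "cluster_id",
    "timestamp",
    "x",
    "y",
    "lon",
    "lat",
]


# ---------------------------------------------------------------------------
# fixes

def _sniff_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters=_DELIMITERS).delimiter
    except csv.Error:
        return ","


def read_fixes(path, column_map: dict, config: StudyConfig) -> List[GpsFix]:
    """Read GPS fixes from a CSV or GeoJSON point layer.

    ``column_map`` maps the roles ``animal``, ``timestamp``, ``x``, ``y`` to
    source column names (``x``/``y`` are ignored for GeoJSON, where the
    geometry provides coordinates).  Output is deduplicated on
    (animal, timestamp) and sorted ascending per animal.  CSV coordinates
    are taken to be in ``config.crs_epsg`` already; geographic sources are
    projected.  WGS84 lon/lat are retained or derived (for UTM study CRS)
    for GPX and map export.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    for role in ("animal", "timestamp"):
        if role not in column_map:
            raise ConfigError(f"column_map is missing the {role!r} role")

    if path.suffix.lower() in (".geojson", ".json"):
        fixes = _read_fixes_geojson(path, column_map, config)
    else:
        fixes = _read_fixes_csv(path, column_map, config)

    # collapse exact duplicates, keep first occurrence, log the count
    seen = set()
    unique = []
    dropped = 0
    for f in fixes:
        k = (f.animal_id, f.timestamp)
        if k in seen:
            dropped += 1
        else:
            seen.add(k)
            unique.append(f)
    if dropped:
        log.info("collapsed %d duplicate (animal, timestamp) rows", dropped)
    unique.sort(key=lambda f: (f.animal_id, f.timestamp))
    if crs.is_utm_epsg(config.crs_epsg):
        crs.derive_lonlat(unique, config.crs_epsg)
    return unique


def _parse_rows(records, column_map, *, row_offset=0) -> List[GpsFix]:
    fixes = []
    for i, rec in enumerate(records):
        try:
            ts = parse_timestamp(rec["timestamp"])
        except ValueError as exc:
            raise InputError(f"row {i + row_offset}: {exc}") from exc
        fixes.append(
            GpsFix(
                animal_id=str(rec["animal"]),
                timestamp=ts,
                x=rec["x"],
                y=rec["y"],
                lon=rec.get("lon"),
                lat=rec.get("lat"),
            )
        )
    return fixes


def _read_fixes_csv(path: Path, column_map: dict, config: StudyConfig) -> List[GpsFix]:
    for role in ("x", "y"):
        if role not in column_map:
            raise ConfigError(f"column_map is missing the {role!r} role")
    with open(path, newline="") as fh:
        sample = fh.readline()
    sep = _sniff_delimiter(sample)
    try:
        df = pd.read_csv(path, sep=sep, dtype={column_map["animal"]: str})
    except Exception as exc:
        raise InputError(f"could not read {path}: {exc}") from exc
    for role in ("animal", "timestamp", "x", "y"):
        col = column_map[role]
        if col not in df.columns:
            raise ConfigError(
                f"column {col!r} (role {role!r}) not found in {path.name}; "
                f"available: {list(df.columns)}"
            )
    records = (
        {
            "animal": row[column_map["animal"]],
            "timestamp": row[column_map["timestamp"]],
            "x": float(row[column_map["x"]]),
            "y": float(row[column_map["y"]]),
        }
        for _, row in df.iterrows()
    )
    return _parse_rows(records, column_map)


def _read_fixes_geojson(path: Path, column_map: dict, config: StudyConfig) -> List[GpsFix]:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise InputError(f"invalid GeoJSON in {path}: {exc}") from exc
    feats = doc.get("features", [])
    if not crs.is_utm_epsg(config.crs_epsg):
        raise ConfigError(
            f"GeoJSON input is geographic (WGS84) but EPSG:{config.crs_epsg} is not a "
            "supported UTM zone; set crs_epsg to the UTM zone of your study area"
        )
    records = []
    for i, feat in enumerate(feats):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Point":
            raise InputError(f"feature {i}: expected Point geometry, got {geom.get('type')}")
        lon, lat = geom["coordinates"][:2]
        props = feat.get("properties", {})
        for role in ("animal", "timestamp"):
            col = column_map[role]
            if col not in props:
                raise ConfigError(f"property {col!r} (role {role!r}) missing in feature {i}")
        x, y = crs.lonlat_to_projected(lon, lat, config.crs_epsg)
        records.append(
            {
                "animal": props[column_map["animal"]],
                "timestamp": props[column_map["timestamp"]],
                "x": x,
                "y": y,
                "lon": float(lon),
                "lat": float(lat),
            }
        )
    return _parse_rows(records, column_map)


# ---------------------------------------------------------------------------
# settings sidecar

_SIDECAR_KEYS = [
    "label",
    "buffer_m",
    "min_locations",
    "consecutive_only",
    "subsample_minutes",
    "period_start",
    "period_end",
    "crs_epsg",
    "add_summary_columns",
    "mark_done_on_import",
    "analysis_time",
    "app_version",
    "source_fix_file",
]


def write_settings(sidecar: SettingsSidecar, path) -> Path:
    """Write the settings sidecar as one ``key = value`` per line."""
    cfg = sidecar.config
    values = {
        "label": cfg.label,
        "buffer_m": repr(cfg.buffer_m),
        "min_locations": str(cfg.min_locations),
        "consecutive_only": str(cfg.consecutive_only).lower(),
        "subsample_minutes": repr(cfg.subsample_minutes),
        "period_start": format_timestamp(cfg.period_start),
        "period_end": format_timestamp(cfg.period_end),
        "crs_epsg": str(cfg.crs_epsg),
        "add_summary_columns": str(cfg.add_summary_columns).lower(),
        "mark_done_on_import": str(cfg.mark_done_on_import).lower(),
        "analysis_time": format_timestamp(sidecar.analysis_time),
        "app_version": sidecar.app_version,
        "source_fix_file": sidecar.source_fix_file,
    }
    path = Path(path)
    path.write_text("".join(f"{k} = {values[k]}\n" for k in _SIDECAR_KEYS))
    return path


def parse_settings(path) -> SettingsSidecar:
    """Parse a settings sidecar back into a :class:`SettingsSidecar`.

    Round-trips :func:`write_settings` losslessly for every field.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"settings sidecar not found: {path}")
    values = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise InputError(f"{path.name}:{lineno}: expected 'key = value', got {line!r}")
        key, _, val = line.partition("=")
        values[key.strip()] = val.strip()
    missing = [k for k in _SIDECAR_KEYS if k not in values and k != "source_fix_file"]
    if missing:
        raise InputError(f"settings sidecar {path.name} is missing keys: {missing}")

    def as_bool(s):
        return s.lower() in ("true", "1", "yes")

    try:
        config = StudyConfig(
            label=values["label"],
            buffer_m=float(values["buffer_m"]),
            min_locations=int(values["min_locations"]),
            consecutive_only=as_bool(values["consecutive_only"]),
            subsample_minutes=float(values["subsample_minutes"]),
            period_start=parse_timestamp(values["period_start"]),
            period_end=parse_timestamp(values["period_end"]),
            crs_epsg=int(values["crs_epsg"]),
            add_summary_columns=as_bool(values["add_summary_columns"]),
            mark_done_on_import=as_bool(values["mark_done_on_import"]),
        )
        return SettingsSidecar(
            config=config,
            analysis_time=parse_timestamp(values["analysis_time"]),
            app_version=values["app_version"],
            source_fix_file=values.get("source_fix_file", ""),
        )
    except (ValueError, KeyError) as exc:
        raise InputError(f"corrupt settings sidecar {path.name}: {exc}") from exc


# ---------------------------------------------------------------------------
# cluster layer

def _cluster_properties(c: Cluster) -> dict:
    return {
        "animal_id": c.animal_id,
        "seq_number": c.seq_number,
        "cluster_id": c.cluster_id,
        "first_time": format_timestamp(c.first_time),
        "last_time": format_timestamp(c.last_time),
        "mean_x": c.mean_x,
        "mean_y": c.mean_y,
        "n_inside": c.n_inside,
        "n_outside": c.n_outside,
        "percent_time": c.percent_time,
        "state": c.state,
        "event": c.event,
        "date_done": c.date_done or "",
        "technician": c.technician,
        "notes": c.notes,
        "member_point_ids": ";".join(c.member_point_ids),
        "member_times": ";".join(format_timestamp(t) for t in c.member_times),
    }


def write_cluster_file(
    result: AnalysisResult,
    directory,
    app_version: str = "0",
    source_fix_file: str = "",
) -> dict:
    """Write the cluster layer (GeoJSON polygons) and its settings sidecar.

    One feature per cluster carrying the full attribute table, including the
    editable field-status columns and the member lists needed to keep IDs
    stable in subsequent analyses.  Returns
    ``{"layer": path, "settings": path}``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stamp = result.analysis_time.strftime("%Y%m%d%H%M%S")
    base = f"{result.config.label}_clusters_{stamp}"
    layer_path = directory / f"{base}.geojson"

    features = [
        {
            "type": "Feature",
            "geometry": mapping(c.polygon),
            "properties": _cluster_properties(c),
        }
        for c in result.clusters
    ]
    doc = {
        "type": "FeatureCollection",
        "crs": {
            "type": "name",
            "properties": {"name": f"urn:ogc:def:crs:EPSG::{result.config.crs_epsg}"},
        },
        "features": features,
    }
    try:
        layer_path.write_text(json.dumps(doc))
    except OSError as exc:
        raise InputError(f"cannot write cluster layer to {directory}: {exc}") from exc

    sidecar = SettingsSidecar(
        config=result.config,
        analysis_time=result.analysis_time,
        app_version=app_version,
        source_fix_file=source_fix_file,
    )
    settings_path = write_settings(sidecar, directory / f"{base}.settings.txt")
    return {"layer": layer_path, "settings": settings_path}


def read_cluster_file(layer_path) -> List[Cluster]:
    """Load a previously written cluster layer."""
    layer_path = Path(layer_path)
    try:
        doc = json.loads(layer_path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise InputError(f"cannot read cluster layer {layer_path}: {exc}") from exc
    clusters = []
    for feat in doc.get("features", []):
        p = feat["properties"]
        clusters.append(
            Cluster(
                animal_id=p["animal_id"],
                seq_number=int(p["seq_number"]),
                member_point_ids=[s for s in p["member_point_ids"].split(";") if s],
                member_times=[parse_timestamp(s) for s in p["member_times"].split(";") if s],
                polygon=shape(feat["geometry"]),
                mean_x=float(p["mean_x"]),
                mean_y=float(p["mean_y"]),
                first_time=parse_timestamp(p["first_time"]),
                last_time=parse_timestamp(p["last_time"]),
                n_inside=int(p["n_inside"]),
                n_outside=int(p["n_outside"]),
                percent_time=float(p["percent_time"]),
                state=p["state"],
                event=p.get("event", ""),
                date_done=p.get("date_done") or None,
                technician=p.get("technician", ""),
                notes=p.get("notes", ""),
            )
        )
    return clusters


def discover_previous(directory, label: str) -> Optional[PreviousAnalysis]:
    """Find the most recent prior cluster analysis for ``label``.

    Scans ``directory`` for cluster layers whose filename embeds the study
    label and returns the one whose *sidecar* analysis_time is most recent
    (filesystem mtimes are ignored).  Returns ``None`` when no prior layer
    exists; the caller then logs the notice "No latest cluster file" and
    proceeds as an initial analysis.  A matching layer without a readable
    sidecar raises :class:`InputError`, since its settings cannot be
    restored.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise InputError(f"directory not found: {directory}")
    candidates = sorted(directory.glob(f"{label}_clusters_*.geojson"))
    if not candidates:
        return None
    best = None
    for layer in candidates:
        sidecar_path = layer.parent / (layer.name[: -len(".geojson")] + ".settings.txt")
        if not sidecar_path.exists():
            raise InputError(
                f"cluster layer {layer.name} has no settings sidecar; "
                "settings cannot be restored — supply them explicitly"
            )
        sidecar = parse_settings(sidecar_path)
        if sidecar.config.label != label:
            continue
        if best is None or sidecar.analysis_time > best[0].analysis_time:
            best = (sidecar, layer)
    if best is None:
        return None
    sidecar, layer = best
    return PreviousAnalysis(clusters=read_cluster_file(layer), sidecar=sidecar)


# ---------------------------------------------------------------------------
# GPX

def write_gpx(items: Sequence[Union[Cluster, GpsFix]], path, epsg: Optional[int] = None) -> Path:
    """Write clusters or fixes as GPX 1.1 waypoints for hand-held units.

    Cluster waypoints sit at the mean center (reprojected to WGS84 via
    ``epsg``) and are named by cluster ID; fix waypoints use the Point ID
    and the fix's geographic coordinates.  Pass a pre-filtered ``items``
    list to export a table selection.
    """
    wpts = []
    for item in items:
        if isinstance(item, Cluster):
            if epsg is None:
                raise ConfigError("epsg required to reproject cluster mean centers for GPX")
            lon, lat = crs.projected_to_lonlat(item.mean_x, item.mean_y, epsg)
            wpts.append((lat, lon, item.cluster_id, item.last_time))
        else:
            lon, lat = item.lon, item.lat
            if lon is None or lat is None:
                if epsg is None:
                    raise ConfigError("fix has no geographic coordinates and no epsg given")
                lon, lat = crs.projected_to_lonlat(item.x, item.y, epsg)
            wpts.append((lat, lon, item.point_id or "", item.timestamp))

    ET.register_namespace("", GPX_NS)
    root = ET.Element(
        f"{{{GPX_NS}}}gpx", attrib={"version": "1.1", "creator": "gpscluster"}
    )
    for lat, lon, name, time in wpts:
        wpt = ET.SubElement(
            root, f"{{{GPX_NS}}}wpt", attrib={"lat": f"{lat:.8f}", "lon": f"{lon:.8f}"}
        )
        # wptType schema order: time precedes name
        t = ET.SubElement(wpt, f"{{{GPX_NS}}}time")
        t.text = format_timestamp(time)
        n = ET.SubElement(wpt, f"{{{GPX_NS}}}name")
        n.text = str(name)
    tree = ET.ElementTree(root)
    ET.indent(tree)
    path = Path(path)
    tree.write(path, encoding="unicode", xml_declaration=True)
    return path


# ---------------------------------------------------------------------------
# tables

def cluster_table(result: AnalysisResult) -> pd.DataFrame:
    """The "GPS location clusters" table, in the documented column order.

    The overview columns ``n_inside``/``n_outside``/``percent_time`` are
    present only when ``config.add_summary_columns`` is set.
    """
    rows = [
        {
            "animal_id": c.animal_id,
            "cluster_id": c.cluster_id,
            "first_time": format_timestamp(c.first_time),
            "last_time": format_timestamp(c.last_time),
            "mean_x": c.mean_x,
            "mean_y": c.mean_y,
            "n_inside": c.n_inside,
            "n_outside": c.n_outside,
            "percent_time": c.percent_time,
            "state": c.state,
            "event": c.event,
            "date_done": c.date_done or "",
            "technician": c.technician,
            "notes": c.notes,
        }
        for c in result.clusters
    ]
    cols = list(CLUSTER_TABLE_COLUMNS)
    if not result.config.add_summary_columns:
        cols = [c for c in cols if c not in SUMMARY_COLUMNS]
    return pd.DataFrame(rows, columns=cols)


def fix_table(result: AnalysisResult) -> pd.DataFrame:
    """The "GPS data" table: one row per fix used in the analysis."""
    rows = [
        {
            "animal_id": f.animal_id,
            "point_id": f.point_id or "",
            "cluster_id": f"{f.animal_id}_{f.cluster_seq}" if f.cluster_seq else "",
            "timestamp": format_timestamp(f.timestamp),
            "x": f.x,
            "y": f.y,
            "lon": f.lon,
            "lat": f.lat,
        }
        for f in result.fixes
    ]
    return pd.DataFrame(rows, columns=FIX_TABLE_COLUMNS)


def write_tables(
    result: AnalysisResult,
    path,
    which: str = "clusters",
    format: str = "csv",
    row_filter: Optional[Callable[[dict], bool]] = None,
) -> Path:
    """Export the cluster or fix table as CSV or XLSX.

    ``row_filter`` receives each row as a dict and keeps rows it returns
    True for — mirroring the filtered-table export of the interactive
    workflow.
    """
    if which == "clusters":
        df = cluster_table(result)
    elif which == "fixes":
        df = fix_table(result)
    else:
        raise ConfigError(f"unknown table {which!r}; expected 'clusters' or 'fixes'")
    if row_filter is not None:
        keep = [row_filter(dict(row)) for _, row in df.iterrows()]
        df = df[pd.Series(keep, index=df.index)]
    path = Path(path)
    if format == "csv":
        df.to_csv(path, index=False)
    elif format == "xlsx":
        df.to_excel(path, index=False, engine="openpyxl")
    else:
        raise ConfigError(f"unknown format {format!r}; expected 'csv' or 'xlsx'")
    return path
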