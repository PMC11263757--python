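"""Core domain types for GPS activity-cluster analysis.

A *fix* is one timestamped position of one collared animal, held in a
projected, meter-unit coordinate reference system so that buffer distances
are planar Euclidean meters.  A *cluster* is a connected set of fixes whose
circular buffers of radius ``buffer_m`` overlap (centers at most
``2 * buffer_m`` apart) and that meets a minimum-member-count rule.  The
:class:`StudyConfig` carries every parameter of an analysis run and must stay
constant across all re-analyses of one study so clusters remain comparable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from typing import Optional, Sequence

from shapely.geometry.base import BaseGeometry

__all__ = [
    "GpsFix",
    "StudyConfig",
    "SettingsSidecar",
    "Cluster",
    "AnalysisResult",
    "PreviousAnalysis",
    "parse_timestamp",
    "format_timestamp",
    "fix_key",
]

#: Allowed values of a cluster's field-status ``state`` column.
CLUSTER_STATES = ("New", "Grown", "Done")


def parse_timestamp(value) -> datetime:
    """Parse an ISO 8601 or ``YYYY-MM-DD HH:MM:SS`` timestamp as UTC.

    Naive timestamps are taken to be UTC (collar convention); aware ones are
    converted.  Raises ``ValueError`` for unparseable input.
    """
    if isinstance(value, datetime):
        ts = value
    else:
        text = str(value).strip()
        if not text or text.lower() in ("nan", "nat", "none"):
            raise ValueError(f"empty timestamp: {value!r}")
        text = text.replace("Z", "+00:00")
        try:
            ts = datetime.fromisoformat(text)
        except ValueError as exc:
            raise ValueError(f"unparseable timestamp: {value!r}") from exc
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc).replace(microsecond=0)


def format_timestamp(ts: datetime) -> str:
    """Render a UTC instant as ``YYYY-MM-DDTHH:MM:SSZ``."""
    ts = parse_timestamp(ts)
    return ts.strftime("%Y-%m-%dT%H:%M:%SZ")


@dataclass
class GpsFix:
    """One timestamped, projected-coordinate location of one animal.

    ``x``/``y`` are easting/northing in meters in the study CRS.  ``lon`` and
    ``lat`` (WGS84 degrees) are kept, or derived at ingest, for GPX and map
    export.  ``point_id`` and ``cluster_seq`` are filled post-clustering;
    ``cluster_seq is None`` marks a single point (SP).
    """

    animal_id: str
    timestamp: datetime
    x: float
    y: float
    lon: Optional[float] = None
    lat: Optional[float] = None
    point_id: Optional[str] = None
    cluster_seq: Optional[int] = None

    def __post_init__(self):
        self.animal_id = str(self.animal_id)
        self.timestamp = parse_timestamp(self.timestamp)
        self.x = float(self.x)
        self.y = float(self.y)
        if self.lat is not None and not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude out of range: {self.lat}")
        if self.lon is not None and not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude out of range: {self.lon}")

    @property
    def is_finite(self) -> bool:
        return math.isfinite(self.x) and math.isfinite(self.y)

    def copy(self, **changes) -> "GpsFix":
        return replace(self, **changes)


def fix_key(fix: GpsFix) -> tuple:
    """Identity of a fix within a study: (animal_id, timestamp)."""
    return (fix.animal_id, fix.timestamp)


@dataclass
class StudyConfig:
    """Full parameter set of one analysis run.

    ``buffer_m`` is the buffer radius x in meters (clusters form when centers
    are within 2x), ``min_locations`` the minimum member count y, and
    ``subsample_minutes`` the z-minute fix-rate filter (0 keeps every fix).
    These must not change between the initial and any subsequent analysis of
    a study; :func:`gpscluster.incremental.reconcile` enforces that.
    """

    label: str
    buffer_m: float
    min_locations: int
    period_start: datetime
    period_end: datetime
    crs_epsg: int
    consecutive_only: bool = False
    subsample_minutes: float = 0.0
    add_summary_columns: bool = True
    mark_done_on_import: bool = False

    #: fields that must match between runs for cluster IDs to be comparable
    CLUSTERING_FIELDS = (
        "label",
        "buffer_m",
        "min_locations",
        "consecutive_only",
        "subsample_minutes",
        "period_start",
        "period_end",
        "crs_epsg",
    )

    def __post_init__(self):
        self.label = str(self.label)
        if not self.label:
            raise ValueError("label must be non-empty")
        if any(sep in self.label for sep in ("/", "\\", "\0")):
            raise ValueError(f"label may not contain path separators: {self.label!r}")
        self.buffer_m = float(self.buffer_m)
        if not self.buffer_m > 0:
            raise ValueError(f"buffer_m must be > 0, got {self.buffer_m}")
        self.min_locations = int(self.min_locations)
        if self.min_locations < 2:
            raise ValueError(f"min_locations must be >= 2, got {self.min_locations}")
        self.subsample_minutes = float(self.subsample_minutes)
        if self.subsample_minutes < 0:
            raise ValueError("subsample_minutes must be >= 0")
        self.period_start = parse_timestamp(self.period_start)
        self.period_end = parse_timestamp(self.period_end)
        if not self.period_start < self.period_end:
            raise ValueError("period_start must be before period_end")
        self.crs_epsg = int(self.crs_epsg)
        if self.crs_epsg <= 0:
            raise ValueError("crs_epsg must be a positive EPSG code")
        self.consecutive_only = bool(self.consecutive_only)
        self.add_summary_columns = bool(self.add_summary_columns)
        self.mark_done_on_import = bool(self.mark_done_on_import)

    def clustering_fingerprint(self) -> dict:
        return {f: getattr(self, f) for f in self.CLUSTERING_FIELDS}

    def differing_fields(self, other: "StudyConfig") -> list:
        """Clustering-relevant fields on which ``self`` and ``other`` differ."""
        return [
            f
            for f in self.CLUSTERING_FIELDS
            if getattr(self, f) != getattr(other, f)
        ]


@dataclass
class SettingsSidecar:
    """Provenance record written next to every cluster layer.

    Stores the full :class:`StudyConfig` plus the analysis instant, the
    writing package version and the source fix file, so field methods can be
    retraced season-to-season without the original operator.
    """

    config: StudyConfig
    analysis_time: datetime
    app_version: str = "0"
    source_fix_file: str = ""

    def __post_init__(self):
        self.analysis_time = parse_timestamp(self.analysis_time)


@dataclass
class Cluster:
    """One activity cluster of one animal.

    ``cluster_id`` is ``<animal_id>_<seq_number>``; once issued by a run it is
    never reassigned to a different site in subsequent runs.  ``n_outside``
    counts the animal's non-member fixes between the cluster's first and last
    visit, and ``percent_time`` is the fix-count share
    ``100 * n_inside / (n_inside + n_outside)``.  ``state``, ``event``,
    ``date_done``, ``technician`` and ``notes`` are the editable field-status
    columns carried forward across analyses.
    """

    animal_id: str
    seq_number: int
    member_point_ids: list
    member_times: list
    polygon: BaseGeometry
    mean_x: float
    mean_y: float
    first_time: datetime
    last_time: datetime
    n_inside: int
    n_outside: int
    percent_time: float
    state: str = "New"
    event: str = ""
    date_done: Optional[str] = None
    technician: str = ""
    notes: str = ""

    def __post_init__(self):
        self.seq_number = int(self.seq_number)
        if self.seq_number < 1:
            raise ValueError("seq_number must be a positive integer")
        if self.state not in CLUSTER_STATES:
            raise ValueError(f"state must be one of {CLUSTER_STATES}, got {self.state!r}")
        self.first_time = parse_timestamp(self.first_time)
        self.last_time = parse_timestamp(self.last_time)
        if self.first_time > self.last_time:
            raise ValueError("first_time must be <= last_time")
        self.member_times = [parse_timestamp(t) for t in self.member_times]

    @property
    def cluster_id(self) -> str:
        return f"{self.animal_id}_{self.seq_number}"

    def member_keys(self) -> set:
        return {(self.animal_id, t) for t in self.member_times}


@dataclass
class AnalysisResult:
    """Clusters plus the preprocessed fix table that produced them."""

    config: StudyConfig
    clusters: list
    fixes: list
    analysis_time: datetime = field(default_factory=lambda: datetime.now(timezone.utc))

    def __post_init__(self):
        self.analysis_time = parse_timestamp(self.analysis_time)

    def clusters_for(self, animal_id: str) -> list:
        return [c for c in self.clusters if c.animal_id == animal_id]

    def animal_ids(self) -> list:
        seen = dict.fromkeys(f.animal_id for f in self.fixes)
        for c in self.clusters:
            seen.setdefault(c.animal_id, None)
        return list(seen)


@dataclass
class PreviousAnalysis:
    """A previously written cluster layer with its settings sidecar."""

    clusters: list
    sidecar: SettingsSidecar

    def __post_init__(self):
        ids = [c.cluster_id for c in self.clusters]
        if len(ids) != len(set(ids)):
            raise ValueError("previous cluster IDs are not unique")

    @property
    def config(self) -> StudyConfig:
        return self.sidecar.config
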