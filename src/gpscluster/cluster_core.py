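"""Buffer-overlap cluster formation and cluster summaries.

The clustering rule: draw a disc of radius ``buffer_m`` (the buffer, x)
around every fix; two fixes are linked when their buffers overlap, i.e. when
their centers are at most ``2 * buffer_m`` apart (tangency counts).  In the
default mode a cluster is any connected component of that link graph with at
least ``min_locations`` (y) members; in consecutive-only mode a cluster is a
maximal run of time-adjacent fixes in which every consecutive pair is
linked, so spatial revisits separated in time do not cluster.  Clustering is
strictly per animal; fixes of different animals never share a cluster.

Neighbor pairs come from a k-d tree, so the default mode runs in roughly
O(n log n + m) per animal for m overlapping pairs rather than O(n^2).
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import Point
from shapely.ops import unary_union

from . import crs
from .model import AnalysisResult, Cluster, GpsFix, StudyConfig
from .preprocess import preprocess

__all__ = [
    "Partition",
    "find_clusters",
    "find_clusters_consecutive",
    "build_polygon",
    "summarize_cluster",
    "assign_point_ids",
    "run_analysis",
]

#: minimum segments approximating a full buffer circle (8 per quadrant)
CIRCLE_QUAD_SEGS = 8


@dataclass
class Partition:
    """Member partition of one animal's fixes: index sets into the input list."""

    clusters: List[List[int]] = field(default_factory=list)
    singles: set = field(default_factory=set)

    def as_sets(self) -> List[frozenset]:
        return [frozenset(c) for c in self.clusters]


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        root = i
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[i] != root:  # path compression
            self.parent[i], i = root, self.parent[i]
        return root

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _check_single_animal(fixes: Sequence[GpsFix]) -> None:
    animals = {f.animal_id for f in fixes}
    if len(animals) > 1:
        raise ValueError(f"clustering is per animal; got fixes of {sorted(animals)}")


def find_clusters(fixes: Sequence[GpsFix], config: StudyConfig) -> Partition:
    """Default-mode clustering of one animal's fixes.

    Connected components of the "centers within 2 * buffer_m" graph;
    components smaller than ``min_locations`` become singles.
    """
    _check_single_animal(fixes)
    n = len(fixes)
    if n == 0:
        return Partition()
    coords = np.array([(f.x, f.y) for f in fixes])
    uf = _UnionFind(n)
    if n > 1:
        tree = cKDTree(coords)
        for i, j in tree.query_pairs(r=2.0 * config.buffer_m):
            uf.union(i, j)
    components: Dict[int, List[int]] = {}
    for i in range(n):
        components.setdefault(uf.find(i), []).append(i)
    part = Partition()
    for comp in components.values():
        if len(comp) >= config.min_locations:
            part.clusters.append(sorted(comp))
        else:
            part.singles.update(comp)
    part.clusters.sort(key=lambda c: min(fixes[i].timestamp for i in c))
    return part


def find_clusters_consecutive(fixes: Sequence[GpsFix], config: StudyConfig) -> Partition:
    """Consecutive-only clustering: maximal time-sorted runs of linked fixes.

    Every adjacent-in-time pair within a run must be within
    ``2 * buffer_m``; overlapping buffers that are not sequential in time do
    not form a cluster.
    """
    _check_single_animal(fixes)
    n = len(fixes)
    part = Partition()
    if n == 0:
        return part
    order = sorted(range(n), key=lambda i: fixes[i].timestamp)
    limit = 2.0 * config.buffer_m
    run = [order[0]]
    runs = []
    for prev, cur in zip(order, order[1:]):
        a, b = fixes[prev], fixes[cur]
        if np.hypot(b.x - a.x, b.y - a.y) <= limit:
            run.append(cur)
        else:
            runs.append(run)
            run = [cur]
    runs.append(run)
    for r in runs:
        if len(r) >= config.min_locations:
            part.clusters.append(sorted(r))
        else:
            part.singles.update(r)
    part.clusters.sort(key=lambda c: min(fixes[i].timestamp for i in c))
    return part


def build_polygon(members: Sequence[GpsFix], buffer_m: float):
    """Union of circular buffers around the member fixes.

    Circles are approximated by 32-segment regular polygons.  Tangent discs
    (centers exactly ``2 * buffer_m`` apart) touch in a single point; a
    morphological closing with a sub-millimeter epsilon welds such contacts
    so a valid cluster is always one single-part polygon.
    """
    if not members:
        raise ValueError("a cluster polygon needs at least one member fix")
    discs = [Point(f.x, f.y).buffer(buffer_m, quad_segs=CIRCLE_QUAD_SEGS) for f in members]
    poly = unary_union(discs)
    if poly.geom_type != "Polygon":
        eps = max(buffer_m * 1e-6, 1e-6)
        poly = poly.buffer(eps, quad_segs=2).buffer(-eps, quad_segs=2)
    return poly


def summarize_cluster(
    cluster_members: Sequence[GpsFix],
    all_animal_fixes: Sequence[GpsFix],
    config: StudyConfig,
) -> dict:
    """Summary attributes of one cluster.

    ``n_outside`` counts the animal's non-member fixes falling inside the
    cluster's visit window [first_time, last_time]; ``percent_time`` is the
    fix-count share of time spent at the cluster during that window, which
    equals the duration share under a regular fix schedule.
    """
    times = [f.timestamp for f in cluster_members]
    first_time, last_time = min(times), max(times)
    member_keys = {(f.animal_id, f.timestamp) for f in cluster_members}
    n_inside = len(cluster_members)
    n_outside = sum(
        1
        for f in all_animal_fixes
        if (f.animal_id, f.timestamp) not in member_keys
        and first_time <= f.timestamp <= last_time
    )
    xs = [f.x for f in cluster_members]
    ys = [f.y for f in cluster_members]
    return {
        "first_time": first_time,
        "last_time": last_time,
        "n_inside": n_inside,
        "n_outside": n_outside,
        "percent_time": 100.0 * n_inside / (n_inside + n_outside),
        "mean_x": float(np.mean(xs)),
        "mean_y": float(np.mean(ys)),
    }


def _time_token(ts: datetime) -> str:
    return ts.strftime("%m%d%H")


def assign_point_ids(result: AnalysisResult) -> AnalysisResult:
    """Assign a unique Point ID to every fix, in place.

    Grammar: ``<animal>_<C{seq}|SP>_<MMDDHH>`` with zero-padded month, day
    and hour; SP marks a single point.  When several fixes of one animal
    share the same ID, the zero-padded minute is appended to each, and any
    remaining collision gets a running lowercase letter in timestamp order.
    """
    groups: Dict[str, List[GpsFix]] = {}
    for f in result.fixes:
        token = f"C{f.cluster_seq}" if f.cluster_seq is not None else "SP"
        base = f"{f.animal_id}_{token}_{_time_token(f.timestamp)}"
        groups.setdefault(base, []).append(f)

    assigned: Dict[str, List[GpsFix]] = {}
    for base, members in groups.items():
        if len(members) == 1:
            assigned.setdefault(base, []).append(members[0])
        else:
            for f in members:
                assigned.setdefault(base + f.timestamp.strftime("%M"), []).append(f)

    letters = string.ascii_lowercase
    for pid, members in assigned.items():
        if len(members) == 1:
            members[0].point_id = pid
        else:
            members.sort(key=lambda f: f.timestamp)
            for k, f in enumerate(members):
                suffix = letters[k % 26] * (1 + k // 26)
                f.point_id = pid + suffix

    by_key = {(f.animal_id, f.timestamp): f.point_id for f in result.fixes}
    for c in result.clusters:
        c.member_point_ids = [by_key[(c.animal_id, t)] for t in c.member_times]
    return result


def run_analysis(
    fixes: Sequence[GpsFix],
    config: StudyConfig,
    analysis_time: Optional[datetime] = None,
) -> AnalysisResult:
    """Full single-batch analysis: preprocess, cluster, summarize, label.

    Pipeline: validate -> period filter -> z-minute subsample -> per-animal
    clustering (default or consecutive-only per ``config``) -> per-animal
    sequence numbering by first visit time (earliest cluster = 1) -> buffer
    polygons, summaries and Point IDs.  Every cluster starts in state
    ``New``.  Deterministic: the same input always yields the same tables.
    """
    work = [f.copy(point_id=None, cluster_seq=None) for f in fixes]
    clean, _report = preprocess(work, config)

    per_animal: Dict[str, List[GpsFix]] = {}
    for f in clean:
        per_animal.setdefault(f.animal_id, []).append(f)

    clusters: List[Cluster] = []
    for animal_id in sorted(per_animal):
        animal_fixes = per_animal[animal_id]
        if config.consecutive_only:
            part = find_clusters_consecutive(animal_fixes, config)
        else:
            part = find_clusters(animal_fixes, config)
        # partition clusters are already ordered by first member time
        for seq, idxs in enumerate(part.clusters, start=1):
            members = sorted((animal_fixes[i] for i in idxs), key=lambda f: f.timestamp)
            for f in members:
                f.cluster_seq = seq
            summary = summarize_cluster(members, animal_fixes, config)
            clusters.append(
                Cluster(
                    animal_id=animal_id,
                    seq_number=seq,
                    member_point_ids=[],  # filled by assign_point_ids
                    member_times=[f.timestamp for f in members],
                    polygon=build_polygon(members, config.buffer_m),
                    state="New",
                    **summary,
                )
            )

    result = AnalysisResult(
        config=config,
        clusters=clusters,
        fixes=clean,
        analysis_time=analysis_time or datetime.now(timezone.utc),
    )
    assign_point_ids(result)
    if crs.is_utm_epsg(config.crs_epsg):
        crs.derive_lonlat(result.fixes, config.crs_epsg)
    return result
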