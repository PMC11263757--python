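"""Subsequent analyses: keep previously issued cluster IDs constant.

Field crews re-run the cluster analysis every few days as new fixes arrive.
New data can grow an existing cluster, bridge two previous clusters into
one, or create entirely new clusters — but a cluster ID that technicians
have already visited and written on datasheets must never move to a
different site or be reused.  The strategy here: recompute clustering on
the full (old + new) fix set with the identical parameters, then *relabel*
the fresh clusters from the previous run's IDs.  Because clustering is
deterministic, this one code path guarantees the incremental result has
exactly the single-batch member partition, with only the labels carried
over.

Matching uses member fix identity (animal id, timestamp): with unchanged
parameters and appended data, every previous cluster's member set is wholly
contained in exactly one cluster of the recomputed run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .cluster_core import assign_point_ids, run_analysis
from .errors import InputError, SettingsMismatchError
from .model import (
    AnalysisResult,
    GpsFix,
    PreviousAnalysis,
    SettingsSidecar,
    StudyConfig,
)

__all__ = ["ReconciliationReport", "reconcile", "batch_equivalence_check", "as_previous"]


@dataclass
class ReconciliationReport:
    """Which previous IDs were kept, grew, merged, and which IDs are new."""

    kept_ids: List[str] = field(default_factory=list)
    grown_ids: List[str] = field(default_factory=list)
    merged: List[Tuple[str, str]] = field(default_factory=list)  # (absorbed -> surviving)
    new_ids: List[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = (
            [{"cluster_id": i, "outcome": "kept", "into": ""} for i in self.kept_ids]
            + [{"cluster_id": i, "outcome": "grown", "into": ""} for i in self.grown_ids]
            + [{"cluster_id": a, "outcome": "absorbed", "into": s} for a, s in self.merged]
            + [{"cluster_id": i, "outcome": "new", "into": ""} for i in self.new_ids]
        )
        return pd.DataFrame(rows, columns=["cluster_id", "outcome", "into"])


def as_previous(
    result: AnalysisResult, app_version: str = "0", source_fix_file: str = ""
) -> PreviousAnalysis:
    """Wrap an in-memory result as the previous analysis of a later run."""
    return PreviousAnalysis(
        clusters=list(result.clusters),
        sidecar=SettingsSidecar(
            config=result.config,
            analysis_time=result.analysis_time,
            app_version=app_version,
            source_fix_file=source_fix_file,
        ),
    )


def reconcile(
    current: AnalysisResult,
    previous: PreviousAnalysis,
    config: StudyConfig,
) -> Tuple[AnalysisResult, ReconciliationReport]:
    """Relabel a freshly computed result so previous cluster IDs persist.

    ``current`` must have been computed by :func:`run_analysis` on the full
    fix set (old + new) under ``config``, and ``config`` must match the
    previous run on every clustering-relevant field — changing parameters
    mid-study makes clusters incomparable and raises
    :class:`SettingsMismatchError`.

    Outcomes per current cluster: identical member set to one previous
    cluster -> *kept* (ID and state carried over); superset of one previous
    cluster -> *grown* (same ID, state ``Grown``); superset of several ->
    the lowest previous sequence number survives and the others are
    recorded as absorbed, their field notes concatenated; no previous
    members -> *new*, numbered from (per-animal max previous seq) + 1 so an
    absorbed number is never reused.  Editable columns (event, date done,
    technician, notes) always carry over from the matched previous cluster.
    """
    differing = config.differing_fields(previous.config)
    if differing:
        raise SettingsMismatchError(
            "clustering parameters changed since the previous analysis; "
            f"differing fields: {differing}. Parameters must stay the same "
            "throughout the study period."
        )

    prev_clusters = list(previous.clusters)
    if config.mark_done_on_import:
        for c in prev_clusters:
            c.state = "Done"

    current_keys = {(f.animal_id, f.timestamp) for f in current.fixes}
    for pc in prev_clusters:
        missing = pc.member_keys() - current_keys
        if missing:
            raise InputError(
                f"previous cluster {pc.cluster_id} has members absent from the "
                f"current fix file (e.g. {sorted(missing)[:3]}); the fix file "
                "appears truncated — subsequent analyses must include all earlier data"
            )

    # map each previous cluster to the current cluster containing its members
    key_to_current: Dict[tuple, int] = {}
    for ci, cc in enumerate(current.clusters):
        for k in cc.member_keys():
            key_to_current[k] = ci
    matches: Dict[int, List] = {ci: [] for ci in range(len(current.clusters))}
    for pc in prev_clusters:
        homes = {key_to_current.get(k) for k in pc.member_keys()}
        if len(homes) != 1 or None in homes:
            raise InputError(
                f"previous cluster {pc.cluster_id} no longer maps to a single "
                "cluster; new data must extend the time series, not interleave it"
            )
        matches[homes.pop()].append(pc)

    report = ReconciliationReport()
    max_prev_seq: Dict[str, int] = {}
    for pc in prev_clusters:
        max_prev_seq[pc.animal_id] = max(max_prev_seq.get(pc.animal_id, 0), pc.seq_number)
    next_seq = dict(max_prev_seq)

    # deterministic new-ID order: first visit time
    order = sorted(range(len(current.clusters)), key=lambda i: current.clusters[i].first_time)
    for ci in order:
        cc = current.clusters[ci]
        prev_matched = sorted(matches[ci], key=lambda p: p.seq_number)
        if not prev_matched:
            seq = next_seq.get(cc.animal_id, 0) + 1
            next_seq[cc.animal_id] = seq
            cc.seq_number = seq
            cc.state = "New"
            report.new_ids.append(cc.cluster_id)
            continue
        survivor = prev_matched[0]
        cc.seq_number = survivor.seq_number
        cc.event = survivor.event
        cc.date_done = survivor.date_done
        cc.technician = survivor.technician
        cc.notes = survivor.notes
        if len(prev_matched) == 1 and cc.member_keys() == survivor.member_keys():
            cc.state = survivor.state
            report.kept_ids.append(cc.cluster_id)
        else:
            cc.state = "Grown"
            report.grown_ids.append(cc.cluster_id)
            for absorbed in prev_matched[1:]:
                fragments = [
                    f"{name}={value}"
                    for name, value in (
                        ("state", absorbed.state),
                        ("event", absorbed.event),
                        ("date_done", absorbed.date_done or ""),
                        ("technician", absorbed.technician),
                        ("notes", absorbed.notes),
                    )
                    if value
                ]
                tag = f"[absorbed {absorbed.cluster_id}: " + "; ".join(fragments) + "]"
                cc.notes = (cc.notes + " " + tag).strip()
                report.merged.append((absorbed.cluster_id, cc.cluster_id))

    # rewrite fix cluster_seq to the persistent numbers, then point IDs
    new_seq_by_key: Dict[tuple, int] = {}
    for cc in current.clusters:
        for k in cc.member_keys():
            new_seq_by_key[k] = cc.seq_number
    for f in current.fixes:
        f.cluster_seq = new_seq_by_key.get((f.animal_id, f.timestamp))
    current.clusters.sort(key=lambda c: (c.animal_id, c.seq_number))
    assign_point_ids(current)
    return current, report


def batch_equivalence_check(
    fixes: Sequence[GpsFix], split_time: datetime, config: StudyConfig
) -> bool:
    """True iff incremental (two-stage) analysis matches the single batch.

    Runs the analysis on fixes up to ``split_time``, reconciles a full-data
    re-run against it, and compares member partitions with a direct
    single-batch run on all fixes.  IDs may legitimately differ only where
    merges relabeled a cluster.
    """
    batch = run_analysis(fixes, config)
    stage1 = run_analysis([f for f in fixes if f.timestamp <= split_time], config)
    stage2_input = run_analysis(fixes, config)
    stage2, _report = reconcile(stage2_input, as_previous(stage1), config)

    def partition(result: AnalysisResult) -> set:
        return {frozenset(c.member_keys()) for c in result.clusters}

    return partition(batch) == partition(stage2)
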