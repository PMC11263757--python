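"""Fix-table preprocessing: validation, study-period filter, z-minute subsampling.

Pipeline order is fixed as validate -> filter_period -> subsample; the period
filter and the subsampler do not commute (subsampling anchors at each
animal's first *in-period* fix), so callers should go through
:func:`preprocess` or :func:`gpscluster.cluster_core.run_analysis` rather
than composing the steps ad hoc.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import timedelta
from typing import List

from .model import GpsFix, StudyConfig, fix_key

__all__ = ["ValidationReport", "validate", "filter_period", "subsample", "preprocess"]


@dataclass
class ValidationReport:
    n_input: int = 0
    n_duplicates_dropped: int = 0
    n_nonfinite_dropped: int = 0
    n_output: int = 0
    messages: list = field(default_factory=list)


def validate(fixes: List[GpsFix]) -> tuple:
    """Sort per (animal, timestamp), drop non-finite rows and exact duplicates.

    Duplicate (animal, timestamp) rows keep the first occurrence.  Returns
    ``(clean_fixes, report)``; raises ``ValueError`` when nothing survives of
    a non-empty input.
    """
    report = ValidationReport(n_input=len(fixes))
    finite = []
    for f in fixes:
        if f.is_finite:
            finite.append(f)
        else:
            report.n_nonfinite_dropped += 1
    seen = set()
    unique = []
    for f in finite:  # input order decides which duplicate is "first"
        k = fix_key(f)
        if k in seen:
            report.n_duplicates_dropped += 1
        else:
            seen.add(k)
            unique.append(f)
    unique.sort(key=fix_key)
    report.n_output = len(unique)
    if report.n_duplicates_dropped:
        report.messages.append(
            f"collapsed {report.n_duplicates_dropped} duplicate (animal, timestamp) rows"
        )
    if report.n_nonfinite_dropped:
        report.messages.append(
            f"dropped {report.n_nonfinite_dropped} rows with non-finite coordinates"
        )
    if fixes and not unique:
        raise ValueError("no usable fixes")
    return unique, report


def filter_period(fixes: List[GpsFix], config: StudyConfig) -> List[GpsFix]:
    """Keep fixes inside the closed study period [period_start, period_end]."""
    return [
        f for f in fixes if config.period_start <= f.timestamp <= config.period_end
    ]


def subsample(fixes: List[GpsFix], z_minutes: float) -> List[GpsFix]:
    """Thin each animal's track to at most one fix per ``z_minutes``.

    Greedy forward rule anchored at the animal's first fix: keep the first
    fix, then keep the next fix whose timestamp is at least ``z_minutes``
    after the last kept fix.  Neutralizes burst/proximity oversampling while
    leaving an already-regular schedule untouched.  ``z_minutes == 0`` keeps
    everything.
    """
    if z_minutes < 0:
        raise ValueError("z_minutes must be >= 0")
    if z_minutes == 0 or not fixes:
        return list(fixes)
    gap = timedelta(minutes=z_minutes)
    kept: List[GpsFix] = []
    last_kept_per_animal: dict = {}
    for f in fixes:
        last = last_kept_per_animal.get(f.animal_id)
        if last is None or f.timestamp - last >= gap:
            kept.append(f)
            last_kept_per_animal[f.animal_id] = f.timestamp
    return kept


def preprocess(fixes: List[GpsFix], config: StudyConfig) -> tuple:
    """Full preprocessing pipeline; returns (fixes, ValidationReport)."""
    clean, report = validate(fixes)
    in_period = filter_period(clean, config)
    thinned = subsample(in_period, config.subsample_minutes)
    report.messages.append(
        f"{len(clean) - len(in_period)} fixes outside the study period; "
        f"{len(in_period) - len(thinned)} removed by {config.subsample_minutes:g}-minute subsampling"
    )
    return thinned, report
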