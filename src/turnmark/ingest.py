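"""Reading raw PIT-tag detections and turning them into filtered visit records.

The processing chain is: parse a read table, chain-collapse reads by the same
carer that fall within a gap window (default 2 min) into single visits, segment
visits into observation days, then apply the standard data filters (minimum
brood age, fledge day, disturbance windows).
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd

from .types import AttemptMetadata, PitRead, ProvisioningAttempt, Visit, VisitDay

__all__ = [
    "read_visit_table",
    "collapse_reads",
    "segment_days",
    "default_day_calendar",
    "apply_filters",
    "read_canonical_visits",
    "write_canonical_visits",
    "attempt_from_reads",
]

log = logging.getLogger(__name__)

DEFAULT_GAP_WINDOW = 120.0  # seconds: reads by one carer within 2 min chain into a visit
DEFAULT_MIN_BROOD_AGE = 10.0  # days: younger broods confound brooding with provisioning

_REQUIRED_COLUMNS = ("attempt_id", "carer_id", "timestamp")


def _parse_timestamp(value, row: int) -> float:
    """Accept epoch seconds or an ISO-8601 string; error names the data row."""
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        if not np.isfinite(value):
            raise ValueError(f"row {row}: non-finite timestamp {value!r}")
        return float(value)
    text = str(value).strip()
    try:
        return float(text)
    except ValueError:
        pass
    ts = pd.to_datetime(text, errors="coerce", utc=True)
    if pd.isna(ts):
        raise ValueError(f"row {row}: malformed timestamp {value!r}")
    return ts.timestamp()


def read_visit_table(source) -> list[PitRead]:
    """Parse a CSV of reads (columns attempt_id, carer_id, timestamp).

    Returns reads sorted ascending by time within attempt; the sort is stable,
    so input order is preserved on exact time ties.  Data rows are numbered
    from 1 (excluding the header) in error messages.
    """
    df = pd.read_csv(source, dtype={"attempt_id": str, "carer_id": str})
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    reads = [
        PitRead(row.attempt_id, row.carer_id, _parse_timestamp(row.timestamp, i))
        for i, row in enumerate(df.itertuples(index=False), start=1)
    ]
    reads.sort(key=lambda r: (r.attempt_id, r.time))  # stable: ties keep input order
    return reads


def collapse_reads(reads: list[PitRead], gap_window: float = DEFAULT_GAP_WINDOW) -> list[Visit]:
    """Chain-collapse consecutive reads by the same carer into visits.

    A read extends the current visit of its carer while the gap to that
    carer's previous read is <= ``gap_window``; otherwise it starts a new
    visit.  The visit time is the first read of the chain (arrival at the
    nest).  Reads by different carers never merge.
    """
    if gap_window < 0:
        raise ValueError(f"gap_window must be nonnegative, got {gap_window}")
    visits: list[Visit] = []
    # (attempt, carer) -> [start_time, last_read_time, n_reads]
    open_chains: dict[tuple[str, str], list] = {}

    def _close(key) -> None:
        start, _last, n = open_chains.pop(key)
        visits.append(Visit(key[0], key[1], start, n_reads=n))

    for read in reads:
        key = (read.attempt_id, read.carer_id)
        chain = open_chains.get(key)
        if chain is not None and read.time - chain[1] <= gap_window:
            chain[1] = read.time
            chain[2] += 1
        else:
            if chain is not None:
                _close(key)
            open_chains[key] = [read.time, read.time, 1]
    for key in list(open_chains):
        _close(key)
    visits.sort(key=lambda v: (v.attempt_id, v.time))
    return visits


def default_day_calendar(times, day_length: float = 86400.0) -> list[tuple[float, float]]:
    """One half-open window per calendar day (period of ``day_length`` from epoch 0)."""
    days = sorted({int(np.floor(t / day_length)) for t in times})
    return [(d * day_length, (d + 1) * day_length) for d in days]


def segment_days(
    visits: list[Visit], day_calendar: list[tuple[float, float]]
) -> list[VisitDay]:
    """Assign visits to half-open calendar windows ``[start, end)``.

    Windows must be disjoint and ordered; visits outside every window are
    dropped (count logged).  Windows with no visits produce no VisitDay.
    """
    for (s1, e1), (s2, e2) in zip(day_calendar, day_calendar[1:]):
        if e1 > s2:
            raise ValueError(f"overlapping day windows [{s1},{e1}) and [{s2},{e2})")
    out: list[VisitDay] = []
    dropped = 0
    by_window: list[list[Visit]] = [[] for _ in day_calendar]
    for v in sorted(visits, key=lambda v: v.time):
        for w, (start, end) in enumerate(day_calendar):
            if start <= v.time < end:
                by_window[w].append(v)
                break
        else:
            dropped += 1
    if dropped:
        log.info("segment_days: dropped %d visit(s) outside all day windows", dropped)
    for w, (start, end) in enumerate(day_calendar):
        if by_window[w]:
            day_index = w + 1
            out.append(
                VisitDay(
                    day_index,
                    start,
                    end,
                    [replace(v, day_index=day_index) for v in by_window[w]],
                )
            )
    return out


def apply_filters(
    attempt: ProvisioningAttempt,
    min_brood_age: float = DEFAULT_MIN_BROOD_AGE,
    allow_missing_metadata: bool = False,
) -> ProvisioningAttempt:
    """Apply the standard data filters, attaching a per-rule removal report.

    Removes: days with brood age <= ``min_brood_age`` (brooding vs.
    provisioning confound), the fledge day when known, and visits inside any
    disturbance window (half-open).  With ``allow_missing_metadata`` the
    brood-age filter passes days that have no recorded age.
    """
    meta = attempt.metadata
    report = {"days_young_brood": 0, "days_fledge": 0, "visits_disturbance": 0}
    kept_days: list[VisitDay] = []
    for day in attempt.days:
        age = meta.brood_age.get(day.day_index)
        if age is None:
            if not allow_missing_metadata:
                raise ValueError(
                    f"no brood age recorded for day {day.day_index}; "
                    "set allow_missing_metadata=True to skip the age filter"
                )
        elif age <= min_brood_age:
            report["days_young_brood"] += 1
            continue
        if meta.fledge_day_index is not None and day.day_index == meta.fledge_day_index:
            report["days_fledge"] += 1
            continue
        if meta.disturbance_windows:
            kept = [
                v
                for v in day.visits
                if not any(s <= v.time < e for s, e in meta.disturbance_windows)
            ]
            report["visits_disturbance"] += day.n_visits - len(kept)
            day = replace(day, visits=kept)
        kept_days.append(day)
    for rule, n in report.items():
        if n:
            log.info("apply_filters[%s]: removed %d (%s)", attempt.attempt_id, n, rule)
    return ProvisioningAttempt(
        attempt.attempt_id, kept_days, meta, filter_report=report
    )


def attempt_from_reads(
    reads: list[PitRead],
    metadata: AttemptMetadata | None = None,
    gap_window: float = DEFAULT_GAP_WINDOW,
    day_calendar: list[tuple[float, float]] | None = None,
) -> ProvisioningAttempt:
    """Convenience: collapse + segment one attempt's reads into an attempt."""
    ids = {r.attempt_id for r in reads}
    if len(ids) != 1:
        raise ValueError(f"expected reads from exactly one attempt, got {sorted(ids)}")
    visits = collapse_reads(reads, gap_window=gap_window)
    if day_calendar is None:
        day_calendar = default_day_calendar([v.time for v in visits])
    days = segment_days(visits, day_calendar)
    return ProvisioningAttempt(ids.pop(), days, metadata or AttemptMetadata())


def write_canonical_visits(attempt: ProvisioningAttempt, path) -> None:
    """Write the canonical visit CSV: attempt_id,day_index,carer_id,time_s.

    ``time_s`` is seconds from the day's observation start.
    """
    rows = [
        (attempt.attempt_id, d.day_index, v.carer_id, v.time - d.day_start)
        for d in attempt.days
        for v in d.visits
    ]
    pd.DataFrame(rows, columns=["attempt_id", "day_index", "carer_id", "time_s"]).to_csv(
        path, index=False
    )


def read_canonical_visits(
    source,
    metadata: AttemptMetadata | None = None,
    day_length: float = 86400.0,
) -> list[ProvisioningAttempt]:
    """Read the canonical visit CSV back into attempts (one per attempt_id).

    Day windows are reconstructed as ``[k*day_length, (k+1)*day_length)`` with
    k = day_index - 1, matching what :func:`write_canonical_visits` emits for
    simulated or pre-segmented data.
    """
    df = pd.read_csv(source, dtype={"attempt_id": str, "carer_id": str})
    need = {"attempt_id", "day_index", "carer_id", "time_s"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(sorted(missing))}")
    attempts = []
    for aid, grp in df.groupby("attempt_id", sort=True):
        days = []
        for di, dgrp in grp.groupby("day_index", sort=True):
            di = int(di)
            start = (di - 1) * day_length
            dgrp = dgrp.sort_values("time_s", kind="stable")
            visits = [
                Visit(aid, r.carer_id, start + float(r.time_s), day_index=di)
                for r in dgrp.itertuples(index=False)
            ]
            days.append(VisitDay(di, start, start + day_length, visits))
        attempts.append(ProvisioningAttempt(aid, days, metadata or AttemptMetadata()))
    return attempts
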