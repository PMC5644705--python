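"""Core record types for provisioning-visit analysis.

The central object is a :class:`ProvisioningAttempt`: one nest's visit record
for one breeding attempt, segmented into observation days.  All timestamps are
seconds (floats).  Within a day, visit times lie in the half-open observation
window ``[day_start, day_end)``; inter-visit intervals never span a day
boundary anywhere downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PitRead",
    "Visit",
    "VisitDay",
    "AttemptMetadata",
    "ProvisioningAttempt",
    "day_arrays",
]


@dataclass(frozen=True)
class PitRead:
    """A single raw transponder detection at the nest antenna."""

    attempt_id: str
    carer_id: str
    time: float  # seconds since a fixed epoch

    def __post_init__(self) -> None:
        if not np.isfinite(self.time):
            raise ValueError(f"non-finite read time for carer {self.carer_id!r}")
        if not self.carer_id:
            raise ValueError("empty carer_id in PIT read")


@dataclass(frozen=True)
class Visit:
    """A discrete provisioning visit (possibly collapsed from several reads)."""

    attempt_id: str
    carer_id: str
    time: float
    day_index: int = 0
    n_reads: int = 1


@dataclass
class VisitDay:
    """One observation day: an ordered list of visits within a time window."""

    day_index: int
    day_start: float
    day_end: float
    visits: list[Visit] = field(default_factory=list)

    def __post_init__(self) -> None:
        times = [v.time for v in self.visits]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError(f"day {self.day_index}: visits not sorted by time")
        if times and (times[0] < self.day_start or times[-1] >= self.day_end):
            raise ValueError(
                f"day {self.day_index}: visit outside [{self.day_start}, {self.day_end})"
            )

    @property
    def n_visits(self) -> int:
        return len(self.visits)


@dataclass
class AttemptMetadata:
    """Attempt-level metadata used by the data filters and carer classes.

    brood_age maps day_index -> brood age in days; disturbance windows are
    half-open absolute-time intervals ``[start, end)``; carer_class maps
    carer_id -> one of breeding_male / breeding_female / helper / unknown.
    """

    brood_size: int | None = None
    brood_age: dict[int, float] = field(default_factory=dict)
    fledge_day_index: int | None = None
    disturbance_windows: list[tuple[float, float]] = field(default_factory=list)
    carer_class: dict[str, str] = field(default_factory=dict)


@dataclass
class ProvisioningAttempt:
    """All observation days of one breeding attempt, plus metadata."""

    attempt_id: str
    days: list[VisitDay]
    metadata: AttemptMetadata = field(default_factory=AttemptMetadata)
    filter_report: dict | None = None

    def __post_init__(self) -> None:
        idx = [d.day_index for d in self.days]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("days must be ordered by strictly increasing day_index")

    @property
    def n_visits(self) -> int:
        return sum(d.n_visits for d in self.days)

    @property
    def carer_ids(self) -> list[str]:
        """Distinct carer ids in order of first appearance."""
        seen: dict[str, None] = {}
        for day in self.days:
            for v in day.visits:
                seen.setdefault(v.carer_id, None)
        return list(seen)

    def visit_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for day in self.days:
            for v in day.visits:
                counts[v.carer_id] = counts.get(v.carer_id, 0) + 1
        return counts

    def restrict_to(self, carer_ids) -> "ProvisioningAttempt":
        """Drop visits by carers outside ``carer_ids`` (order preserved)."""
        keep = set(carer_ids)
        days = [
            replace(d, visits=[v for v in d.visits if v.carer_id in keep])
            for d in self.days
        ]
        return ProvisioningAttempt(self.attempt_id, days, self.metadata)


def day_arrays(
    attempt: ProvisioningAttempt, carer_ids: list[str]
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Convert each day to ``(times, codes)`` numpy arrays.

    ``codes[k]`` is the index of the k-th visitor in ``carer_ids``.  Visits by
    carers not in ``carer_ids`` are dropped.  This is the fast path used by the
    model fits and the randomization machinery.
    """
    index = {cid: i for i, cid in enumerate(carer_ids)}
    out = []
    for day in attempt.days:
        kept = [(v.time, index[v.carer_id]) for v in day.visits if v.carer_id in index]
        if kept:
            t, c = zip(*kept)
        else:
            t, c = (), ()
        out.append((np.asarray(t, dtype=float), np.asarray(c, dtype=np.intp)))
    return out
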