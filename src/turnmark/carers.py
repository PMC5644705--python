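"""Identifying the significant carers of a breeding attempt.

Rarely visiting individuals (often immigrants or juveniles) have little
opportunity to respond to the investment of others, and their transition rates
are poorly identified, so they are excluded by an iterative rule: the
least-visiting carer is removed whenever its visit count fails to exceed a
fraction (default 20%) of the mean count of the rest of the group, and the
test repeats on the next-lowest until the lowest retained carer passes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

__all__ = [
    "CarerEntry",
    "CarerSet",
    "classify_significant",
    "validate_for_fitting",
    "rank_helpers",
]

log = logging.getLogger(__name__)

DEFAULT_THRESHOLD_FRAC = 0.2
DEFAULT_MIN_VISITS = 10  # significant carers must visit strictly more than this
DEFAULT_MAX_CARERS = 6  # data demand grows as c^2; larger groups flagged


@dataclass
class CarerEntry:
    carer_id: str
    visit_count: int
    carer_class: str = "unknown"
    helper_rank: int | None = None  # 1 = primary helper; highest rank = terminal
    terminal: bool = False


@dataclass
class CarerSet:
    """Significant carers of one attempt, ordered by descending visit count."""

    attempt_id: str
    carers: list[CarerEntry]
    excluded: list[tuple[str, int, int]] = field(default_factory=list)  # (id, count, round)

    @property
    def c(self) -> int:
        return len(self.carers)

    @property
    def carer_ids(self) -> list[str]:
        return [e.carer_id for e in self.carers]

    def counts(self) -> dict[str, int]:
        return {e.carer_id: e.visit_count for e in self.carers}


def classify_significant(
    visit_counts: dict[str, int],
    threshold_frac: float = DEFAULT_THRESHOLD_FRAC,
    attempt_id: str = "",
    carer_classes: dict[str, str] | None = None,
) -> CarerSet:
    """Apply the iterative 20%-of-the-rest exclusion rule.

    Each round tests only the currently least-visiting carer: it is excluded
    iff its count <= threshold_frac * mean(counts of the other retained
    carers).  "Failed to exceed" is read strictly, so a count exactly at the
    cutoff is excluded.  The retained set is independent of input ordering
    (ties broken by carer id for determinism).
    """
    if not visit_counts:
        raise ValueError("empty visit_counts")
    if threshold_frac < 0:
        raise ValueError(f"threshold_frac must be >= 0, got {threshold_frac}")
    # descending count, ascending id on ties: deterministic regardless of input order
    retained = sorted(visit_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    excluded: list[tuple[str, int, int]] = []
    rnd = 0
    while len(retained) > 1:
        cid, count = retained[-1]
        rest_mean = sum(n for _, n in retained[:-1]) / (len(retained) - 1)
        if count <= threshold_frac * rest_mean:
            rnd += 1
            excluded.append((cid, count, rnd))
            retained.pop()
        else:
            break
    classes = carer_classes or {}
    carers = [
        CarerEntry(cid, n, classes.get(cid, "unknown")) for cid, n in retained
    ]
    if excluded:
        log.info(
            "classify_significant[%s]: excluded %d carer(s): %s",
            attempt_id,
            len(excluded),
            ", ".join(f"{cid} ({n} visits, round {r})" for cid, n, r in excluded),
        )
    return CarerSet(attempt_id, carers, excluded)


def validate_for_fitting(
    carer_set: CarerSet,
    min_visits: int = DEFAULT_MIN_VISITS,
    max_carers: int = DEFAULT_MAX_CARERS,
    transition_counts=None,
) -> dict:
    """Report whether the attempt supports fitting the visit-rate models.

    Invalid when any significant carer has <= ``min_visits`` visits (the rates
    of rare visitors are inestimable) or when only one significant carer
    remains (no alternation is possible).  Large groups (c > ``max_carers``)
    and (previous, next) carer pairs never observed (given ``transition_counts``,
    a c-by-c matrix aligned with ``carer_set.carer_ids``) produce warnings but
    do not block fitting.
    """
    warnings: list[str] = []
    valid = True
    low = [e for e in carer_set.carers if e.visit_count <= min_visits]
    if low:
        valid = False
        warnings.append(
            "carer(s) with too few visits (need more than "
            f"{min_visits}): " + ", ".join(f"{e.carer_id}={e.visit_count}" for e in low)
        )
    if carer_set.c == 1:
        valid = False
        warnings.append("single significant carer: turn-taking analysis undefined")
    if carer_set.c > max_carers:
        warnings.append(
            f"{carer_set.c} significant carers: data demand grows as c^2; "
            "rate estimates may be unreliable"
        )
    zero_pairs: list[tuple[str, str]] = []
    if transition_counts is not None:
        ids = carer_set.carer_ids
        for i, prev in enumerate(ids):
            for j, nxt in enumerate(ids):
                if transition_counts[i][j] == 0:
                    zero_pairs.append((prev, nxt))
        if zero_pairs:
            warnings.append(
                f"{len(zero_pairs)} carer pair(s) with zero observed transitions: "
                "full-model rates for these pairs are inestimable (fitted as 0)"
            )
    return {
        "attempt_id": carer_set.attempt_id,
        "valid": valid,
        "c": carer_set.c,
        "warnings": warnings,
        "zero_transition_pairs": zero_pairs,
    }


def rank_helpers(carer_set: CarerSet) -> CarerSet:
    """Rank helpers 1..k by descending visit count (1 = primary helper).

    The lowest-ranked helper is flagged terminal.  Ties in count are broken by
    the stable descending-count order already in the carer list, and logged.
    Breeders keep ``helper_rank=None``.  Mutates and returns ``carer_set``.
    """
    helpers = [e for e in carer_set.carers if e.carer_class == "helper"]
    counts = [e.visit_count for e in helpers]
    if len(set(counts)) < len(counts):
        log.info(
            "rank_helpers[%s]: tied helper visit counts; ranks use stable order",
            carer_set.attempt_id,
        )
    for rank, entry in enumerate(helpers, start=1):
        entry.helper_rank = rank
        entry.terminal = False
    if helpers:
        helpers[-1].terminal = True
    return carer_set
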