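"""Synthetic provisioning data with known generating mechanisms.

Three generative modes cover the structures the analysis must distinguish:

* ``markov`` — the fitted model run generatively: given the last visitor i,
  carers compete with exponential clocks at rates ``Q[i, j]``.  Ground truth
  for parameter recovery and likelihood-ratio calibration.
* ``mechanistic`` — renewal-style carers with an optional refractory period
  (zero hazard while travelling/foraging after an own visit: passive
  turn-taking only) and an optional active response: a carer's hazard is
  multiplied by ``repeat_suppression`` < 1 while it is itself the last
  visitor (active turn-taking, the lambda > mu signature).
* ``bouts`` — synchronous group provisioning: Poisson bout onsets at which
  each carer visits with some probability at a small jittered offset, for
  exercising the bout-clustering runs test.

Defaults emulate the field setting the analysis is built for: groups of a few
carers provisioning at roughly 7 visits/h each (median individual IVIs of
6-10 min), a refractory period of a few minutes, 12-h observation days over
multiple days.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import AttemptMetadata, ProvisioningAttempt, Visit, VisitDay

__all__ = [
    "Refractory",
    "SimConfig",
    "simulate",
    "simulate_markov",
    "simulate_mechanistic",
    "simulate_bouts",
]

HOUR = 3600.0
DAY_SECONDS = 86400.0


@dataclass(frozen=True)
class Refractory:
    """Post-visit dead time: none, fixed duration, or gamma-distributed."""

    kind: str = "none"  # none | fixed | gamma
    duration: float = 0.0  # seconds (fixed)
    shape: float = 2.0  # gamma
    scale: float = 90.0  # seconds (gamma)

    def sample(self, rng: np.random.Generator) -> float:
        if self.kind == "none":
            return 0.0
        if self.kind == "fixed":
            return self.duration
        if self.kind == "gamma":
            return float(rng.gamma(self.shape, self.scale))
        raise ValueError(f"unknown refractory kind {self.kind!r}")


@dataclass
class SimConfig:
    """Generative parameters for one synthetic breeding attempt."""

    mode: str = "mechanistic"  # markov | mechanistic | bouts
    c: int = 4
    Q: np.ndarray | None = None  # (c, c) rates per hour, markov mode
    base_rates: np.ndarray | None = None  # per-carer hazard per hour (default 7.0)
    refractory: Refractory = field(default_factory=lambda: Refractory("gamma", shape=2.0, scale=90.0))
    repeat_suppression: float = 1.0  # hazard multiplier while own last visitor; 1 = passive only
    day_length: float = 12 * HOUR
    n_days: int = 3
    seed: int | None = None
    attempt_id: str = "sim"
    # bouts mode
    bout_rate: float = 6.0  # bout onsets per hour
    bout_p: float = 0.8  # probability a given carer joins a bout
    bout_jitter: float = 60.0  # seconds: spread of visits within a bout

    def __post_init__(self) -> None:
        if self.c < 1:
            raise ValueError("need at least one carer")
        if not (0.0 <= self.repeat_suppression <= 1.0):
            raise ValueError("repeat_suppression must lie in [0, 1]")
        if self.Q is not None:
            self.Q = np.asarray(self.Q, dtype=float)
            if self.Q.shape != (self.c, self.c) or (self.Q < 0).any():
                raise ValueError("Q must be a nonnegative (c, c) matrix")
        if self.base_rates is None:
            self.base_rates = np.full(self.c, 7.0)
        else:
            self.base_rates = np.asarray(self.base_rates, dtype=float)
            if self.base_rates.shape != (self.c,) or (self.base_rates < 0).any():
                raise ValueError("base_rates must be nonnegative with length c")

    @property
    def carer_ids(self) -> list[str]:
        return [f"carer_{i}" for i in range(self.c)]


def _default_metadata(config: SimConfig) -> AttemptMetadata:
    """Metadata making the synthetic attempt pass the standard filters."""
    classes = {}
    for i, cid in enumerate(config.carer_ids):
        classes[cid] = ("breeding_female", "breeding_male")[i] if i < 2 else "helper"
    return AttemptMetadata(
        brood_size=3,
        brood_age={d: 10 + d for d in range(1, config.n_days + 1)},
        carer_class=classes,
    )


def _wrap(config: SimConfig, events_per_day: list[list[tuple[float, int]]]) -> ProvisioningAttempt:
    ids = config.carer_ids
    days = []
    for d, events in enumerate(events_per_day, start=1):
        start = (d - 1) * DAY_SECONDS
        visits = [
            Visit(config.attempt_id, ids[k], start + t, day_index=d)
            for t, k in sorted(events)
        ]
        days.append(VisitDay(d, start, start + config.day_length, visits))
    return ProvisioningAttempt(config.attempt_id, days, _default_metadata(config))


def simulate_markov(config: SimConfig) -> ProvisioningAttempt:
    """Generate visits from the last-visitor Markov model with rate matrix Q.

    Each day starts afresh: the first visitor arrives after an exponential
    time at the summed column-average rates and is drawn proportional to
    them (the first interval of a day never enters the likelihood, so this
    initialization cannot bias fitting).  Thereafter, given last visitor i,
    the next visit is by carer j after Exp(sum_k Q[i,k]) time with
    probability Q[i,j] / sum_k Q[i,k].
    """
    if config.mode != "markov" or config.Q is None:
        raise ValueError("simulate_markov requires mode='markov' and a Q matrix")
    rng = np.random.default_rng(config.seed)
    q = config.Q / HOUR  # per second
    row_rates = q.sum(axis=1)
    init = q.mean(axis=0)  # column-averaged arrival rates
    init_total = init.sum()
    days = []
    for _ in range(config.n_days):
        events: list[tuple[float, int]] = []
        if init_total > 0:
            t = rng.exponential(1.0 / init_total)
            state = rng.choice(config.c, p=init / init_total)
            while t < config.day_length:
                events.append((t, int(state)))
                r = row_rates[state]
                if r == 0:
                    break
                t += rng.exponential(1.0 / r)
                state = rng.choice(config.c, p=q[state] / r)
        days.append(events)
    return _wrap(config, days)


def simulate_mechanistic(config: SimConfig) -> ProvisioningAttempt:
    """Event-driven simulation with refractory periods and repeat suppression.

    Carer i's hazard at time t is 0 while inside its refractory window after
    its own last visit, and otherwise base_rate_i times ``repeat_suppression``
    if i is the current last visitor (else times 1).  Hazards are piecewise
    constant with change points at visits and refractory expirations, so the
    simulation is exact: within each constant piece, competing exponential
    clocks are drawn and the earliest wins; if it lands beyond the next
    change point, the clocks are redrawn there (memorylessness).
    """
    if config.mode != "mechanistic":
        raise ValueError("simulate_mechanistic requires mode='mechanistic'")
    rng = np.random.default_rng(config.seed)
    base = config.base_rates / HOUR
    beta = config.repeat_suppression
    days = []
    for _ in range(config.n_days):
        events: list[tuple[float, int]] = []
        ready_at = np.zeros(config.c)  # refractory expiry per carer
        last: int | None = None
        t = 0.0
        while t < config.day_length:
            active = (ready_at <= t) & (base > 0)
            haz = np.where(active, base, 0.0)
            if last is not None and active[last]:
                haz[last] *= beta
            change = np.min(ready_at[ready_at > t], initial=config.day_length)
            total = haz.sum()
            if total == 0:
                if change >= config.day_length:
                    break
                t = change
                continue
            dt = rng.exponential(1.0 / total)
            if t + dt > change:
                t = change  # hazard profile changes; redraw (exact by memorylessness)
                continue
            t += dt
            k = int(rng.choice(config.c, p=haz / total))
            if t >= config.day_length:
                break
            events.append((t, k))
            ready_at[k] = t + config.refractory.sample(rng)
            last = k
        days.append(events)
    return _wrap(config, days)


def simulate_bouts(config: SimConfig) -> ProvisioningAttempt:
    """Synchronous provisioning bouts: Poisson onsets, joint jittered visits."""
    if config.mode != "bouts":
        raise ValueError("simulate_bouts requires mode='bouts'")
    rng = np.random.default_rng(config.seed)
    rate = config.bout_rate / HOUR
    days = []
    for _ in range(config.n_days):
        events: list[tuple[float, int]] = []
        t = rng.exponential(1.0 / rate) if rate > 0 else np.inf
        while t < config.day_length:
            for k in range(config.c):
                if rng.random() < config.bout_p:
                    tk = t + rng.uniform(0.0, config.bout_jitter)
                    if tk < config.day_length:
                        events.append((tk, k))
            t += rng.exponential(1.0 / rate)
        days.append(events)
    attempt = _wrap(config, days)
    if attempt.n_visits == 0:
        import logging

        logging.getLogger(__name__).warning("bout simulation produced no visits")
    return attempt


def simulate(config: SimConfig) -> ProvisioningAttempt:
    """Dispatch on ``config.mode``."""
    return {
        "markov": simulate_markov,
        "mechanistic": simulate_mechanistic,
        "bouts": simulate_bouts,
    }[config.mode](config)
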