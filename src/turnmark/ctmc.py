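"""Continuous-time Markov models of who-follows-whom at the nest.

The model state is the identity of the last carer to visit.  Every visit is an
exactly observed transition, so with ``n[i][j]`` = number of visits by carer j
made while i was the last visitor, and ``T[i]`` = total time spent with i as
the last visitor (summed over fully observed within-day intervals), the
log-likelihood of a rate matrix ``q`` is

    logL(q) = sum_ij n[i][j] * log q[i][j]  -  sum_i T[i] * sum_j q[i][j]

and the maximum-likelihood estimates are closed-form ratios of counts to
exposures.  Three nested models are fitted:

* full           — c^2 free rates q[i][j] (how likely each carer is to follow
                   each particular other carer);
* per_individual — each carer i has one rate when following any other bird
                   (lambda_i) and one repeat-visit rate (mu_i): 2c parameters;
* pooled         — a single following rate lambda_0 and repeat rate mu_0
                   shared by all carers: 2 parameters.

Turn-taking appears as lambda exceeding mu: a carer is more likely to visit
when somebody else was the last visitor than to make a repeat visit.

Units: the likelihood and the fits are unit-agnostic — rates come out in
events per unit of whatever time unit ``T`` is measured in.  The pipeline
keeps exposures in seconds and converts reported rates to per-hour.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .carers import CarerSet
from .types import ProvisioningAttempt, day_arrays

__all__ = [
    "SufficientStats",
    "TransitionRates",
    "FitResult",
    "LRTResult",
    "sufficient_stats",
    "stats_from_days",
    "log_likelihood",
    "fit_full",
    "fit_per_individual",
    "fit_pooled",
    "lrt",
    "turn_taking_ratio",
    "reciprocity_correlation",
    "wilcoxon_lambda_mu",
    "export_msm_structure",
]

SECONDS_PER_HOUR = 3600.0

_NESTING = {"pooled": 0, "per_individual": 1, "full": 2}


@dataclass
class SufficientStats:
    """Transition counts and state exposures: all likelihoods derive from these.

    n[i][j] counts visits by carer j immediately following a visit by carer i
    within one day; T[i] is the total time with i as last visitor over fully
    observed intervals.  The interval after a day's last visit and before its
    first visit contribute nothing.
    """

    carers: list[str]
    n: np.ndarray  # (c, c) nonnegative ints
    T: np.ndarray  # (c,) nonnegative, same time unit throughout
    n_days: int = 0
    n_visits: int = 0

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=float)
        self.T = np.asarray(self.T, dtype=float)
        c = len(self.carers)
        if self.n.shape != (c, c) or self.T.shape != (c,):
            raise ValueError("shape mismatch between carers, n and T")
        if (self.n < 0).any() or (self.T < 0).any():
            raise ValueError("negative counts or exposures")

    @property
    def c(self) -> int:
        return len(self.carers)


@dataclass
class TransitionRates:
    """c-by-c rate matrix: q[i][j] = rate of carer j visiting when i was last."""

    carers: list[str]
    q: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if (self.q < 0).any() or not np.isfinite(self.q).all():
            raise ValueError("rates must be finite and nonnegative")


@dataclass
class FitResult:
    model: str  # full | per_individual | pooled
    rates: TransitionRates  # expanded c x c form for constrained models
    logLik: float
    n_params: int
    lambda_i: np.ndarray | None = None  # per_individual
    mu_i: np.ndarray | None = None
    lambda0: float | None = None  # pooled
    mu0: float | None = None
    flags: list[str] = field(default_factory=list)


@dataclass
class LRTResult:
    stat: float
    df: int
    p: float
    general: str
    constrained: str
    flags: list[str] = field(default_factory=list)


def stats_from_days(days, carers: list[str]) -> SufficientStats:
    """Accumulate sufficient statistics from ``(times, codes)`` day arrays.

    Days with fewer than two visits contribute visits to the total but no
    transitions or exposure.
    """
    c = len(carers)
    n = np.zeros((c, c))
    T = np.zeros(c)
    n_days = 0
    n_visits = 0
    for times, codes in days:
        n_visits += len(times)
        if len(times) == 0:
            continue
        n_days += 1
        if len(times) < 2:
            continue
        prev, nxt = codes[:-1], codes[1:]
        np.add.at(n, (prev, nxt), 1.0)
        np.add.at(T, prev, np.diff(times))
    return SufficientStats(list(carers), n, T, n_days=n_days, n_visits=n_visits)


def sufficient_stats(
    attempt: ProvisioningAttempt, carer_set: CarerSet | list[str]
) -> SufficientStats:
    """Sufficient statistics for an attempt, restricted to significant carers."""
    carers = carer_set.carer_ids if isinstance(carer_set, CarerSet) else list(carer_set)
    return stats_from_days(day_arrays(attempt, carers), carers)


def log_likelihood(rates: TransitionRates, stats: SufficientStats) -> float:
    """Exact-transition-time log-likelihood; -inf when a needed rate is zero.

    Uses the convention 0 * log 0 = 0, so zero rates are harmless wherever the
    corresponding count is zero.
    """
    q, n, T = rates.q, stats.n, stats.T
    if np.any((q == 0) & (n > 0)):
        return -np.inf
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n > 0, n * np.log(np.where(q > 0, q, 1.0)), 0.0)
    return float(terms.sum() - (T * q.sum(axis=1)).sum())


def _safe_div(num, den):
    num, den = np.asarray(num, float), np.asarray(den, float)
    out = np.zeros(np.broadcast_shapes(num.shape, den.shape))
    np.divide(num, den, out=out, where=den > 0)
    return out


def fit_full(stats: SufficientStats) -> FitResult:
    """MLE of the saturated model: q_ij = n_ij / T_i (0 when T_i = 0)."""
    q = _safe_div(stats.n, stats.T[:, None])
    rates = TransitionRates(stats.carers, q)
    flags = []
    if (stats.n == 0).any():
        flags.append("zero-count transitions fitted at the boundary rate 0")
    return FitResult("full", rates, log_likelihood(rates, stats), stats.c**2, flags=flags)


def fit_per_individual(stats: SufficientStats) -> FitResult:
    """MLE with one following-another rate and one repeat rate per carer.

    mu_i = n_ii / T_i;  lambda_i = (sum_{j != i} n_ji) / (sum_{j != i} T_j),
    i.e. visits by i while somebody else was last, over the time somebody else
    was last.
    """
    if stats.c < 2:
        raise ValueError("per_individual model needs at least 2 carers")
    n, T = stats.n, stats.T
    diag = np.diag(n)
    mu = _safe_div(diag, T)
    follow_counts = n.sum(axis=0) - diag  # visits by i following another
    other_T = T.sum() - T  # time with someone other than i last
    lam = _safe_div(follow_counts, other_T)
    q = np.tile(lam, (stats.c, 1))
    np.fill_diagonal(q, mu)
    rates = TransitionRates(stats.carers, q)
    return FitResult(
        "per_individual",
        rates,
        log_likelihood(rates, stats),
        2 * stats.c,
        lambda_i=lam,
        mu_i=mu,
    )


def fit_pooled(stats: SufficientStats) -> FitResult:
    """MLE with a single following rate lambda_0 and repeat rate mu_0.

    lambda_0 = (off-diagonal transitions) / ((c-1) * total exposure) because
    from any state there are c-1 distinct carers each following at lambda_0.
    """
    if stats.c < 2:
        raise ValueError("pooled model needs at least 2 carers")
    n, T = stats.n, stats.T
    total_T = T.sum()
    off = n.sum() - np.trace(n)
    lam0 = float(_safe_div(off, (stats.c - 1) * total_T))
    mu0 = float(_safe_div(np.trace(n), total_T))
    q = np.full((stats.c, stats.c), lam0)
    np.fill_diagonal(q, mu0)
    rates = TransitionRates(stats.carers, q)
    return FitResult(
        "pooled", rates, log_likelihood(rates, stats), 2, lambda0=lam0, mu0=mu0
    )


def lrt(general: FitResult, constrained: FitResult) -> LRTResult:
    """Likelihood-ratio test of a constrained model against a nesting one."""
    if _NESTING.get(constrained.model, -1) >= _NESTING.get(general.model, -1):
        raise ValueError(
            f"{constrained.model!r} is not nested in {general.model!r}"
        )
    stat = 2.0 * (general.logLik - constrained.logLik)
    if stat < 0:
        if stat < -1e-8:
            raise ValueError(f"negative LRT statistic {stat}: fits inconsistent")
        stat = 0.0
    df = general.n_params - constrained.n_params
    flags = []
    if general.flags or constrained.flags:
        flags.append("boundary zero rates present: chi-squared asymptotics degrade")
    return LRTResult(
        stat, df, float(sps.chi2.sf(stat, df)), general.model, constrained.model, flags
    )


def turn_taking_ratio(fit: FitResult) -> dict:
    """Per-carer and group-level lambda/mu turn-taking ratios.

    A group ratio above 1 means carers visit faster after another bird than
    after themselves.  The group ratio is mean(lambda_i) / mean(mu_i); carers
    with mu_i = 0 give an infinite individual ratio (flagged).
    """
    if fit.model != "per_individual" or fit.lambda_i is None:
        raise ValueError("turn_taking_ratio requires a per_individual fit")
    lam, mu = fit.lambda_i, fit.mu_i
    flags = []
    with np.errstate(divide="ignore", invalid="ignore"):
        per = np.where(mu > 0, lam / np.where(mu > 0, mu, 1.0), np.inf)
    per = np.where((mu == 0) & (lam == 0), np.nan, per)
    if np.isinf(per).any():
        flags.append("carer(s) with zero repeat rate: individual ratio infinite")
    mean_mu = mu.mean()
    if mean_mu > 0:
        group = float(lam.mean() / mean_mu)
    else:
        group = float("nan")
        flags.append("mean repeat rate is zero: group ratio undefined")
    return {
        "carers": list(fit.rates.carers),
        "per_carer": per.tolist(),
        "group_ratio": group,
        "flags": flags,
    }


def reciprocity_correlation(
    rates: TransitionRates, n_perm: int = 999, seed: int | None = None
) -> dict:
    """Do carers preferentially follow the birds that follow them?

    Spearman rank correlation between q[i][j] and q[j][i] over unordered pairs
    i < j, with a seeded permutation p-value (two-sided).  Undefined for
    c < 3 (a single pair carries no correlation).
    """
    c = len(rates.carers)
    if c < 3:
        return {"rho": None, "p": None, "flags": ["undefined for fewer than 3 carers"]}
    iu = np.triu_indices(c, k=1)
    x, y = rates.q[iu], rates.q.T[iu]
    rho = sps.spearmanr(x, y).statistic
    if not np.isfinite(rho):
        return {"rho": None, "p": None, "flags": ["constant rates: rho undefined"]}
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        r = sps.spearmanr(x, rng.permutation(y)).statistic
        if np.isfinite(r) and abs(r) >= abs(rho) - 1e-12:
            hits += 1
    return {"rho": float(rho), "p": (hits + 1) / (n_perm + 1), "flags": []}


def wilcoxon_lambda_mu(fit: FitResult) -> dict:
    """Wilcoxon signed-rank test of lambda_i vs mu_i across carers.

    Exact distribution for n <= 25 carers, normal approximation above (or when
    ties/zero differences make the exact distribution unavailable).
    """
    if fit.model != "per_individual" or fit.lambda_i is None:
        raise ValueError("wilcoxon_lambda_mu requires a per_individual fit")
    lam, mu = fit.lambda_i, fit.mu_i
    n = len(lam)
    if n < 2 or np.allclose(lam, mu):
        return {"stat": None, "p": None, "flags": ["too few carers or no differences"]}
    method = "exact" if n <= 25 else "approx"
    try:
        res = sps.wilcoxon(lam, mu, method=method)
    except ValueError:
        res = sps.wilcoxon(lam, mu, method="approx")
        method = "approx"
    return {"stat": float(res.statistic), "p": float(res.pvalue), "method": method, "flags": []}


def export_msm_structure(c: int, reset_rate: float = 1e6) -> dict:
    """The 2c-state dummy/reset encoding used to coerce general multi-state fitters.

    Each carer i has a base state (i was the last visitor) and a dummy state
    entered on a repeat visit, from which an instantaneous reset (a fixed,
    arbitrarily high rate) returns to the base state.  The graph has 2c states
    and c(c+1) transitions: c^2 estimated visit rates plus c fixed resets.
    This export exists for cross-validation against general multi-state
    toolchains; the likelihood here never needs it.
    """
    if c < 1:
        raise ValueError("need at least one carer")
    states = [f"base_{i}" for i in range(c)] + [f"dummy_{i}" for i in range(c)]
    transitions = []
    for i in range(c):
        for j in range(c):
            dest = f"dummy_{i}" if j == i else f"base_{j}"
            transitions.append(
                {"from": f"base_{i}", "to": dest, "kind": "visit", "prev": i, "next": j}
            )
    for i in range(c):
        transitions.append(
            {
                "from": f"dummy_{i}",
                "to": f"base_{i}",
                "kind": "reset",
                "rate": reset_rate,
            }
        )
    return {
        "c": c,
        "states": states,
        "transitions": transitions,
        "n_states": len(states),
        "n_visit_transitions": sum(t["kind"] == "visit" for t in transitions),
        "n_transitions": len(transitions),
    }
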