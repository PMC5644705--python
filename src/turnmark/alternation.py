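"""Sequence-level turn-taking statistics.

These are the model-free companions to the rate models: the proportion of
alternated visits, a k-category runs test (which corrects the naive
alternation expectation for group size and unequal visit rates), a
Wald-Wolfowitz runs test for synchronous provisioning bouts in the group
inter-visit intervals, descriptive IVI summaries, and an ordering diagnostic
that checks the exchangeability assumption behind the randomization null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .carers import CarerSet
from .types import ProvisioningAttempt, day_arrays

__all__ = [
    "RunsTestResult",
    "OrderingResult",
    "proportion_alternated",
    "attempt_sequences",
    "count_runs",
    "k_category_runs_test",
    "ww_bout_test",
    "per_carer_ivis",
    "group_ivis",
    "ivi_summaries",
    "ordering_score",
]

HOUR = 3600.0


@dataclass
class RunsTestResult:
    R_obs: int
    E_R: float
    Var_R: float
    z: float | None
    p: float
    alternative: str  # more_runs | fewer_runs | two_sided
    method: str  # normal_approx | monte_carlo
    n_mc: int | None = None
    degenerate: bool = False


@dataclass
class OrderingResult:
    carers: list[str]
    p_scores: list[float]
    mean: float | None
    sd: float | None
    flags: list[str]


def attempt_sequences(
    attempt: ProvisioningAttempt, carer_set: CarerSet | list[str]
) -> list[np.ndarray]:
    """Per-day visitor-code sequences restricted to significant carers."""
    carers = carer_set.carer_ids if isinstance(carer_set, CarerSet) else list(carer_set)
    return [codes for _, codes in day_arrays(attempt, carers)]


def proportion_alternated(sequences) -> dict:
    """Fraction of consecutive within-day visit pairs with a different visitor.

    ``sequences`` is a list of per-day visitor sequences (ids or codes);
    cross-day pairs never count.  Undefined (flagged, proportion None) when no
    day holds two visits.
    """
    n_alt = n_rep = 0
    for seq in sequences:
        seq = np.asarray(seq)
        if len(seq) < 2:
            continue
        diff = seq[1:] != seq[:-1]
        n_alt += int(diff.sum())
        n_rep += int((~diff).sum())
    total = n_alt + n_rep
    if total == 0:
        return {"proportion": None, "n_alt": 0, "n_rep": 0,
                "flags": ["no day with at least two visits"]}
    return {"proportion": n_alt / total, "n_alt": n_alt, "n_rep": n_rep, "flags": []}


def count_runs(seq: np.ndarray) -> int:
    """Number of maximal same-category runs in a sequence."""
    seq = np.asarray(seq)
    if len(seq) == 0:
        return 0
    return int(1 + (seq[1:] != seq[:-1]).sum())


def _runs_moments(counts: np.ndarray) -> tuple[float, float]:
    """Mean and variance of the run count under random arrangement.

    For category counts n_1..n_k with N = sum n_i:
      E[R]   = (N(N+1) - sum n_i^2) / N
      Var[R] = [sum n_i^2 (sum n_i^2 + N(N+1)) - 2N sum n_i^3 - N^3]
               / (N^2 (N-1))
    Both are exact (cross-checked against exhaustive enumeration in the test
    suite for N <= 8).
    """
    N = counts.sum()
    s2 = float((counts.astype(float) ** 2).sum())
    s3 = float((counts.astype(float) ** 3).sum())
    e_r = (N * (N + 1) - s2) / N
    var_r = (s2 * (s2 + N * (N + 1)) - 2 * N * s3 - N**3) / (N**2 * (N - 1))
    return e_r, var_r


def _tail_p(z: float, alternative: str) -> float:
    if alternative == "more_runs":
        return float(sps.norm.sf(z))
    if alternative == "fewer_runs":
        return float(sps.norm.cdf(z))
    return float(min(1.0, 2 * min(sps.norm.sf(z), sps.norm.cdf(z))))


def k_category_runs_test(
    sequence,
    alternative: str = "more_runs",
    method: str = "normal_approx",
    n_mc: int = 9999,
    seed: int | None = None,
) -> RunsTestResult:
    """Runs test for a sequence over k >= 2 categories.

    More runs than expected under random arrangement indicates alternation;
    fewer indicates clustering.  The expectation and variance condition on the
    category counts, so group size and unequal visit rates are accounted for.
    ``method="monte_carlo"`` permutes the sequence (seeded) and reports the
    add-one empirical p-value; the normal approximation uses no continuity
    correction.
    """
    if alternative not in ("more_runs", "fewer_runs", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    seq = np.asarray(sequence)
    if len(seq) < 2:
        raise ValueError("runs test needs at least 2 observations")
    _, counts = np.unique(seq, return_counts=True)
    r_obs = count_runs(seq)
    if len(counts) < 2:
        return RunsTestResult(r_obs, float(r_obs), 0.0, None, 1.0,
                              alternative, method, degenerate=True)
    e_r, var_r = _runs_moments(counts)
    if method == "normal_approx":
        if var_r <= 0:  # R is deterministic (e.g. every count is 1)
            return RunsTestResult(r_obs, e_r, var_r, None, 1.0,
                                  alternative, "normal_approx", degenerate=True)
        z = (r_obs - e_r) / np.sqrt(var_r)
        return RunsTestResult(r_obs, e_r, var_r, float(z), _tail_p(z, alternative),
                              alternative, "normal_approx")
    if method != "monte_carlo":
        raise ValueError(f"unknown method {method!r}")
    if n_mc < 100:
        raise ValueError(f"n_mc must be >= 100, got {n_mc}")
    rng = np.random.default_rng(seed)
    more = fewer = 0
    work = seq.copy()
    for _ in range(n_mc):
        rng.shuffle(work)
        r = count_runs(work)
        if r >= r_obs:
            more += 1
        if r <= r_obs:
            fewer += 1
    if alternative == "more_runs":
        p = (more + 1) / (n_mc + 1)
    elif alternative == "fewer_runs":
        p = (fewer + 1) / (n_mc + 1)
    else:
        p = min(1.0, 2 * min(more + 1, fewer + 1) / (n_mc + 1))
    return RunsTestResult(r_obs, e_r, var_r, None, p, alternative, "monte_carlo", n_mc)


def ww_bout_test(ivis, threshold: float | None = None) -> RunsTestResult:
    """Wald-Wolfowitz runs test for clustering of group inter-visit intervals.

    Each IVI is categorized short (<= threshold, default the median) or long;
    synchronous provisioning bouts produce consecutive short IVIs, i.e. fewer
    runs than expected, so the test is one-sided toward fewer runs with
      E[R] = 2 n1 n2 / N + 1,
      Var[R] = 2 n1 n2 (2 n1 n2 - N) / (N^2 (N - 1)).
    """
    ivis = np.asarray(ivis, dtype=float)
    if len(ivis) < 4:
        raise ValueError("bout test needs at least 4 intervals")
    if threshold is None:
        threshold = float(np.median(ivis))
    cats = (ivis <= threshold).astype(int)  # ties count as short
    n1 = int(cats.sum())
    n2 = len(cats) - n1
    r_obs = count_runs(cats)
    if n1 == 0 or n2 == 0:
        return RunsTestResult(r_obs, float(r_obs), 0.0, None, 1.0,
                              "fewer_runs", "normal_approx", degenerate=True)
    N = n1 + n2
    e_r = 2 * n1 * n2 / N + 1
    var_r = 2 * n1 * n2 * (2 * n1 * n2 - N) / (N**2 * (N - 1))
    z = (r_obs - e_r) / np.sqrt(var_r)
    return RunsTestResult(r_obs, e_r, var_r, float(z),
                          _tail_p(z, "fewer_runs"), "fewer_runs", "normal_approx")


def per_carer_ivis(
    attempt: ProvisioningAttempt, carer_set: CarerSet | list[str]
) -> dict[str, np.ndarray]:
    """Within-day inter-visit intervals per carer, concatenated in temporal order."""
    carers = carer_set.carer_ids if isinstance(carer_set, CarerSet) else list(carer_set)
    parts: dict[str, list[np.ndarray]] = {cid: [] for cid in carers}
    for times, codes in day_arrays(attempt, carers):
        for k, cid in enumerate(carers):
            own = times[codes == k]
            if len(own) >= 2:
                parts[cid].append(np.diff(own))
    return {
        cid: (np.concatenate(p) if p else np.empty(0)) for cid, p in parts.items()
    }


def group_ivis(
    attempt: ProvisioningAttempt,
    carer_set: CarerSet | list[str],
    first_day_only: bool = False,
) -> list[np.ndarray]:
    """Per-day intervals between successive visits by anyone."""
    carers = carer_set.carer_ids if isinstance(carer_set, CarerSet) else list(carer_set)
    days = day_arrays(attempt, carers)
    if first_day_only:
        days = days[:1]
    return [np.diff(times) for times, _ in days if len(times) >= 2]


def ivi_summaries(
    attempt: ProvisioningAttempt, carer_set: CarerSet | list[str]
) -> dict:
    """Descriptive IVI statistics per carer and for the whole group."""
    per_carer = {}
    flags = []
    for cid, iv in per_carer_ivis(attempt, carer_set).items():
        if len(iv) == 0:
            per_carer[cid] = {"n_ivi": 0, "median_s": None, "mean_s": None,
                              "frac_below_1h": None}
            flags.append(f"carer {cid}: no within-day IVIs")
            continue
        per_carer[cid] = {
            "n_ivi": int(len(iv)),
            "median_s": float(np.median(iv)),
            "mean_s": float(iv.mean()),
            "frac_below_1h": float((iv < HOUR).mean()),
        }
    giv = group_ivis(attempt, carer_set)
    all_g = np.concatenate(giv) if giv else np.empty(0)
    return {
        "per_carer": per_carer,
        "group": {
            "n_ivi": int(len(all_g)),
            "median_s": float(np.median(all_g)) if len(all_g) else None,
        },
        "flags": flags,
    }


def ordering_score(
    ivis_by_carer: dict[str, np.ndarray],
    n_perm: int = 999,
    seed: int | None = None,
    min_ivis: int = 5,
) -> OrderingResult:
    """Are a carer's IVIs ordered in time?  (Randomization-validity diagnostic.)

    Per carer: Spearman correlation between IVI length and temporal index,
    with a two-sided seeded permutation p-score using the add-one estimator.
    Under no ordering the p-scores are uniform, mean about 0.5; systematic
    trends in interval length (which would bias the IVI-shuffling null) push
    the mean toward 0.  Carers with fewer than ``min_ivis`` intervals are
    skipped, constant-IVI carers score 1 (flagged).
    """
    rng = np.random.default_rng(seed)
    carers, scores, flags = [], [], []
    for cid, iv in ivis_by_carer.items():
        iv = np.asarray(iv, dtype=float)
        if len(iv) < min_ivis:
            flags.append(f"carer {cid}: fewer than {min_ivis} IVIs, skipped")
            continue
        idx = np.arange(len(iv))
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant input: rho is nan, handled below
            rho = sps.spearmanr(iv, idx).statistic
        if not np.isfinite(rho):
            carers.append(cid)
            scores.append(1.0)
            flags.append(f"carer {cid}: constant IVIs, p-score set to 1")
            continue
        hits = 0
        for _ in range(n_perm):
            r = sps.spearmanr(rng.permutation(iv), idx).statistic
            if np.isfinite(r) and abs(r) >= abs(rho) - 1e-12:
                hits += 1
        carers.append(cid)
        scores.append((hits + 1) / (n_perm + 1))
    if scores:
        mean = float(np.mean(scores))
        sd = float(np.std(scores, ddof=1)) if len(scores) > 1 else 0.0
    else:
        mean = sd = None
        flags.append("no carer with enough IVIs for the ordering diagnostic")
    return OrderingResult(carers, scores, mean, sd, flags)
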