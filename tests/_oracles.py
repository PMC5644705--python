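"""Independent oracles used by the test suite.

These deliberately avoid the closed-form estimator paths in the package:
the MLE oracle maximizes the log-likelihood numerically coordinate by
coordinate (the likelihood is separable per rate parameter in all three
models), and the runs oracle enumerates every distinct arrangement of a
sequence.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import minimize_scalar

from turnmark.alternation import count_runs
from turnmark.ctmc import SufficientStats, TransitionRates, log_likelihood


def _optimize_coords(stats: SufficientStats, expand, n_coords: int) -> np.ndarray:
    """Maximize logL over nonnegative coordinates by per-coordinate Brent search.

    ``expand(x)`` maps the coordinate vector to a TransitionRates.  Each
    coordinate enters the likelihood through terms of the form
    a*log(q) - b*q only, so the objective is separable and coordinate-wise
    optimization finds the global maximum; two sweeps guard against any
    coupling slip.  Boundary handling probes q=0: if the likelihood is finite
    there, the boundary competes with the interior optimum.
    """
    x = np.ones(n_coords)

    def negll_at(k: int, u: float, xcur: np.ndarray) -> float:
        xt = xcur.copy()
        xt[k] = np.exp(u)
        return -log_likelihood(expand(xt), stats)

    for _ in range(2):
        for k in range(n_coords):
            x0 = x.copy()
            x0[k] = 0.0
            boundary = -log_likelihood(expand(x0), stats)
            res = minimize_scalar(
                lambda u: negll_at(k, u, x),
                bounds=(-25.0, 10.0),
                method="bounded",
                options={"xatol": 1e-13, "maxiter": 500},
            )
            if boundary <= res.fun:
                x[k] = 0.0
            else:
                x[k] = np.exp(res.x)
    return x


def numeric_mle_full(stats: SufficientStats) -> np.ndarray:
    c = stats.c

    def expand(x):
        return TransitionRates(stats.carers, x.reshape(c, c))

    return _optimize_coords(stats, expand, c * c).reshape(c, c)


def numeric_mle_per_individual(stats: SufficientStats) -> tuple[np.ndarray, np.ndarray]:
    c = stats.c

    def expand(x):
        lam, mu = x[:c], x[c:]
        q = np.tile(lam, (c, 1))
        np.fill_diagonal(q, mu)
        return TransitionRates(stats.carers, q)

    x = _optimize_coords(stats, expand, 2 * c)
    return x[:c], x[c:]


def numeric_mle_pooled(stats: SufficientStats) -> tuple[float, float]:
    c = stats.c

    def expand(x):
        q = np.full((c, c), x[0])
        np.fill_diagonal(q, x[1])
        return TransitionRates(stats.carers, q)

    x = _optimize_coords(stats, expand, 2)
    return float(x[0]), float(x[1])


def runs_distribution(counts: dict) -> np.ndarray:
    """Run counts of every distinct arrangement of a category multiset.

    Exhaustive (distinct permutations are equally likely under random
    arrangement); intended for N <= 8.
    """
    seq = tuple(itertools.chain.from_iterable([k] * v for k, v in counts.items()))
    return np.array(
        [count_runs(np.array(p)) for p in set(itertools.permutations(seq))]
    )
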