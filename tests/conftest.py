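import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from turnmark import SimConfig, SufficientStats, simulate_markov

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def ab_stats() -> SufficientStats:
    """The two-carer worked toy: one day of visits A@0, B@10, B@25, A@40 min.

    Transitions A->B, B->B, B->A; exposures T_A = 10 min, T_B = 30 min.
    Time unit deliberately minutes: the fits are unit-agnostic.
    """
    return SufficientStats(
        ["A", "B"], np.array([[0, 1], [1, 1]]), np.array([10.0, 30.0]),
        n_days=1, n_visits=4,
    )


def simulated_stats(seed: int, c: int, n_days: int = 2, day_hours: float = 10.0):
    """Sufficient stats from a markov-mode simulation with a varied known Q."""
    rng = np.random.default_rng(seed)
    q = rng.uniform(3.0, 9.0, size=(c, c))
    cfg = SimConfig(
        mode="markov", c=c, Q=q, day_length=day_hours * 3600, n_days=n_days,
        seed=seed,
    )
    from turnmark import sufficient_stats

    attempt = simulate_markov(cfg)
    return sufficient_stats(attempt, cfg.carer_ids), q
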