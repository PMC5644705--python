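import numpy as np
import pytest

from turnmark import (
    Refractory,
    SimConfig,
    day_arrays,
    fit_full,
    proportion_alternated,
    simulate,
    simulate_bouts,
    simulate_markov,
    simulate_mechanistic,
    sufficient_stats,
    ww_bout_test,
)
from turnmark.alternation import attempt_sequences


def _alternation(attempt, carers):
    return proportion_alternated(attempt_sequences(attempt, carers))["proportion"]


class TestCommonContracts:
    @pytest.mark.parametrize("mode", ["markov", "mechanistic", "bouts"])
    def test_deterministic_under_seed(self, mode):
        kwargs = {"mode": mode, "c": 3, "seed": 11, "n_days": 1}
        if mode == "markov":
            kwargs["Q"] = np.full((3, 3), 6.0)
        a = simulate(SimConfig(**kwargs))
        b = simulate(SimConfig(**kwargs))
        va = [(v.carer_id, v.time) for d in a.days for v in d.visits]
        vb = [(v.carer_id, v.time) for d in b.days for v in d.visits]
        assert va == vb
        c = simulate(SimConfig(**{**kwargs, "seed": 12}))
        vc = [(v.carer_id, v.time) for d in c.days for v in d.visits]
        assert va != vc

    @pytest.mark.parametrize("mode", ["markov", "mechanistic", "bouts"])
    def test_times_within_day_and_increasing_per_carer(self, mode):
        kwargs = {"mode": mode, "c": 3, "seed": 21, "n_days": 2}
        if mode == "markov":
            kwargs["Q"] = np.full((3, 3), 6.0)
        cfg = SimConfig(**kwargs)
        attempt = simulate(cfg)
        for day, (times, codes) in zip(attempt.days, day_arrays(attempt, cfg.carer_ids)):
            assert np.all(times >= day.day_start)
            assert np.all(times < day.day_start + cfg.day_length)
            for k in range(cfg.c):
                own = times[codes == k]
                assert np.all(np.diff(own) > 0)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(c=0)
        with pytest.raises(ValueError):
            SimConfig(repeat_suppression=1.5)
        with pytest.raises(ValueError):
            SimConfig(mode="markov", c=2, Q=np.full((3, 3), 1.0))


class TestMarkovMode:
    def test_equal_rate_pair_alternates_half_the_time(self):
        cfg = SimConfig(mode="markov", c=2, Q=np.full((2, 2), 8.0),
                        day_length=12 * 3600, n_days=30, seed=31)
        attempt = simulate_markov(cfg)
        prop = _alternation(attempt, cfg.carer_ids)
        n_pairs = attempt.n_visits - len(attempt.days)
        assert abs(prop - 0.5) < 3 * np.sqrt(0.25 / n_pairs)

    def test_symmetric_group_repeats_one_over_c(self):
        c = 4
        cfg = SimConfig(mode="markov", c=c, Q=np.full((c, c), 6.0),
                        day_length=12 * 3600, n_days=25, seed=32)
        attempt = simulate_markov(cfg)
        prop = _alternation(attempt, cfg.carer_ids)
        n_pairs = attempt.n_visits - len(attempt.days)
        p0 = (c - 1) / c
        assert abs(prop - p0) < 3 * np.sqrt(p0 * (1 - p0) / n_pairs)

    def test_counts_over_exposures_converge_to_q(self):
        q = np.array([[2.0, 6.0, 4.0], [8.0, 3.0, 5.0], [5.0, 7.0, 2.0]])
        cfg = SimConfig(mode="markov", c=3, Q=q, day_length=12 * 3600,
                        n_days=80, seed=33)
        attempt = simulate_markov(cfg)
        st = sufficient_stats(attempt, cfg.carer_ids)
        q_hat = fit_full(st).rates.q * 3600
        # each n_ij is Poisson(T_i q_ij): compare within 3 MC SDs
        se = 3600 * np.sqrt(st.n) / np.maximum(st.T, 1.0)
        assert np.all(np.abs(q_hat - q) <= 3.5 * se + 1e-9)

    def test_all_zero_rates_give_empty_days(self):
        cfg = SimConfig(mode="markov", c=2, Q=np.zeros((2, 2)), n_days=2, seed=1)
        assert simulate_markov(cfg).n_visits == 0


class TestMechanisticMode:
    def test_reduces_to_markov_without_refractory_or_response(self):
        base = np.array([5.0, 8.0, 11.0])
        mech_cfg = SimConfig(mode="mechanistic", c=3, base_rates=base,
                             refractory=Refractory("none"),
                             day_length=12 * 3600, n_days=40, seed=41)
        mark_cfg = SimConfig(mode="markov", c=3, Q=np.tile(base, (3, 1)),
                             day_length=12 * 3600, n_days=40, seed=42)
        mech = simulate_mechanistic(mech_cfg)
        mark = simulate_markov(mark_cfg)
        p1 = _alternation(mech, mech_cfg.carer_ids)
        p2 = _alternation(mark, mark_cfg.carer_ids)
        assert abs(p1 - p2) < 0.02
        r1 = fit_full(sufficient_stats(mech, mech_cfg.carer_ids)).rates.q * 3600
        assert np.all(np.abs(r1 - np.tile(base, (3, 1))) < 0.15 * np.tile(base, (3, 1)) + 1.0)

    def test_total_repeat_suppression_forces_pure_alternation(self):
        cfg = SimConfig(mode="mechanistic", c=2, base_rates=np.full(2, 8.0),
                        refractory=Refractory("none"), repeat_suppression=0.0,
                        day_length=12 * 3600, n_days=3, seed=43)
        attempt = simulate_mechanistic(cfg)
        assert _alternation(attempt, cfg.carer_ids) == 1.0

    def test_strong_refractory_yields_passive_alternation(self):
        # high rates + a long fixed refractory: near-perfect alternation with
        # no behavioral response at all
        cfg = SimConfig(mode="mechanistic", c=2, base_rates=np.full(2, 40.0),
                        refractory=Refractory("fixed", duration=600.0),
                        day_length=12 * 3600, n_days=2, seed=44)
        attempt = simulate_mechanistic(cfg)
        assert _alternation(attempt, cfg.carer_ids) > 0.9

    def test_refractory_enforces_minimum_own_interval(self):
        cfg = SimConfig(mode="mechanistic", c=2, base_rates=np.full(2, 20.0),
                        refractory=Refractory("fixed", duration=300.0),
                        day_length=12 * 3600, n_days=2, seed=45)
        attempt = simulate_mechanistic(cfg)
        for times, codes in day_arrays(attempt, cfg.carer_ids):
            for k in range(2):
                own = times[codes == k]
                if len(own) > 1:
                    assert np.min(np.diff(own)) >= 300.0


class TestBoutMode:
    def test_strong_bouts_cluster_group_ivis(self):
        # whole-group bouts whose spread is comparable to the onset gaps:
        # short within-bout intervals chain into long runs below the median
        small_p = 0
        for seed in range(10):
            cfg = SimConfig(mode="bouts", c=6, bout_rate=10.0, bout_p=1.0,
                            bout_jitter=400.0, day_length=12 * 3600, n_days=1,
                            seed=seed)
            attempt = simulate_bouts(cfg)
            times, _ = day_arrays(attempt, cfg.carer_ids)[0]
            ivis = np.diff(times)
            if len(ivis) >= 4 and ww_bout_test(ivis).p < 0.05:
                small_p += 1
        assert small_p >= 6

    def test_single_carer_bouts_reduce_to_renewal_stream(self):
        cfg = SimConfig(mode="bouts", c=1, bout_rate=6.0, bout_p=1.0,
                        day_length=12 * 3600, n_days=1, seed=9)
        attempt = simulate_bouts(cfg)
        times, _ = day_arrays(attempt, cfg.carer_ids)[0]
        assert len(times) > 10
        assert np.all(np.diff(times) > 0)

    def test_zero_bout_rate_gives_empty_attempt(self):
        cfg = SimConfig(mode="bouts", c=3, bout_rate=0.0, n_days=1, seed=1)
        assert simulate_bouts(cfg).n_visits == 0
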