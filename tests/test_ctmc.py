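import numpy as np
import pytest

from _oracles import numeric_mle_full, numeric_mle_per_individual, numeric_mle_pooled
from conftest import simulated_stats
from turnmark import (
    ProvisioningAttempt,
    SufficientStats,
    TransitionRates,
    Visit,
    VisitDay,
    export_msm_structure,
    fit_full,
    fit_per_individual,
    fit_pooled,
    log_likelihood,
    lrt,
    reciprocity_correlation,
    sufficient_stats,
    turn_taking_ratio,
    wilcoxon_lambda_mu,
)

MIN = 60.0


def _ab_attempt(n_copies: int = 1) -> ProvisioningAttempt:
    """Days of A@0, B@10, B@25, A@40 (minutes), repeated n_copies times."""
    days = []
    for d in range(1, n_copies + 1):
        start = (d - 1) * 86400.0
        visits = [
            Visit("n1", cid, start + m * MIN, day_index=d)
            for cid, m in [("A", 0), ("B", 10), ("B", 25), ("A", 40)]
        ]
        days.append(VisitDay(d, start, start + 86400, visits))
    return ProvisioningAttempt("n1", days)


class TestSufficientStats:
    def test_worked_example_counts_and_exposures(self):
        st = sufficient_stats(_ab_attempt(), ["A", "B"])
        assert st.n.tolist() == [[0, 1], [1, 1]]
        assert st.T.tolist() == [10 * MIN, 30 * MIN]
        assert st.n.sum() == st.n_visits - st.n_days

    def test_two_copies_double_everything(self):
        s1 = sufficient_stats(_ab_attempt(1), ["A", "B"])
        s2 = sufficient_stats(_ab_attempt(2), ["A", "B"])
        assert np.array_equal(s2.n, 2 * s1.n)
        assert np.allclose(s2.T, 2 * s1.T)

    def test_single_visit_days_contribute_nothing(self):
        days = [
            VisitDay(d, (d - 1) * 86400.0, d * 86400.0,
                     [Visit("n1", "A", (d - 1) * 86400.0 + 100, day_index=d)])
            for d in (1, 2)
        ]
        st = sufficient_stats(ProvisioningAttempt("n1", days), ["A", "B"])
        assert st.n.sum() == 0 and st.T.sum() == 0
        assert st.n_visits == 2


class TestLogLikelihood:
    def test_worked_example_value(self, ab_stats):
        # hand computation: ln 0.1 - 10*0.1 + 2*(ln(1/30)) - 30*(2/30)
        rates = TransitionRates(["A", "B"], np.array([[0.0, 0.1], [1 / 30, 1 / 30]]))
        assert log_likelihood(rates, ab_stats) == pytest.approx(-12.1050, abs=5e-5)

    def test_empty_data_gives_zero(self):
        st = SufficientStats(["A", "B"], np.zeros((2, 2)), np.zeros(2))
        rates = TransitionRates(["A", "B"], np.full((2, 2), 2.0))
        assert log_likelihood(rates, st) == 0.0

    def test_zero_rate_with_positive_count_is_minus_inf(self, ab_stats):
        rates = TransitionRates(["A", "B"], np.array([[0.0, 0.0], [1.0, 1.0]]))
        assert log_likelihood(rates, ab_stats) == -np.inf


class TestClosedFormFits:
    def test_full_mle_worked_example(self, ab_stats):
        fit = fit_full(ab_stats)
        assert np.allclose(fit.rates.q, [[0.0, 0.1], [1 / 30, 1 / 30]])
        assert fit.n_params == 4
        assert fit.logLik == pytest.approx(-12.1050, abs=5e-5)

    def test_full_mle_constructed_constant(self):
        # n = k*T row-wise forces q-hat identically k
        T = np.array([2.0, 5.0, 3.0])
        k = 1.5
        st = SufficientStats(list("abc"), np.tile(k * T[:, None], (1, 3)), T)
        assert np.allclose(fit_full(st).rates.q, k)

    def test_per_individual_worked_example(self, ab_stats):
        fit = fit_per_individual(ab_stats)
        assert np.allclose(fit.mu_i, [0.0, 1 / 30])
        assert np.allclose(fit.lambda_i, [1 / 30, 0.1])
        assert fit.n_params == 4

    def test_per_individual_symmetric_stats(self):
        st = SufficientStats(
            list("abc"), np.full((3, 3), 4.0), np.full(3, 10.0)
        )
        fit = fit_per_individual(st)
        assert np.allclose(fit.lambda_i, fit.lambda_i[0])
        assert np.allclose(fit.mu_i, fit.mu_i[0])

    def test_pooled_worked_example(self, ab_stats):
        fit = fit_pooled(ab_stats)
        assert fit.lambda0 == pytest.approx(0.05)
        assert fit.mu0 == pytest.approx(0.025)
        assert fit.n_params == 2

    @pytest.mark.parametrize("seed,c", [(11, 2), (12, 3), (13, 4)])
    def test_nesting_of_log_likelihoods(self, seed, c):
        st, _ = simulated_stats(seed, c, n_days=1, day_hours=6)
        ll_full = fit_full(st).logLik
        ll_pi = fit_per_individual(st).logLik
        ll_pool = fit_pooled(st).logLik
        assert ll_full >= ll_pi - 1e-9 >= ll_pool - 2e-9

    @pytest.mark.parametrize("seed,c", [(21, 2), (22, 4)])
    def test_closed_form_matches_numerical_maximization(self, seed, c):
        st, _ = simulated_stats(seed, c)
        fit = fit_full(st)
        q_num = numeric_mle_full(st)
        free = st.n > 0
        assert np.allclose(fit.rates.q[free], q_num[free], rtol=1e-7)
        pi = fit_per_individual(st)
        lam, mu = numeric_mle_per_individual(st)
        assert np.allclose(pi.lambda_i, lam, rtol=1e-7)
        assert np.allclose(pi.mu_i[pi.mu_i > 0], mu[pi.mu_i > 0], rtol=1e-7)
        po = fit_pooled(st)
        lam0, mu0 = numeric_mle_pooled(st)
        assert po.lambda0 == pytest.approx(lam0, rel=1e-7)
        assert po.mu0 == pytest.approx(mu0, rel=1e-7)

    def test_no_small_perturbation_improves_the_full_mle(self):
        st, _ = simulated_stats(31, 3)
        fit = fit_full(st)
        base = fit.logLik
        for i in range(3):
            for j in range(3):
                for factor in (0.99, 1.01):
                    q = fit.rates.q.copy()
                    q[i, j] *= factor
                    assert log_likelihood(TransitionRates(st.carers, q), st) <= base + 1e-9

    def test_time_unit_equivariance(self):
        st, _ = simulated_stats(41, 3)
        scaled = SufficientStats(st.carers, st.n, st.T * 60.0)
        f1, f2 = fit_full(st), fit_full(scaled)
        assert np.allclose(f2.rates.q * 60.0, f1.rates.q)
        # logLik changes only by the deterministic Jacobian n_trans*log 60
        assert f2.logLik + st.n.sum() * np.log(60.0) == pytest.approx(f1.logLik)
        # LRT statistics are invariant
        l1 = lrt(f1, fit_pooled(st))
        l2 = lrt(f2, fit_pooled(scaled))
        assert l1.stat == pytest.approx(l2.stat)


class TestLRT:
    def test_degrees_of_freedom_c4(self):
        st, _ = simulated_stats(51, 4)
        full, pi, po = fit_full(st), fit_per_individual(st), fit_pooled(st)
        assert lrt(full, pi).df == 16 - 8
        assert lrt(pi, po).df == 8 - 2
        assert lrt(full, po).df == 16 - 2

    def test_non_nested_pair_rejected(self):
        st, _ = simulated_stats(52, 3)
        with pytest.raises(ValueError, match="nested"):
            lrt(fit_pooled(st), fit_full(st))

    def test_stat_nonnegative_and_p_in_range(self):
        st, _ = simulated_stats(53, 3)
        res = lrt(fit_full(st), fit_per_individual(st))
        assert res.stat >= 0
        assert 0 <= res.p <= 1


class TestTurnTakingRatio:
    def test_worked_example_group_ratio(self, ab_stats):
        out = turn_taking_ratio(fit_per_individual(ab_stats))
        assert out["group_ratio"] == pytest.approx(4.0)
        # mu_A = 0 with lambda_A > 0: individual ratio infinite, flagged
        assert np.isinf(out["per_carer"][0])
        assert out["flags"]

    def test_equal_rates_give_ratio_one(self):
        st = SufficientStats(list("ab"), np.full((2, 2), 5.0), np.full(2, 10.0))
        out = turn_taking_ratio(fit_per_individual(st))
        assert out["group_ratio"] == pytest.approx(1.0)

    def test_requires_per_individual_fit(self, ab_stats):
        with pytest.raises(ValueError):
            turn_taking_ratio(fit_full(ab_stats))


class TestReciprocity:
    def test_symmetric_rates_have_rho_one(self):
        q = np.array([[1.0, 2.0, 3.0], [2.0, 1.0, 5.0], [3.0, 5.0, 1.0]])
        out = reciprocity_correlation(TransitionRates(list("abc"), q), seed=0)
        assert out["rho"] == pytest.approx(1.0)

    def test_two_carers_undefined(self):
        q = np.ones((2, 2))
        out = reciprocity_correlation(TransitionRates(list("ab"), q), seed=0)
        assert out["rho"] is None and out["flags"]

    def test_independent_rates_p_roughly_uniform(self):
        # over seeded replicates of i.i.d. off-diagonals the p-value mean is ~0.5
        rng = np.random.default_rng(7)
        ps = []
        for _ in range(40):
            q = rng.uniform(1, 10, size=(4, 4))
            ps.append(
                reciprocity_correlation(
                    TransitionRates(list("abcd"), q), n_perm=199, seed=1
                )["p"]
            )
        assert 0.3 < np.mean(ps) < 0.7


def test_wilcoxon_detects_lambda_above_mu():
    st, _ = simulated_stats(61, 4)
    # force a strong lambda > mu signature by zero-weighting the diagonal
    n = st.n.copy()
    np.fill_diagonal(n, np.maximum(1, np.diag(n) // 8))
    strong = SufficientStats(st.carers, n, st.T)
    out = wilcoxon_lambda_mu(fit_per_individual(strong))
    assert out["method"] == "exact"
    assert out["p"] < 0.15  # n=4 carers: exact two-sided floor is 0.125


class TestMsmStructureExport:
    def test_four_carer_graph_counts(self):
        g = export_msm_structure(4)
        assert g["n_states"] == 8
        assert g["n_visit_transitions"] == 16
        assert g["n_transitions"] == 20

    @pytest.mark.parametrize("c", [1, 2, 3, 5, 6])
    def test_counts_scale_as_c(self, c):
        g = export_msm_structure(c)
        assert g["n_states"] == 2 * c
        assert g["n_transitions"] == c * (c + 1)
        resets = [t for t in g["transitions"] if t["kind"] == "reset"]
        assert len(resets) == c
        assert all(t["rate"] > 1e5 for t in resets)
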