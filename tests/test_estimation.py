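"""Forward-backward and Baum-Welch against enumeration and hmmlearn."""

import numpy as np
import pytest

import crisishmm as ch
from crisishmm import CrisisSeries, FitConfig, ModelParams
from crisishmm.estimation import _S, _U, _draw_inits, _em_batch

from conftest import enumerate_posteriors, random_valid_params


def _random_feasible_case(rng, max_T=8):
    """Params, prior and observations with nonzero likelihood."""
    m = random_valid_params(rng)
    T = int(rng.integers(2, max_T + 1))
    obs = rng.integers(0, 2, T)
    prior = float(rng.uniform(0.05, 0.95))
    return m, prior, obs


class TestForwardBackwardOracle:
    def test_likelihood_matches_path_enumeration(self, rng):
        for _ in range(40):
            m, prior, obs = _random_feasible_case(rng)
            lik, _, _ = enumerate_posteriors(m, prior, obs)
            _, _, loglik = ch.forward_pass(m, prior, obs)
            assert np.exp(loglik) == pytest.approx(lik, abs=1e-10)

    def test_likelihood_matches_hmmlearn(self, rng):
        hmm = pytest.importorskip("hmmlearn.hmm")
        for _ in range(20):
            m, prior, obs = _random_feasible_case(rng)
            ref = hmm.CategoricalHMM(n_components=2, init_params="",
                                     params="")
            ref.startprob_ = np.array([1 - prior, prior])
            ref.transmat_ = m.transition_matrix
            ref.emissionprob_ = np.array([[1.0, 0.0], [1 - m.p, m.p]])
            _, _, loglik = ch.forward_pass(m, prior, obs)
            assert loglik == pytest.approx(
                ref.score(obs.reshape(-1, 1)), abs=1e-10
            )

    def test_two_week_toy_sequence(self):
        # crisis then quiet week; all four state paths enumerated by hand
        m = ModelParams(p=0.5, q=0.2, r=0.5)
        lik, _, _ = enumerate_posteriors(m, 0.5, [1, 0])
        _, _, loglik = ch.forward_pass(m, 0.5, [1, 0])
        assert np.exp(loglik) == pytest.approx(lik, abs=1e-12)
        # UxS and UxU are the only live paths: 0.5*0.5*(0.5*1 + 0.5*0.5)
        assert lik == pytest.approx(0.25 * 0.75, abs=1e-12)

    def test_certain_quiet_sequence_has_probability_one(self):
        m = ModelParams(p=1.0, q=0.0, r=0.6)
        _, _, loglik = ch.forward_pass(m, 0.0, [0, 0, 0, 0])
        assert loglik == pytest.approx(0.0, abs=1e-12)

    def test_impossible_sequence_signals_zero_likelihood(self):
        with pytest.raises(ch.ZeroLikelihoodError):
            ch.forward_pass(ModelParams(0.9, 0.0, 0.5), 0.0, [1])

    def test_backward_terminal_condition_and_enumeration(self, rng):
        for _ in range(20):
            m, prior, obs = _random_feasible_case(rng)
            beta = ch.backward_pass(m, obs)
            np.testing.assert_allclose(beta[-1], 1.0)
            # unscaled beta(x_0) = P(y_1..T | x_0) by enumeration over
            # the future paths only (beta never involves y_0)
            from itertools import product
            for x0 in (0, 1):
                total = 0.0
                for path in product([0, 1], repeat=len(obs) - 1):
                    pr, prev = 1.0, x0
                    for t, x in enumerate(path, start=1):
                        if prev == 1:
                            pr *= m.r if x == 1 else 1 - m.r
                        else:
                            pr *= m.q if x == 1 else 1 - m.q
                        if x == 1:
                            pr *= m.p if obs[t] else 1 - m.p
                        else:
                            pr *= 0.0 if obs[t] else 1.0
                        prev = x
                    total += pr
                assert beta[0, x0] == pytest.approx(total, abs=1e-10)

    def test_uninformative_emissions_make_beta_symmetric(self):
        m = ModelParams(p=0.0, q=0.2, r=0.7)
        beta = ch.backward_pass(m, [0] * 6)
        np.testing.assert_allclose(beta[:, _S], beta[:, _U], atol=1e-12)


class TestPosteriors:
    def test_match_enumeration(self, rng):
        for _ in range(30):
            m, prior, obs = _random_feasible_case(rng)
            _, gamma_ref, xi_ref = enumerate_posteriors(m, prior, obs)
            tb = ch.posterior_tables(m, prior, obs)
            np.testing.assert_allclose(tb.gamma, gamma_ref, atol=1e-10)
            np.testing.assert_allclose(tb.xi, xi_ref, atol=1e-10)

    def test_invariants(self, rng):
        for _ in range(30):
            m, prior, obs = _random_feasible_case(rng, max_T=40)
            tb = ch.posterior_tables(m, prior, obs)
            np.testing.assert_allclose(tb.gamma.sum(axis=1), 1.0, atol=1e-10)
            if len(tb.xi):
                np.testing.assert_allclose(
                    tb.xi.sum(axis=(1, 2)), 1.0, atol=1e-10
                )
                # transition posteriors marginalise to state posteriors
                np.testing.assert_allclose(
                    tb.xi.sum(axis=2), tb.gamma[:-1], atol=1e-10
                )

    def test_crisis_forces_unstable_state(self, rng):
        m = ModelParams(0.6, 0.2, 0.7)
        obs = np.array([0, 1, 0, 1, 1, 0])
        tb = ch.posterior_tables(m, 0.5, obs)
        np.testing.assert_allclose(tb.gamma[obs == 1, _U], 1.0, atol=1e-12)

    def test_p_zero_reduces_to_chain_marginals(self):
        m = ModelParams(p=0.0, q=0.15, r=0.65)
        prior = 0.3
        tb = ch.posterior_tables(m, prior, [0] * 8)
        pi = np.array([1 - prior, prior])
        for t in range(8):
            np.testing.assert_allclose(tb.gamma[t], pi, atol=1e-12)
            pi = pi @ m.transition_matrix


class TestMStep:
    def test_toy_ratios_match_hand_sums(self, rng):
        for _ in range(20):
            m, prior, obs = _random_feasible_case(rng, max_T=6)
            tb = ch.posterior_tables(m, prior, obs)
            est = ch.m_step_single(tb, obs, current=m)
            g, x = tb.gamma, tb.xi
            if g[:-1, _S].sum() > 1e-12:
                assert est.q == pytest.approx(
                    x[:, _S, _U].sum() / g[:-1, _S].sum()
                )
            if g[:-1, _U].sum() > 1e-12:
                assert est.r == pytest.approx(
                    x[:, _U, _U].sum() / g[:-1, _U].sum()
                )
            assert est.p == pytest.approx(
                (obs * g[:, _U]).sum() / g[:, _U].sum()
            )

    def test_degenerate_all_crisis_mass(self):
        m = ModelParams(0.9, 0.3, 0.7)
        obs = np.array([1, 1, 1])
        tb = ch.posterior_tables(m, 0.5, obs)
        est = ch.m_step_single(tb, obs, current=m)
        assert est.p == pytest.approx(1.0)
        assert est.r == pytest.approx(1.0)

    def test_zero_occupancy_signals_unidentifiable(self):
        m = ModelParams(0.9, 0.0, 0.7)
        obs = np.array([0, 0, 0])
        tb = ch.posterior_tables(m, 0.0, obs)  # never in U
        with pytest.raises(ch.UnidentifiableError):
            ch.m_step_single(tb, obs)
        frozen = ch.m_step_single(tb, obs, current=m)
        assert (frozen.p, frozen.r) == (m.p, m.r)


class TestBaumWelch:
    def test_loglik_non_decreasing_and_best_restart(self, rng):
        m = ModelParams(0.9, 0.08, 0.75)
        sim = ch.simulate_patient(m, 150, None, rng, "x")
        fr = ch.baum_welch_single(
            CrisisSeries("x", sim.crises),
            FitConfig(max_iter=300, n_restarts=5, seed=7),
        )
        assert np.all(np.diff(fr.loglik_history) >= -1e-8)
        assert fr.loglik == pytest.approx(np.max(fr.restart_logliks))
        assert len(fr.restart_logliks) == 5

    def test_engine_matches_scalar_em_reference(self, rng):
        m = ModelParams(0.85, 0.1, 0.7)
        sim = ch.simulate_patient(m, 80, None, rng, "x")
        obs = sim.crises
        init = np.array([[0.5, 0.1, 0.7]])
        res = _em_batch(obs[None, :], init, 1e-5, 40, 0.5,
                        track_history=True)
        params = ModelParams(0.5, 0.1, 0.7)
        hist, prev = [], None
        for _ in range(40):
            tb = ch.posterior_tables(params, 0.5, obs)
            hist.append(tb.loglik)
            if prev is not None and abs(tb.loglik - prev) < 1e-5:
                break
            prev = tb.loglik
            params = ch.m_step_single(tb, obs, current=params)
        np.testing.assert_allclose(res["history"][0], hist, atol=1e-9)

    def test_recovers_generating_parameters(self, rng):
        # four years of weekly data from a moderately active patient
        true = ModelParams(p=0.9, q=0.05, r=0.8)
        sim = ch.simulate_patient(true, 208, None, rng, "x")
        fr = ch.baum_welch_single(
            CrisisSeries("x", sim.crises),
            FitConfig(max_iter=1000, n_restarts=10, seed=3),
        )
        assert fr.converged
        assert fr.params.q == pytest.approx(true.q, abs=0.05)
        assert fr.params.r == pytest.approx(true.r, abs=0.15)
        assert fr.params.p == pytest.approx(true.p, abs=0.15)

    def test_isolated_crises_fit_r_near_zero(self, rng):
        true = ModelParams(p=0.95, q=0.04, r=0.0)
        sim = ch.simulate_patient(true, 260, None, rng, "x")
        assert sim.crises.sum() >= 3
        fr = ch.baum_welch_single(
            CrisisSeries("x", sim.crises),
            FitConfig(max_iter=1000, n_restarts=10, seed=5),
        )
        assert fr.params.r == pytest.approx(0.0, abs=0.05)

    def test_all_zero_sequence_flagged_unidentifiable(self):
        fr = ch.baum_welch_single(
            CrisisSeries("x", np.zeros(30, dtype=np.int8)),
            FitConfig(max_iter=100, n_restarts=2, seed=0),
        )
        assert fr.unidentifiable

    def test_fit_cohort_matches_per_series_batches(self, rng):
        series = []
        for i in range(6):
            m = random_valid_params(rng)
            sim = ch.simulate_patient(m, 120, None, rng, f"s{i}")
            if sim.crises.sum() == 0:
                continue
            series.append(CrisisSeries(f"s{i}", sim.crises))
        cfg = FitConfig(max_iter=200, n_restarts=4, seed=11)
        fits = ch.fit_cohort(series, cfg)
        children = np.random.SeedSequence(11).spawn(len(series))
        for i, s in enumerate(series):
            inits = _draw_inits(np.random.default_rng(children[i]), 4)
            res = _em_batch(np.tile(s.obs, (4, 1)), inits, cfg.tol,
                            cfg.max_iter, cfg.init_prior_U)
            j = int(np.argmax(res["loglik"]))
            assert fits[i].loglik == pytest.approx(res["loglik"][j],
                                                   abs=1e-9)
            assert fits[i].params.p == pytest.approx(res["p"][j], abs=1e-9)


class TestPooled:
    def test_cohort_of_one_reduces_to_single(self, rng):
        m = ModelParams(0.9, 0.06, 0.75)
        sim = ch.simulate_patient(m, 100, None, rng, "a")
        s = CrisisSeries("a", sim.crises)
        cfg = FitConfig(max_iter=200, n_restarts=4, seed=11)
        pooled = ch.baum_welch_pooled([s], cfg)
        single = ch.baum_welch_single(s, cfg)
        assert pooled.loglik == pytest.approx(single.loglik, abs=1e-9)
        assert pooled.params.p == pytest.approx(single.params.p, abs=1e-9)
        assert pooled.params.q == pytest.approx(single.params.q, abs=1e-9)

    def test_pooled_loglik_is_sum_over_patients(self, rng):
        series = []
        for i in range(4):
            sim = ch.simulate_patient(ModelParams(0.9, 0.07, 0.7), 80, None,
                                      rng, f"s{i}")
            series.append(CrisisSeries(f"s{i}", sim.crises))
        fr = ch.baum_welch_pooled(series,
                                  FitConfig(max_iter=300, n_restarts=3,
                                            seed=2))
        total = sum(
            ch.forward_pass(fr.params, 0.5, s.obs)[2] for s in series
        )
        assert fr.loglik == pytest.approx(total, abs=1e-8)

    def test_pooled_recovers_shared_parameters(self, rng):
        true = ModelParams(0.9, 0.08, 0.75)
        series = [
            CrisisSeries(f"s{i}",
                         ch.simulate_patient(true, 150, None, rng,
                                             f"s{i}").crises)
            for i in range(30)
        ]
        fr = ch.baum_welch_pooled(series,
                                  FitConfig(max_iter=300, n_restarts=3,
                                            seed=4))
        assert fr.params.q == pytest.approx(true.q, abs=0.02)
        assert fr.params.r == pytest.approx(true.r, abs=0.05)
        assert fr.params.p == pytest.approx(true.p, abs=0.05)


class TestAssignParameters:
    def _cohort(self):
        return [
            CrisisSeries("short", np.tile([1, 0], 5)),        # 10 weeks
            CrisisSeries("boundary", np.tile([1, 0, 0], 5)[:13]),
            CrisisSeries("long", np.tile([1, 0, 0, 0], 10)),
        ]

    def test_three_month_rule(self):
        pooled = ModelParams(0.95, 0.037, 0.86)
        indiv = ModelParams(0.5, 0.1, 0.2)
        fits = {s.patient_id: ch.FitResult(indiv, -1.0, 5, True,
                                           np.array([-1.0]))
                for s in self._cohort()}
        out = ch.assign_parameters(self._cohort(), pooled, fits, 13)
        assert out["short"] == pooled          # < 13 weeks -> pooled
        assert out["boundary"] == indiv        # exactly 13 -> individual
        assert out["long"] == indiv

    def test_threshold_zero_everyone_individual(self):
        pooled = ModelParams(0.95, 0.037, 0.86)
        indiv = ModelParams(0.5, 0.1, 0.2)
        fits = {s.patient_id: ch.FitResult(indiv, -1.0, 5, True,
                                           np.array([-1.0]))
                for s in self._cohort()}
        out = ch.assign_parameters(self._cohort(), pooled, fits, 0)
        assert all(v == indiv for v in out.values())


def test_crisis_series_validation():
    with pytest.raises(ValueError):
        CrisisSeries("x", np.array([0, 2, 1]))
    with pytest.raises(ValueError):
        CrisisSeries("x", np.array([]))
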