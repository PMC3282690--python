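"""HMM likelihood, posteriors, and Baum-Welch fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as hst

import smtrace as st
from smtrace.hmm import (
    EmissionParams,
    HmmParams,
    get_param,
    log_likelihood,
    posterior_state_probs,
    set_param,
)
from smtrace.models import EmissionSpec, ModelSpec, Topology
from smtrace.traces import Trace

from _oracles import brute_force_loglik, brute_force_posteriors, random_instance


class TestLikelihoodOracle:
    @given(
        seed=hst.integers(min_value=0, max_value=10_000),
        K=hst.integers(min_value=1, max_value=3),
        T=hst.integers(min_value=2, max_value=8),
        family=hst.sampled_from(["poisson", "gaussian"]),
    )
    def test_forward_matches_path_enumeration(self, seed, K, T, family):
        rng = np.random.default_rng(seed)
        trace, params = random_instance(rng, K, T, family)
        assert log_likelihood(trace, params) == pytest.approx(
            brute_force_loglik(trace, params), abs=1e-9
        )

    @given(
        seed=hst.integers(min_value=0, max_value=10_000),
        K=hst.integers(min_value=1, max_value=3),
        T=hst.integers(min_value=2, max_value=7),
    )
    def test_posteriors_match_path_enumeration(self, seed, K, T):
        rng = np.random.default_rng(seed)
        trace, params = random_instance(rng, K, T)
        got = posterior_state_probs(trace, params)
        np.testing.assert_allclose(got, brute_force_posteriors(trace, params), atol=1e-9)

    def test_long_trace_no_underflow(self):
        rng = np.random.default_rng(0)
        x = rng.poisson(100.0, size=30_000).astype(float)
        trace = Trace("long", 1.0, x[:, None])
        A = np.array([[0.9, 0.1], [0.1, 0.9]])
        params = HmmParams(
            A,
            EmissionParams(("poisson",), np.array([[95.0], [110.0]])),
            st.stationary_distribution(A),
        )
        ll = log_likelihood(trace, params)
        assert math.isfinite(ll) and ll < 0

    def test_hmmlearn_cross_check_gaussian(self):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        rng = np.random.default_rng(42)
        x = rng.normal(3.0, 2.0, size=(500, 1))
        trace = Trace("g", 1.0, x)
        A = np.array([[0.8, 0.2], [0.4, 0.6]])
        mu = np.array([[1.0], [6.0]])
        sigma = np.array([[1.5], [2.5]])
        pi0 = np.array([0.3, 0.7])
        mine = log_likelihood(
            trace, HmmParams(A, EmissionParams(("gaussian",), mu, sigma), pi0)
        )
        ref = hmmlearn.GaussianHMM(n_components=2, covariance_type="diag", init_params="")
        ref.startprob_ = pi0
        ref.transmat_ = A
        ref.means_ = mu
        ref.covars_ = sigma**2
        assert mine == pytest.approx(ref.score(x), abs=1e-8)


class TestParamNaming:
    def _params(self):
        A = np.array([[0.8, 0.2], [0.3, 0.7]])
        return HmmParams(
            A,
            EmissionParams(("poisson",), np.array([[100.0], [120.0]])),
            st.stationary_distribution(A),
        )

    def test_get_aliases(self):
        p = self._params()
        assert get_param(p, "k12") == get_param(p, "A[1][2]") == 0.2
        assert get_param(p, "mu[2][1]") == 120.0

    def test_set_renormalizes_row_and_pi0(self):
        p = set_param(self._params(), "k12", 0.4)
        assert p.A[0, 0] == pytest.approx(0.6)
        np.testing.assert_allclose(p.pi0 @ p.A, p.pi0, atol=1e-12)

    def test_set_invalid_values_rejected(self):
        p = self._params()
        with pytest.raises(ValueError):
            set_param(p, "k12", 1.2)
        with pytest.raises(ValueError):
            set_param(p, "mu[1][1]", -5.0)
        with pytest.raises(ValueError):
            get_param(p, "bogus")


class TestFitting:
    def test_recovers_two_state_kinetics(self, snr5_trace, snr5_fit):
        _, _, truth = snr5_trace
        fit = snr5_fit
        assert fit.converged
        assert fit.params.A[0, 1] == pytest.approx(truth.A[0, 1], rel=0.25)
        assert fit.params.A[1, 0] == pytest.approx(truth.A[1, 0], rel=0.25)
        np.testing.assert_allclose(
            np.sort(fit.params.emissions.mu[:, 0]),
            np.sort(truth.emissions.mu[:, 0]),
            rtol=0.02,
        )

    def test_loglik_path_monotone(self, snr5_fit):
        path = np.array(snr5_fit.loglik_path)
        assert path.size >= 2
        assert np.all(np.diff(path) >= -1e-8 * np.maximum(1.0, np.abs(path[:-1])))

    def test_states_sorted_by_mean(self, snr5_fit):
        mu = snr5_fit.params.emissions.mu[:, 0]
        assert mu[0] < mu[1]

    def test_pi0_is_stationary_by_default(self, snr5_fit):
        p = snr5_fit.params
        np.testing.assert_allclose(p.pi0 @ p.A, p.pi0, atol=1e-10)

    def test_forbidden_transitions_stay_zero(self, menu):
        params = st.linear_chain_params(0.1, 4.0)
        cfg = st.SimulationConfig(params=params, snr=4.0, c=10_000, seed=99)
        tr, _ = st.simulate_trace(cfg, 0)
        fit = st.fit_hmm(tr, menu["3-linear"], seed=1)
        assert fit.params.A[0, 2] == 0.0 and fit.params.A[2, 0] == 0.0
        np.testing.assert_allclose(fit.params.A.sum(axis=1), 1.0, atol=1e-12)

    def test_detailed_balance_constraint_holds(self, menu):
        params = st.linear_chain_params(0.1, 4.0)
        cfg = st.SimulationConfig(params=params, snr=4.0, c=10_000, seed=21)
        tr, _ = st.simulate_trace(cfg, 0)
        fit = st.fit_hmm(tr, menu["3-thermo"], seed=1)
        pi = st.stationary_distribution(fit.params.A)
        flux = pi[:, None] * fit.params.A
        np.testing.assert_allclose(flux, flux.T, atol=1e-8)

    def test_constraint_costs_likelihood(self, menu):
        params = st.linear_chain_params(0.1, 4.0)
        cfg = st.SimulationConfig(params=params, snr=4.0, c=10_000, seed=22)
        tr, _ = st.simulate_trace(cfg, 0)
        free = st.fit_hmm(tr, menu["3-cycle"], seed=1)
        constrained = st.fit_hmm(tr, menu["3-thermo"], seed=1)
        assert free.loglik >= constrained.loglik - 1e-6

    def test_fixed_params_pinned(self, snr5_trace, menu):
        tr, _, _ = snr5_trace
        fit = st.fit_hmm(
            tr, menu["2-state"], fixed_params={"k12": 0.17}, sort_states=False
        )
        assert fit.params.A[0, 1] == pytest.approx(0.17, abs=1e-12)

    def test_fixed_param_reduces_loglik(self, snr5_trace, snr5_fit, menu):
        tr, _, _ = snr5_trace
        pinned = st.fit_hmm(
            tr, menu["2-state"], fixed_params={"k12": 0.05}, sort_states=False
        )
        assert pinned.loglik <= snr5_fit.loglik + 1e-6

    def test_tied_emissions_shared(self):
        spec = ModelSpec(
            "3-tied",
            Topology(3, frozenset({(0, 1), (1, 0), (1, 2), (2, 1)})),
            EmissionSpec(("poisson",), tie_groups=(((0, 2), (1,)),)),
        )
        params = st.linear_chain_params(0.1, 4.0)
        # make states 1 and 3 emit identically, matching the tie
        params.emissions.mu[2, 0] = params.emissions.mu[0, 0]
        cfg = st.SimulationConfig(params=params, length_mode="fixed", T=4000, seed=5)
        tr, _ = st.simulate_trace(cfg, 0)
        fit = st.fit_hmm(tr, spec, seed=0, sort_states=False)
        assert fit.params.emissions.mu[0, 0] == fit.params.emissions.mu[2, 0]

    def test_posteriors_shape_and_normalization(self, snr5_trace, snr5_fit):
        tr, _, _ = snr5_trace
        post = snr5_fit.posteriors
        assert post.shape == (tr.T, 2)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_posteriors_track_hidden_states(self, snr5_trace, snr5_fit):
        _, states, _ = snr5_trace
        viterbi_like = snr5_fit.posteriors.argmax(axis=1)
        assert np.mean(viterbi_like == states) > 0.9

    def test_channel_mismatch_rejected(self, snr5_trace):
        tr, _, _ = snr5_trace
        two_ch = st.builtin_models(n_channels=2)["2-state"]
        with pytest.raises(ValueError, match="channels"):
            st.fit_hmm(tr, two_ch)

    def test_one_state_fit_is_sample_mean(self, noise_trace, menu):
        fit = st.fit_hmm(noise_trace, menu["1-state"], n_restarts=1)
        assert fit.params.emissions.mu[0, 0] == pytest.approx(
            noise_trace.channels.mean(), rel=1e-9
        )

    def test_multichannel_fit(self):
        params = st.two_state_params(0.2, 0.2, 5.0, n_channels=2)
        cfg = st.SimulationConfig(params=params, snr=5.0, c=6000, seed=77)
        tr, _ = st.simulate_trace(cfg, 0)
        fit = st.fit_hmm(tr, st.builtin_models(n_channels=2)["2-state"], seed=0)
        np.testing.assert_allclose(
            fit.params.emissions.mu, params.emissions.mu, rtol=0.02
        )
        assert fit.params.A[0, 1] == pytest.approx(0.2, rel=0.3)
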