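"""Simulator: SNR algebra, photobleaching lengths, and statistical sanity."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as hst

import smtrace as st


class TestSnr:
    def test_poisson_worked_example(self):
        # state means 100 and 110 give an SNR of about one
        assert st.snr_two_state(100.0, 110.0) == pytest.approx(0.9759, abs=1e-4)

    def test_symmetry(self):
        assert st.snr_two_state(100.0, 140.0) == st.snr_two_state(140.0, 100.0)

    def test_gaussian_form(self):
        assert st.snr_two_state(
            0.0, 3.0, family="gaussian", sigma1=1.0, sigma2=1.0
        ) == pytest.approx(3.0)

    def test_combined_two_unit_channels(self):
        assert st.combined_snr([1.0, 1.0]) == pytest.approx(math.sqrt(2.0), abs=1e-9)

    def test_combined_single_channel_identity(self):
        assert st.combined_snr([2.7]) == pytest.approx(2.7)

    @given(
        snr=hst.floats(min_value=0.05, max_value=40.0),
        mu1=hst.floats(min_value=1.0, max_value=1e4),
    )
    def test_means_for_snr_inverts_snr(self, snr, mu1):
        mu2 = st.means_for_snr(snr, mu1)
        assert st.snr_two_state(mu1, mu2) == pytest.approx(snr, rel=1e-9)

    def test_two_state_params_achieve_target_snr(self):
        p = st.two_state_params(0.3, 0.3, 5.0, n_channels=2)
        per = [
            st.snr_two_state(p.emissions.mu[0, c], p.emissions.mu[1, c])
            for c in range(2)
        ]
        assert st.combined_snr(per) == pytest.approx(5.0, rel=1e-9)
        # donor/acceptor anti-correlation: channel means move in opposition
        assert p.emissions.mu[0, 0] < p.emissions.mu[1, 0]
        assert p.emissions.mu[0, 1] > p.emissions.mu[1, 1]


class TestTraceLength:
    def test_photobleach_coupling(self):
        p = st.two_state_params(0.1, 0.1, 4.0)
        cfg = st.SimulationConfig(params=p, snr=4.0, c=10_000)
        assert cfg.trace_length() == 2500

    def test_fixed_mode(self):
        p = st.two_state_params(0.1, 0.1, 4.0)
        cfg = st.SimulationConfig(params=p, length_mode="fixed", T=123)
        assert cfg.trace_length() == 123

    def test_too_short_rejected(self):
        p = st.two_state_params(0.1, 0.1, 4.0)
        cfg = st.SimulationConfig(params=p, snr=1e5, c=10.0)
        with pytest.raises(ValueError, match="< 2"):
            cfg.trace_length()


class TestSimulation:
    def _cfg(self, seed=0, n=3):
        p = st.two_state_params(0.3, 0.3, 5.0)
        return st.SimulationConfig(params=p, snr=5.0, c=10_000, n_traces=n, seed=seed)

    def test_deterministic_given_seed(self):
        t1, s1 = st.simulate_trace(self._cfg(seed=7), 0)
        t2, s2 = st.simulate_trace(self._cfg(seed=7), 0)
        np.testing.assert_array_equal(t1.channels, t2.channels)
        np.testing.assert_array_equal(s1, s2)

    def test_traces_differ_across_indices_and_seeds(self):
        a, _ = st.simulate_trace(self._cfg(seed=7), 0)
        b, _ = st.simulate_trace(self._cfg(seed=7), 1)
        c, _ = st.simulate_trace(self._cfg(seed=8), 0)
        assert not np.array_equal(a.channels, b.channels)
        assert not np.array_equal(a.channels, c.channels)

    def test_population_ids_unique_and_sized(self):
        ts, paths = st.simulate_population(self._cfg(n=5))
        assert len(ts) == 5 and len(set(ts.ids())) == 5
        assert set(paths) == set(ts.ids())

    def test_poisson_channels_are_nonnegative_integers(self):
        tr, _ = st.simulate_trace(self._cfg(), 0)
        x = tr.channels
        assert np.all(x >= 0)
        np.testing.assert_array_equal(x, np.round(x))

    def test_emission_means_match_hidden_states(self):
        cfg = self._cfg()
        tr, states = st.simulate_trace(cfg, 0)
        mu = cfg.params.emissions.mu[:, 0]
        for s in (0, 1):
            mask = states == s
            n = int(mask.sum())
            assert n > 100
            # Poisson mean within 5 standard errors
            se = math.sqrt(mu[s] / n)
            assert abs(tr.channels[mask, 0].mean() - mu[s]) < 5 * se

    def test_empirical_transition_frequency(self):
        p = st.two_state_params(0.25, 0.25, 5.0)
        cfg = st.SimulationConfig(
            params=p, length_mode="fixed", T=30_000, n_traces=1, seed=11
        )
        _, states = st.simulate_trace(cfg, 0)
        from1 = np.flatnonzero(states[:-1] == 0)
        phat = np.mean(states[from1 + 1] == 1)
        se = math.sqrt(0.25 * 0.75 / from1.size)
        assert abs(phat - 0.25) < 5 * se

    def test_initial_state_from_stationary(self):
        # asymmetric kinetics: pi = (k21, k12)/(k12+k21) = (0.8, 0.2)
        p = st.two_state_params(0.05, 0.2, 5.0)
        firsts = []
        cfg = st.SimulationConfig(
            params=p, length_mode="fixed", T=2, n_traces=400, seed=5
        )
        for i in range(cfg.n_traces):
            _, s = st.simulate_trace(cfg, i)
            firsts.append(s[0])
        frac1 = np.mean(np.array(firsts) == 0)
        assert abs(frac1 - 0.8) < 5 * math.sqrt(0.8 * 0.2 / 400)

    def test_gaussian_family_simulation(self):
        from smtrace.hmm import EmissionParams, HmmParams

        A = np.array([[0.9, 0.1], [0.1, 0.9]])
        em = EmissionParams(
            ("gaussian",), mu=np.array([[0.0], [5.0]]), sigma=np.array([[1.0], [1.0]])
        )
        p = HmmParams(A, em, st.stationary_distribution(A))
        cfg = st.SimulationConfig(params=p, length_mode="fixed", T=5000, seed=3)
        tr, states = st.simulate_trace(cfg, 0)
        assert tr.channels[states == 1, 0].mean() == pytest.approx(5.0, abs=0.15)
        assert tr.channels[states == 0, 0].std() == pytest.approx(1.0, abs=0.1)


class TestStationaryDistribution:
    def test_two_state_closed_form(self):
        A = np.array([[0.9, 0.1], [0.3, 0.7]])
        pi = st.stationary_distribution(A)
        np.testing.assert_allclose(pi, [0.75, 0.25], atol=1e-12)

    @given(
        rows=hst.lists(
            hst.lists(
                hst.floats(min_value=0.05, max_value=1.0), min_size=3, max_size=3
            ),
            min_size=3,
            max_size=3,
        )
    )
    def test_fixed_point_property(self, rows):
        A = np.array(rows)
        A = A / A.sum(axis=1, keepdims=True)
        pi = st.stationary_distribution(A)
        np.testing.assert_allclose(pi @ A, pi, atol=1e-10)
        assert pi.sum() == pytest.approx(1.0)

    def test_reducible_chain_rejected(self):
        with pytest.raises(ValueError):
            st.stationary_distribution(np.eye(3))
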