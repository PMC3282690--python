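"""Uncertainty-weighted EM clustering of per-trace estimates."""

import math

import numpy as np
import pytest
from scipy.stats import norm

import smtrace as st
from smtrace.clustering import ClusterInput
from smtrace.confidence import CiResult
from smtrace.hmm import EmissionParams, FitResult, HmmParams
from smtrace.models import builtin_models


def _fake_fit(trace_id, k12, k21, rel_halfwidth=0.2, level=0.90):
    """A synthetic converged fit with symmetric CIs around (k12, k21)."""
    A = np.array([[1 - k12, k12], [k21, 1 - k21]])
    params = HmmParams(
        A,
        EmissionParams(("poisson",), np.array([[100.0], [150.0]])),
        st.stationary_distribution(A),
    )
    fit = FitResult(
        trace_id=trace_id,
        spec=builtin_models()["2-state"],
        params=params,
        loglik=-1000.0,
        n_iter=10,
        converged=True,
        posteriors=np.empty((0, 2)),
    )
    for name, v in (("k12", k12), ("k21", k21)):
        h = rel_halfwidth * v
        fit.cis[name] = CiResult(name, level, v - h, v + h, "conditional", v)
    return fit


def _synthetic_input(n_a=20, n_b=20, sep=2.0, spread=0.05, seed=0):
    """Fits drawn from two log-normal populations separated by factor `sep`."""
    rng = np.random.default_rng(seed)
    fits, labels = [], []
    for i in range(n_a + n_b):
        pop = 0 if i < n_a else 1
        k21 = 0.1 * (sep if pop else 1.0) * 10 ** rng.normal(0, spread)
        k12 = 0.1 * 10 ** rng.normal(0, spread)
        fits.append(_fake_fit(f"tr{i}", k12, k21))
        labels.append(pop)
    inp = st.build_cluster_input(fits, ["k12", "k21"])
    return inp, np.array(labels)


class TestBuildInput:
    def test_log_transform_and_sd_by_hand(self):
        fit = _fake_fit("x", 0.1, 0.2, rel_halfwidth=0.3, level=0.90)
        inp = st.build_cluster_input([fit], ["k12"])
        assert inp.theta[0, 0] == pytest.approx(math.log10(0.1))
        z = norm.ppf(0.95)
        half = 0.5 * (math.log10(0.13) - math.log10(0.07))
        assert inp.var[0, 0] == pytest.approx((half / z) ** 2, rel=1e-9)

    def test_linear_transform(self):
        fit = _fake_fit("x", 0.1, 0.2, rel_halfwidth=0.3)
        inp = st.build_cluster_input([fit], ["k12"], transform="linear")
        assert inp.theta[0, 0] == pytest.approx(0.1)
        assert inp.var[0, 0] == pytest.approx((0.03 / norm.ppf(0.95)) ** 2)

    def test_zero_clipped_lower_bound_floored(self):
        fit = _fake_fit("x", 0.1, 0.2)
        fit.cis["k12"] = CiResult("k12", 0.90, 0.0, 0.15, "conditional", 0.1, clipped_lo=True)
        inp = st.build_cluster_input([fit], ["k12"])
        assert np.isfinite(inp.theta).all() and np.isfinite(inp.var).all()

    def test_missing_ci_is_named(self):
        fit = _fake_fit("x", 0.1, 0.2)
        with pytest.raises(KeyError, match="mu"):
            st.build_cluster_input([fit], ["mu[1][1]"])


class TestEm:
    def test_single_cluster_center_is_precision_weighted_mean(self):
        theta = np.array([[0.0], [1.0], [2.0]])
        var = np.array([[1.0], [1.0], [0.01]])
        inp = ClusterInput(theta, var, ["a", "b", "c"], ["k12"], "linear", 0.9)
        fit = st.fit_clusters(inp, 1)
        expected = np.sum(theta[:, 0] / var[:, 0]) / np.sum(1.0 / var[:, 0])
        assert fit.centers[0, 0] == pytest.approx(expected, rel=1e-6)

    def test_loglik_path_monotone(self):
        inp, _ = _synthetic_input()
        fit = st.fit_clusters(inp, 2)
        path = np.array(fit.loglik_path)
        assert np.all(np.diff(path) >= -1e-8 * np.maximum(1.0, np.abs(path[:-1])))

    def test_separated_populations_recovered(self):
        inp, labels = _synthetic_input(sep=4.0, spread=0.03)
        fit = st.fit_clusters(inp, 2)
        assert st.partition_accuracy(fit, labels) > 0.95
        # centers straddle the two generating k21 values in log10 space
        k21_col = inp.param_names.index("k21")
        lo, hi = sorted(fit.centers[:, k21_col])
        assert lo == pytest.approx(math.log10(0.1), abs=0.15)
        assert hi == pytest.approx(math.log10(0.4), abs=0.15)

    def test_weights_sum_to_one_and_resp_normalized(self):
        inp, _ = _synthetic_input()
        fit = st.fit_clusters(inp, 3)
        assert fit.weights.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(fit.responsibilities.sum(axis=1), 1.0, atol=1e-9)

    def test_deterministic_given_seed(self):
        inp, _ = _synthetic_input()
        a = st.fit_clusters(inp, 2, seed=5)
        b = st.fit_clusters(inp, 2, seed=5)
        np.testing.assert_array_equal(a.centers, b.centers)

    def test_too_many_clusters_rejected(self):
        inp, _ = _synthetic_input(n_a=2, n_b=1)
        with pytest.raises(ValueError):
            st.fit_clusters(inp, 10)


class TestSelection:
    def test_bic_table_picks_two_for_separated_data(self):
        inp, _ = _synthetic_input(sep=4.0, spread=0.03)
        table, fits = st.select_cluster_number(inp, cmax=3)
        assert list(table["C"]) == [1, 2, 3]
        best = int(table.loc[table["best"], "C"].iloc[0])
        assert best == 2
        assert set(fits) == {1, 2, 3}

    def test_k_column_formula(self):
        inp, _ = _synthetic_input(n_a=5, n_b=5)
        table, _ = st.select_cluster_number(inp, cmax=2)
        # d = 2 parameters per center, plus C - 1 free weights
        assert list(table["k"]) == [2, 5]

    def test_homogeneous_population_prefers_one(self):
        inp, _ = _synthetic_input(sep=1.0, spread=0.02, seed=3)
        table, _ = st.select_cluster_number(inp, cmax=2)
        assert int(table.loc[table["best"], "C"].iloc[0]) == 1


class TestPartitionAccuracy:
    def test_label_permutation_invariance(self):
        inp, labels = _synthetic_input(sep=4.0)
        fit = st.fit_clusters(inp, 2)
        assert st.partition_accuracy(fit, labels) == st.partition_accuracy(
            fit, 1 - labels
        )

    def test_perfect_and_worst_case(self):
        inp, labels = _synthetic_input(sep=8.0, spread=0.02)
        fit = st.fit_clusters(inp, 2)
        acc = st.partition_accuracy(fit, labels)
        assert 0.5 <= acc <= 1.0
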