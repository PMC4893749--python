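"""SparCC: log-ratio variances, the sparsity solve, recovery, networks."""

import numpy as np
import pandas as pd
import pytest

from conftest import null_lognormal_counts, planted_block_counts
from cagflow.sparcc import (
    SparccResult,
    basis_correlations_once,
    build_network,
    log_ratio_variances,
    network_edge_list,
    sparcc_estimate,
    sparcc_null_pvalues,
)


class TestLogRatioVariances:
    def test_matches_direct_variance_computation(self):
        fractions = np.array(
            [
                [0.5, 0.2, 0.2, 0.1],
                [0.4, 0.3, 0.2, 0.1],
                [0.3, 0.3, 0.3, 0.1],
                [0.6, 0.1, 0.2, 0.1],
            ]
        )
        T = log_ratio_variances(fractions)
        logf = np.log(fractions)
        for i in range(4):
            for j in range(4):
                direct = np.var(logf[:, i] - logf[:, j], ddof=1)
                assert T[i, j] == pytest.approx(direct, abs=1e-12)

    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(0)
        f = rng.dirichlet(np.ones(6), size=10)
        T = log_ratio_variances(f)
        np.testing.assert_allclose(T, T.T)
        np.testing.assert_allclose(np.diag(T), 0.0)

    def test_proportional_otus_have_zero_variance(self):
        rng = np.random.default_rng(1)
        base = rng.dirichlet(np.ones(4), size=8)
        f = np.column_stack([base[:, 0], base[:, 0], base[:, 1], base[:, 2]])
        f /= f.sum(axis=1, keepdims=True)
        T = log_ratio_variances(f)
        assert T[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_zero_fraction_rejected(self):
        f = np.array([[0.5, 0.5, 0.0, 0.0]] * 5)
        with pytest.raises(ValueError, match="positive"):
            log_ratio_variances(f)


class TestBasisCorrelations:
    def test_diagonal_exactly_one(self):
        rng = np.random.default_rng(2)
        f = rng.dirichlet(np.ones(10), size=50)
        rho, omega = basis_correlations_once(log_ratio_variances(f))
        np.testing.assert_allclose(np.diag(rho), 1.0)
        assert np.abs(rho).max() <= 1.0

    def test_uncorrelated_basis_gives_small_rho(self):
        rng = np.random.default_rng(3)
        lat = rng.normal(size=(200, 50)) + rng.normal(0, 1, 50)
        f = np.exp(lat)
        f /= f.sum(axis=1, keepdims=True)
        rho, _ = basis_correlations_once(log_ratio_variances(f))
        off = rho.copy()
        np.fill_diagonal(off, 0.0)
        assert np.abs(off).max() < 0.3

    def test_planted_pair_close_to_latent_pearson(self):
        rng = np.random.default_rng(4)
        n, p = 300, 30
        z = rng.normal(size=n)
        lat = rng.normal(size=(n, p))
        lat[:, 0] = np.sqrt(0.8) * z + np.sqrt(0.2) * lat[:, 0]
        lat[:, 1] = np.sqrt(0.8) * z + np.sqrt(0.2) * lat[:, 1]
        lat += rng.normal(0, 1, p)
        truth = np.corrcoef(lat[:, 0], lat[:, 1])[0, 1]
        f = np.exp(lat)
        f /= f.sum(axis=1, keepdims=True)
        rho, _ = basis_correlations_once(log_ratio_variances(f))
        assert rho[0, 1] == pytest.approx(truth, abs=0.15)


class TestSparccEstimate:
    def test_deterministic_given_seed(self):
        counts = planted_block_counts(0, n_samples=40, n_otus=20, n_blocks=2)
        r1 = sparcc_estimate(counts, n_est_iter=5, seed=3)
        r2 = sparcc_estimate(counts, n_est_iter=5, seed=3)
        pd.testing.assert_frame_equal(r1.rho, r2.rho)
        pd.testing.assert_series_equal(r1.omega, r2.omega)

    def test_block_structure_recovered(self):
        counts = planted_block_counts(5)
        res = sparcc_estimate(counts, seed=1)
        R = res.rho.to_numpy()
        within = []
        for b in range(5):
            blk = R[b * 10 : (b + 1) * 10, b * 10 : (b + 1) * 10]
            within.extend(blk[np.triu_indices(10, 1)])
        between = R[:10, 10:].ravel()
        assert np.mean(within) > np.mean(between) + 0.3

    def test_compositional_invariance_to_per_sample_scaling(self):
        # the estimator sees counts only through per-sample fractions, so
        # multiplying any sample's counts by a positive constant changes
        # nothing (power-of-two scale keeps the float division bitwise equal)
        counts = planted_block_counts(6, n_samples=30, n_otus=10, n_blocks=1)
        c1 = counts.to_numpy().astype(float) + 1.0  # no zeros for the log
        c2 = c1.copy()
        c2[0] *= 4.0
        c2[17] *= 1024.0
        f1 = c1 / c1.sum(axis=1, keepdims=True)
        f2 = c2 / c2.sum(axis=1, keepdims=True)
        rho1, _ = basis_correlations_once(log_ratio_variances(f1))
        rho2, _ = basis_correlations_once(log_ratio_variances(f2))
        np.testing.assert_array_equal(rho1, rho2)

    def test_too_few_otus_rejected(self):
        counts = pd.DataFrame(np.ones((10, 3), dtype=int))
        with pytest.raises(ValueError, match="4"):
            sparcc_estimate(counts, seed=0)


@pytest.fixture(scope="module")
def null_setup():
    counts = null_lognormal_counts(7, n_samples=60, n_otus=15)
    obs = sparcc_estimate(counts, n_est_iter=5, seed=0)
    p = sparcc_null_pvalues(counts, obs.rho, n_null=60, seed=1, n_est_iter=3)
    return obs, p


class TestNullPvalues:
    def test_floor_symmetry_and_range(self, null_setup):
        _, p = null_setup
        arr = p.to_numpy()
        np.testing.assert_allclose(arr, arr.T)
        off = arr[np.triu_indices_from(arr, 1)]
        assert off.min() >= 1 / 61
        assert off.max() <= 1.0

    def test_null_rejection_rate_calibrated(self, null_setup):
        _, p = null_setup
        off = p.to_numpy()[np.triu_indices(15, 1)]
        assert 0.0 <= (off < 0.05).mean() <= 0.10

    def test_n_null_must_be_positive(self, null_setup):
        obs, _ = null_setup
        counts = null_lognormal_counts(7, n_samples=60, n_otus=15)
        with pytest.raises(ValueError):
            sparcc_null_pvalues(counts, obs.rho, n_null=0, seed=0)


class TestNetwork:
    @pytest.fixture()
    def result(self):
        ids = ["A", "B", "C", "D"]
        rho = pd.DataFrame(
            [
                [1.0, 0.8, -0.6, 0.1],
                [0.8, 1.0, 0.2, -0.2],
                [-0.6, 0.2, 1.0, 0.4],
                [0.1, -0.2, 0.4, 1.0],
            ],
            index=ids,
            columns=ids,
        )
        omega = pd.Series(np.ones(4), index=ids)
        return SparccResult(rho=rho, omega=omega)

    def test_edges_match_brute_force_count(self, result):
        g = build_network(result, edge_threshold=0.5)
        arr = result.rho.to_numpy()
        expected = int(
            (np.abs(arr[np.triu_indices(4, 1)]) > 0.5).sum()
        )
        assert g.number_of_edges() == expected == 2
        assert g["A"]["B"]["sign"] == "positive"
        assert g["A"]["C"]["sign"] == "negative"

    def test_threshold_zero_gives_complete_graph(self, result):
        g = build_network(result, edge_threshold=0.0)
        assert g.number_of_edges() == 6
        assert not any(a == b for a, b in g.edges)

    def test_high_threshold_gives_no_edges(self, result):
        g = build_network(result, edge_threshold=0.9)
        assert g.number_of_edges() == 0
        assert network_edge_list(g).empty
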