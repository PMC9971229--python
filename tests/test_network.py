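"""Nonparanormal transform, graphical lasso path and EBIC selection."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import ndtri

from nmssnet import (
    GeneratorConfig,
    ebic,
    estimate_network,
    glasso_path,
    make_lambda_grid,
    npn_transform,
    simulate,
    small_config,
)
from nmssnet.network import EstimatorSettings, precision_to_pcor


class TestNpnTransform:
    def test_rank_preserving(self, rng):
        # monotone map: ordering preserved (Winsorization may tie extremes)
        x = rng.normal(size=(80, 1))
        z = npn_transform(x)
        order = np.argsort(x[:, 0])
        assert (np.diff(z[order, 0]) >= 0).all()
        assert stats.spearmanr(x[:, 0], z[:, 0]).statistic > 0.999

    def test_ties_get_identical_values(self, rng):
        x = rng.integers(0, 4, size=(60, 1)).astype(float)
        z = npn_transform(x)
        for v in np.unique(x):
            assert np.ptp(z[x[:, 0] == v, 0]) == 0

    def test_normal_input_approximately_identity(self, rng):
        x = rng.standard_normal((5000, 1))
        z = npn_transform(x)
        assert np.mean(np.abs(np.sort(z[:, 0]) - np.sort(x[:, 0]))) < 0.05

    def test_winsorized_extremes_n16(self):
        """For 16 distinct values the ECDF extremes hit the Winsorization
        bounds delta and 1 - delta exactly."""
        n = 16
        x = np.arange(n, dtype=float).reshape(-1, 1)
        z = npn_transform(x)
        delta = 1.0 / (4.0 * n**0.25 * np.sqrt(np.pi * np.log(n)))
        raw = ndtri(np.clip(np.arange(1, n + 1) / n, delta, 1.0 - delta))
        expected = raw / raw.std(ddof=1)
        assert z[:, 0] == pytest.approx(expected)
        assert ndtri(1.0 - delta) == pytest.approx(raw[-1])

    def test_constant_column_rejected(self):
        x = np.column_stack([np.ones(20), np.arange(20.0)])
        with pytest.raises(ValueError, match="0"):
            npn_transform(x)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="n >= 10"):
            npn_transform(np.arange(5.0).reshape(-1, 1))

    def test_unit_variance(self, rng):
        z = npn_transform(rng.exponential(size=(300, 3)))
        assert z.std(axis=0, ddof=1) == pytest.approx(np.ones(3))


class TestGlassoPath:
    S3 = np.array([[1.0, 0.5, 0.3], [0.5, 1.0, 0.0], [0.3, 0.0, 1.0]])

    def test_full_shrinkage_gives_empty_network(self):
        precisions, _ = glasso_path(self.S3, [0.6])
        off = precisions[0] - np.diag(np.diag(precisions[0]))
        assert np.abs(off).max() == 0.0

    def test_lambda_zero_gives_inverse(self):
        precisions, _ = glasso_path(self.S3, [0.0])
        assert np.abs(precisions[0] - np.linalg.inv(self.S3)).max() < 1e-4

    def test_edge_count_monotone_in_lambda(self, rng):
        X = rng.standard_normal((200, 6)) @ rng.standard_normal((6, 6))
        S = np.corrcoef(X, rowvar=False)
        grid = make_lambda_grid(S, 30)
        precisions, kept = glasso_path(S, grid)
        counts = [
            int((np.abs(t[np.triu_indices(6, 1)]) > 1e-10).sum()) for t in precisions
        ]
        # lambda descends, edges accumulate; the lasso path may transiently
        # drop a single edge, so allow one-edge dips but no real reversals
        assert (np.diff(counts) >= -1).all()
        assert counts[-1] >= counts[0]
        assert counts[0] <= 1 and counts[-1] >= 3

    def test_matches_bruteforce_p3(self):
        from scipy.optimize import minimize

        lam = 0.1
        S = self.S3

        def negobj(x):
            theta = np.array(
                [[x[0], x[3], x[4]], [x[3], x[1], x[5]], [x[4], x[5], x[2]]]
            )
            sign, logdet = np.linalg.slogdet(theta)
            if sign <= 0:
                return 1e10
            return -(logdet - np.trace(S @ theta) - lam * 2 * np.abs(x[3:]).sum())

        res = minimize(
            negobj,
            np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0]),
            method="Nelder-Mead",
            options=dict(xatol=1e-10, fatol=1e-12, maxiter=50000, maxfev=50000),
        )
        brute = np.array(
            [
                [res.x[0], res.x[3], res.x[4]],
                [res.x[3], res.x[1], res.x[5]],
                [res.x[4], res.x[5], res.x[2]],
            ]
        )
        precisions, _ = glasso_path(S, [lam])
        assert np.abs(precisions[0] - brute).max() < 1e-4


class TestEbic:
    def test_no_edges_reduces_to_loglik_term(self):
        assert ebic(-12.5, 0, 100, 30) == pytest.approx(25.0)

    def test_worked_arithmetic(self):
        val = ebic(-100.0, 10, 499, 30, 0.5)
        expected = 200.0 + 10 * np.log(499) + 20 * np.log(30)
        assert val == pytest.approx(expected)
        assert val == pytest.approx(330.15, abs=0.01)

    def test_gamma_zero_is_bic(self):
        diff = ebic(-50.0, 7, 200, 30, 0.5) - ebic(-50.0, 7, 200, 30, 0.0)
        assert diff == pytest.approx(2 * 7 * np.log(30))


class TestEstimateNetwork:
    def test_symmetry_zero_diagonal_and_edge_bound(self, small_pair, fast_settings):
        net, path = estimate_network(small_pair[0], fast_settings)
        assert np.allclose(net.weights, net.weights.T)
        assert np.abs(np.diag(net.weights)).max() == 0
        assert np.abs(net.weights).max() < 1
        assert net.n_edges <= net.n_possible_edges == 28
        assert path.selected_index == int(np.argmin(path.ebic_values))

    def test_thirty_node_input_has_435_possible_edges(self, nmss_pair, fast_settings):
        net, _ = estimate_network(nmss_pair[0], fast_settings)
        assert net.n_possible_edges == 435

    def test_identity_precision_few_spurious_edges(self):
        cfg = small_config(21, n_subjects=2000)
        cfg = GeneratorConfig(
            n_subjects=2000,
            precision_matrix=np.eye(8),
            severity_thresholds=cfg.severity_thresholds,
            frequency_thresholds=cfg.frequency_thresholds,
            followup_drift=cfg.followup_drift,
            retest_correlation=cfg.retest_correlation,
            seed=21,
            scale=cfg.scale,
        )
        baseline, _ = simulate(cfg)
        net, _ = estimate_network(baseline, EstimatorSettings())
        assert net.n_edges <= 1  # gamma=0.5 is edge-conservative under the null

    def test_chain_precision_recovered_with_signs(self):
        # latent chain: theta_{i,i+1} = -0.4 (partial correlation +0.4)
        p = 6
        theta = np.eye(p)
        for i in range(p - 1):
            theta[i, i + 1] = theta[i + 1, i] = -0.4
        cfg = small_config(22, n_subjects=2000, n_items=p, n_cross_edges=0)
        cfg = GeneratorConfig(
            n_subjects=2000,
            precision_matrix=theta,
            severity_thresholds=cfg.severity_thresholds,
            frequency_thresholds=cfg.frequency_thresholds,
            followup_drift=cfg.followup_drift,
            retest_correlation=cfg.retest_correlation,
            seed=22,
            scale=cfg.scale,
        )
        baseline, _ = simulate(cfg)
        net, _ = estimate_network(baseline, EstimatorSettings())
        for i in range(p - 1):
            assert net.weights[i, i + 1] > 0

    def test_constant_item_rejected(self, rng):
        X = rng.integers(0, 4, size=(50, 4)).astype(float)
        X[:, 2] = 3.0
        with pytest.raises(ValueError, match="constant"):
            estimate_network(X, EstimatorSettings(n_lambda=5))

    def test_precision_to_pcor_standardization(self):
        theta = np.array([[2.0, -0.5], [-0.5, 1.0]])
        pcor = precision_to_pcor(theta)
        assert pcor[0, 1] == pytest.approx(0.5 / np.sqrt(2.0))
        assert pcor[0, 0] == 0.0
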