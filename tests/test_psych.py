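"""Acceptability, reliability and paired Wilcoxon comparisons."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nmssnet import (
    ItemMatrix,
    acceptability,
    corrected_item_total,
    cronbach_alpha,
    effect_size_r,
    item_homogeneity,
    paired_wilcoxon,
    simulate,
    small_config,
    table_one,
)


def _matrix(scores, **kw):
    scores = np.asarray(scores)
    ids = [f"P{i}" for i in range(scores.shape[0])]
    return ItemMatrix(subject_ids=ids, timepoint="t", scores=scores, **kw)


class TestAcceptability:
    def test_all_zero_item_is_pure_floor(self):
        rep = acceptability(_matrix(np.zeros((5, 30), dtype=int)))
        assert (rep.floor == 1.0).all() and (rep.ceiling == 0.0).all()
        assert not rep.floor_ok.any()

    def test_half_floor_half_ceiling(self):
        s = np.zeros((4, 30), dtype=int)
        s[2:, 0] = 12
        rep = acceptability(_matrix(s))
        assert rep.floor.iloc[0] == 0.5 and rep.ceiling.iloc[0] == 0.5

    def test_computable_fraction(self):
        s = np.zeros((4, 30), dtype=int)
        rep = acceptability(_matrix(s))
        assert rep.computable_fraction == 1.0 and rep.computable_ok
        miss = np.zeros_like(s, dtype=bool)
        miss[0, 0] = True
        rep = acceptability(_matrix(s, missing=miss))
        assert rep.computable_fraction == 0.75

    def test_empty_matrix_rejected(self):
        with pytest.raises(Exception):
            acceptability(_matrix(np.zeros((0, 30), dtype=int)))


class TestCronbachAlpha:
    def test_duplicated_item_gives_one(self, rng):
        x = rng.normal(size=100)
        assert cronbach_alpha(np.column_stack([x, x])) == pytest.approx(1.0)

    def test_parallel_items_give_one(self):
        X = np.array([[1, 1, 1], [2, 2, 2], [3, 3, 3], [4, 4, 4]], dtype=float)
        assert cronbach_alpha(X) == pytest.approx(1.0)

    def test_independent_items_give_near_zero(self, rng):
        X = rng.uniform(size=(10000, 2))
        assert cronbach_alpha(X) == pytest.approx(0.0, abs=0.05)

    def test_zero_variance_signalled(self):
        with pytest.raises(ValueError, match="variance"):
            cronbach_alpha(np.ones((5, 3)))

    @given(st.floats(-50, 50))
    @settings(max_examples=20, derandomize=True, deadline=None)
    def test_invariant_to_constant_shift(self, c):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(50, 4))
        shifted = X.copy()
        shifted[:, 2] += c
        assert cronbach_alpha(shifted) == pytest.approx(cronbach_alpha(X))


class TestHomogeneityAndItemTotal:
    def test_perfectly_correlated_pair(self, rng):
        x = rng.normal(size=200)
        assert item_homogeneity(np.column_stack([x, 2 * x + 1])) == pytest.approx(1.0)

    def test_mean_of_pairwise_correlations(self, rng):
        # construct three columns, then verify against the direct mean
        X = rng.normal(size=(500, 3)) @ np.linalg.cholesky(
            np.array([[1, 0.2, 0.4], [0.2, 1, 0.6], [0.4, 0.6, 1]])
        ).T
        R = np.corrcoef(X, rowvar=False)
        expected = (R[0, 1] + R[0, 2] + R[1, 2]) / 3
        assert item_homogeneity(X) == pytest.approx(expected)

    def test_independent_item_total_near_zero(self, rng):
        X = rng.normal(size=(20000, 5))
        assert corrected_item_total(X, 0) == pytest.approx(0.0, abs=0.03)

    def test_constant_column_warns_nan(self):
        X = np.column_stack([np.ones(20), np.arange(20.0), np.arange(20.0) ** 2])
        with pytest.warns(UserWarning):
            assert np.isnan(corrected_item_total(X, 0))


class TestPairedWilcoxon:
    def test_identical_vectors_degenerate(self):
        x = np.arange(20.0)
        res = paired_wilcoxon(x, x)
        assert res.z == 0.0 and res.p == 1.0 and res.r == 0.0 and res.degenerate

    def test_effect_size_reproduces_reported_rows(self):
        # r = |Z|/sqrt(N) for the cohort of 499 completers
        assert round(effect_size_r(-6.040, 499), 3) == 0.270
        assert round(effect_size_r(-5.059, 499), 3) == 0.226
        assert round(effect_size_r(-3.457, 499), 3) == 0.155

    def test_effect_size_sign_invariant(self):
        assert effect_size_r(-2.5, 100) == effect_size_r(2.5, 100)

    def test_matches_scipy_zstatistic(self, rng):
        from scipy import stats

        x = rng.integers(0, 13, size=60).astype(float)
        y = x + rng.integers(-3, 4, size=60)
        res = paired_wilcoxon(x, y)
        ref = stats.wilcoxon(y, x, zero_method="wilcox", correction=False, method="approx")
        assert res.z == pytest.approx(float(ref.zstatistic))
        assert res.p == pytest.approx(float(ref.pvalue))
        assert res.r == pytest.approx(abs(res.z) / np.sqrt(60))

    def test_null_pvalues_uniform(self):
        """Under no drift, Wilcoxon p-values over replicates are uniform."""
        from scipy import stats

        pvals = []
        for rep in range(500):
            cfg = small_config(3000 + rep, n_subjects=200, drift=0.0,
                               retest_correlation=0.6)
            baseline, followup = simulate(cfg)
            res = paired_wilcoxon(baseline.scores[:, 0], followup.scores[:, 0])
            pvals.append(res.p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_table_one_shape_and_direction(nmss_pair):
    baseline, followup = nmss_pair
    t1 = table_one(baseline, followup)
    assert len(t1) == 1 + 9 + 30
    total = t1[t1.variable == "total_score"].iloc[0]
    # generator drift worsens symptoms: median total should not decrease
    assert total.median_followup >= total.median_baseline
    assert 0 <= total.p <= 1 and total.r == pytest.approx(
        abs(total.z) / np.sqrt(total.n)
    )
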