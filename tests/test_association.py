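"""Statistical core: rank correlation, ensemble p, CV regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurocost.association import (CVConfig, cumulative_variance_curve,
                                   cv_predict, nonparametric_p,
                                   per_layer_associations, spearman_assoc)


class TestSpearman:
    def test_perfect_antimonotone(self):
        assert spearman_assoc([1, 2, 3], [3, 2, 1]).rho == pytest.approx(-1.0)

    def test_hand_worked_rank_case(self):
        # ranks differ by d = (0, 1, -1, 0): rho = 1 - 6*2/(4*15) = 0.8
        assert spearman_assoc([1, 2, 3, 4],
                              [1, 3, 2, 4]).rho == pytest.approx(0.8)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_assoc([1, 1, 1], [1, 2, 3])

    def test_short_input_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            spearman_assoc([1, 2], [2, 1])

    def test_ci_brackets_rho(self, rng):
        x = rng.standard_normal(50)
        y = x + rng.standard_normal(50)
        r = spearman_assoc(x, y, ci_level=0.95)
        assert r.ci_low <= r.rho <= r.ci_high


class TestNonparametricP:
    def test_strict_count_arithmetic(self, rng):
        """18 of 1,000 nulls strictly below the observed value -> 0.018."""
        nulls = np.concatenate([np.full(18, -0.5), np.full(982, 0.2)])
        assert nonparametric_p(-0.16, nulls, tail="lower") == 0.018

    def test_edge_counts(self):
        assert nonparametric_p(0.0, np.ones(10), tail="lower") == 0.0
        assert nonparametric_p(2.0, np.ones(10), tail="lower") == 1.0

    def test_add_one_variant(self):
        assert nonparametric_p(2.0, np.ones(9), tail="lower",
                               add_one=True) == pytest.approx(1.0)
        assert nonparametric_p(0.0, np.ones(9), tail="lower",
                               add_one=True) == pytest.approx(0.1)

    def test_empty_nulls_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            nonparametric_p(0.0, [])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1), st.sampled_from(["lower", "upper"]))
    def test_matches_counting_loop(self, seed, tail):
        rng = np.random.default_rng(seed)
        nulls = rng.standard_normal(rng.integers(1, 40))
        obs = rng.standard_normal()
        if tail == "lower":
            want = sum(1 for v in nulls if v < obs) / nulls.size
        else:
            want = sum(1 for v in nulls if v > obs) / nulls.size
        assert nonparametric_p(obs, nulls, tail=tail) == want


class TestCVPredict:
    def test_noiseless_linear_recovery(self, rng):
        X = rng.random((80, 4))
        beta = np.array([2.0, -1.0, 0.5, 3.0])
        y = X @ beta + 1.5
        res = cv_predict(X, y, CVConfig(k=10, seed=0))
        assert res.accuracy_rho >= 0.99
        rel = np.abs(res.fold_coefficients[:, 1:] - beta) / np.abs(beta)
        assert rel.max() <= 1e-6

    def test_loo_matches_refit_oracle(self, rng):
        """k = n: pooled predictions equal an explicit leave-one-out refit."""
        n = 20
        X = rng.random((n, 3))
        y = X @ [1.0, -2.0, 0.5] + rng.normal(0, 0.3, n)
        res = cv_predict(X, y, CVConfig(k=n, shuffle=False, seed=0))
        want = np.empty(n)
        for i in range(n):
            keep = np.arange(n) != i
            A = np.column_stack([np.ones(n - 1), X[keep]])
            coef, *_ = np.linalg.lstsq(A, y[keep], rcond=None)
            want[i] = np.concatenate([[1.0], X[i]]) @ coef
        np.testing.assert_allclose(res.predictions, want, atol=1e-8)

    def test_fold_partition_properties(self, rng):
        n = 53
        kf = CVConfig(k=10, seed=0).splitter(n)
        seen = np.zeros(n, dtype=int)
        sizes = []
        for _, test in kf.split(np.zeros((n, 1))):
            seen[test] += 1
            sizes.append(len(test))
        assert (seen == 1).all()
        assert max(sizes) - min(sizes) <= 1

    def test_accuracy_invariant_to_column_scaling(self, rng):
        X = rng.random((60, 3))
        y = X @ [1.0, 1.0, -2.0] + rng.normal(0, 0.5, 60)
        a = cv_predict(X, y, CVConfig(k=5, seed=1))
        b = cv_predict(X * np.array([10.0, 0.01, 3.0]), y,
                       CVConfig(k=5, seed=1))
        assert a.accuracy_rho == pytest.approx(b.accuracy_rho, abs=1e-10)

    def test_permuted_outcome_within_null_band(self, rng):
        X = rng.random((100, 3))
        y = rng.standard_normal(100)
        obs = abs(cv_predict(X, y, CVConfig(k=5, seed=0)).accuracy_rho)
        null = []
        for s in range(50):
            perm = np.random.default_rng(s).permutation(100)
            null.append(abs(cv_predict(X, y[perm],
                                       CVConfig(k=5, seed=0)).accuracy_rho))
        assert obs <= np.quantile(null, 0.99) + 0.05

    def test_rank_deficient_design_warns(self, rng):
        X = np.repeat(rng.random((30, 1)), 2, axis=1)  # duplicated column
        y = rng.standard_normal(30)
        with pytest.warns(UserWarning, match="rank-deficient"):
            cv_predict(X, y, CVConfig(k=3, seed=0))


class TestCumulativeCurve:
    def test_single_informative_block(self, rng):
        n = 60
        X = rng.standard_normal((n, 5))
        y = 2.0 * X[:, 2]  # only depth 3 carries signal
        with np.errstate(all="ignore"):
            curve = cumulative_variance_curve(X, y, CVConfig(k=5, seed=0))
        assert curve[1] < 0.3
        assert curve[2] > 0.9
        assert curve[4] >= curve[2] - 1e-10

    def test_duplicated_predictor_adds_nothing(self, rng):
        X = rng.random((40, 3))
        y = X @ [1.0, -1.0, 2.0] + rng.normal(0, 0.2, 40)
        Xdup = np.column_stack([X, X[:, 0]])
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # collinearity warning expected
            curve = cumulative_variance_curve(Xdup, y, CVConfig(k=4, seed=0))
        assert curve[3] - curve[2] <= 1e-10

    def test_monotone_and_final_value(self, rng):
        X = rng.random((50, 4))
        y = X @ [1.0, 0.5, -1.0, 0.2] + rng.normal(0, 0.5, 50)
        res = cv_predict(X, y, CVConfig(k=5, seed=2))
        assert np.all(np.diff(res.cumulative_r2) >= -1e-10)
        assert res.cumulative_r2[-1] == pytest.approx(res.cv_train_r2,
                                                      abs=1e-10)


class TestPerLayer:
    def test_identity_ranks_give_rho_one(self, rng):
        y = rng.standard_normal(30)
        from scipy.stats import rankdata
        X = np.column_stack([rankdata(y), rng.standard_normal(30)])
        df = per_layer_associations(X, y)
        assert df.loc[0, "rho"] == pytest.approx(1.0)

    def test_constant_column_flagged_not_raised(self, rng):
        X = np.column_stack([np.ones(20), rng.standard_normal(20)])
        df = per_layer_associations(X, rng.standard_normal(20))
        assert bool(df.loc[0, "undefined"])
        assert not bool(df.loc[1, "undefined"])
        assert np.isfinite(df.loc[1, "p_adj"])

    def test_planted_negative_block_detected(self, rng):
        hits = 0
        for s in range(20):
            r = np.random.default_rng(s)
            y = r.standard_normal(120)
            X = r.standard_normal((120, 4))
            X[:, 1] = -y + r.normal(0, 0.5, 120)  # strong negative link
            df = per_layer_associations(X, y)
            if df.loc[1, "rho"] < 0 and df.loc[1, "p_adj"] < 0.05:
                hits += 1
        assert hits >= 18  # >= 90% of seeds

    def test_type_one_error_rate_calibrated(self):
        ps = []
        for s in range(40):
            r = np.random.default_rng(1000 + s)
            df = per_layer_associations(r.standard_normal((50, 5)),
                                        r.standard_normal(50))
            ps.extend(df["p"].tolist())
        rate = np.mean(np.asarray(ps) < 0.05)
        assert 0.01 < rate < 0.10  # ~5% of 200 unadjusted tests
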