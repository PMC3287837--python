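import numpy as np
import pytest
from scipy import stats

from rareqtl.assoc import LassoSelection, _fit_path, lasso_select, nested_f_test
from rareqtl.assoc import test_cmc as cmc_test
from rareqtl.assoc import test_collapse_only as collapse_only_test
from rareqtl.assoc import test_lasso as lasso_test
from rareqtl.collapse import RareScore


def f_test_oracle(y, covariates, genetic):
    """Brute-force nested F-test via explicit normal-equation solves."""
    n = len(y)
    X0 = np.column_stack([np.ones(n)] + ([covariates] if covariates is not None else []))
    X1 = np.column_stack([X0, genetic])

    def rss(X):
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        r = y - X @ beta
        return r @ r

    rss0, rss1 = rss(X0), rss(X1)
    q = X1.shape[1] - X0.shape[1]
    df_den = n - X1.shape[1]
    f = ((rss0 - rss1) / q) / (rss1 / df_den)
    return f, q, df_den, stats.f.sf(f, q, df_den)


class TestNestedFTest:
    def test_small_fixed_dataset_matches_oracle(self):
        rng = np.random.default_rng(11)
        n = 20
        cov = rng.normal(size=(n, 1))
        g = rng.binomial(2, 0.3, size=(n, 1)).astype(float)
        y = 0.4 * g[:, 0] + 0.2 * cov[:, 0] + rng.normal(size=n)
        res = nested_f_test(y, cov, g)
        f_o, q_o, dfd_o, p_o = f_test_oracle(y, cov, g)
        assert res.f_stat == pytest.approx(f_o, abs=1e-10, rel=1e-10)
        assert res.p_value == pytest.approx(p_o, abs=1e-12)
        assert (res.df_num, res.df_den) == (q_o, dfd_o)

    def test_single_term_f_equals_t_squared(self, rng, small_covariates):
        n = 200
        g = rng.binomial(2, 0.2, size=n).astype(float)
        y = 0.3 * g + rng.normal(size=n)
        res = nested_f_test(y, small_covariates, g)
        # t statistic from the full-model fit (statsmodels-free closed form)
        X1 = np.column_stack([np.ones(n), small_covariates, g])
        beta = np.linalg.solve(X1.T @ X1, X1.T @ y)
        resid = y - X1 @ beta
        s2 = resid @ resid / (n - X1.shape[1])
        se = np.sqrt(np.diag(s2 * np.linalg.inv(X1.T @ X1)))
        t = beta[-1] / se[-1]
        assert res.f_stat == pytest.approx(t**2, rel=1e-9)

    def test_perfect_fit_limit(self, rng, small_covariates):
        n = 200
        g = rng.binomial(2, 0.3, size=n).astype(float)
        res = nested_f_test(2.5 * g + 1.0, small_covariates, g)
        assert res.f_stat == np.inf
        assert res.p_value == 0.0

    def test_rank_reduction_drops_duplicate(self, rng, small_covariates):
        n = 200
        g = rng.binomial(2, 0.3, size=n).astype(float)
        G = np.column_stack([g, g])  # duplicated term
        y = 0.3 * g + rng.normal(size=n)
        res = nested_f_test(y, small_covariates, G)
        assert res.df_num == 1
        assert res.dropped == [1]
        single = nested_f_test(y, small_covariates, g)
        assert res.f_stat == pytest.approx(single.f_stat, rel=1e-12)

    def test_all_collinear_returns_skipped(self, rng, small_covariates):
        n = 200
        G = np.column_stack([np.ones(n), small_covariates[:, 0]])
        res = nested_f_test(rng.normal(size=n), small_covariates, G)
        assert res.skipped and res.df_num == 0

    def test_f_nonnegative_and_rss_monotone(self, rng, small_covariates):
        for _ in range(20):
            n = 200
            G = rng.binomial(2, 0.3, size=(n, 3)).astype(float)
            y = rng.normal(size=n)
            res = nested_f_test(y, small_covariates, G)
            assert res.f_stat >= 0.0

    def test_no_residual_df_errors(self, rng):
        n = 5
        G = rng.normal(size=(n, 4))
        with pytest.raises(ValueError, match="degrees of freedom"):
            nested_f_test(rng.normal(size=n), None, G)

    def test_null_pvalues_uniform(self, rng, small_covariates):
        # calibration: fixed informative score, Gaussian null trait
        n = 200
        g = rng.binomial(2, 0.3, size=n).astype(float)
        pvals = [
            nested_f_test(rng.normal(size=n), small_covariates, g).p_value
            for _ in range(2000)
        ]
        assert stats.kstest(pvals, "uniform").pvalue > 0.001


class TestCollapseOnly:
    def test_constant_score_skipped(self, rng, small_covariates):
        score = RareScore("count", np.zeros(200))
        res = collapse_only_test(score, rng.normal(size=200), small_covariates)
        assert res.skipped and res.skip_reason == "constant score"

    def test_score_collinear_with_covariate_skipped(self, rng, small_covariates):
        score = RareScore("count", small_covariates[:, 0])
        res = collapse_only_test(score, rng.normal(size=200), small_covariates)
        assert res.skipped

    def test_df_num_is_one(self, rng, small_covariates):
        score = RareScore("count", rng.binomial(2, 0.2, 200).astype(float))
        res = collapse_only_test(score, rng.normal(size=200), small_covariates)
        assert res.df_num == 1 and not res.skipped
        assert 0.0 <= res.p_value <= 1.0


class TestCmc:
    def test_zero_common_equals_collapse_only(self, rng, small_covariates):
        score = RareScore("count", rng.binomial(2, 0.2, 200).astype(float))
        y = rng.normal(size=200)
        a = collapse_only_test(score, y, small_covariates)
        b = cmc_test(score, None, y, small_covariates)
        c = cmc_test(score, np.empty((200, 0)), y, small_covariates)
        assert b.f_stat == a.f_stat and b.p_value == a.p_value
        assert c.f_stat == a.f_stat and c.p_value == a.p_value
        assert b.df_num == a.df_num == 1

    def test_correlated_common_dropped(self, rng, small_covariates):
        n = 200
        score = RareScore("count", rng.binomial(2, 0.2, n).astype(float))
        common = rng.binomial(2, 0.3, size=(n, 1)).astype(float)
        C = np.column_stack([common, common])  # perfectly correlated pair
        res = cmc_test(score, C, rng.normal(size=n), small_covariates)
        assert res.df_num == 2  # score + 1 surviving common

    def test_cmc_power_exceeds_collapse_only(self):
        # Monte Carlo: one causal common variant; joint test should win
        rng = np.random.default_rng(99)
        n, reps, alpha = 697, 200, 0.05
        rare = rng.binomial(2, 0.02, size=(n, 5)).astype(float)
        common = rng.binomial(2, 0.3, size=(n, 2)).astype(float)
        score = RareScore("count", rare.sum(axis=1))
        wins_cmc = wins_only = 0
        for _ in range(reps):
            y = 0.5 * common[:, 0] + rng.normal(size=n)
            wins_only += collapse_only_test(score, y, None).p_value < alpha
            wins_cmc += cmc_test(score, common, y, None).p_value < alpha
        assert wins_cmc > wins_only


class TestLassoSelect:
    def test_no_common_variants_empty(self, rng, small_covariates):
        score = RareScore("count", rng.binomial(2, 0.2, 200).astype(float))
        sel = lasso_select(score, None, rng.normal(size=200), small_covariates)
        assert sel.n_selected == 0
        assert sel.lambda_min is None and sel.lambda_1se is None

    def test_full_shrinkage_limit(self, rng, small_covariates):
        n = 200
        score = RareScore("count", rng.binomial(2, 0.2, n).astype(float))
        C = rng.binomial(2, 0.3, size=(n, 5)).astype(float)
        y = 3.0 * C[:, 0] + rng.normal(size=n)  # strong signal
        sel = lasso_select(score, C, y, small_covariates, lambda_override=1e6)
        assert sel.n_selected == 0

    def test_soft_threshold_closed_form(self):
        # orthonormalized single penalized predictor, forced terms absent
        rng = np.random.default_rng(5)
        n = 400
        x = rng.normal(size=n)
        x = (x - x.mean()) / x.std()  # mean 0, population sd 1
        y = 0.3 * x + rng.normal(size=n)
        score = RareScore("count", np.zeros(n))  # constant: carries nothing
        inner = abs(float(x @ (y - y.mean())) / n)
        for lam in [0.5 * inner, 0.9 * inner, 0.999 * inner, 1.001 * inner,
                    1.5 * inner]:
            sel = lasso_select(score, x[:, None], y, None, lambda_override=lam)
            assert (sel.n_selected == 1) == (inner > lam)

    def test_selection_count_monotone_in_lambda(self, rng, small_covariates):
        n = 200
        score = RareScore("count", rng.binomial(2, 0.1, n).astype(float))
        C = rng.binomial(2, 0.25, size=(n, 8)).astype(float)
        y = C @ rng.normal(0, 0.3, 8) + rng.normal(size=n)
        X = np.column_stack([score.values, small_covariates, C])
        penalty = np.r_[np.zeros(1 + small_covariates.shape[1]), np.ones(8)]
        lambdas = np.logspace(0, -4, 40)
        B, *_ = _fit_path(X, y, penalty, lambdas)
        counts = (np.abs(B[:, -8:]) > 0).sum(axis=1)
        assert (np.diff(counts) >= 0).all()  # lambda decreasing along path

    def test_cv_selects_signal_variant(self, rng, small_covariates):
        n = 200
        score = RareScore("count", rng.binomial(2, 0.1, n).astype(float))
        C = rng.binomial(2, 0.3, size=(n, 4)).astype(float)
        y = 2.0 * C[:, 2] + rng.normal(size=n)
        sel = lasso_select(score, C, y, small_covariates, fold_seed=1)
        assert 2 in sel.selected_common_idx
        assert sel.lambda_1se >= sel.lambda_min

    def test_constant_trait_error(self, rng, small_covariates):
        score = RareScore("count", rng.binomial(2, 0.2, 200).astype(float))
        C = rng.binomial(2, 0.3, size=(200, 3)).astype(float)
        with pytest.raises(ValueError, match="constant"):
            lasso_select(score, C, np.ones(200), small_covariates)

    def test_invariant_lambda_order(self):
        with pytest.raises(ValueError, match="lambda_1se"):
            LassoSelection(
                lambda_path=np.array([1.0, 0.5]),
                cv_errors=np.array([1.0, 1.1]),
                cv_se=np.array([0.1, 0.1]),
                lambda_min=1.0,
                lambda_1se=0.5,
                selected_common_idx=np.array([], dtype=int),
                fold_seed=0,
            )


class TestTestLasso:
    def test_empty_selection_equals_collapse_only(self, rng, small_covariates):
        n = 200
        score = RareScore("count", rng.binomial(2, 0.2, n).astype(float))
        C = rng.binomial(2, 0.3, size=(n, 4)).astype(float)
        y = rng.normal(size=n)
        sel = lasso_select(score, C, y, small_covariates, lambda_override=1e6)
        a = lasso_test(score, C, y, small_covariates, sel)
        b = collapse_only_test(score, y, small_covariates)
        assert a.f_stat == b.f_stat and a.p_value == b.p_value

    def test_full_selection_equals_cmc(self, rng, small_covariates):
        n = 200
        score = RareScore("count", rng.binomial(2, 0.2, n).astype(float))
        C = rng.binomial(2, 0.3, size=(n, 4)).astype(float)
        y = C @ [1.0, 0.8, 0.9, 1.1] + rng.normal(size=n)
        sel = lasso_select(score, C, y, small_covariates, lambda_override=1e-9)
        assert sel.n_selected == 4
        a = lasso_test(score, C, y, small_covariates, sel)
        b = cmc_test(score, C, y, small_covariates)
        assert a.f_stat == b.f_stat and a.p_value == b.p_value
        assert a.lambda_used == pytest.approx(1e-9)

    def test_null_inflation_direction(self):
        # post-selection inference: empirical type I error above nominal
        rng = np.random.default_rng(123)
        n, n_reps = 697, 400
        score = RareScore("count", rng.binomial(2, 0.02, n).astype(float))
        C = rng.binomial(2, 0.2, size=(n, 10)).astype(float)
        rej_lasso = rej_cmc = 0
        for r in range(n_reps):
            y = rng.normal(size=n)
            sel = lasso_select(score, C, y, None, fold_seed=r)
            rej_lasso += lasso_test(score, C, y, None, sel).p_value < 0.05
            rej_cmc += cmc_test(score, C, y, None).p_value < 0.05
        assert rej_lasso / n_reps > 0.05
        assert rej_lasso >= rej_cmc
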