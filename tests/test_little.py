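import numpy as np
import pytest

from wearmiss import GeneratorConfig, generate, to_wide
from wearmiss.little import em_mvn, little_test


def random_missing_table(rng, n=30, p=4, miss=0.25):
    """Gaussian table with MCAR holes; every variable observed somewhere."""
    mean = rng.normal(size=p) * 3
    A = rng.normal(size=(p, p))
    cov = A @ A.T + p * np.eye(p)
    X = rng.multivariate_normal(mean, cov, size=n)
    mask = rng.random((n, p)) < miss
    mask[0] = False  # keep one complete row
    X[mask] = np.nan
    return X


class TestEM:
    def test_complete_data_fixed_point(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 3)) * [1.0, 50.0, 2000.0]
        em = em_mvn(X)
        assert em.converged
        np.testing.assert_allclose(em.mean, X.mean(axis=0), rtol=1e-8, atol=1e-6)
        np.testing.assert_allclose(em.cov, np.cov(X.T, bias=True), rtol=1e-6)

    def test_bivariate_monotone_matches_factored_ml(self):
        # independent oracle: with x complete and y missing on a monotone
        # block, the observed-data ML factors into the x-marginal and the
        # complete-case regression of y on x (closed form, no EM)
        rng = np.random.default_rng(1)
        n, m = 80, 50  # y observed on the first m rows only
        x = rng.normal(10, 2, size=n)
        y = 3.0 + 0.8 * x + rng.normal(0, 1.5, size=n)
        X = np.column_stack([x, y])
        X[m:, 1] = np.nan

        mu_x, s_xx = x.mean(), x.var()
        xc, yc = x[:m], y[:m]
        b = np.cov(xc, yc, bias=True)[0, 1] / xc.var()
        a = yc.mean() - b * xc.mean()
        s_res = np.mean((yc - a - b * xc) ** 2)
        mu_y = a + b * mu_x
        s_yy = s_res + b**2 * s_xx
        s_xy = b * s_xx

        em = em_mvn(X, tol=1e-10, max_iter=2000)
        np.testing.assert_allclose(em.mean, [mu_x, mu_y], atol=1e-4)
        np.testing.assert_allclose(
            em.cov, [[s_xx, s_xy], [s_xy, s_yy]], atol=1e-4, rtol=1e-4
        )

    @pytest.mark.parametrize("seed", range(20))
    def test_loglik_monotone_nondecreasing(self, seed):
        X = random_missing_table(np.random.default_rng(seed))
        em = em_mvn(X)
        assert np.all(np.diff(em.loglik) >= -1e-7)

    def test_never_observed_variable_errors(self):
        X = np.ones((5, 2))
        X[:, 1] = np.nan
        with pytest.raises(ValueError, match="never observed"):
            em_mvn(X)

    def test_nonconvergence_flagged_not_raised(self):
        X = random_missing_table(np.random.default_rng(3))
        em = em_mvn(X, tol=1e-14, max_iter=2)
        assert not em.converged
        assert em.n_iter == 2


def oracle_d2(X, mu, sigma):
    """Independent quadratic-form recomputation from the EM output."""
    X = np.asarray(X, float)
    groups = {}
    for row in X:
        key = tuple(np.isnan(row))
        groups.setdefault(key, []).append(row)
    d2, df = 0.0, 0
    for key, rows in groups.items():
        o = [i for i, m in enumerate(key) if not m]
        if not o:
            continue
        rows = np.array(rows)
        ybar = rows[:, o].mean(axis=0)
        diff = ybar - mu[o]
        d2 += len(rows) * diff @ np.linalg.inv(sigma[np.ix_(o, o)]) @ diff
        df += len(o)
    return d2, df - X.shape[1]


class TestLittle:
    def test_complete_data_degenerate(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 3))
        with pytest.warns(UserWarning, match="single missingness pattern"):
            res = little_test(X)
        assert res.d2 == pytest.approx(0.0, abs=1e-8)
        assert res.df == 0
        assert np.isnan(res.p_value)

    @pytest.mark.parametrize("seed", range(20))
    def test_d2_matches_quadratic_form_oracle(self, seed):
        X = random_missing_table(np.random.default_rng(100 + seed), n=40, p=3)
        res = little_test(X)
        em = em_mvn(X)
        d2, df = oracle_d2(X, em.mean, em.cov)
        assert res.df == df
        assert res.d2 == pytest.approx(d2, abs=1e-4, rel=1e-6)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(5)
        X = random_missing_table(rng)
        perm = rng.permutation(len(X))
        a, b = little_test(X), little_test(X[perm])
        assert a.d2 == pytest.approx(b.d2, rel=1e-8)
        assert a.df == b.df

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(6)
        X = random_missing_table(rng)
        scale = np.array([2.0, 1000.0, 0.01, 5.0])
        shift = np.array([-3.0, 500.0, 0.0, 9.0])
        a, b = little_test(X), little_test(X * scale + shift)
        assert a.d2 == pytest.approx(b.d2, rel=1e-5)
        assert a.df == b.df

    def test_all_missing_rows_skipped_but_counted(self):
        rng = np.random.default_rng(7)
        X = random_missing_table(rng)
        X_aug = np.vstack([X, np.full((3, X.shape[1]), np.nan)])
        a, b = little_test(X), little_test(X_aug)
        assert b.n_empty_rows == 3
        assert b.df == a.df
        assert b.d2 == pytest.approx(a.d2, rel=1e-8)

    def test_power_under_strong_covariate_dependence(self):
        # employment multiplies the missingness odds ~20x: pattern-wise
        # employment means separate strongly and the test should reject far
        # more often than the nominal 5%
        rej = 0
        for s in range(10):
            cfg = GeneratorConfig(
                mechanism="MAR",
                mar_coefficients=(-2.5, 0.2554, 3.0),
                n_participants=150,
                seed=900 + s,
            )
            w = to_wide(generate(cfg))
            rej += little_test(w).p_value < 0.05
        assert rej >= 5
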