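"""Mediation engine: OLS paths, decomposition identities, bootstrap behaviour,
and agreement with an independent statsmodels-based reference implementation."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from gcmm import (
    BootstrapSettings,
    FeatureSet,
    FitError,
    ParallelMediation,
    bootstrap,
    fit_point_estimates,
    ols_fit,
    run_all_types,
    simulate_mediation_dataset,
)


def _featureset(x, M, y, names=None):
    names = names or [f"M{j+1}" for j in range(M.shape[1])]
    df = pd.DataFrame(M, columns=names)
    df.insert(0, "X", x)
    df["Y"] = y
    return FeatureSet(focal_type="test", df=df)


class TestOlsFit:
    def test_exact_predictor_recovered(self, rng):
        n = 50
        x = rng.normal(size=(n, 2))
        design = np.column_stack([np.ones(n), x])
        coef = ols_fit(x[:, 0], design)
        np.testing.assert_allclose(coef, [0, 1, 0], atol=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        n, p = 8, 3
        X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
        y = rng.normal(size=n)
        expected = np.linalg.inv(X.T @ X) @ X.T @ y  # independent matrix oracle
        np.testing.assert_allclose(ols_fit(y, X), expected, rtol=1e-10)

    def test_constant_outcome_gives_zero_slopes(self, rng):
        n = 20
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        coef = ols_fit(np.full(n, 3.0), X)
        np.testing.assert_allclose(coef[1:], 0, atol=1e-12)

    def test_collinear_column_named(self, rng):
        n = 30
        a = rng.normal(size=n)
        X = np.column_stack([np.ones(n), a, 2 * a])
        # either member of the collinear pair is a valid culprit to name
        with pytest.raises(FitError, match="collinear column\\(s\\): (a|dup)"):
            ols_fit(rng.normal(size=n), X, column_names=["const", "a", "dup"])


class TestPointEstimates:
    def test_constructed_identity_path(self, rng):
        """Y == M3 and M3 ~= X gives a3 = b3 = indirect3 = 1, c' ~= 0."""
        n = 400
        x = (rng.random(n) < 0.5).astype(float)
        M = rng.normal(size=(n, 6))
        M[:, 2] = x + 1e-3 * rng.normal(size=n)
        y = M[:, 2].copy()
        fit = fit_point_estimates(_featureset(x, M, y))
        assert fit.a[2] == pytest.approx(1.0, abs=1e-3)
        assert fit.b[2] == pytest.approx(1.0, abs=1e-9)
        assert fit.indirect[2] == pytest.approx(1.0, abs=1e-3)
        assert fit.c_prime == pytest.approx(0.0, abs=1e-9)

    def test_permuted_exposure_gives_null_effects(self, rng):
        fs, _ = simulate_mediation_dataset(
            5000, a=[0.5] * 6, b=[0.4] * 6, c_prime=0.3, seed=7
        )
        df = fs.df.copy()
        df["X"] = rng.permutation(df["X"].to_numpy())
        fit = fit_point_estimates(FeatureSet("perm", df))
        assert np.abs(fit.indirect).max() < 0.05
        assert abs(fit.total) < 0.15

    def test_planted_paths_recovered(self):
        a = np.array([0.5, 0.4, 0.3, 0.2, 0.1, 0.0])
        b = np.array([0.4, 0.3, 0.5, 0.2, 0.0, 0.3])
        fs, truth = simulate_mediation_dataset(40000, a, b, c_prime=0.2, seed=21)
        fit = fit_point_estimates(fs)
        np.testing.assert_allclose(fit.indirect, a * b, atol=0.03)
        assert fit.c_prime == pytest.approx(0.2, abs=0.05)

    def test_constant_exposure_rejected(self, rng):
        M = rng.normal(size=(30, 2))
        with pytest.raises(FitError, match="constant"):
            fit_point_estimates(_featureset(np.ones(30), M, rng.normal(size=30)))

    def test_constant_mediator_named(self, rng):
        n = 30
        x = (rng.random(n) < 0.5).astype(float)
        M = rng.normal(size=(n, 3))
        M[:, 1] = 2.0
        with pytest.raises(FitError, match="M2"):
            fit_point_estimates(_featureset(x, M, rng.normal(size=n)))


class TestDecomposition:
    def test_identity_holds_in_point_fit_and_every_resample(self, rng):
        fs, _ = simulate_mediation_dataset(
            600, a=[0.5, 0.2, 0.0], b=[0.3, 0.0, 0.4], c_prime=0.1,
            seed=3, noise_sd_y=2.0
        )
        fit = bootstrap(fs, BootstrapSettings(B=500, seed=9))
        assert fit.total == pytest.approx(fit.c_prime + fit.indirect.sum(), abs=0)
        assert fit.decomposition_gap < 1e-12

    def test_total_equals_simple_regression_slope(self):
        fs, _ = simulate_mediation_dataset(300, a=[0.4, 0.1], b=[0.5, 0.2], seed=5)
        fit = fit_point_estimates(fs)
        slope = sm.OLS(fs.Y, sm.add_constant(fs.X)).fit().params[1]
        assert fit.total == pytest.approx(slope, rel=1e-10)

    def test_affine_equivariance_of_effects_and_cis(self):
        fs, _ = simulate_mediation_dataset(250, a=[0.5, 0.2], b=[0.4, 0.1], seed=13)
        k = 7.3
        df2 = fs.df.copy()
        df2["Y"] = k * df2["Y"]
        s = BootstrapSettings(B=300, seed=99)
        f1 = bootstrap(fs, s)
        f2 = bootstrap(FeatureSet("scaled", df2), s)
        np.testing.assert_allclose(f2.indirect, k * f1.indirect, rtol=1e-9)
        np.testing.assert_allclose(f2.total, k * f1.total, rtol=1e-9)
        for name, (lo, hi) in f1.ci.items():
            if name.startswith("a:"):
                continue  # a-paths do not involve Y
            lo2, hi2 = f2.ci[name]
            np.testing.assert_allclose([lo2, hi2], [k * lo, k * hi], rtol=1e-9)
        assert f1.relevant == f2.relevant


class TestBootstrap:
    def test_perfect_outcome_fit_collapses_b_and_direct_cis(self, rng):
        """With a noiseless outcome equation, b and c' are identical in every
        resample, so their intervals collapse to the point estimates."""
        fs, _ = simulate_mediation_dataset(
            200, a=[0.5, 0.3], b=[0.4, 0.2], c_prime=0.1, seed=2, noise_sd_y=0.0
        )
        fit = bootstrap(fs, BootstrapSettings(B=200, seed=4))
        for j, med in enumerate(fit.mediators):
            lo, hi = fit.ci[f"b:{med}"]
            assert lo == pytest.approx(fit.b[j], abs=1e-9)
            assert hi == pytest.approx(fit.b[j], abs=1e-9)
        lo, hi = fit.ci["c_prime"]
        assert hi - lo < 1e-9

    def test_deterministic_under_fixed_seed(self):
        fs, _ = simulate_mediation_dataset(150, a=[0.5, 0.1], b=[0.3, 0.2], seed=6)
        s = BootstrapSettings(B=250, seed=42)
        f1, f2 = bootstrap(fs, s), bootstrap(fs, s)
        assert f1.ci == f2.ci

    def test_rare_exposure_triggers_redraws_not_failure(self, rng):
        n = 60
        x = np.zeros(n)
        x[:3] = 1.0  # ~5% of resamples lose all exposed rows
        M = rng.normal(size=(n, 2))
        y = 0.5 * M[:, 0] + rng.normal(size=n)
        fit = bootstrap(_featureset(x, M, y), BootstrapSettings(B=300, seed=1))
        assert fit.n_redraws > 0
        assert fit.B == 300

    def test_hopelessly_degenerate_data_aborts(self, rng):
        n = 60
        x = np.zeros(n)
        x[0] = 1.0  # a single exposed row: ~37% of resamples lose it
        M = rng.normal(size=(n, 2))
        with pytest.raises(FitError, match="rank deficient"):
            bootstrap(_featureset(x, M, rng.normal(size=n)),
                      BootstrapSettings(B=200, seed=3))

    def test_ci_width_shrinks_like_root_n(self):
        widths = []
        for n in (400, 6400):
            fs, _ = simulate_mediation_dataset(n, a=[0.5, 0.2], b=[0.4, 0.1], seed=n)
            fit = bootstrap(fs, BootstrapSettings(B=400, seed=8))
            lo, hi = fit.ci["indirect:M1"]
            widths.append(hi - lo)
        ratio = widths[0] / widths[1]  # expect ~ sqrt(6400/400) = 4
        assert 2.5 < ratio < 6.0


class TestReferenceImplementation:
    """Dual-route check: the batched engine against a naive per-resample
    statsmodels OLS loop on a 50-row, 2-mediator fixture with the identical
    resample index sequence."""

    @staticmethod
    def _naive(fs, B, seed, ci_level=0.95):
        x, M, y = fs.X, fs.M, fs.Y
        n, m = M.shape

        def effects(xi, Mi, yi):
            a = np.empty(m)
            for j in range(m):
                a[j] = sm.OLS(Mi[:, j], sm.add_constant(xi)).fit().params[1]
            res = sm.OLS(yi, sm.add_constant(np.column_stack([xi, Mi]))).fit()
            c = res.params[1]
            b = res.params[2:]
            return a, b, c

        a, b, c = effects(x, M, y)
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(B, n))
        boot = np.empty((B, m))
        for i in range(B):
            ai, bi, _ = effects(x[idx[i]], M[idx[i]], y[idx[i]])
            boot[i] = ai * bi
        alpha = 1 - ci_level
        ci = np.percentile(boot, [100 * alpha / 2, 100 * (1 - alpha / 2)], axis=0)
        return a, b, c, a * b, ci

    def test_agreement_on_fixture(self):
        fs, _ = simulate_mediation_dataset(
            50, a=[0.6, 0.2], b=[0.5, 0.1], c_prime=0.2, seed=17
        )
        B, seed = 400, 23
        fit = bootstrap(fs, BootstrapSettings(B=B, seed=seed))
        a, b, c, ind, ci = self._naive(fs, B, seed)
        np.testing.assert_allclose(fit.a, a, atol=1e-10)
        np.testing.assert_allclose(fit.b, b, atol=1e-10)
        assert fit.c_prime == pytest.approx(c, abs=1e-10)
        np.testing.assert_allclose(fit.indirect, ind, atol=1e-10)
        for j, med in enumerate(fit.mediators):
            lo, hi = fit.ci[f"indirect:{med}"]
            # same resample sequence; linear-interpolation quantiles match
            assert lo == pytest.approx(ci[0, j], abs=1e-10)
            assert hi == pytest.approx(ci[1, j], abs=1e-10)


class TestRunAllTypes:
    def test_one_fit_per_catalog_type(self, gamblers, fast_config):
        res = run_all_types(gamblers, config=fast_config)
        assert len(res.fits) + len(res.failures) == 15
        assert not res.failures

    def test_restricted_catalog(self, gamblers, fast_config):
        cat = gamblers.catalog.subset(["lotto_offline", "scratch_offline"])
        res = run_all_types(gamblers, cat, fast_config)
        assert set(res.fits) == {"lotto_offline", "scratch_offline"}

    def test_same_master_seed_reproduces_cis(self, gamblers, fast_config):
        r1 = run_all_types(gamblers, config=fast_config)
        r2 = run_all_types(gamblers, config=fast_config)
        for t in r1.fits:
            assert r1.fits[t].ci == r2.fits[t].ci

    def test_decomposition_holds_at_reduced_b(self, gamblers, fast_config):
        res = run_all_types(gamblers, config=fast_config.replace(bootstrap_B=50))
        assert all(f.decomposition_gap < 1e-10 for f in res.fits.values())
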