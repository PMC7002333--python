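"""Model engine: correlation forms, likelihood, separability, fitting, WAIC."""

import numpy as np
import pandas as pd
import pytest

from snowsync.covariance import (ar1_correlation_matrix, matern_correlation,
                                 matern_matrix, temporal_precision)
from snowsync.model import (ModelSpec, extract_range, fit, nb_loglik,
                            predict_surface, spatial_residuals, waic)

from conftest import toy_design


class TestMaternCorrelation:
    def test_unit_at_zero_and_decay(self):
        assert matern_correlation(0.0, 100.0) == 1.0
        assert matern_correlation(1e5, 100.0) == pytest.approx(0.0, abs=1e-10)

    def test_value_at_range(self):
        # sqrt(8) K_1(sqrt(8)) ~ 0.1397: the defining property of the range
        assert matern_correlation(100.0, 100.0) == pytest.approx(0.1397, abs=5e-4)

    def test_monotone_decreasing(self):
        d = np.linspace(0, 500, 200)
        r = matern_correlation(d, 120.0)
        assert np.all(np.diff(r) <= 1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            matern_correlation(10.0, -1.0)
        with pytest.raises(ValueError):
            matern_correlation(-1.0, 10.0)


class TestNbLoglik:
    def test_normalises_to_one(self):
        for mu, alpha in [(1.0, 0.5), (2.0, 1.0), (10.0, 5.0)]:
            y = np.arange(0, 500)
            total = np.exp(nb_loglik(y, np.full_like(y, mu, dtype=float), alpha)).sum()
            assert total == pytest.approx(1.0, abs=1e-8)

    def test_poisson_limit(self):
        # alpha -> inf: log P(0 | mu=1) -> -1
        assert nb_loglik(0, 1.0, 1e9) == pytest.approx(-1.0, abs=1e-6)

    def test_variance_identity_by_moment_summation(self):
        mu, alpha = 2.0, 1.0
        y = np.arange(0, 2000)
        p = np.exp(nb_loglik(y, np.full_like(y, mu, dtype=float), alpha))
        mean = (y * p).sum()
        var = ((y - mean) ** 2 * p).sum()
        assert mean == pytest.approx(2.0, abs=1e-8)
        assert var == pytest.approx(mu + mu ** 2 / alpha, abs=1e-6)  # = 6

    def test_rejects_nonpositive_parameters(self):
        with pytest.raises(ValueError):
            nb_loglik(1, -1.0, 1.0)
        with pytest.raises(ValueError):
            nb_loglik(1, 1.0, 0.0)


class TestSeparability:
    def test_kronecker_identity_entrywise(self):
        """The inverse of the Kronecker precision matches
        sigma^2 * Matern(d_ij) * rho^|t-t'| entry by entry."""
        rng = np.random.default_rng(0)
        S, T, sigma, rho, rng_km = 6, 5, 0.8, 0.55, 150.0
        coords = rng.uniform(0, 300, (S, 2))
        M = matern_matrix(coords, rng_km)
        Qt = temporal_precision(T, "AR1", rho)
        Q = np.kron(Qt, np.linalg.inv(M)) / sigma ** 2
        cov = np.linalg.inv(Q)
        R = ar1_correlation_matrix(T, rho)
        d = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        for _ in range(30):
            i, j = rng.integers(0, S * T, 2)
            ti, si = divmod(int(i), S)
            tj, sj = divmod(int(j), S)
            expected = sigma ** 2 * matern_correlation(d[si, sj], rng_km) * R[ti, tj]
            assert cov[i, j] == pytest.approx(expected, abs=1e-8)

    def test_ar1_precision_inverts_correlation(self):
        T, rho = 7, 0.8
        Q = temporal_precision(T, "AR1", rho)
        assert np.linalg.inv(Q) == pytest.approx(ar1_correlation_matrix(T, rho),
                                                 abs=1e-10)


class TestFit:
    def test_null_weights_covered(self):
        """beta = 0, no field: the 95% intervals cover 0 nearly always."""
        hits = 0
        total = 0
        for seed in range(20):
            design, _ = toy_design(seed=seed, n_sites=50, n_years=4,
                                   beta=(-1.0, 0.0, 0.0), field=False)
            f = fit(design, ModelSpec(covariates=("c1", "c2"),
                                      spatial_process="none",
                                      temporal_process="none"),
                    compute_uncertainty=False, n_draws=5)
            for c in f.coefficients[1:]:
                total += 1
                hits += c.q2_5 <= 0.0 <= c.q97_5
        assert hits / total >= 0.90

    def test_quantile_ordering_and_mode(self):
        design, _ = toy_design(seed=1, n_sites=30, n_years=4, field=False)
        f = fit(design, ModelSpec(covariates=("c1", "c2"), spatial_process="none",
                                  temporal_process="none"),
                compute_uncertainty=False, n_draws=5)
        for c in f.coefficients:
            assert c.q2_5 <= c.median <= c.q97_5
            assert np.isfinite(c.mode)
            assert c.mode == c.mean  # Gaussian approximation

    def test_st_fit_recovers_weights_and_is_deterministic(self):
        design, beta = toy_design(seed=2, n_sites=40, n_years=6)
        spec = ModelSpec(covariates=("c1", "c2"))
        f1 = fit(design, spec, seed=7, compute_uncertainty=False, n_draws=40)
        f2 = fit(design, spec, seed=7, compute_uncertainty=False, n_draws=40)
        assert f1.waic == f2.waic
        for c, b in zip(f1.coefficients, beta):
            assert abs(c.mean - b) < 4 * c.sd
        assert f1.hyper.rho == f2.hyper.rho

    def test_rw1_alternative_fits(self):
        design, _ = toy_design(seed=3, n_sites=25, n_years=6, rho=0.9)
        f = fit(design, ModelSpec(covariates=("c1", "c2"),
                                  temporal_process="RW1"),
                compute_uncertainty=False, n_draws=30)
        assert np.isfinite(f.waic)
        assert np.isnan(f.hyper.rho)  # no AR1 coefficient in a RW1 model

    def test_unknown_covariate_rejected(self):
        design, _ = toy_design(seed=4, n_sites=20, n_years=3, field=False)
        with pytest.raises(ValueError, match="not in design"):
            fit(design, ModelSpec(covariates=("nope",), spatial_process="none",
                                  temporal_process="none"))


@pytest.fixture(scope="module")
def st_fit():
    design, _ = toy_design(seed=5, n_sites=30, n_years=5)
    return fit(design, ModelSpec(covariates=("c1", "c2")),
               seed=3, compute_uncertainty=False, n_draws=60)


@pytest.fixture(scope="module")
def st_fit_surface():
    design, _ = toy_design(seed=6, n_sites=35, n_years=5, field_sd=0.9)
    return fit(design, ModelSpec(covariates=("c1", "c2")),
               seed=2, compute_uncertainty=True, n_draws=30)


class TestWaic:
    def test_deterministic_given_seed(self, st_fit):
        assert waic(st_fit, n_draws=100, seed=5) == waic(st_fit, n_draws=100, seed=5)

    def test_single_draw_errors(self, st_fit):
        with pytest.raises(ValueError, match="two"):
            waic(st_fit, n_draws=1)

    def test_matches_stored_draws_formula(self, st_fit):
        from scipy.special import logsumexp
        ll = st_fit.pointwise_loglik
        lppd = np.sum(logsumexp(ll, axis=0) - np.log(ll.shape[0]))
        p_w = np.sum(np.var(ll, axis=0, ddof=1))
        assert waic(st_fit) == pytest.approx(-2 * (lppd - p_w))
        assert ll.shape[1] == st_fit.n_obs  # one entry per analysis row


class TestRangeAndSurfaces:

    def test_extract_range_positive_with_sd(self, st_fit_surface):
        r, sd = extract_range(st_fit_surface)
        assert r > 0 and np.isfinite(sd)
        # consistency: correlation at the fitted range is the Matérn constant
        assert matern_correlation(r, r) == pytest.approx(0.1397, abs=5e-4)

    def test_extract_range_requires_spatial_term(self):
        design, _ = toy_design(seed=7, n_sites=20, n_years=3, field=False)
        f = fit(design, ModelSpec(covariates=("c1",), spatial_process="none",
                                  temporal_process="none"),
                compute_uncertainty=False, n_draws=5)
        with pytest.raises(ValueError, match="no spatial"):
            extract_range(f)

    def test_kriging_interpolates_fitted_field(self, st_fit_surface):
        """Predicting at an observed site returns exp(intercept + u) there."""
        engine, state = st_fit_surface._engine, st_fit_surface._state
        year = int(st_fit_surface._years[2])
        out = predict_surface(st_fit_surface, st_fit_surface._site_coords, year)
        u_t = state.u.reshape(engine.T, engine.S)[2]
        expected = np.exp(state.beta[0] + u_t)
        assert out["density"].to_numpy() == pytest.approx(expected, rel=1e-6)
        assert not out["extrapolated"].any()

    def test_far_nodes_flagged_extrapolated(self, st_fit_surface):
        year = int(st_fit_surface._years[0])
        out = predict_surface(st_fit_surface, np.array([[5000.0, 5000.0]]), year)
        assert out["extrapolated"].all()

    def test_year_outside_span_rejected(self, st_fit_surface):
        with pytest.raises(ValueError, match="span"):
            predict_surface(st_fit_surface, np.zeros((1, 2)), 1900)

    def test_residual_table_one_row_per_triangle(self, st_fit_surface):
        res = spatial_residuals(st_fit_surface)
        assert len(res) == st_fit_surface.design.data["triangle_id"].nunique()
        assert {"triangle_id", "residual", "x_km", "y_km"} <= set(res.columns)

    def test_gradient_field_predicts_gradient(self):
        """A deterministic north-south log-rate gradient shows up as a
        monotone predicted-density gradient."""
        rng = np.random.default_rng(8)
        S, T = 40, 4
        coords = np.column_stack([rng.uniform(0, 200, S), rng.uniform(0, 400, S)])
        site = np.tile(np.arange(S), T)
        year = np.repeat(np.arange(T), S)
        grad = 1.5 * (coords[:, 1] / 400.0 - 0.5)
        eta = np.log(12.0) - 1.0 + grad[site]
        y = rng.poisson(np.exp(eta))
        data = pd.DataFrame({
            "triangle_id": [f"T{i}" for i in site], "year": 2000 + year,
            "x_km": coords[site, 0], "y_km": coords[site, 1],
            "length_km": 12.0, "squirrel_tracks": y})
        from snowsync.covariates import DesignMatrix
        design = DesignMatrix(data=data, covariates=(),
                              offset=np.full(S * T, np.log(12.0)))
        f = fit(design, ModelSpec(covariates=()), compute_uncertainty=False,
                n_draws=10)
        grid = np.column_stack([np.full(20, 100.0), np.linspace(20, 380, 20)])
        out = predict_surface(f, grid, 2001)
        corr = np.corrcoef(out["y_km"], np.log(out["density"]))[0, 1]
        assert corr > 0.8
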