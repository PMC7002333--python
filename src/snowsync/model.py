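"""Hierarchical NB spatiotemporal model: fitting, WAIC, ranges, surfaces.

Public wrapper around the Laplace engine.  A model is specified by its
covariate list and latent structure (spatial Matérn field or none; AR1, RW1
or no temporal process); ``{none, none}`` with covariates reproduces an
independent negative-binomial regression, the usual non-spatial baseline.

Reported per-coefficient summaries are mean, SD, 2.5% / 50% / 97.5%
quantiles and mode, the quantiles taken from seeded draws of the Gaussian
posterior approximation (under which the mode coincides with the mean).
WAIC is computed from pointwise posterior-predictive log densities:
``WAIC = -2 (lppd - p_waic)`` with ``p_waic`` the summed pointwise variance
of the log density over draws; lower is better.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from ._laplace import STEngine, nb_loglik_terms, ConvergenceError, GeometryError
from .covariance import matern_correlation, matern_matrix
from .covariates import DesignMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec", "HyperParams", "CoefficientEstimate", "ModelFit",
    "matern_correlation", "nb_loglik", "fit", "waic", "extract_range",
    "predict_surface", "spatial_residuals", "ConvergenceError", "GeometryError",
]


@dataclass(frozen=True)
class ModelSpec:
    """Structure of one candidate model.

    ``covariates`` may be empty (smoothing-only model).  ``temporal_process``
    in {"AR1", "RW1", "none"}; ``spatial_process`` in {"matern", "none"}.
    With no spatial process the model is the independent NB regression
    baseline regardless of the temporal choice.
    """

    covariates: tuple = ()
    temporal_process: str = "AR1"
    spatial_process: str = "matern"
    prior_beta_sd: float = 10.0
    rw1_ridge: float = 1e-5
    name: str = ""

    def __post_init__(self):
        if self.temporal_process not in ("AR1", "RW1", "none"):
            raise ValueError("temporal_process must be AR1, RW1 or none")
        if self.spatial_process not in ("matern", "none"):
            raise ValueError("spatial_process must be matern or none")


@dataclass
class HyperParams:
    """Estimated hyperparameters on their natural scales (with SDs)."""

    range_km: float = np.nan
    range_sd: float = np.nan
    field_sd: float = np.nan
    field_sd_sd: float = np.nan
    rho: float = np.nan
    rho_sd: float = np.nan
    overdispersion: float = np.nan
    overdispersion_sd: float = np.nan


@dataclass
class CoefficientEstimate:
    name: str
    mean: float
    sd: float
    q2_5: float
    median: float
    q97_5: float
    mode: float


@dataclass
class ModelFit:
    """Posterior summaries and per-observation quantities of one fitted model."""

    spec: ModelSpec
    coefficients: list
    hyper: HyperParams
    waic: float
    lppd: float
    p_waic: float
    pointwise_loglik: np.ndarray        # (n_draws, n_obs) posterior draws
    fitted: pd.DataFrame                # triangle_id, year, observed, fitted mean/sd
    loglik_at_mode: float
    logml: float
    design: DesignMatrix
    n_obs: int
    # engine internals (posterior sampling, kriging)
    _engine: object = None
    _state: object = None
    _years: np.ndarray | None = None
    _site_coords: np.ndarray | None = None

    @property
    def aic(self) -> float:
        """2k - 2 log L at the posterior mode (meaningful for the
        independent baseline, where the mode is essentially the MLE)."""
        k = len(self.coefficients) + 1  # + overdispersion
        return 2.0 * k - 2.0 * self.loglik_at_mode

    def coefficient_table(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "name": c.name, "mean": c.mean, "sd": c.sd, "q2.5": c.q2_5,
            "median": c.median, "q97.5": c.q97_5, "mode": c.mode,
        } for c in self.coefficients])


def nb_loglik(y, mu, alpha):
    """NB2 log probability mass: mean ``mu``, variance ``mu + mu**2/alpha``."""
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0) or alpha <= 0:
        raise ValueError("mu and alpha must be positive")
    out = nb_loglik_terms(np.asarray(y, dtype=float), np.log(mu), alpha)[0]
    return float(out) if np.isscalar(y) else out


def _summaries(names, mean, cov, n_draws, rng):
    draws = rng.multivariate_normal(mean, cov, size=n_draws, method="cholesky")
    qs = np.percentile(draws, [2.5, 50.0, 97.5], axis=0)
    out = []
    for j, name in enumerate(names):
        out.append(CoefficientEstimate(
            name=name, mean=float(mean[j]), sd=float(np.sqrt(cov[j, j])),
            q2_5=float(qs[0, j]), median=float(qs[1, j]), q97_5=float(qs[2, j]),
            mode=float(mean[j])))  # Gaussian approximation: mode == mean
    return out


def fit(design: DesignMatrix, spec: ModelSpec, seed: int = 0,
        n_draws: int = 400, coef_draws: int = 4000,
        compute_uncertainty: bool = True, maxfev: int = 150) -> ModelFit:
    """Fit one model by empirical-Bayes Laplace approximation.

    Hyperparameters maximise the Laplace marginal likelihood; the latent
    posterior is Gaussian at the joint mode.  ``n_draws`` controls the
    posterior draws used for WAIC and fitted-count summaries, ``coef_draws``
    the draws behind coefficient quantiles.  Deterministic given ``seed``.
    """
    data = design.data
    y = design.response
    covs = tuple(spec.covariates)
    unknown = [c for c in covs if c not in data.columns]
    if unknown:
        raise ValueError(f"covariates not in design: {unknown}")
    X = np.column_stack([np.ones(len(data))]
                        + [data[c].to_numpy(dtype=float) for c in covs])
    names = ["intercept"] + list(covs)

    sites = data[["x_km", "y_km"]].drop_duplicates().reset_index(drop=True)
    site_key = {(x, y_): i for i, (x, y_) in
                enumerate(zip(sites["x_km"], sites["y_km"]))}
    site_idx = np.array([site_key[(x, y_)] for x, y_ in
                         zip(data["x_km"], data["y_km"])])
    years = np.sort(data["year"].unique())
    year_key = {int(v): t for t, v in enumerate(years)}
    year_idx = np.array([year_key[int(v)] for v in data["year"]])

    engine = STEngine(
        y=y, X=X, offset=design.offset,
        coords=sites.to_numpy(dtype=float), site_idx=site_idx,
        year_idx=year_idx, n_years=len(years),
        spatial=spec.spatial_process, temporal=spec.temporal_process,
        prior_beta_sd=spec.prior_beta_sd, rw1_ridge=spec.rw1_ridge)

    psi_hat, state = engine.optimize(maxfev=maxfev)

    hyper = HyperParams(overdispersion=state.alpha)
    kw = engine._unpack(psi_hat)
    if spec.spatial_process == "matern":
        hyper.range_km = kw["range_km"]
        hyper.field_sd = kw["sigma"]
        if spec.temporal_process == "AR1":
            hyper.rho = kw["rho"]
    if compute_uncertainty:
        H = engine.hyper_hessian(psi_hat)
        try:
            cov_psi = np.linalg.inv(H)
            sd_psi = np.sqrt(np.clip(np.diag(cov_psi), 0, None))
        except np.linalg.LinAlgError:
            sd_psi = np.full(len(psi_hat), np.nan)
        pnames = engine._psi_names()
        for nm, sd in zip(pnames, sd_psi):
            if nm == "log_range":
                hyper.range_sd = hyper.range_km * sd     # delta method
            elif nm == "log_sigma":
                hyper.field_sd_sd = hyper.field_sd * sd
            elif nm == "z_rho":
                hyper.rho_sd = (1.0 - hyper.rho ** 2) * sd
            elif nm == "log_alpha":
                hyper.overdispersion_sd = hyper.overdispersion * sd

    rng = np.random.default_rng(seed)
    coeffs = _summaries(names, state.beta, state.beta_cov, coef_draws, rng)

    if state.u is not None:
        eta_draws = engine.sample_eta(state, n_draws, rng)
    else:
        zb = rng.standard_normal((n_draws, len(state.beta)))
        betas = state.beta + zb @ np.linalg.cholesky(state.beta_cov).T
        eta_draws = design.offset[None, :] + betas @ X.T
    ll_draws = np.empty_like(eta_draws)
    for m in range(eta_draws.shape[0]):
        ll_draws[m] = nb_loglik_terms(y, eta_draws[m], state.alpha)[0]
    lppd = float(np.sum(logsumexp(ll_draws, axis=0) - np.log(ll_draws.shape[0])))
    p_w = float(np.sum(np.var(ll_draws, axis=0, ddof=1)))
    waic_val = -2.0 * (lppd - p_w)

    mu_draws = np.exp(eta_draws)
    fitted = pd.DataFrame({
        "triangle_id": data["triangle_id"],
        "year": data["year"],
        "observed": y,
        "fitted_mean": mu_draws.mean(axis=0),
        "fitted_sd": mu_draws.std(axis=0, ddof=1),
    })

    ll_mode = float(nb_loglik_terms(y, state.eta, state.alpha)[0].sum())
    return ModelFit(spec=spec, coefficients=coeffs, hyper=hyper,
                    waic=float(waic_val), lppd=lppd, p_waic=p_w,
                    pointwise_loglik=ll_draws, fitted=fitted,
                    loglik_at_mode=ll_mode, logml=state.logml, design=design,
                    n_obs=len(y), _engine=engine, _state=state,
                    _years=years, _site_coords=sites.to_numpy(dtype=float))


def waic(fit_result: ModelFit, n_draws: int | None = None, seed: int = 1) -> float:
    """WAIC from pointwise posterior log densities (lower is better).

    With ``n_draws`` given, fresh linear-predictor draws are taken;
    otherwise the draws stored on the fit are reused.
    """
    if n_draws is not None:
        if n_draws < 2:
            raise ValueError("WAIC needs at least two posterior draws")
        rng = np.random.default_rng(seed)
        state, engine = fit_result._state, fit_result._engine
        y = fit_result.design.response
        if state.u is not None:
            eta = engine.sample_eta(state, n_draws, rng)
        else:
            zb = rng.standard_normal((n_draws, len(state.beta)))
            betas = state.beta + zb @ np.linalg.cholesky(state.beta_cov).T
            eta = fit_result.design.offset[None, :] + betas @ engine.X.T
        ll = np.stack([nb_loglik_terms(y, e, state.alpha)[0] for e in eta])
    else:
        ll = fit_result.pointwise_loglik
    if ll.shape[0] < 2:
        raise ValueError("WAIC needs at least two posterior draws")
    lppd = np.sum(logsumexp(ll, axis=0) - np.log(ll.shape[0]))
    p_w = np.sum(np.var(ll, axis=0, ddof=1))
    return float(-2.0 * (lppd - p_w))


def extract_range(fit_result: ModelFit):
    """Spatial range (km) of the fitted Matérn field, with delta-method SD.

    The range is ``sqrt(8)/kappa``, the distance at which the spatial
    correlation has decayed to ~0.14.
    """
    if fit_result.spec.spatial_process != "matern":
        raise ValueError("model has no spatial field; range is undefined")
    return fit_result.hyper.range_km, fit_result.hyper.range_sd


def predict_surface(fit_result: ModelFit, grid: np.ndarray, year: int,
                    extrapolation_km: float = 50.0) -> pd.DataFrame:
    """Expected track density (tracks/km) on a coordinate grid for one year.

    The posterior-mean latent field is kriged from the transect sites to the
    grid through the fitted Matérn correlation and combined with the
    intercept (covariates are centred, so the intercept is the log density
    at average covariate values).  Nodes farther than ``extrapolation_km``
    from every site are flagged.
    """
    if fit_result.spec.spatial_process != "matern":
        raise ValueError("model has no spatial field to predict from")
    years = fit_result._years
    if year not in set(int(v) for v in years):
        raise ValueError(f"year {year} outside the fitted span")
    t = int(np.flatnonzero(years == year)[0])
    engine, state = fit_result._engine, fit_result._state
    coords = fit_result._site_coords
    grid = np.asarray(grid, dtype=float)
    K0 = matern_matrix(grid, fit_result.hyper.range_km, coords)
    M = matern_matrix(coords, fit_result.hyper.range_km)
    M[np.diag_indices_from(M)] += 1e-8
    u_year = state.u.reshape(engine.T, engine.S)[t]
    w_grid = K0 @ np.linalg.solve(M, u_year)
    beta0 = state.beta[0]
    dmin = np.sqrt(((grid[:, None, :] - coords[None, :, :]) ** 2).sum(-1)).min(axis=1)
    return pd.DataFrame({
        "x_km": grid[:, 0], "y_km": grid[:, 1], "year": year,
        "density": np.exp(beta0 + w_grid),
        "extrapolated": dmin > extrapolation_km,
    })


def spatial_residuals(fit_result: ModelFit) -> pd.DataFrame:
    """Per-triangle mean of observed minus fitted counts across years."""
    f = fit_result.fitted.copy()
    f["residual"] = f["observed"] - f["fitted_mean"]
    coords = fit_result.design.data[["triangle_id", "x_km", "y_km"]].drop_duplicates()
    out = (f.groupby("triangle_id", as_index=False)["residual"].mean()
           .merge(coords, on="triangle_id"))
    mid = out["y_km"].median()
    south = out.loc[out["y_km"] <= mid, "residual"].sum()
    north = out.loc[out["y_km"] > mid, "residual"].sum()
    logger.info("summed residuals: south %.3f, north %.3f", south, north)
    return out
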