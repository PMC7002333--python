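import numpy as np
import pandas as pd
import pytest

from snowsync.covariates import DesignMatrix
from snowsync.simulate import GenerativeConfig, StudyRegion, simulate_dataset


@pytest.fixture(scope="session")
def small_region():
    return StudyRegion(width_km=300.0, height_km=500.0, southern_cut_y_km=200.0)


@pytest.fixture(scope="session")
def small_config():
    """Reduced-scale generative configuration used by several suites."""
    return GenerativeConfig(
        n_wildlife=80, n_field=30, n_years=8, start_year=2000,
        census_prob_per_year=0.8, matern_range_km=150.0, field_sd=0.6,
        ar1_rho=0.6, nb_overdispersion=1.5, n_cone_sites=40,
        nest_density_per_100km2=3.0, failure_years=frozenset({2001, 2005}),
        seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config, small_region):
    return simulate_dataset(small_config, small_region)


def toy_design(seed=0, n_sites=40, n_years=6, beta=(-1.0, 0.5, -0.4),
               range_km=120.0, field_sd=0.7, rho=0.6, alpha=1.5,
               extent=(400.0, 400.0), length_km=12.0, field=True):
    """Small regression data set with (optionally) a latent ST field.

    Returns (DesignMatrix with covariates c1, c2, true beta vector).
    """
    from snowsync.simulate import simulate_matern_ar1_field
    rng = np.random.default_rng(seed)
    S, T = n_sites, n_years
    coords = np.column_stack([rng.uniform(0, extent[0], S),
                              rng.uniform(0, extent[1], S)])
    n = S * T
    site = np.tile(np.arange(S), T)
    year = np.repeat(np.arange(T), S)
    x1 = rng.normal(0, 0.5, n)
    x2 = rng.normal(0, 0.5, n)
    eta = np.log(length_km) + beta[0] + beta[1] * x1 + beta[2] * x2
    if field:
        w = simulate_matern_ar1_field(coords, T, range_km, field_sd, rho, rng)
        eta = eta + w[year, site]
    mu = np.exp(eta)
    y = rng.poisson(rng.gamma(alpha, mu / alpha))
    data = pd.DataFrame({
        "triangle_id": [f"T{i:03d}" for i in site],
        "year": 2000 + year,
        "x_km": coords[site, 0], "y_km": coords[site, 1],
        "length_km": length_km, "squirrel_tracks": y,
        "c1": x1, "c2": x2,
    })
    design = DesignMatrix(data=data, covariates=("c1", "c2"),
                          offset=np.full(n, np.log(length_km)))
    return design, np.asarray(beta)
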