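"""Seeded synthetic data with the generative structure the count model assumes.

The generator emulates a national snow-track monitoring scheme on a planar
rectangular study region (km coordinates; all distances in the analysis are
metric, so no geodesy is involved):

* ~1,900 triangular census transects — 12-km "wildlife" triangles placed
  uniformly, 6-km "field" triangles concentrated in the southern/western
  part — of which a random subset is censused each winter;
* negative-binomial track counts whose log rate is an offset
  (log transect length) plus a linear combination of scaled covariates plus
  a zero-mean separable Matérn(nu=1) x AR1 Gaussian field;
* a masting cone resource: a lognormal shared year effect on top of a smooth
  static spatial surface, with region-wide southern crop failures in listed
  years (zeros, partially recorded as missing);
* raptor nest territories as a homogeneous Poisson point pattern with
  year-to-year occupancy persistence, feeding the predation kernel;
* previous-day temperature and precipitation on a 10x10 km lattice.

Everything is driven by one `numpy` Generator, so an identical
:class:`GenerativeConfig` reproduces byte-identical output tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .covariance import matern_matrix
from .kernel import KernelParams, kernel_covariate

__all__ = [
    "StudyRegion",
    "GenerativeConfig",
    "generate_region_and_triangles",
    "simulate_matern_ar1_field",
    "simulate_cone_series",
    "simulate_nests",
    "simulate_counts",
    "simulate_dataset",
]

#: Cone-crop failure years applied by default (southern region rule).
DEFAULT_FAILURE_YEARS = frozenset({1990, 1994, 1997, 1999, 2001, 2005, 2009, 2013})

#: Generative covariate weights on the 2-SD-scaled design (log scale), the
#: posterior means of the full analysis these simulations emulate.
DEFAULT_BETA = {
    "intercept": -1.73,
    "marten_density": 0.22,
    "goshawk_kernel": 0.11,
    "cone_index": 0.37,
    "triangle_type": -0.57,
    "temperature": 0.30,
    "precipitation": -0.24,
}


@dataclass(frozen=True)
class StudyRegion:
    """Rectangular planar study region in km.

    ``southern_cut_y_km`` is the latitude line below which "southern" rules
    (cone-failure imputation, preferential field-triangle placement) apply.
    The default is a Finland-sized rectangle with the southern boundary at
    roughly the latitude dividing the cone-monitoring regions.
    """

    width_km: float = 600.0
    height_km: float = 1100.0
    southern_cut_y_km: float = 420.0

    def __post_init__(self):
        if self.width_km <= 0 or self.height_km <= 0:
            raise ValueError("region dimensions must be positive")
        if not 0 <= self.southern_cut_y_km <= self.height_km:
            raise ValueError("southern_cut_y_km must lie inside the region")

    @property
    def area_km2(self) -> float:
        return self.width_km * self.height_km


@dataclass
class GenerativeConfig:
    """All knobs of the synthetic monitoring scheme.

    Defaults are the study conditions the analysis assumes: ~1,900 transects
    with ~29 winters and roughly 550 censused per year, covariate weights at
    the published posterior means, a 655-km spatial range, strong temporal
    persistence, and 2–4 nests / 100 km².
    """

    beta: dict = dc_field(default_factory=lambda: dict(DEFAULT_BETA))
    matern_range_km: float = 655.0
    field_sd: float = 1.0
    ar1_rho: float = 0.99
    nb_overdispersion: float = 1.0
    n_wildlife: int = 1400
    n_field: int = 500
    n_years: int = 29
    start_year: int = 1989
    census_prob_per_year: float = 0.29
    failure_years: frozenset = DEFAULT_FAILURE_YEARS
    nest_density_per_100km2: float = 3.0
    nest_persistence_prob: float = 0.9
    n_cone_sites: int = 92
    cone_missing_frac: float = 0.5
    cone_year_sd: float = 1.0
    cone_spatial_range_km: float = 300.0
    cone_spatial_sd: float = 0.5
    habitat_range_km: float = 150.0
    habitat_sd: float = 0.4
    marten_intercept: float = -1.0
    kernel_params: KernelParams = dc_field(default_factory=KernelParams)
    seed: int = 0

    def validate(self) -> None:
        if self.n_wildlife < 0 or self.n_field < 0 or self.n_wildlife + self.n_field < 2:
            raise ValueError("need at least two transects in total")
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")
        if not 0 < self.census_prob_per_year <= 1:
            raise ValueError("census_prob_per_year must be in (0, 1]")
        if self.matern_range_km <= 0 or self.field_sd < 0:
            raise ValueError("field hyperparameters must be positive")
        if not -1 < self.ar1_rho < 1:
            raise ValueError("ar1_rho must be in (-1, 1)")
        if self.nb_overdispersion <= 0:
            raise ValueError("nb_overdispersion must be positive")
        if self.nest_density_per_100km2 <= 0:
            raise ValueError("nest density must be positive")
        if not 0 <= self.cone_missing_frac <= 1:
            raise ValueError("cone_missing_frac must be a probability")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.start_year + self.n_years)

    def to_json_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["failure_years"] = sorted(int(y) for y in self.failure_years)
        d["kernel_params"] = dataclasses.asdict(self.kernel_params)
        return d


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def generate_region_and_triangles(config: GenerativeConfig, region: StudyRegion,
                                  rng=None) -> pd.DataFrame:
    """Transect skeletons (geometry + census flags) for every year.

    Wildlife triangles (12 km perimeter) are placed uniformly over the
    region; field triangles (6 km) go to the southern band with probability
    0.85 and are skewed westward within it, mimicking the concentration of
    farmland transects in the south-west.  Each transect is independently
    censused each year with ``census_prob_per_year``.
    """
    config.validate()
    rng = _rng(config.seed if rng is None else rng)
    n_w, n_f = config.n_wildlife, config.n_field

    xw = rng.uniform(0, region.width_km, n_w)
    yw = rng.uniform(0, region.height_km, n_w)

    south = rng.random(n_f) < 0.85
    xf = region.width_km * rng.beta(1.0, 2.0, n_f)  # westward skew
    yf = np.where(south,
                  rng.uniform(0, region.southern_cut_y_km, n_f),
                  rng.uniform(region.southern_cut_y_km, region.height_km, n_f))

    tri = pd.DataFrame({
        "triangle_id": [f"W{i:05d}" for i in range(n_w)] + [f"F{i:05d}" for i in range(n_f)],
        "triangle_type": ["wildlife"] * n_w + ["field"] * n_f,
        "x_km": np.concatenate([xw, xf]),
        "y_km": np.concatenate([yw, yf]),
        "length_km": np.array([12.0] * n_w + [6.0] * n_f),
    })

    years = config.years
    skel = tri.loc[tri.index.repeat(len(years))].reset_index(drop=True)
    skel["year"] = np.tile(years, len(tri))
    skel["censused"] = rng.random(len(skel)) < config.census_prob_per_year
    return skel


def simulate_matern_ar1_field(coords: np.ndarray, n_years: int, range_km: float,
                              field_sd: float, rho: float, rng) -> np.ndarray:
    """Draw a zero-mean separable Matérn(nu=1) x AR1 field.

    Returns an array of shape ``(n_years, n_sites)`` whose covariance is
    ``field_sd**2 * Matern(d; range_km) * rho**|t-t'|``; the AR1 recursion is
    initialised at stationarity so every ``w(s, t)`` has marginal variance
    ``field_sd**2``.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or len(coords) < 2:
        raise ValueError("need at least two sites")
    if not -1 < rho < 1:
        raise ValueError("|rho| must be < 1")
    rng = _rng(rng)
    from scipy.spatial.distance import pdist
    if len(coords) > 1 and pdist(coords).min() == 0.0:
        raise ValueError("singular spatial covariance: duplicate site coordinates")
    M = matern_matrix(coords, range_km)
    try:
        L = np.linalg.cholesky(M + 1e-10 * np.eye(len(M)))
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular spatial covariance (duplicate site coordinates?)") from exc
    S = len(coords)
    w = np.empty((n_years, S))
    w[0] = L @ rng.standard_normal(S)
    innov_scale = np.sqrt(1.0 - rho ** 2)
    for t in range(1, n_years):
        w[t] = rho * w[t - 1] + innov_scale * (L @ rng.standard_normal(S))
    return field_sd * w


def _cone_log_process(coords: np.ndarray, n_years: int, rng,
                      year_sd: float, spatial_range_km: float, spatial_sd: float,
                      base_log: float = np.log(10.0), site_noise_sd: float = 0.3):
    """Latent log cone crop at arbitrary coordinates: shared lognormal year
    effect x smooth static spatial surface x small site-year noise."""
    coords = np.asarray(coords, dtype=float)
    year_eff = rng.normal(0.0, year_sd, n_years)
    M = matern_matrix(coords, spatial_range_km)
    L = np.linalg.cholesky(M + 1e-10 * np.eye(len(M)))
    surface = spatial_sd * (L @ rng.standard_normal(len(coords)))
    noise = rng.normal(0.0, site_noise_sd, (n_years, len(coords)))
    return base_log + year_eff[:, None] + surface[None, :] + noise


def simulate_cone_series(sites: pd.DataFrame, years, failure_years, rng,
                         southern_cut_y_km: float = 420.0,
                         missing_frac: float = 0.5,
                         year_sd: float = 1.0,
                         spatial_range_km: float = 300.0,
                         spatial_sd: float = 0.5) -> pd.DataFrame:
    """Cone counts per tree at monitoring sites, with masting failure years.

    ``sites`` needs columns ``site_id``, ``x_km``, ``y_km``.  In failure
    years, southern sites (y < ``southern_cut_y_km``) crop exactly 0 and a
    fraction ``missing_frac`` of those zeros is recorded as missing instead —
    emulating censuses skipped for want of cones, the gap the downstream
    zero-imputation rule exists to fill.
    """
    years = np.asarray(list(years), dtype=int)
    failure_years = set(int(y) for y in failure_years)
    if not failure_years <= set(years.tolist()) and failure_years:
        failure_years = failure_years & set(years.tolist())
    rng = _rng(rng)
    coords = sites[["x_km", "y_km"]].to_numpy(dtype=float)
    logc = _cone_log_process(coords, len(years), rng, year_sd,
                             spatial_range_km, spatial_sd)
    values = np.exp(logc)  # (T, S)
    south = coords[:, 1] < southern_cut_y_km
    rows = []
    for ti, yr in enumerate(years):
        v = values[ti].copy()
        if int(yr) in failure_years:
            v[south] = 0.0
            miss = south & (rng.random(len(v)) < missing_frac)
            v[miss] = np.nan
        rows.append(pd.DataFrame({
            "site_id": sites["site_id"].to_numpy(),
            "x_km": coords[:, 0],
            "y_km": coords[:, 1],
            "year": int(yr),
            "cones_per_tree": v,
        }))
    return pd.concat(rows, ignore_index=True)


def simulate_nests(region: StudyRegion, years, nest_density_per_100km2: float,
                   persistence_prob: float, rng) -> pd.DataFrame:
    """Raptor nest territories: homogeneous Poisson pattern with persistence.

    The number of territories is Poisson with mean density x area; each is
    occupied in the first year and stays occupied from one year to the next
    with ``persistence_prob`` (abandonment is permanent, matching the
    decades-long territory fidelity the kernel's occupancy window encodes).
    """
    if nest_density_per_100km2 <= 0:
        raise ValueError("nest density must be positive")
    years = np.asarray(list(years), dtype=int)
    rng = _rng(rng)
    n = rng.poisson(nest_density_per_100km2 * region.area_km2 / 100.0)
    x = rng.uniform(0, region.width_km, n)
    y = rng.uniform(0, region.height_km, n)
    occupied = np.ones((len(years), n), dtype=bool)
    for ti in range(1, len(years)):
        occupied[ti] = occupied[ti - 1] & (rng.random(n) < persistence_prob)
    rows = []
    for ti, yr in enumerate(years):
        rows.append(pd.DataFrame({
            "nest_id": [f"N{i:05d}" for i in range(n)],
            "x_km": x,
            "y_km": y,
            "year": int(yr),
            "occupied": occupied[ti],
        }))
    return pd.concat(rows, ignore_index=True)


def _simulate_weather(skel: pd.DataFrame, rng, cell_km: float = 10.0) -> pd.DataFrame:
    """Previous-day weather on a 10x10 km lattice sampled at the transects.

    Mid-winter temperature declines northward (smooth gradient) with a
    shared year effect and day-level cell noise; precipitation is lognormal
    cell-by-cell.  Transects in the same lattice cell and year share values.
    """
    out = skel.copy()
    cy = (skel["y_km"] // cell_km).astype(int)
    cx = (skel["x_km"] // cell_km).astype(int)
    key = pd.DataFrame({"cx": cx, "cy": cy, "year": skel["year"]})
    uniq = key.drop_duplicates().reset_index(drop=True)
    years = np.sort(skel["year"].unique())
    year_off = dict(zip(years, rng.normal(0.0, 2.0, len(years))))
    temp_u = (-4.0 - 8.0 * (uniq["cy"] * cell_km) / max(skel["y_km"].max(), 1.0)
              + uniq["year"].map(year_off).to_numpy()
              + rng.normal(0.0, 3.0, len(uniq)))
    prec_u = np.exp(rng.normal(np.log(2.0), 0.8, len(uniq)))
    uniq["temperature_prev_day"] = np.round(temp_u, 2)
    uniq["precipitation_prev_day"] = np.round(prec_u, 2)
    merged = key.merge(uniq, on=["cx", "cy", "year"], how="left")
    out["temperature_prev_day"] = merged["temperature_prev_day"].to_numpy()
    out["precipitation_prev_day"] = merged["precipitation_prev_day"].to_numpy()
    return out


class MissingCovariateError(ValueError):
    """A censused transect-year lacks a covariate required by the model."""


def two_sd_scale(x: np.ndarray):
    """Centre and divide by twice the SD (so the column has SD 0.5),
    putting numeric covariates on the scale of a binary indicator."""
    x = np.asarray(x, dtype=float)
    m, s = float(np.mean(x)), float(np.std(x, ddof=0))
    if s == 0:
        raise ValueError("cannot 2-SD-scale a constant column")
    return (x - m) / (2.0 * s), m, s


def simulate_counts(skeletons: pd.DataFrame, config: GenerativeConfig,
                    field_values: np.ndarray | None, rng) -> np.ndarray:
    """Negative-binomial track counts for censused rows.

    ``skeletons`` must carry one column per covariate named in
    ``config.beta`` (already on the scale the weights refer to) plus
    ``length_km``; ``field_values`` is the latent field value per row (or
    None for no field).  Counts are NB2: mean ``mu``, variance
    ``mu + mu**2 / alpha``, drawn as a gamma-mixed Poisson.
    """
    rng = _rng(rng)
    eta = np.log(skeletons["length_km"].to_numpy(dtype=float))
    for name, b in config.beta.items():
        if name == "intercept":
            eta = eta + b
            continue
        if name not in skeletons.columns:
            raise MissingCovariateError(f"covariate {name!r} absent from skeleton table")
        col = skeletons[name].to_numpy(dtype=float)
        if np.any(~np.isfinite(col)):
            i = int(np.flatnonzero(~np.isfinite(col))[0])
            raise MissingCovariateError(
                f"missing covariate {name!r} for triangle "
                f"{skeletons['triangle_id'].iloc[i]} year {skeletons['year'].iloc[i]}")
        eta = eta + b * col
    if field_values is not None:
        eta = eta + np.asarray(field_values, dtype=float)
    mu = np.exp(eta)
    alpha = config.nb_overdispersion
    if np.isinf(alpha):
        return rng.poisson(mu)
    lam = rng.gamma(shape=alpha, scale=mu / alpha)
    return rng.poisson(lam)


def simulate_dataset(config: GenerativeConfig, region: StudyRegion | None = None):
    """End-to-end synthetic data set.

    Returns a dict with keys ``census`` (one row per transect x year;
    counts and weather only on censused rows), ``nests``, ``cones``,
    ``truth`` (config echo plus the realized covariate scaling and, for
    engine-level testing, the true scaled design of the censused rows).
    """
    config.validate()
    region = region or StudyRegion()
    rng = np.random.default_rng(config.seed)

    skel = generate_region_and_triangles(config, region, rng)
    years = config.years
    y0, y1 = int(years[0]), int(years[-1])

    # nests and cones are collected in the years preceding each census winter
    nest_years = range(y0 - 5, y1)
    nests = simulate_nests(region, nest_years, config.nest_density_per_100km2,
                           config.nest_persistence_prob, rng)

    cone_years = np.arange(y0 - 1, y1)
    cone_sites = pd.DataFrame({
        "site_id": [f"C{i:03d}" for i in range(config.n_cone_sites)],
        "x_km": rng.uniform(0, region.width_km, config.n_cone_sites),
        "y_km": rng.uniform(0, region.height_km, config.n_cone_sites),
    })

    # joint latent cone process at monitoring sites and transects, so the
    # generative covariate at a transect is the true (not interpolated) crop
    tri = skel[["triangle_id", "x_km", "y_km"]].drop_duplicates("triangle_id")
    all_coords = np.vstack([cone_sites[["x_km", "y_km"]].to_numpy(),
                            tri[["x_km", "y_km"]].to_numpy()])
    logc = _cone_log_process(all_coords, len(cone_years), rng,
                             config.cone_year_sd, config.cone_spatial_range_km,
                             config.cone_spatial_sd)
    cone_vals = np.exp(logc)
    n_cs = len(cone_sites)
    failure = set(int(y) for y in config.failure_years)
    south_sites = cone_sites["y_km"].to_numpy() < region.southern_cut_y_km
    south_tri = tri["y_km"].to_numpy() < region.southern_cut_y_km

    cone_rows = []
    tri_cone = {}  # (triangle_id, autumn year) -> true crop
    for ti, yr in enumerate(cone_years):
        v = cone_vals[ti, :n_cs].copy()
        tv = cone_vals[ti, n_cs:].copy()
        if int(yr) in failure:
            v[south_sites] = 0.0
            tv[south_tri] = 0.0
            miss = south_sites & (rng.random(n_cs) < config.cone_missing_frac)
            v[miss] = np.nan
        cone_rows.append(pd.DataFrame({
            "site_id": cone_sites["site_id"],
            "x_km": cone_sites["x_km"],
            "y_km": cone_sites["y_km"],
            "year": int(yr),
            "cones_per_tree": np.round(v, 3),
        }))
        for tid, val in zip(tri["triangle_id"], tv):
            tri_cone[(tid, int(yr))] = val
    cones = pd.concat(cone_rows, ignore_index=True)

    skel = _simulate_weather(skel, rng)

    # shared habitat-quality surface: both species like the same forests
    tri_coords = tri[["x_km", "y_km"]].to_numpy()
    Mh = matern_matrix(tri_coords, config.habitat_range_km)
    Lh = np.linalg.cholesky(Mh + 1e-10 * np.eye(len(Mh)))
    habitat = config.habitat_sd * (Lh @ rng.standard_normal(len(tri)))
    hab_by_tid = dict(zip(tri["triangle_id"], habitat))

    # marten counts: independent log-Gaussian intensity on the shared surface
    eta_m = (config.marten_intercept
             + skel["triangle_id"].map(hab_by_tid).to_numpy()
             + rng.normal(0.0, 0.5, len(skel)))
    marten_counts = rng.poisson(skel["length_km"].to_numpy() * np.exp(eta_m))

    # predation-pressure covariate from the simulated nests (true shape)
    kc = kernel_covariate(skel, nests, config.kernel_params)
    skel = skel.merge(kc.rename(columns={"kernel_value": "goshawk_kernel_raw"}),
                      on=["triangle_id", "year"], how="left")

    # latent spatiotemporal field at every transect x year
    w = simulate_matern_ar1_field(tri_coords, len(years), config.matern_range_km,
                                  config.field_sd, config.ar1_rho, rng)
    tid_ix = {tid: i for i, tid in enumerate(tri["triangle_id"])}
    yr_ix = {int(y): t for t, y in enumerate(years)}
    w_rows = w[[yr_ix[int(y)] for y in skel["year"]],
               [tid_ix[t] for t in skel["triangle_id"]]]

    cens_mask = skel["censused"].to_numpy()
    cens = skel[cens_mask].copy()
    cens["marten_density_raw"] = marten_counts[cens_mask] / cens["length_km"].to_numpy()
    cens["cone_index_raw"] = [
        tri_cone[(tid, int(yr) - 1)] for tid, yr in zip(cens["triangle_id"], cens["year"])
    ]
    cens["triangle_type_ind"] = (cens["triangle_type"] == "wildlife").astype(float)

    raw_of = {
        "marten_density": "marten_density_raw",
        "goshawk_kernel": "goshawk_kernel_raw",
        "cone_index": "cone_index_raw",
        "temperature": "temperature_prev_day",
        "precipitation": "precipitation_prev_day",
    }
    scaling = {}
    design = pd.DataFrame({
        "triangle_id": cens["triangle_id"], "year": cens["year"],
        "length_km": cens["length_km"],
    })
    for name in config.beta:
        if name == "intercept":
            continue
        if name == "triangle_type":
            design[name] = cens["triangle_type_ind"].to_numpy()
            continue
        if name == "x":
            raw = cens["x_km"].to_numpy(dtype=float)
        elif name == "y":
            raw = cens["y_km"].to_numpy(dtype=float)
        elif name == "xy":
            raw = cens["x_km"].to_numpy(dtype=float) * cens["y_km"].to_numpy(dtype=float)
        else:
            raw = cens[raw_of[name]].to_numpy(dtype=float)
        scaled, m, s = two_sd_scale(raw)
        design[name] = scaled
        scaling[name] = {"mean": m, "sd": s}

    counts = simulate_counts(design, config, w_rows[cens_mask], rng)

    census = skel.copy()
    census["squirrel_tracks"] = pd.array([pd.NA] * len(census), dtype="Int64")
    census.loc[cens_mask, "squirrel_tracks"] = counts
    census["marten_tracks"] = pd.array([pd.NA] * len(census), dtype="Int64")
    census.loc[cens_mask, "marten_tracks"] = marten_counts[cens_mask]
    census.loc[~cens_mask, ["temperature_prev_day", "precipitation_prev_day"]] = np.nan
    census = census.drop(columns=["goshawk_kernel_raw"])
    census["x_km"] = np.round(census["x_km"], 3)
    census["y_km"] = np.round(census["y_km"], 3)

    truth = {
        "config": config.to_json_dict(),
        "region": dataclasses.asdict(region),
        "scaling": scaling,
    }
    design_out = design.copy()
    design_out["squirrel_tracks"] = counts
    design_out["w_true"] = w_rows[cens_mask]
    return {
        "census": census.reset_index(drop=True),
        "nests": nests,
        "cones": cones,
        "truth": truth,
        "true_design": design_out.reset_index(drop=True),
    }
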