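"""Design-matrix assembly: resource surfaces, densities, lags and scaling.

The count model's covariates are prepared here: per-km track densities, the
cone-crop index interpolated from monitoring sites to transects by
thin-plate-spline regression (with zero imputation of missing southern
observations in listed crop-failure years), previous-day weather, the
predation-kernel covariate, and the triangle-type indicator.  Lag structure:
a census made in the winter of year *y* is explained by the cone crop of
autumn *y − 1* and nest occupancy of summer *y − 1* and earlier (the latter
handled inside the kernel itself).

Numeric covariates are centred and divided by twice their standard
deviation, so their weights are directly comparable to that of the binary
triangle-type indicator (which stays unscaled, wildlife = 1, field = 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.interpolate import RBFInterpolator

from .simulate import DEFAULT_FAILURE_YEARS

__all__ = [
    "DesignMatrix",
    "track_density",
    "impute_failure_zeros",
    "interpolate_cone_surface",
    "assemble_design",
]

#: Covariates of the full model, in reporting order.
DEFAULT_COVARIATES = ("marten_density", "goshawk_kernel", "cone_index",
                      "triangle_type", "temperature", "precipitation")


@dataclass
class DesignMatrix:
    """Analysis-ready design: one row per censused transect-year.

    ``data`` holds identifiers (triangle_id, year, x_km, y_km), the response
    ``squirrel_tracks``, and one column per entry of ``covariates`` already
    on the fitted scale.  ``offset`` is ``log(length_km)`` per row.
    ``scaling`` maps each scaled column to the mean/SD used (binary columns
    are absent from it), and ``drops`` ledgers every excluded row with its
    reason.
    """

    data: pd.DataFrame
    covariates: tuple
    offset: np.ndarray
    scaling: dict = dc_field(default_factory=dict)
    drops: pd.DataFrame | None = None

    def matrix(self, with_intercept: bool = True) -> np.ndarray:
        X = self.data[list(self.covariates)].to_numpy(dtype=float)
        if with_intercept:
            X = np.column_stack([np.ones(len(X)), X])
        return X

    @property
    def response(self) -> np.ndarray:
        return self.data["squirrel_tracks"].to_numpy(dtype=float)

    def unscale(self, name: str, scaled_value):
        """Invert the 2-SD scaling for one column."""
        meta = self.scaling[name]
        return np.asarray(scaled_value) * 2.0 * meta["sd"] + meta["mean"]


def track_density(count, length_km):
    """Snow tracks per km of census line."""
    length = np.asarray(length_km, dtype=float)
    if np.any(length <= 0):
        raise ValueError("transect length must be positive")
    c = np.asarray(count, dtype=float)
    if np.any(c[np.isfinite(c)] < 0):
        raise ValueError("counts must be non-negative")
    out = c / length
    return float(out) if np.isscalar(count) else out


def impute_failure_zeros(cones: pd.DataFrame,
                         failure_years=DEFAULT_FAILURE_YEARS,
                         southern_cut_y_km: float = 420.0) -> pd.DataFrame:
    """Replace missing southern cone records with zeros in crop-failure years.

    In the listed failure years a missing southern observation effectively
    means the census was skipped because there were no cones, so those cells
    become 0; all other missing values stay missing and present values are
    never touched.
    """
    out = cones.copy()
    mask = (out["cones_per_tree"].isna()
            & out["year"].isin(set(int(y) for y in failure_years))
            & (out["y_km"] < southern_cut_y_km))
    out.loc[mask, "cones_per_tree"] = 0.0
    return out


def _tps(points: np.ndarray, values: np.ndarray, smoothing: float) -> RBFInterpolator:
    return RBFInterpolator(points, values, kernel="thin_plate_spline",
                           smoothing=smoothing, degree=1)


def _gcv_smoothing(points: np.ndarray, values: np.ndarray,
                   grid=tuple(10.0 ** e for e in range(-6, 4))) -> float:
    """Pick the TPS smoothing parameter by generalized cross-validation.

    The influence matrix S(lambda) is obtained by fitting the spline to the
    identity matrix (one output per site); GCV(lambda) =
    n ||(I - S) y||^2 / (n - tr S)^2.
    """
    n = len(values)
    best_lam, best_score = 0.0, np.inf
    eye = np.eye(n)
    for lam in grid:
        S = _tps(points, eye, lam)(points)
        tr = float(np.trace(S))
        if n - tr < 1e-8:
            continue
        resid = values - S @ values
        score = n * float(resid @ resid) / (n - tr) ** 2
        if score < best_score:
            best_lam, best_score = lam, score
    return best_lam


def interpolate_cone_surface(cones_year: pd.DataFrame, targets: np.ndarray,
                             smoothing="gcv", year=None) -> np.ndarray:
    """Thin-plate-spline cone surface for one autumn, evaluated at targets.

    Missing observations are excluded from the fit.  ``smoothing`` is
    ``"gcv"`` (default), ``"exact"`` (interpolating spline) or a non-negative
    float.  Negative predictions are clamped to 0.  Raises if fewer than 4
    sites with values remain or the sites are collinear.
    """
    obs = cones_year.dropna(subset=["cones_per_tree"])
    label = f"year {year}" if year is not None else "this year"
    if len(obs) < 4:
        raise ValueError(f"too few cone observations to interpolate for {label}")
    pts = obs[["x_km", "y_km"]].to_numpy(dtype=float)
    vals = obs["cones_per_tree"].to_numpy(dtype=float)
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError(f"cone sites are collinear for {label}; TPS is degenerate")
    if smoothing == "gcv":
        lam = _gcv_smoothing(pts, vals)
    elif smoothing == "exact":
        lam = 0.0
    else:
        lam = float(smoothing)
    pred = _tps(pts, vals, lam)(np.asarray(targets, dtype=float))
    return np.maximum(pred, 0.0)


def _two_sd(x: np.ndarray):
    m, s = float(np.mean(x)), float(np.std(x, ddof=0))
    if s == 0:
        raise ValueError("cannot 2-SD-scale a constant column")
    return (x - m) / (2.0 * s), {"mean": m, "sd": s}


def assemble_design(census: pd.DataFrame,
                    kernel_cov: pd.DataFrame,
                    cones: pd.DataFrame,
                    covariates=DEFAULT_COVARIATES,
                    include_xy: bool = False,
                    southern_cut_y_km: float = 420.0,
                    failure_years=DEFAULT_FAILURE_YEARS,
                    tps_smoothing="gcv",
                    include_marten_lag: bool = False) -> DesignMatrix:
    """Build the scaled design matrix from the raw tables.

    ``census`` follows the census-record schema; ``kernel_cov`` has columns
    (triangle_id, year, kernel_value) with the year being the census year;
    ``cones`` the cone-observation schema (autumn years).  Rows that are not
    valid censuses, or that lack any included covariate, are dropped and
    ledgered.  Coordinate covariates (x, y, x*y) are appended when
    ``include_xy`` and scaled like any numeric column.
    """
    cens = census[census["censused"].astype(bool)].copy()
    drops = []
    if cens.empty:
        raise ValueError("no valid censused rows")

    cones_imp = impute_failure_zeros(cones, failure_years, southern_cut_y_km)

    cens = cens.merge(kernel_cov.rename(columns={"kernel_value": "goshawk_kernel"}),
                      on=["triangle_id", "year"], how="left")
    cens["marten_density"] = track_density(
        cens["marten_tracks"].to_numpy(dtype=float), cens["length_km"])
    cens["triangle_type"] = (cens["triangle_type"] == "wildlife").astype(float)
    cens["temperature"] = cens["temperature_prev_day"]
    cens["precipitation"] = cens["precipitation_prev_day"]

    # cone index: autumn y-1 surface intersected at the census transects
    cens["cone_index"] = np.nan
    cone_years = set(cones_imp["year"].unique().tolist())
    for yr, grp in cens.groupby("year"):
        autumn = int(yr) - 1
        if autumn not in cone_years:
            continue
        cy = cones_imp[cones_imp["year"] == autumn]
        try:
            vals = interpolate_cone_surface(
                cy, grp[["x_km", "y_km"]].to_numpy(dtype=float),
                smoothing=tps_smoothing, year=autumn)
        except ValueError:
            continue  # too few sites that autumn: rows drop as missing
        cens.loc[grp.index, "cone_index"] = vals

    if include_marten_lag:
        lag = cens[["triangle_id", "year", "marten_density"]].copy()
        lag["year"] = lag["year"] + 1
        lag = lag.rename(columns={"marten_density": "marten_density_lag1"})
        cens = cens.merge(lag, on=["triangle_id", "year"], how="left")

    covs = list(covariates)
    if include_marten_lag and "marten_density_lag1" not in covs:
        covs.append("marten_density_lag1")
    if include_xy:
        cens["x"] = cens["x_km"].astype(float)
        cens["y"] = cens["y_km"].astype(float)
        cens["xy"] = cens["x"] * cens["y"]
        covs += [c for c in ("x", "y", "xy") if c not in covs]

    needed = covs + ["squirrel_tracks"]
    for col in needed:
        if col not in cens.columns:
            raise ValueError(f"covariate column {col!r} cannot be built from inputs")
        bad = cens[col].isna()
        if bad.any():
            for _, row in cens.loc[bad, ["triangle_id", "year"]].iterrows():
                drops.append({"triangle_id": row["triangle_id"],
                              "year": int(row["year"]),
                              "reason": f"missing {col}"})
            cens = cens[~bad]
    if cens.empty:
        raise ValueError("no complete-case rows left after filtering")

    scaling = {}
    for col in covs:
        if col == "triangle_type":
            continue  # binary indicator stays unscaled
        scaled, meta = _two_sd(cens[col].to_numpy(dtype=float))
        cens[col] = scaled
        scaling[col] = meta

    keep = ["triangle_id", "triangle_type", "year", "x_km", "y_km",
            "length_km", "squirrel_tracks"] + [c for c in covs if c != "triangle_type"]
    data = cens[keep].reset_index(drop=True)
    data["squirrel_tracks"] = data["squirrel_tracks"].astype(int)
    offset = np.log(data["length_km"].to_numpy(dtype=float))
    return DesignMatrix(data=data, covariates=tuple(covs), offset=offset,
                        scaling=scaling,
                        drops=pd.DataFrame(drops, columns=["triangle_id", "year", "reason"]))
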