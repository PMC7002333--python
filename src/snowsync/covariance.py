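"""Spatial and temporal correlation primitives shared by the simulator and the model.

The spatial process uses the Matérn family with smoothness ``nu = 1``; its
"range" is parameterised as ``sqrt(8) / kappa``, the distance at which the
correlation has dropped to roughly 0.14 and spatial dependence is considered
negligible.  The temporal process is a stationary first-order autoregression
(AR1) with unit marginal variance, or its intrinsic random-walk (RW1) limit.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform
from scipy.special import kv

__all__ = [
    "matern_correlation",
    "matern_matrix",
    "ar1_correlation_matrix",
    "temporal_precision",
]

#: Matérn nu=1 correlation at d == range: sqrt(8) * K_1(sqrt(8))
RANGE_CORRELATION = float(np.sqrt(8.0) * kv(1, np.sqrt(8.0)))


def matern_correlation(d_km, range_km: float):
    """Matérn (nu = 1) correlation at distance ``d_km`` for a given range.

    With ``kappa = sqrt(8) / range_km`` the correlation is
    ``(kappa d) K_1(kappa d)`` where ``K_1`` is the modified Bessel function
    of the second kind; it equals 1 at zero distance and ~0.14 at
    ``d == range_km``.
    """
    if range_km <= 0:
        raise ValueError("range_km must be positive")
    d = np.asarray(d_km, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    kappa = np.sqrt(8.0) / range_km
    x = kappa * d
    with np.errstate(invalid="ignore", over="ignore"):
        rho = np.where(x > 0, x * kv(1, np.where(x > 0, x, 1.0)), 1.0)
    # K_1 underflows for very large arguments; the limit is 0.
    rho = np.nan_to_num(rho, nan=0.0, posinf=0.0, neginf=0.0)
    out = np.clip(rho, 0.0, 1.0)
    return float(out) if np.isscalar(d_km) else out


def matern_matrix(coords: np.ndarray, range_km: float, coords2: np.ndarray | None = None) -> np.ndarray:
    """Matérn (nu=1) correlation matrix between site coordinates (km)."""
    coords = np.asarray(coords, dtype=float)
    if coords2 is None:
        d = squareform(pdist(coords))
    else:
        d = cdist(coords, np.asarray(coords2, dtype=float))
    return matern_correlation(d, range_km)


def ar1_correlation_matrix(n_years: int, rho: float) -> np.ndarray:
    """Stationary AR1 correlation matrix ``rho ** |t - t'|`` (unit variance)."""
    if not (-1.0 < rho < 1.0):
        raise ValueError("AR1 coefficient must lie in (-1, 1)")
    t = np.arange(n_years)
    return rho ** np.abs(t[:, None] - t[None, :])


def temporal_precision(n_years: int, process: str, rho: float | None = None,
                       rw1_ridge: float = 1e-5) -> np.ndarray:
    """Precision matrix of the unit-variance temporal process.

    AR1: the analytic tridiagonal inverse of the stationary correlation
    matrix.  RW1: the first-difference (path-graph Laplacian) precision made
    proper by a small diagonal ridge, which acts as a diffuse prior on the
    overall level in place of an explicit sum-to-zero constraint.  "none":
    temporally independent replicates (identity).
    """
    T = int(n_years)
    if T < 1:
        raise ValueError("need at least one year")
    if process == "none":
        return np.eye(T)
    if process == "RW1":
        D = np.diff(np.eye(T), axis=0)
        return D.T @ D + rw1_ridge * np.eye(T)
    if process == "AR1":
        if rho is None or not (-1.0 < rho < 1.0):
            raise ValueError("AR1 requires |rho| < 1")
        Q = np.zeros((T, T))
        if T == 1:
            Q[0, 0] = 1.0
            return Q
        idx = np.arange(T)
        Q[idx, idx] = 1.0 + rho ** 2
        Q[0, 0] = Q[-1, -1] = 1.0
        Q[idx[:-1], idx[1:]] = -rho
        Q[idx[1:], idx[:-1]] = -rho
        return Q / (1.0 - rho ** 2)
    raise ValueError(f"unknown temporal process {process!r}")
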