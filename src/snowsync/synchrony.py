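"""Per-year Moran's I correlograms for spatial synchrony.

Synchrony between sites is quantified by Moran's I computed within 20-km
distance bins up to 750 km, separately for each year (site-level time
series contain missing values, so per-year statistics are preferable to a
multivariate correlogram), with the across-year standard deviation pooled
per bin.  Under spatial independence the expectation of Moran's I is
``-1/(n-1)``, slightly below zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = ["Correlogram", "morans_i", "correlogram"]


@dataclass
class Correlogram:
    """Per-year Moran's I by distance bin.

    ``table`` has one row per (bin, year) with columns bin_lo, bin_hi, year,
    I (NaN when the bin holds fewer than ``min_pairs`` pairs), n_pairs and
    the across-year pooled_sd of the bin.
    """

    table: pd.DataFrame
    bin_width_km: float
    max_dist_km: float
    min_pairs: int

    @property
    def bins(self) -> np.ndarray:
        return self.table[["bin_lo", "bin_hi"]].drop_duplicates().to_numpy()


def morans_i(values: np.ndarray, coords: np.ndarray, bin_interval,
             _dists: np.ndarray | None = None) -> float:
    """Moran's I with binary weights for site pairs inside a distance bin.

    ``I = (n / W) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2``
    with ``w_ij = 1`` when ``lo < d_ij <= hi`` and ``i != j``.  Returns NaN
    when the bin contains no pair; raises on zero-variance values.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least two sites")
    dev = x - x.mean()
    denom = float(dev @ dev)
    if denom == 0:
        raise ValueError("Moran's I is undefined for constant values")
    lo, hi = bin_interval
    D = squareform(pdist(np.asarray(coords, dtype=float))) if _dists is None else _dists
    W = (D > lo) & (D <= hi)
    np.fill_diagonal(W, False)
    w_sum = int(W.sum())
    if w_sum == 0:
        return np.nan
    num = float(dev @ (W @ dev))
    return (n / w_sum) * num / denom


def correlogram(panel: pd.DataFrame, bin_width_km: float = 20.0,
                max_dist_km: float = 750.0, min_pairs: int = 10,
                value_column: str = "value") -> Correlogram:
    """Per-year Moran's I correlogram of a site-indexed panel.

    ``panel`` needs columns x_km, y_km, year and ``value_column``; each
    year uses only the sites observed (non-missing) that year.  Bins are
    half-open ``(lo, hi]`` of ``bin_width_km`` covering (0, max_dist_km]
    (the last bin may be partial).  ``pooled_sd`` per bin is the unweighted
    SD of the per-year I values.
    """
    years = np.sort(panel["year"].unique())
    if len(years) < 2:
        raise ValueError("need at least two years for a correlogram")
    n_bins = int(np.ceil(max_dist_km / bin_width_km))
    edges = [(i * bin_width_km, min((i + 1) * bin_width_km, max_dist_km))
             for i in range(n_bins)]
    rows = []
    for yr in years:
        sub = panel[(panel["year"] == yr) & panel[value_column].notna()]
        x = sub[value_column].to_numpy(dtype=float)
        coords = sub[["x_km", "y_km"]].to_numpy(dtype=float)
        ok = len(x) >= 2 and np.ptp(x) > 0
        D = squareform(pdist(coords)) if ok else None
        for lo, hi in edges:
            if not ok:
                rows.append({"bin_lo": lo, "bin_hi": hi, "year": int(yr),
                             "I": np.nan, "n_pairs": 0})
                continue
            W = (D > lo) & (D <= hi)
            np.fill_diagonal(W, False)
            n_pairs = int(W.sum()) // 2
            if n_pairs < min_pairs:
                rows.append({"bin_lo": lo, "bin_hi": hi, "year": int(yr),
                             "I": np.nan, "n_pairs": n_pairs})
                continue
            I = morans_i(x, coords, (lo, hi), _dists=D)
            rows.append({"bin_lo": lo, "bin_hi": hi, "year": int(yr),
                         "I": I, "n_pairs": n_pairs})
    table = pd.DataFrame(rows)
    pooled = (table.groupby(["bin_lo", "bin_hi"])["I"]
              .std(ddof=1).rename("pooled_sd").reset_index())
    table = table.merge(pooled, on=["bin_lo", "bin_hi"], how="left")
    return Correlogram(table=table, bin_width_km=bin_width_km,
                       max_dist_km=max_dist_km, min_pairs=min_pairs)
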