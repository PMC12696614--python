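"""Per-cell trend detection and change significance for annual series.

Monotonic trends are detected with the nonparametric Mann-Kendall test
(two-sided, continuity-corrected normal approximation with the standard tie
correction of the score variance) and their magnitude is summarized with the
Theil-Sen median-of-pairwise-slopes estimator.  Long-term (aridity-style)
changes between the two halves of the study period are assessed by the
difference of half-period means against a permutation null of 300 random
re-partitions of the pooled values: the observed difference is significant
when it falls outside the null's 10th-90th percentile range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr
from scipy import stats

__all__ = [
    "TrendResult",
    "ChangeResult",
    "mann_kendall",
    "theil_sen",
    "period_mean_difference",
    "bootstrap_change_significance",
    "grid_trends",
]

DIRECTION_NONE = 0
DIRECTION_INCREASING = 1
DIRECTION_DECREASING = -1

#: a cell's series must retain at least this many valid years
MIN_VALID_YEARS = 10


class InsufficientDataError(ValueError):
    """Too few non-missing values for the requested statistic."""


@dataclass(frozen=True)
class TrendResult:
    """Mann-Kendall test outcome plus Theil-Sen slope for one series."""

    s: int
    var_s: float
    z: float
    p: float
    slope: float
    significant: bool
    direction: int  # +1 increasing, -1 decreasing, 0 none


@dataclass(frozen=True)
class ChangeResult:
    """Half-period mean difference against its permutation null."""

    observed: float
    null: np.ndarray
    significant: bool


def _valid(series) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(series, dtype=float).ravel()
    t = np.arange(x.size, dtype=float)
    keep = np.isfinite(x)
    return x[keep], t[keep]


def mann_kendall(series, alpha: float = 0.1) -> TrendResult:
    """Mann-Kendall trend test of an annual series (missing values dropped).

    S sums the signs of all pairwise differences; its variance carries the
    tie correction sum t_k (t_k - 1)(2 t_k + 5)/18, the normal deviate uses
    the +/-1 continuity correction, and the p-value is two-sided.  Requires
    at least 4 non-missing values; a constant series yields S = 0, p = 1.
    """
    x, t = _valid(series)
    n = x.size
    if n < 4:
        raise InsufficientDataError(f"Mann-Kendall needs >= 4 values, got {n}")

    diff = np.subtract.outer(x, x)  # diff[i, j] = x_i - x_j
    s = int(np.sign(diff[np.triu_indices(n, k=1)[::-1]]).sum())

    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1]
    var_s = (
        n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))
    ) / 18.0

    if s > 0:
        z = (s - 1) / np.sqrt(var_s)
    elif s < 0:
        z = (s + 1) / np.sqrt(var_s)
    else:
        z = 0.0
    if var_s == 0:  # all values tied
        z = 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    slope = theil_sen(x, t)
    direction = DIRECTION_NONE if s == 0 else (DIRECTION_INCREASING if s > 0 else DIRECTION_DECREASING)
    return TrendResult(
        s=s,
        var_s=float(var_s),
        z=float(z),
        p=float(p),
        slope=float(slope),
        significant=bool(p < alpha),
        direction=direction,
    )


def theil_sen(series, times=None) -> float:
    """Median of all pairwise slopes (x_j - x_i) / (t_j - t_i), i < j.

    ``times`` defaults to the series' integer positions, so missing values
    keep their original spacing when dropped.
    """
    if times is None:
        x, t = _valid(series)
    else:
        x = np.asarray(series, dtype=float).ravel()
        t = np.asarray(times, dtype=float).ravel()
        keep = np.isfinite(x)
        x, t = x[keep], t[keep]
    if x.size == 0:
        raise InsufficientDataError("all values missing")
    if np.unique(t).size < 2:
        raise InsufficientDataError("need >= 2 distinct time points")
    if np.ptp(x) == 0:
        return 0.0
    slope, *_ = stats.theilslopes(x, t)
    return float(slope)


def period_mean_difference(series, split_index: int) -> float:
    """mean(second half) - mean(first half), NaNs ignored within each half."""
    x = np.asarray(series, dtype=float).ravel()
    first, second = x[:split_index], x[split_index:]
    if np.isfinite(first).sum() == 0 or np.isfinite(second).sum() == 0:
        raise InsufficientDataError("a half-period has no valid values")
    return float(np.nanmean(second) - np.nanmean(first))


def bootstrap_change_significance(
    series,
    split_index: int,
    n_draws: int = 300,
    seed: int | np.random.Generator | None = None,
    replace: bool = False,
) -> ChangeResult:
    """Significance of the half-period mean difference via a resampling null.

    The pooled values are randomly re-partitioned ``n_draws`` times into
    pseudo-halves of the original sizes (without replacement by default, i.e.
    a permutation null; with replacement behind ``replace=True``) and the
    observed difference is compared with the null's strict 10th/90th
    percentiles.  Deterministic for a fixed seed.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    x = np.asarray(series, dtype=float).ravel()
    n1 = int(np.isfinite(x[:split_index]).sum())
    pool = x[np.isfinite(x)]
    if n1 < 2 or pool.size - n1 < 2:
        raise InsufficientDataError("each half needs >= 2 valid values")
    observed = period_mean_difference(x, split_index)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if replace:
        a = rng.choice(pool, size=(n_draws, n1), replace=True).mean(axis=1)
        b = rng.choice(pool, size=(n_draws, pool.size - n1), replace=True).mean(axis=1)
        null = b - a
    else:
        order = np.argsort(rng.random((n_draws, pool.size)), axis=1)
        perm = pool[order]
        null = perm[:, n1:].mean(axis=1) - perm[:, :n1].mean(axis=1)
    lo, hi = np.percentile(null, [10.0, 90.0])
    significant = bool(observed > hi or observed < lo)
    return ChangeResult(observed=observed, null=null, significant=significant)


def grid_trends(
    da: xr.DataArray,
    years: tuple[int, int] | None = None,
    alpha: float = 0.1,
    min_valid: int = MIN_VALID_YEARS,
) -> xr.Dataset:
    """Cell-wise Mann-Kendall + Theil-Sen over the selected year window.

    Cells with fewer than ``min_valid`` valid years are marked missing
    (NaN statistics, direction 0, not significant).
    """
    if years is not None:
        da = da.sel(year=slice(years[0], years[1]))
        if da.sizes["year"] == 0:
            raise ValueError(f"empty year range {years}")
    nlat, nlon = da.sizes["lat"], da.sizes["lon"]
    vals = da.values

    s = np.full((nlat, nlon), np.nan)
    var_s = np.full((nlat, nlon), np.nan)
    z = np.full((nlat, nlon), np.nan)
    p = np.full((nlat, nlon), np.nan)
    slope = np.full((nlat, nlon), np.nan)
    significant = np.zeros((nlat, nlon), dtype=bool)
    direction = np.zeros((nlat, nlon), dtype=np.int8)

    for i in range(nlat):
        for j in range(nlon):
            cell = vals[i, j]
            if np.isfinite(cell).sum() < min_valid:
                continue
            res = mann_kendall(cell, alpha=alpha)
            s[i, j] = res.s
            var_s[i, j] = res.var_s
            z[i, j] = res.z
            p[i, j] = res.p
            slope[i, j] = res.slope
            significant[i, j] = res.significant
            direction[i, j] = res.direction

    ds = xr.Dataset(
        {
            "s": (("lat", "lon"), s),
            "var_s": (("lat", "lon"), var_s),
            "z": (("lat", "lon"), z),
            "p": (("lat", "lon"), p),
            "slope": (("lat", "lon"), slope),
            "significant": (("lat", "lon"), significant),
            "direction": (("lat", "lon"), direction),
        },
        coords={"lat": da["lat"].values, "lon": da["lon"].values},
        attrs={"alpha": alpha, "variable": da.name or ""},
    )
    ds["direction"].attrs["codes"] = "-1:decreasing 0:none 1:increasing"
    return ds
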