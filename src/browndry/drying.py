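"""Derived water variables, drying agreement, greenness categories and
coincidence statistics.

Drying at a cell means decreasing water availability or increasing
atmospheric water demand: a significant decreasing trend in root-zone soil
moisture or precipitation, or a significant increasing trend in vapor
pressure deficit or the dryness index.  A cell counts as drying when at
least 2 of those 4 variables agree.  Greenness cells are categorized by the
sign and significance of the LAI trend, with cells masked out of the study
area when any decadal mean LAI falls below 0.5.  Coincidence maps intersect
browning with drying; area statistics weight cells by the cosine of their
center latitude; the spatial correspondence of two categorical maps is
measured by Cramer's V.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import xarray as xr
from scipy.stats.contingency import association

from .grid import cos_lat_weights

__all__ = [
    "compute_vpd",
    "compute_dryness_index",
    "classify_drying",
    "classify_greenness",
    "coincidence_map",
    "area_fraction",
    "cramers_v",
    "browning_drying_summary",
    "default_decades",
    "GREENNESS_CODES",
    "COINCIDENCE_CODES",
    "WATER_TREND_DIRECTIONS",
]

# Magnus / Tetens saturation vapor pressure over water, temperature in deg C,
# result in kPa (the 0.6108 coefficient fixes the unit).
_MAGNUS_A = 0.6108
_MAGNUS_B = 17.27
_MAGNUS_C = 237.3

LATENT_HEAT_VAPORIZATION = 2.45e6  # J kg-1
SECONDS_PER_YEAR = 365.25 * 86400.0

# Drying direction per water variable: -1 = significant decrease is drying
# (water availability), +1 = significant increase is drying (water demand).
WATER_TREND_DIRECTIONS = {
    "soil_moisture": -1,
    "precipitation": -1,
    "vpd": +1,
    "dryness_index": +1,
}

GREENNESS_CODES = {
    "masked": 0,
    "greening_significant": 1,
    "greening_nonsignificant": 2,
    "browning_significant": 3,
    "browning_nonsignificant": 4,
}
BROWNING_SIG = GREENNESS_CODES["browning_significant"]
BROWNING_ANY = (GREENNESS_CODES["browning_significant"], GREENNESS_CODES["browning_nonsignificant"])

COINCIDENCE_CODES = {
    "masked": 0,
    "neither": 1,
    "browning_only": 2,
    "drying_only": 3,
    "browning_and_drying": 4,
}


class VPDDomainError(ValueError):
    """Temperature at or below the Magnus singularity (-237.3 degC)."""


def saturation_vapor_pressure(t_celsius):
    """Magnus formula: e_s(T) = 0.6108 exp(17.27 T / (T + 237.3)), kPa."""
    t = np.asarray(t_celsius, dtype=float)
    if np.any(t[np.isfinite(t)] <= -_MAGNUS_C):
        raise VPDDomainError("temperature at or below -237.3 degC")
    return _MAGNUS_A * np.exp(_MAGNUS_B * t / (t + _MAGNUS_C))


def compute_vpd(t_air, t_dew, pascals: bool = False):
    """Vapor pressure deficit e_s(T) - e_a(Td) from air and dew-point temperature.

    Inputs in degrees Celsius; output in kPa (``pascals=True`` multiplies by
    1000).  Cells where Td exceeds T (supersaturation, a data artifact) are
    clipped to VPD = 0 and counted in ``attrs["n_clipped"]`` when the inputs
    are xarray objects.
    """
    es = saturation_vapor_pressure(np.asarray(t_air, dtype=float))
    ea = saturation_vapor_pressure(np.asarray(t_dew, dtype=float))
    vpd = es - ea
    n_clipped = int(np.sum(vpd < 0))
    vpd = np.clip(vpd, 0.0, None)
    if pascals:
        vpd = vpd * 1000.0
    if isinstance(t_air, xr.DataArray):
        out = t_air.copy(data=vpd)
        out.name = "vpd"
        out.attrs = {"units": "Pa" if pascals else "kPa", "n_clipped": n_clipped}
        return out
    return vpd


def compute_dryness_index(net_radiation, precipitation):
    """Dryness index: net radiation over energy-equivalent precipitation.

    ``net_radiation`` in W m-2 and ``precipitation`` in mm yr-1; the
    precipitation mass flux is converted to a latent-heat-equivalent energy
    flux with lambda = 2.45 MJ kg-1, so an index above 1 marks energy surplus
    relative to water supply.  Non-positive precipitation yields a missing
    value (count in ``attrs["n_missing"]`` for xarray inputs).
    """
    rn = np.asarray(net_radiation, dtype=float)
    p = np.asarray(precipitation, dtype=float)
    flux = p * LATENT_HEAT_VAPORIZATION / SECONDS_PER_YEAR  # W m-2
    with np.errstate(divide="ignore", invalid="ignore"):
        index = np.where(p > 0, rn / flux, np.nan)
    n_missing = int(np.sum(np.isfinite(rn) & ~(p > 0)))
    if isinstance(net_radiation, xr.DataArray):
        out = net_radiation.copy(data=index)
        out.name = "dryness_index"
        out.attrs = {"units": "1", "n_missing": n_missing}
        return out
    return index


def classify_drying(
    trend_results: dict[str, xr.Dataset],
    threshold: int = 2,
    require_significant: bool = True,
) -> xr.Dataset:
    """Per-cell drying flags and their agreement across the 4 water variables.

    A variable flags drying when its trend points in the drying direction
    (decrease for soil moisture / precipitation, increase for VPD / dryness
    index) and, unless ``require_significant=False`` (the sensitivity
    variant), is significant.  ``drying`` is true where at least
    ``threshold`` of the 4 flags agree; cells missing any variable's trend
    are missing.
    """
    missing = set(WATER_TREND_DIRECTIONS) - set(trend_results)
    if missing:
        raise ValueError(f"missing trend results for {sorted(missing)}")
    flags = {}
    valid = None
    for name, sign in WATER_TREND_DIRECTIONS.items():
        tr = trend_results[name]
        flag = tr["direction"] == sign
        if require_significant:
            flag = flag & tr["significant"]
        ok = np.isfinite(tr["p"])
        valid = ok if valid is None else (valid & ok)
        flags[f"{name}_drying"] = flag
    count = sum(f.astype(np.int8) for f in flags.values())
    ds = xr.Dataset(flags)
    ds["agreement_count"] = count.where(valid, other=-1).astype(np.int8)
    ds["drying"] = (count >= threshold) & valid
    ds["valid"] = valid
    ds.attrs["threshold"] = threshold
    ds.attrs["require_significant"] = int(require_significant)
    return ds


def default_decades(years: np.ndarray) -> list[tuple[int, int]]:
    """Calendar-decade windows (1981-1990 style) clipped to the year axis."""
    years = np.asarray(years)
    first, last = int(years.min()), int(years.max())
    start = ((first - 1) // 10) * 10 + 1
    decades = []
    while start <= last:
        decades.append((max(start, first), min(start + 9, last)))
        start += 10
    return decades


def classify_greenness(
    lai_trend: xr.Dataset,
    lai: xr.DataArray,
    decades: list[tuple[int, int]] | None = None,
    lai_threshold: float = 0.5,
) -> xr.DataArray:
    """Greenness category per cell from the LAI trend and the study mask.

    Cells are masked out of the study area when the decadal mean LAI is
    below ``lai_threshold`` in any decade (computed on the full LAI series,
    not only the trend window).  Otherwise the category is the Theil-Sen
    slope sign crossed with Mann-Kendall significance; an exactly zero slope
    ties to nonsignificant greening.
    """
    decades = decades or default_decades(lai["year"].values)
    masked = None
    for y0, y1 in decades:
        dec_mean = lai.sel(year=slice(y0, y1)).mean("year")
        low = ~(dec_mean >= lai_threshold)  # NaN decadal mean also masks
        masked = low if masked is None else (masked | low)

    slope = lai_trend["slope"]
    sig = lai_trend["significant"]
    browning = slope < 0
    code = xr.where(
        browning,
        xr.where(sig, GREENNESS_CODES["browning_significant"], GREENNESS_CODES["browning_nonsignificant"]),
        xr.where(sig & (slope > 0), GREENNESS_CODES["greening_significant"], GREENNESS_CODES["greening_nonsignificant"]),
    )
    code = xr.where(masked | ~np.isfinite(slope), GREENNESS_CODES["masked"], code)
    out = code.astype(np.int8).rename("greenness")
    out.attrs["codes"] = " ".join(f"{v}:{k}" for k, v in GREENNESS_CODES.items())
    return out


def coincidence_map(
    greenness: xr.DataArray,
    drying: xr.Dataset,
    require_significant_browning: bool = True,
) -> xr.DataArray:
    """Intersect browning with drying into a categorical coincidence map."""
    if greenness.sizes != {k: drying.sizes[k] for k in ("lat", "lon")}:
        raise ValueError("greenness and drying maps are on different grids")
    if require_significant_browning:
        browning = greenness == BROWNING_SIG
    else:
        browning = greenness.isin(list(BROWNING_ANY))
    dry = drying["drying"]
    code = xr.where(
        browning & dry,
        COINCIDENCE_CODES["browning_and_drying"],
        xr.where(
            browning,
            COINCIDENCE_CODES["browning_only"],
            xr.where(dry, COINCIDENCE_CODES["drying_only"], COINCIDENCE_CODES["neither"]),
        ),
    )
    code = xr.where(greenness == GREENNESS_CODES["masked"], COINCIDENCE_CODES["masked"], code)
    out = code.astype(np.int8).rename("coincidence")
    out.attrs["codes"] = " ".join(f"{v}:{k}" for k, v in COINCIDENCE_CODES.items())
    return out


def area_fraction(mask: xr.DataArray, within: xr.DataArray | None = None) -> float:
    """Latitude-cosine-weighted area fraction of ``mask`` within ``within``."""
    if within is None:
        within = xr.ones_like(mask, dtype=bool)
    if mask.sizes != within.sizes:
        raise ValueError("mask and reference area are on different grids")
    w = cos_lat_weights(mask["lat"])
    denom = float((within * w).sum())
    if denom == 0:
        raise ValueError("empty reference area")
    return float(((mask & within) * w).sum()) / denom


def cramers_v(map_a: xr.DataArray, map_b: xr.DataArray, exclude: tuple[int, ...] = (0,)) -> float:
    """Cramer's V between two categorical maps on their shared valid cells.

    Category codes listed in ``exclude`` (the masked code by default) are
    dropped on either map.  Degenerate tables (fewer than two categories on
    a side) return NaN with a warning.
    """
    a = np.asarray(map_a.values).ravel()
    b = np.asarray(map_b.values).ravel()
    keep = np.isfinite(a) & np.isfinite(b)
    for code in exclude:
        keep &= (a != code) & (b != code)
    a, b = a[keep], b[keep]
    if np.unique(a).size < 2 or np.unique(b).size < 2:
        warnings.warn("degenerate contingency table; Cramer's V undefined", stacklevel=2)
        return float("nan")
    table = pd.crosstab(a, b).to_numpy()
    return float(association(table, method="cramer", correction=False))


def browning_drying_summary(
    greenness: xr.DataArray,
    drying: xr.Dataset,
    include_nonsignificant: bool = False,
) -> pd.DataFrame:
    """Area of browning, partitioned by the drying agreement count (0-4).

    Areas are cosine-weighted fractions of the study area (unmasked cells);
    the per-class areas sum exactly to the total browning area.
    """
    study = greenness != GREENNESS_CODES["masked"]
    if include_nonsignificant:
        browning = greenness.isin(list(BROWNING_ANY))
    else:
        browning = greenness == BROWNING_SIG
    count = drying["agreement_count"]
    rows = []
    for k in range(5):
        frac = area_fraction(browning & (count == k), within=study)
        rows.append({"agreement_count": k, "area_fraction": frac})
    df = pd.DataFrame(rows).set_index("agreement_count")
    df.attrs["total_browning_area"] = area_fraction(browning & (count >= 0), within=study)
    return df
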