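"""Synthetic gridded annual driver and LAI fields with known ground truth.

The generator emulates the structure of the multi-decadal annual datasets the
analysis is designed for: each driver is a per-cell linear trend plus
stationary AR(1) inter-annual noise on a regular lat/lon grid (1982-2020 by
default), and LAI is a known linear response to divide-by-max-normalized
drivers plus white noise.  Rectangular lat/lon "scenario" boxes impose
regional trends (e.g. a coupled soil-moisture/precipitation decline) so that
downstream trend, coincidence and attribution stages can be verified against
the construction.

Every field gets its own deterministic sub-seed derived from the run seed and
the variable name, so adding a variable never perturbs the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import xarray as xr

from .attribution import CANONICAL_PREDICTORS, normalize_per_cell
from .grid import GridSpec, annual_grid

__all__ = [
    "RegionBox",
    "RegionOverride",
    "FieldSpec",
    "CouplingOverride",
    "CouplingSpec",
    "generate_annual_field",
    "generate_driver_suite",
    "generate_lai",
    "generate_member",
    "default_field_specs",
    "default_coupling",
    "drying_scenario",
]


class StationarityError(ValueError):
    """AR(1) coefficient outside [0, 1)."""


class ConfigurationError(ValueError):
    """Incomplete or inconsistent generator configuration."""


# Units attached to generated fields (annual means unless noted).
DEFAULT_UNITS = {
    "lai": "m2 m-2",
    "soil_moisture": "m3 m-3",
    "precipitation": "mm yr-1",
    "vpd": "kPa",
    "temperature": "K",
    "net_radiation": "W m-2",
    "shortwave_radiation": "W m-2",
    "tree_cover": "1",
    "crop_fraction": "1",
    "soil_moisture_annual_min": "m3 m-3",
    "temperature_annual_max": "K",
    "dewpoint_temperature": "K",
}

# Annual extremes are generated as a positive offset from their annual-mean
# partner field, which enforces min <= mean <= max by construction.
EXTREME_PARTNERS = {
    "soil_moisture_annual_min": ("soil_moisture", -1.0),
    "temperature_annual_max": ("temperature", +1.0),
}


@dataclass(frozen=True)
class RegionBox:
    """Axis-aligned lat/lon box (inclusive bounds on cell centers)."""

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float

    def mask(self, grid: GridSpec) -> np.ndarray:
        """(nlat, nlon) boolean mask of cells whose center falls in the box."""
        in_lat = (grid.lats >= self.lat_min) & (grid.lats <= self.lat_max)
        in_lon = (grid.lons >= self.lon_min) & (grid.lons <= self.lon_max)
        return np.logical_and.outer(in_lat, in_lon)


@dataclass(frozen=True)
class RegionOverride:
    """Regional override of a field's trend and/or baseline."""

    box: RegionBox
    trend: float | None = None
    baseline: float | None = None


@dataclass(frozen=True)
class FieldSpec:
    """One variable's generating process: baseline + trend/yr + AR(1) noise.

    ``phi`` is the lag-1 autocorrelation of the noise (must be < 1 for a
    stationary process) and ``sigma`` the innovation standard deviation, both
    in the variable's own units.  Overlapping region overrides resolve by
    last-listed-wins.
    """

    baseline: float
    trend: float = 0.0
    phi: float = 0.0
    sigma: float = 0.0
    regions: tuple[RegionOverride, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi < 1.0:
            raise StationarityError(f"AR(1) coefficient phi={self.phi} not in [0, 1)")
        if self.sigma < 0:
            raise ConfigurationError("innovation sd must be >= 0")
        object.__setattr__(self, "regions", tuple(self.regions))


@dataclass(frozen=True)
class CouplingOverride:
    """Regional override of LAI-response coefficients."""

    box: RegionBox
    coefficients: Mapping[str, float] = field(default_factory=dict)
    intercept: float | None = None


@dataclass(frozen=True)
class CouplingSpec:
    """Linear response of LAI to the normalized drivers.

    LAI(cell, t) = intercept + sum_i beta_i * x_i(cell, t) + eps, where x_i is
    driver i divided by its per-cell maximum over years (the normalization the
    attribution stage uses) and eps is iid Gaussian with sd ``noise_sd``.
    """

    coefficients: Mapping[str, float]
    intercept: float = 1.5
    noise_sd: float = 0.05
    regions: tuple[CouplingOverride, ...] = ()

    def __post_init__(self) -> None:
        unknown = set(self.coefficients) - set(CANONICAL_PREDICTORS)
        for ov in self.regions:
            unknown |= set(ov.coefficients) - set(CANONICAL_PREDICTORS)
        if unknown:
            raise ConfigurationError(
                f"unknown predictor name(s) {sorted(unknown)}; expected "
                f"{list(CANONICAL_PREDICTORS)}"
            )
        if self.noise_sd < 0:
            raise ConfigurationError("LAI noise sd must be >= 0")
        object.__setattr__(self, "regions", tuple(self.regions))
        object.__setattr__(self, "coefficients", dict(self.coefficients))


def _sub_seed(seed: int, name: str) -> np.random.SeedSequence:
    """Stable per-variable sub-seed: run seed mixed with a name hash."""
    return np.random.SeedSequence([int(seed), zlib.crc32(name.encode("utf-8"))])


def _fields_2d(grid: GridSpec, spec: FieldSpec) -> tuple[np.ndarray, np.ndarray]:
    nlat, nlon = grid.lats.size, grid.lons.size
    baseline = np.full((nlat, nlon), float(spec.baseline))
    trend = np.full((nlat, nlon), float(spec.trend))
    for ov in spec.regions:  # last-listed wins
        m = ov.box.mask(grid)
        if ov.trend is not None:
            trend[m] = ov.trend
        if ov.baseline is not None:
            baseline[m] = ov.baseline
    return baseline, trend


def _ar1_noise(
    shape: tuple[int, int, int], phi: float, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Stationary AR(1) noise along the last (year) axis.

    The first year is drawn from the stationary distribution
    N(0, sigma^2 / (1 - phi^2)) so there is no burn-in transient.
    """
    nlat, nlon, nyr = shape
    out = np.empty(shape)
    if sigma == 0:
        out[:] = 0.0
        return out
    out[:, :, 0] = rng.normal(scale=sigma / np.sqrt(1.0 - phi**2), size=(nlat, nlon))
    innovations = rng.normal(scale=sigma, size=(nlat, nlon, nyr - 1))
    for t in range(1, nyr):
        out[:, :, t] = phi * out[:, :, t - 1] + innovations[:, :, t - 1]
    return out


def generate_annual_field(
    grid: GridSpec,
    spec: FieldSpec,
    seed: int | np.random.SeedSequence,
    name: str = "field",
    units: str = "",
) -> xr.DataArray:
    """Generate one annual field: baseline + trend * (year - year0) + AR(1) noise.

    Identical (grid, spec, seed) reproduce bit-identical output.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(int(seed))
    rng = np.random.default_rng(ss)
    baseline, trend = _fields_2d(grid, spec)
    elapsed = (grid.years - grid.years[0]).astype(float)
    values = (
        baseline[:, :, None]
        + trend[:, :, None] * elapsed[None, None, :]
        + _ar1_noise(grid.shape, spec.phi, spec.sigma, rng)
    )
    return annual_grid(grid, values, name, units or DEFAULT_UNITS.get(name, ""))


def generate_driver_suite(
    grid: GridSpec,
    specs: Mapping[str, FieldSpec],
    seed: int,
) -> dict[str, xr.DataArray]:
    """Generate the full predictor suite, one annual field per predictor.

    ``specs`` must cover all canonical predictors; alternatively a
    ``dewpoint_temperature`` spec may replace ``vpd`` (VPD is then derived
    later from temperature and dew point by the drying stage).  Specs for the
    two annual-extreme predictors describe the positive *offset* from the
    corresponding annual-mean field, so the ordering invariants
    (min <= mean, max >= mean) hold at every cell-year.
    """
    names = set(specs)
    required = set(CANONICAL_PREDICTORS)
    if "dewpoint_temperature" in names and "vpd" not in names:
        required = (required - {"vpd"}) | {"dewpoint_temperature"}
    missing = required - names
    if missing:
        raise ConfigurationError(f"missing predictor spec(s): {sorted(missing)}")

    order = [n for n in list(CANONICAL_PREDICTORS) + ["dewpoint_temperature"] if n in required]
    out: dict[str, xr.DataArray] = {}
    for name in order:
        spec = specs[name]
        if name in EXTREME_PARTNERS:
            partner, sign = EXTREME_PARTNERS[name]
            offset = generate_annual_field(grid, spec, _sub_seed(seed, name), name=name)
            base = out[partner]
            values = base.values + sign * np.abs(offset.values)
            out[name] = annual_grid(grid, values, name, DEFAULT_UNITS.get(name, ""))
        else:
            out[name] = generate_annual_field(grid, spec, _sub_seed(seed, name), name=name)
    return out


def generate_lai(
    drivers: Mapping[str, xr.DataArray],
    coupling: CouplingSpec,
    seed: int,
    name: str = "lai",
) -> xr.DataArray:
    """LAI as a known linear response to normalized drivers plus white noise.

    Negative values are clipped to zero; the number of clipped cell-years is
    recorded in ``attrs["n_clipped"]``.
    """
    used = {k: v for k, v in coupling.coefficients.items() if v != 0.0}
    for ov in coupling.regions:
        used.update({k: 1.0 for k in ov.coefficients})
    if not used and coupling.noise_sd == 0:
        import warnings

        warnings.warn("all-zero coupling with zero noise: LAI is constant", stacklevel=2)

    ref = next(iter(drivers.values()))
    grid = GridSpec(ref["lat"].values, ref["lon"].values, ref["year"].values)
    nlat, nlon, nyr = grid.shape

    intercept = np.full((nlat, nlon), float(coupling.intercept))
    coef = {k: np.full((nlat, nlon), float(v)) for k, v in coupling.coefficients.items()}
    for ov in coupling.regions:
        m = ov.box.mask(grid)
        if ov.intercept is not None:
            intercept[m] = ov.intercept
        for k, v in ov.coefficients.items():
            coef.setdefault(k, np.zeros((nlat, nlon)))[m] = v

    values = intercept[:, :, None].repeat(nyr, axis=2)
    for k, beta in coef.items():
        if k not in drivers:
            raise ConfigurationError(f"coupling references missing driver {k!r}")
        values = values + beta[:, :, None] * normalize_per_cell(drivers[k].values)
    rng = np.random.default_rng(_sub_seed(seed, name))
    if coupling.noise_sd > 0:
        values = values + rng.normal(scale=coupling.noise_sd, size=values.shape)

    n_clipped = int((values < 0).sum())
    values = np.clip(values, 0.0, None)
    lai = annual_grid(grid, values, name, DEFAULT_UNITS["lai"])
    lai.attrs["n_clipped"] = n_clipped
    return lai


# ---------------------------------------------------------------------------
# Default study conditions


def default_field_specs() -> dict[str, FieldSpec]:
    """Realistic mid-latitude defaults for the ten predictors.

    Trends are modest relative to inter-annual noise so that significance at
    the 90% level is non-trivial, as with real annual series; the extremes'
    specs are offsets (see :func:`generate_driver_suite`).
    """
    return {
        "soil_moisture": FieldSpec(0.25, 0.0, phi=0.3, sigma=0.012),
        "precipitation": FieldSpec(900.0, 0.0, phi=0.2, sigma=45.0),
        "vpd": FieldSpec(0.90, 0.002, phi=0.3, sigma=0.05),
        "temperature": FieldSpec(288.0, 0.02, phi=0.2, sigma=0.35),
        "net_radiation": FieldSpec(110.0, 0.0, phi=0.2, sigma=4.0),
        "shortwave_radiation": FieldSpec(185.0, 0.0, phi=0.2, sigma=5.0),
        "tree_cover": FieldSpec(0.35, -0.0005, phi=0.5, sigma=0.004),
        "crop_fraction": FieldSpec(0.15, 0.0005, phi=0.5, sigma=0.003),
        "soil_moisture_annual_min": FieldSpec(0.07, 0.0, phi=0.2, sigma=0.006),
        "temperature_annual_max": FieldSpec(16.0, 0.0, phi=0.1, sigma=1.2),
    }


def default_coupling(noise_sd: float = 0.05) -> CouplingSpec:
    """LAI responding mainly to soil moisture, with secondary energy terms."""
    return CouplingSpec(
        coefficients={
            "soil_moisture": 1.2,
            "precipitation": 0.3,
            "vpd": -0.3,
            "shortwave_radiation": 0.2,
        },
        intercept=1.2,
        noise_sd=noise_sd,
    )


def drying_scenario(
    box: RegionBox = RegionBox(5.0, 35.0, -30.0, 40.0),
    mask_box: RegionBox = RegionBox(-55.0, -30.0, -180.0, -60.0),
) -> tuple[dict[str, FieldSpec], CouplingSpec, RegionBox]:
    """Default demo scenario: a coupled drying box plus a low-LAI masked box.

    Inside ``box``, soil moisture and precipitation decline and VPD rises,
    and LAI is strongly coupled to those water drivers, so the box browns
    and dries together.  Outside the box LAI responds only to (trend-free)
    shortwave radiation: coupling LAI to water variables globally would let
    chance 19-year driver trends produce genuinely coincident
    browning-and-drying cells anywhere, leaving the imposed region without a
    well-defined ground truth.  Inside ``mask_box`` the LAI intercept is low
    so decadal means fall below the study threshold.  Returns (field specs,
    coupling, truth box).
    """
    specs = default_field_specs()
    specs["soil_moisture"] = FieldSpec(
        0.25, 0.0, phi=0.3, sigma=0.012,
        regions=(RegionOverride(box, trend=-0.0025),),
    )
    specs["precipitation"] = FieldSpec(
        900.0, 0.0, phi=0.2, sigma=45.0,
        regions=(RegionOverride(box, trend=-8.0),),
    )
    specs["vpd"] = FieldSpec(
        0.90, 0.0, phi=0.3, sigma=0.05,
        regions=(RegionOverride(box, trend=0.012),),
    )
    coupling = CouplingSpec(
        coefficients={"shortwave_radiation": 0.25},
        intercept=1.2,
        noise_sd=0.05,
        regions=(
            CouplingOverride(
                box,
                coefficients={
                    "soil_moisture": 1.2,
                    "precipitation": 0.3,
                    "vpd": -0.3,
                },
            ),
            CouplingOverride(mask_box, intercept=0.2),
        ),
    )
    return specs, coupling, box


def generate_member(
    grid: GridSpec,
    specs: Mapping[str, FieldSpec],
    coupling: CouplingSpec,
    seed: int,
) -> tuple[xr.DataArray, dict[str, xr.DataArray]]:
    """One model-like realization (drivers + LAI) for ensemble experiments."""
    drivers = generate_driver_suite(grid, specs, seed)
    lai = generate_lai(drivers, coupling, seed)
    return lai, drivers


def member_seed(seed: int, member: int) -> int:
    """Per-member seed kept within 31 bits."""
    return int((int(seed) + 7919 * (member + 1)) % (2**31))
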