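"""VPD, dryness index, drying agreement, greenness, coincidence, areas."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from browndry.drying import (
    COINCIDENCE_CODES,
    GREENNESS_CODES,
    LATENT_HEAT_VAPORIZATION,
    SECONDS_PER_YEAR,
    VPDDomainError,
    WATER_TREND_DIRECTIONS,
    area_fraction,
    browning_drying_summary,
    classify_drying,
    classify_greenness,
    coincidence_map,
    compute_dryness_index,
    compute_vpd,
    cramers_v,
    default_decades,
    saturation_vapor_pressure,
)


def make_trend_ds(direction, significant, shape=(2, 2), lat=None, lon=None):
    """Minimal trend dataset with uniform direction/significance."""
    lat = np.linspace(-10, 10, shape[0]) if lat is None else np.asarray(lat, dtype=float)
    lon = np.linspace(0, 30, shape[1]) if lon is None else np.asarray(lon, dtype=float)
    return xr.Dataset(
        {
            "direction": (("lat", "lon"), np.full(shape, direction, dtype=np.int8)),
            "significant": (("lat", "lon"), np.full(shape, significant, dtype=bool)),
            "p": (("lat", "lon"), np.full(shape, 0.01 if significant else 0.5)),
            "slope": (("lat", "lon"), np.full(shape, float(direction))),
        },
        coords={"lat": lat, "lon": lon},
    )


class TestVPD:
    def test_saturated_air_has_zero_deficit(self):
        t = np.array([0.0, 10.0, 25.0, 35.0])
        np.testing.assert_allclose(compute_vpd(t, t), 0.0, atol=1e-15)

    def test_magnus_coefficient_at_zero_celsius(self):
        assert saturation_vapor_pressure(0.0) == 0.6108  # exponent vanishes

    def test_matches_independent_one_line_evaluation(self):
        t, td = 25.0, 15.0
        expected = 0.6108 * np.exp(17.27 * t / (t + 237.3)) - 0.6108 * np.exp(
            17.27 * td / (td + 237.3)
        )
        assert compute_vpd(t, td) == pytest.approx(expected, abs=0)

    def test_strictly_increasing_in_temperature(self):
        t = np.linspace(-20, 45, 200)
        vpd = compute_vpd(t, np.full_like(t, -25.0))
        assert (np.diff(vpd) > 0).all()
        assert (vpd >= 0).all()

    def test_supersaturation_clipped_and_counted(self, small_grid):
        from browndry.grid import annual_grid

        t = annual_grid(small_grid, np.full(small_grid.shape, 10.0), "t")
        td = t + 2.0  # dew point above air temperature everywhere
        out = compute_vpd(t, td)
        assert (out.values == 0).all()
        assert out.attrs["n_clipped"] == t.values.size

    def test_pascals_flag(self):
        assert compute_vpd(25.0, 15.0, pascals=True) == pytest.approx(
            1000 * compute_vpd(25.0, 15.0)
        )

    def test_domain_error_below_singularity(self):
        with pytest.raises(VPDDomainError):
            compute_vpd(-240.0, -250.0)


class TestDrynessIndex:
    def test_linear_in_net_radiation(self, rng):
        p = rng.uniform(100, 2000, size=10)
        rn = rng.uniform(50, 200, size=10)
        np.testing.assert_allclose(
            compute_dryness_index(2 * rn, p), 2 * compute_dryness_index(rn, p)
        )

    def test_unity_when_energy_equals_water_supply(self):
        p = 1000.0  # mm/yr == kg m-2 yr-1
        rn = p * LATENT_HEAT_VAPORIZATION / SECONDS_PER_YEAR
        assert compute_dryness_index(rn, p) == pytest.approx(1.0, abs=1e-12)

    def test_matches_independent_unit_conversion(self, rng):
        rn = rng.uniform(50, 200, size=20)
        p = rng.uniform(200, 2500, size=20)
        expected = rn / (p * 2.45e6 / (365.25 * 86400.0))
        np.testing.assert_allclose(compute_dryness_index(rn, p), expected, rtol=1e-12)

    def test_zero_precipitation_missing_and_counted(self, small_grid):
        from browndry.grid import annual_grid

        rn = annual_grid(small_grid, np.full(small_grid.shape, 100.0), "rn")
        p = annual_grid(small_grid, np.zeros(small_grid.shape), "p")
        out = compute_dryness_index(rn, p)
        assert np.isnan(out.values).all()
        assert out.attrs["n_missing"] == rn.values.size


class TestClassifyDrying:
    def test_all_four_drying(self):
        tr = {
            "soil_moisture": make_trend_ds(-1, True),
            "precipitation": make_trend_ds(-1, True),
            "vpd": make_trend_ds(+1, True),
            "dryness_index": make_trend_ds(+1, True),
        }
        ds = classify_drying(tr)
        assert (ds["agreement_count"].values == 4).all()
        assert bool(ds["drying"].all())

    def test_all_four_wetting(self):
        tr = {
            "soil_moisture": make_trend_ds(+1, True),
            "precipitation": make_trend_ds(+1, True),
            "vpd": make_trend_ds(-1, True),
            "dryness_index": make_trend_ds(-1, True),
        }
        ds = classify_drying(tr)
        assert (ds["agreement_count"].values == 0).all()
        assert not bool(ds["drying"].any())

    def test_two_of_four_threshold(self):
        # exactly soil moisture down + VPD up -> drying by the 2-of-4 rule
        tr = {
            "soil_moisture": make_trend_ds(-1, True),
            "precipitation": make_trend_ds(-1, False),
            "vpd": make_trend_ds(+1, True),
            "dryness_index": make_trend_ds(-1, True),
        }
        ds = classify_drying(tr)
        assert (ds["agreement_count"].values == 2).all()
        assert bool(ds["drying"].all())
        assert not bool(classify_drying(tr, threshold=3)["drying"].any())

    def test_nonsignificant_variant_counts_any_direction(self):
        tr = {
            "soil_moisture": make_trend_ds(-1, False),
            "precipitation": make_trend_ds(-1, False),
            "vpd": make_trend_ds(+1, False),
            "dryness_index": make_trend_ds(-1, False),
        }
        assert not bool(classify_drying(tr)["drying"].any())
        assert bool(classify_drying(tr, require_significant=False)["drying"].all())

    def test_missing_variable_rejected(self):
        with pytest.raises(ValueError, match="vpd"):
            classify_drying({"soil_moisture": make_trend_ds(-1, True)})


class TestGreenness:
    def _lai(self, grid, level):
        from browndry.grid import annual_grid

        return annual_grid(grid, np.full(grid.shape, float(level)), "lai")

    def test_low_lai_masked(self, small_grid):
        from browndry.trends import grid_trends

        lai = self._lai(small_grid, 0.3)
        g = classify_greenness(grid_trends(lai), lai)
        assert (g.values == GREENNESS_CODES["masked"]).all()

    def test_noise_free_positive_trend_is_significant_greening(self, small_grid):
        from browndry.synthetic import FieldSpec, generate_annual_field
        from browndry.trends import grid_trends

        lai = generate_annual_field(small_grid, FieldSpec(1.0, trend=0.02), seed=0, name="lai")
        g = classify_greenness(grid_trends(lai), lai)
        assert (g.values == GREENNESS_CODES["greening_significant"]).all()

    def test_single_low_decade_masks_cell(self, small_grid):
        from browndry.grid import annual_grid
        from browndry.trends import grid_trends

        decades = default_decades(small_grid.years)
        vals = np.full(small_grid.shape, 0.6)
        y0, y1 = decades[-1]
        last = (small_grid.years >= y0) & (small_grid.years <= y1)
        vals[0, 0, last] = 0.4  # decadal means (0.6, 0.6, 0.6, 0.4)
        lai = annual_grid(small_grid, vals, "lai")
        g = classify_greenness(grid_trends(lai), lai)
        assert g.values[0, 0] == GREENNESS_CODES["masked"]
        assert (g.values.ravel()[1:] != GREENNESS_CODES["masked"]).all()

    def test_zero_slope_ties_to_nonsignificant_greening(self, small_grid):
        from browndry.grid import annual_grid
        from browndry.trends import grid_trends

        lai = self._lai(small_grid, 1.0)
        g = classify_greenness(grid_trends(lai), lai)
        assert (g.values == GREENNESS_CODES["greening_nonsignificant"]).all()


class TestCoincidence:
    def _greenness(self, code, shape=(2, 2)):
        lat = np.linspace(-10, 10, shape[0])
        lon = np.linspace(0, 30, shape[1])
        return xr.DataArray(
            np.full(shape, code, dtype=np.int8),
            coords={"lat": lat, "lon": lon},
            dims=("lat", "lon"),
        )

    def _drying(self, flag, shape=(2, 2)):
        tr = {
            k: make_trend_ds(-1 if flag and s < 0 else (1 if flag and s > 0 else 0), flag, shape)
            for k, s in WATER_TREND_DIRECTIONS.items()
        }
        return classify_drying(tr)

    def test_browning_and_drying(self):
        code = coincidence_map(self._greenness(GREENNESS_CODES["browning_significant"]), self._drying(True))
        assert (code.values == COINCIDENCE_CODES["browning_and_drying"]).all()

    def test_masked_propagates(self):
        code = coincidence_map(self._greenness(GREENNESS_CODES["masked"]), self._drying(True))
        assert (code.values == COINCIDENCE_CODES["masked"]).all()

    def test_relaxed_browning_is_superset(self):
        g = self._greenness(GREENNESS_CODES["browning_nonsignificant"])
        strict = coincidence_map(g, self._drying(True), require_significant_browning=True)
        relaxed = coincidence_map(g, self._drying(True), require_significant_browning=False)
        strict_hits = strict.values == COINCIDENCE_CODES["browning_and_drying"]
        relaxed_hits = relaxed.values == COINCIDENCE_CODES["browning_and_drying"]
        assert (relaxed_hits | ~strict_hits).all()  # cell-wise superset
        assert relaxed_hits.sum() > strict_hits.sum()

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            coincidence_map(self._greenness(1, shape=(3, 2)), self._drying(True))


class TestAreaFraction:
    def _map(self, values, lats):
        return xr.DataArray(
            np.asarray(values, dtype=bool),
            coords={"lat": np.asarray(lats, dtype=float), "lon": [0.0]},
            dims=("lat", "lon"),
        )

    def test_full_mask_is_one(self):
        m = self._map([[True], [True]], [0.0, 60.0])
        assert area_fraction(m, m) == 1.0

    def test_cosine_weights_example(self):
        within = self._map([[True], [True]], [0.0, 60.0])
        only_high = self._map([[False], [True]], [0.0, 60.0])
        assert area_fraction(within, within) == 1.0
        assert area_fraction(only_high, within) == pytest.approx(0.5 / 1.5, abs=1e-12)

    def test_matches_explicit_weighted_sum(self, rng, small_grid):
        mask = xr.DataArray(
            rng.random((4, 6)) > 0.5,
            coords={"lat": small_grid.lats, "lon": small_grid.lons},
            dims=("lat", "lon"),
        )
        w = np.cos(np.deg2rad(small_grid.lats))[:, None] * np.ones((1, 6))
        expected = (w * mask.values).sum() / w.sum()
        assert area_fraction(mask) == pytest.approx(expected, abs=1e-12)

    def test_empty_denominator_errors(self):
        m = self._map([[False], [False]], [0.0, 60.0])
        with pytest.raises(ValueError):
            area_fraction(m, m)


class TestCramersV:
    def _cat(self, values):
        a = np.asarray(values)
        return xr.DataArray(
            a,
            coords={"lat": np.arange(a.shape[0], dtype=float), "lon": np.arange(a.shape[1], dtype=float)},
            dims=("lat", "lon"),
        )

    def test_identical_binary_maps(self):
        m = self._cat([[1, 2], [2, 1]])
        assert cramers_v(m, m) == pytest.approx(1.0)

    def test_independent_maps_near_zero(self, rng):
        a = self._cat(rng.integers(1, 4, size=(60, 60)))
        b = self._cat(rng.integers(1, 4, size=(60, 60)))
        assert cramers_v(a, b) < 0.05

    def test_fixed_2x2_table_hand_computed(self):
        # table [[30, 10], [10, 30]]: chi2 = 80*(30*30-10*10)^2/(40^4) = 20, V = 0.5
        a = self._cat(np.repeat([1, 1, 2, 2], 20).reshape(4, 20))
        b_vals = np.concatenate([np.repeat([1, 2], [30, 10]), np.repeat([1, 2], [10, 30])])
        b = self._cat(b_vals.reshape(4, 20))
        assert cramers_v(a, b) == pytest.approx(0.5, abs=1e-12)

    def test_relabeling_invariance(self, rng):
        a = self._cat(rng.integers(1, 5, size=(20, 20)))
        b = self._cat(rng.integers(1, 4, size=(20, 20)))
        relabeled = self._cat(7 - a.values)  # bijective relabeling of categories
        assert cramers_v(a, b) == pytest.approx(cramers_v(relabeled, b), abs=1e-12)

    def test_degenerate_table_warns_nan(self):
        a = self._cat(np.ones((3, 3), dtype=int) * 2)
        b = self._cat(np.arange(9).reshape(3, 3) % 3 + 1)
        with pytest.warns(UserWarning, match="degenerate"):
            assert np.isnan(cramers_v(a, b))


class TestBrowningDryingSummary:
    def _inputs(self, rng, small_grid):
        greenness = xr.DataArray(
            rng.integers(0, 5, size=(4, 6)).astype(np.int8),
            coords={"lat": small_grid.lats, "lon": small_grid.lons},
            dims=("lat", "lon"),
        )
        tr = {
            k: make_trend_ds(s, True, shape=(4, 6), lat=small_grid.lats, lon=small_grid.lons)
            for k, s in WATER_TREND_DIRECTIONS.items()
        }
        drying = classify_drying(tr)
        drying["agreement_count"].values[:] = rng.integers(0, 5, size=(4, 6))
        return greenness, drying

    def test_no_browning_gives_zero_table(self, small_grid):
        greenness = xr.DataArray(
            np.full((4, 6), GREENNESS_CODES["greening_significant"], dtype=np.int8),
            coords={"lat": small_grid.lats, "lon": small_grid.lons},
            dims=("lat", "lon"),
        )
        tr = {
            k: make_trend_ds(s, True, (4, 6), lat=small_grid.lats, lon=small_grid.lons)
            for k, s in WATER_TREND_DIRECTIONS.items()
        }
        table = browning_drying_summary(greenness, classify_drying(tr))
        assert (table["area_fraction"] == 0).all()

    def test_classes_sum_to_total_browning_area(self, rng, small_grid):
        greenness, drying = self._inputs(rng, small_grid)
        table = browning_drying_summary(greenness, drying)
        assert table["area_fraction"].sum() == pytest.approx(
            table.attrs["total_browning_area"], abs=1e-12
        )

    def test_all_count4_browning_lands_in_class_four(self, small_grid):
        greenness = xr.DataArray(
            np.full((4, 6), GREENNESS_CODES["browning_significant"], dtype=np.int8),
            coords={"lat": small_grid.lats, "lon": small_grid.lons},
            dims=("lat", "lon"),
        )
        tr = {
            "soil_moisture": make_trend_ds(-1, True, (4, 6), small_grid.lats, small_grid.lons),
            "precipitation": make_trend_ds(-1, True, (4, 6), small_grid.lats, small_grid.lons),
            "vpd": make_trend_ds(+1, True, (4, 6), small_grid.lats, small_grid.lons),
            "dryness_index": make_trend_ds(+1, True, (4, 6), small_grid.lats, small_grid.lons),
        }
        table = browning_drying_summary(greenness, classify_drying(tr))
        assert table.loc[4, "area_fraction"] == pytest.approx(1.0)
        assert table.loc[:3, "area_fraction"].sum() == 0.0
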