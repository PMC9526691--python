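import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.base import clone

from aeropollen import (
    NonparametricWindRegression,
    PolarGrid,
    SustainedWindIncidence,
    WindObservation,
    dominant_sector,
    joint_probability_rose,
    nwr_estimate,
    swim_estimate,
    yamartino_sigma,
)
from aeropollen.source_receptor import (
    SIGMA_MAX_DEG,
    angular_distance,
    circular_sd,
    compass_sector,
    read_wind_table,
)


class TestYamartino:
    def test_zero_spread(self):
        assert yamartino_sigma([137.0] * 10) == pytest.approx(0.0)

    def test_cardinal_directions_reach_maximum(self):
        # ε = 1 → σ = 90° · 2/√3 ≈ 103.92°
        sigma = yamartino_sigma([0.0, 90.0, 180.0, 270.0])
        assert sigma == pytest.approx(90.0 * 2 / np.sqrt(3), abs=1e-9)
        assert sigma == pytest.approx(103.923, abs=1e-3)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            yamartino_sigma([])

    @given(
        st.lists(st.floats(0, 359.999), min_size=1, max_size=50),
        st.floats(0, 360),
    )
    def test_bounded_and_rotation_invariant(self, dirs, rot):
        sigma = yamartino_sigma(dirs)
        assert 0.0 <= sigma <= SIGMA_MAX_DEG + 1e-9
        rotated = [(d + rot) % 360 for d in dirs]
        assert yamartino_sigma(rotated) == pytest.approx(sigma, abs=1e-6)

    def test_agrees_with_two_pass_circular_sd_at_low_spread(self, rng):
        for spread in (5.0, 15.0, 30.0):
            dirs = rng.normal(180.0, spread, size=5000) % 360
            one_pass = yamartino_sigma(dirs)
            two_pass = circular_sd(dirs)
            assert one_pass == pytest.approx(two_pass, rel=0.02)


def make_wind_frame(directions, speeds, sigmas=None, start="2018-01-01"):
    idx = pd.date_range(start, periods=len(directions), freq="D")
    df = pd.DataFrame({"direction": directions, "speed": speeds}, index=idx)
    if sigmas is not None:
        df["sigma_dir"] = sigmas
    return df


class TestNWR:
    def test_constant_concentration_gives_constant_surface(self, rng):
        n = 50
        wind = make_wind_frame(rng.uniform(0, 360, n), rng.uniform(0, 15, n))
        conc = pd.Series(7.0, index=wind.index)
        grid = nwr_estimate(conc, wind)
        defined = grid.values[~np.isnan(grid.values)]
        assert defined.size > 0
        assert np.allclose(defined, 7.0)

    def test_single_observation_defines_cells_near_it_only(self):
        # one kernel: every defined cell equals the value, and only cells
        # within kernel reach of (90°, 10 km/h) are defined at all
        wind = make_wind_frame([90.0], [10.0])
        conc = pd.Series([5.0], index=wind.index)
        grid = nwr_estimate(conc, wind)
        i = int(np.argmin(angular_distance(grid.direction_centers, 90.0)))
        j = int(np.searchsorted(grid.speed_edges, 10.0)) - 1
        assert grid.values[i, j] == pytest.approx(5.0)
        opposite = int(np.argmin(angular_distance(grid.direction_centers, 270.0)))
        assert np.isnan(grid.values[opposite, 0])
        defined = grid.values[~np.isnan(grid.values)]
        assert np.allclose(defined, 5.0)

    def test_matches_naive_double_loop(self, rng):
        n = 12
        dirs = rng.uniform(0, 360, n)
        speeds = rng.uniform(0, 12, n)
        conc_vals = rng.gamma(2.0, 5.0, n)
        wind = make_wind_frame(dirs, speeds)
        conc = pd.Series(conc_vals, index=wind.index)
        grid = nwr_estimate(conc, wind, n_direction_bins=36, speed_step=1.0)
        hd, hv = 15.0, 2.0
        for i, th in enumerate(grid.direction_centers):
            for j, v in enumerate(grid.speed_centers):
                w = np.exp(-0.5 * (angular_distance(th, dirs) / hd) ** 2)
                w = w * np.exp(-0.5 * ((v - speeds) / hv) ** 2)
                expected = (w @ conc_vals) / w.sum() if w.sum() >= 1e-3 else np.nan
                got = grid.values[i, j]
                if np.isnan(expected):
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(expected, rel=1e-9)

    def test_convex_combination_of_inputs(self, rng):
        n = 60
        wind = make_wind_frame(rng.uniform(0, 360, n), rng.uniform(0, 15, n))
        conc = pd.Series(rng.gamma(1.0, 10.0, n), index=wind.index)
        grid = nwr_estimate(conc, wind)
        defined = grid.values[~np.isnan(grid.values)]
        assert defined.min() >= conc.min() - 1e-9
        assert defined.max() <= conc.max() + 1e-9

    def test_rotating_wind_rotates_grid(self, rng):
        n = 40
        dirs = rng.uniform(0, 360, n)
        speeds = rng.uniform(0, 12, n)
        conc_vals = rng.gamma(2.0, 5.0, n)
        wind_a = make_wind_frame(dirs, speeds)
        wind_b = make_wind_frame((dirs + 45.0) % 360, speeds)
        conc = pd.Series(conc_vals, index=wind_a.index)
        ga = nwr_estimate(conc, wind_a, n_direction_bins=72, max_speed=12.0)
        gb = nwr_estimate(conc, wind_b, n_direction_bins=72, max_speed=12.0)
        shift = int(45.0 / (360.0 / 72))
        np.testing.assert_allclose(
            np.roll(ga.values, shift, axis=0), gb.values, rtol=1e-9, equal_nan=True
        )

    def test_no_overlapping_dates_errors(self):
        wind = make_wind_frame([90.0], [5.0], start="2018-01-01")
        conc = pd.Series([1.0], index=pd.to_datetime(["2019-06-01"]))
        with pytest.raises(ValueError, match="overlapping"):
            nwr_estimate(conc, wind)

    def test_estimator_clone_and_params(self):
        est = SustainedWindIncidence(direction_bandwidth=20.0, normalise=True)
        cloned = clone(est)
        assert cloned.get_params()["direction_bandwidth"] == 20.0
        assert cloned.get_params()["normalise"] is True


class TestSWIM:
    def test_equal_sigmas_reduce_to_nwr(self, rng):
        n = 30
        dirs = rng.uniform(0, 360, n)
        speeds = rng.uniform(0, 12, n)
        conc_vals = rng.gamma(2.0, 5.0, n)
        wind = make_wind_frame(dirs, speeds, sigmas=[20.0] * n)
        conc = pd.Series(conc_vals, index=wind.index)
        swim = swim_estimate(conc, wind)
        nwr = nwr_estimate(conc, wind[["direction", "speed"]])
        np.testing.assert_allclose(swim.values, nwr.values, rtol=1e-9, equal_nan=True)

    def test_sigma_ratio_weights(self):
        # δ = {1, 2} → mean 1.5 → weights δ̄/δ = {1.5, 0.75}: 2:1 ratio
        est = SustainedWindIncidence()
        X = np.array([[90.0, 5.0, 1.0], [90.0, 5.0, 2.0]])
        w = est._observation_weights(X)
        assert w == pytest.approx([1.5, 0.75])
        assert w[0] / w[1] == pytest.approx(2.0)

    def test_weighted_mean_reflects_sigma_ratio(self):
        # identical wind, δ {1, 2}, values {10, 1}: estimate = (1.5·10+0.75·1)/2.25
        wind = make_wind_frame([90.0, 90.0], [5.0, 5.0], sigmas=[1.0, 2.0])
        conc = pd.Series([10.0, 1.0], index=wind.index)
        grid = swim_estimate(conc, wind, weight_floor=1e-9)
        i = np.argmin(angular_distance(grid.direction_centers, 90.0))
        j = np.searchsorted(grid.speed_edges, 5.0) - 1
        assert grid.values[i, j] == pytest.approx((1.5 * 10 + 0.75 * 1) / 2.25)

    def test_zero_sigma_replaced_with_warning(self, caplog):
        import logging

        wind = make_wind_frame([10.0, 20.0], [5.0, 5.0], sigmas=[0.0, 4.0])
        conc = pd.Series([1.0, 2.0], index=wind.index)
        with caplog.at_level(logging.WARNING):
            swim_estimate(conc, wind)
        assert "zero sigma_dir" in caplog.text

    def test_all_zero_concentration_normalisation_skipped(self, caplog):
        import logging

        wind = make_wind_frame([10.0, 200.0], [5.0, 8.0], sigmas=[10.0, 20.0])
        conc = pd.Series([0.0, 0.0], index=wind.index)
        with caplog.at_level(logging.WARNING):
            grid = swim_estimate(conc, wind, normalise=True)
        defined = grid.values[~np.isnan(grid.values)]
        assert np.allclose(defined, 0.0)
        assert "normalisation skipped" in caplog.text

    def test_planted_plume_recovered(self):
        from aeropollen.synthetic import PlumeSpec, generate_wind_with_plume

        wind, conc, truth = generate_wind_with_plume(PlumeSpec(), n_days=730, seed=7)
        grid = swim_estimate(conc, wind)
        sector, band = dominant_sector(grid)
        assert sector == truth["sector"] == "E"
        i, _ = np.unravel_index(np.nanargmax(grid.values), grid.values.shape)
        assert angular_distance(grid.direction_centers[i], 90.0) <= 15.0


class TestJointProbabilityRose:
    def test_single_bin(self):
        wind = make_wind_frame([45.0] * 5, [3.0] * 5)
        grid = joint_probability_rose(wind)
        assert np.nanmax(grid.values) == pytest.approx(1.0)
        assert grid.values.sum() == pytest.approx(1.0)

    def test_four_distinct_bins(self):
        wind = make_wind_frame([0.0, 90.0, 180.0, 270.0], [1.0, 3.0, 6.0, 10.0])
        grid = joint_probability_rose(wind)
        nonzero = grid.values[grid.values > 0]
        assert len(nonzero) == 4
        assert np.allclose(nonzero, 0.25)

    def test_matches_histogram_oracle(self, rng):
        n = 500
        dirs = rng.uniform(0, 360, n)
        speeds = rng.uniform(0, 14, n)
        wind = make_wind_frame(dirs, speeds)
        edges = np.array([0.0, 2.0, 4.0, 8.0, 12.0, 20.0])
        grid = joint_probability_rose(wind, n_direction_bins=8, speed_edges=edges)
        assert grid.values.sum() == pytest.approx(1.0)
        # oracle: direct binning with sectors centred on compass points
        for i in range(8):
            for j in range(5):
                centre = i * 45.0
                in_dir = angular_distance(dirs, centre) < 22.5
                in_spd = (speeds >= edges[j]) & (speeds < edges[j + 1])
                assert grid.values[i, j] == pytest.approx(
                    np.sum(in_dir & in_spd) / n, abs=1.5 / n
                )


class TestDominantSector:
    def test_uniform_grid_tie_break(self):
        grid = PolarGrid(
            direction_edges=np.linspace(0, 360, 9),
            speed_edges=np.array([0.0, 2.0, 4.0]),
            values=np.ones((8, 2)),
        )
        sector, band = dominant_sector(grid)
        assert sector == "N"
        assert band == (0.0, 2.0)

    def test_single_cell_maps_to_its_sector(self):
        values = np.zeros((72, 10))
        values[40, 3] = 5.0  # direction centre 202.5° → S/SW boundary → S wins
        grid = PolarGrid(
            direction_edges=np.linspace(0, 360, 73),
            speed_edges=np.arange(11.0),
            values=values,
        )
        sector, band = dominant_sector(grid)
        assert sector in ("S", "SW")
        assert band == (3.0, 4.0)
        assert compass_sector(200.0) == "S"
        assert compass_sector(90.0) == "E"
        assert compass_sector(225.0) == "SW"

    def test_all_undefined_errors(self):
        grid = PolarGrid(
            direction_edges=np.linspace(0, 360, 9),
            speed_edges=np.array([0.0, 2.0]),
            values=np.full((8, 1), np.nan),
        )
        with pytest.raises(ValueError, match="no defined cells"):
            dominant_sector(grid)


class TestWindIO:
    def test_knots_converted(self, tmp_path):
        path = tmp_path / "wind.csv"
        path.write_text("date,speed,direction\n01/06/2018,10,90\n")
        df = read_wind_table(path, speed_unit="knots")
        assert df["speed"].iloc[0] == pytest.approx(18.52)

    def test_observation_validation(self):
        with pytest.raises(ValueError):
            WindObservation(pd.Timestamp("2018-06-01"), speed=-1.0, direction=0.0)
        with pytest.raises(ValueError):
            WindObservation(pd.Timestamp("2018-06-01"), speed=1.0, direction=360.0)
        with pytest.raises(ValueError):
            WindObservation(
                pd.Timestamp("2018-06-01"), speed=1.0, direction=0.0, sigma_dir=120.0
            )
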