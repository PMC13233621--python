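"""Synthetic grids, climate, recycling networks and deforestation fronts."""

import numpy as np
import pytest

from tipcascade.hydro import hydro_series
from tipcascade.synthetic import (
    ClimateParams,
    NetworkParams,
    build_network,
    generate_scenario,
    make_deforestation,
    make_grid,
    scenario_preset,
    simulate_climate,
)


class TestMakeGrid:
    def test_single_cell(self):
        grid = make_grid(1, 1, 10_000)
        assert grid.n_gridcells == 1

    def test_counts_and_ids(self):
        grid = make_grid(20, 20, 10_000)
        assert grid.n_cells == 400
        np.testing.assert_array_equal(grid.cell_id, np.arange(400))

    def test_total_area(self):
        assert make_grid(4, 5, 8000).basin_area == pytest.approx(160_000.0)

    @pytest.mark.parametrize("nx,ny", [(0, 3), (3, 0), (-1, 2)])
    def test_bad_dimensions_rejected(self, nx, ny):
        with pytest.raises(ValueError):
            make_grid(nx, ny)


class TestSimulateClimate:
    def test_constant_limit(self):
        grid = make_grid(3, 3)
        params = ClimateParams(
            baseline_map=1200.0, seasonal_amplitude=0.0, interannual_sd=0.0
        )
        p, e = simulate_climate(grid, params, range(2000, 2002))
        np.testing.assert_allclose(p.values, 100.0)
        assert np.all(e.values == params.evaporation_mean)

    def test_deterministic_given_seed(self):
        grid = make_grid(4, 4)
        params = ClimateParams(seed=7)
        p1, _ = simulate_climate(grid, params, range(2000, 2010))
        p2, _ = simulate_climate(grid, params, range(2000, 2010))
        np.testing.assert_array_equal(p1.values, p2.values)

    def test_trend_closed_form_between_decades(self):
        grid = make_grid(2, 2)
        params = ClimateParams(
            seasonal_amplitude=0.0, interannual_sd=0.0,
            trend_map_per_decade=-100.0,
        )
        p, _ = simulate_climate(grid, params, range(2000, 2030))
        annual = p.values.reshape(4, 30, 12).sum(axis=2)
        decade1 = annual[:, 0:10].mean(axis=1)
        decade3 = annual[:, 20:30].mean(axis=1)
        np.testing.assert_allclose(decade3 - decade1, -200.0)

    def test_fields_are_non_negative(self):
        grid = make_grid(3, 3)
        params = ClimateParams(trend_map_per_decade=-400.0, seed=3)
        p, e = simulate_climate(grid, params, range(2000, 2060))
        assert np.all(p.values >= 0) and np.all(e.values >= 0)

    def test_empty_year_range_rejected(self):
        with pytest.raises(ValueError):
            simulate_climate(make_grid(2, 2), ClimateParams(), range(2000, 2000))


class TestBuildNetwork:
    @pytest.fixture
    def grid_fields(self):
        grid = make_grid(7, 7)
        params = ClimateParams(interannual_sd=0.0)
        p, e = simulate_climate(grid, params, range(2000, 2002))
        return grid, p, e

    def test_zero_recycling_gives_empty_network(self, grid_fields):
        grid, p, e = grid_fields
        net = build_network(grid, NetworkParams(recycling_target=0.0), p, e)
        assert net.n_links == 0

    def test_conservation_bound_every_month(self, grid_fields):
        grid, p, e = grid_fields
        net = build_network(grid, NetworkParams(), p, e)
        incoming = net.incoming_sum()
        assert np.all(incoming <= p.values + 1e-9)

    def test_recycling_fraction_capped_by_target(self, grid_fields):
        grid, p, e = grid_fields
        target = 0.5
        net = build_network(grid, NetworkParams(recycling_target=target), p, e)
        annual_in = np.zeros(grid.n_cells)
        np.add.at(annual_in, net.target, net.weights.sum(axis=1))
        annual_p = p.values.sum(axis=1)
        assert np.all(annual_in <= target * annual_p + 1e-9)

    def test_downwind_neighbour_receives_more_than_upwind(self, grid_fields):
        grid, p, e = grid_fields
        net = build_network(
            grid, NetworkParams(wind_vector=(1.0, 0.0), seed=5), p, e
        )
        k = 3 * 7 + 3  # interior source
        total = np.zeros(grid.n_cells)
        np.add.at(total, net.target[net.source == k],
                  net.weights[net.source == k].sum(axis=1))
        assert total[k + 1] > total[k - 1]

    def test_mismatched_grid_rejected(self, grid_fields):
        _, p, e = grid_fields
        with pytest.raises(ValueError):
            build_network(make_grid(3, 3), NetworkParams(), p, e)


class TestMakeDeforestation:
    def test_zero_scenario(self):
        grid = make_grid(5, 5)
        lu = make_deforestation(grid, 0.0, 0.0, range(2021, 2031))
        assert np.all(lu.fraction == 0.0)

    def test_reference_trajectory_reaches_end_fraction(self):
        grid = make_grid(10, 10)
        lu = make_deforestation(grid, 0.18, 0.35, range(2021, 2051))
        basin = lu.basin_fraction(grid)
        assert basin[0] == pytest.approx(0.18, abs=1e-6)
        assert basin[-1] == pytest.approx(0.35, abs=1e-6)

    def test_held_constant_after_ramp(self):
        grid = make_grid(6, 6)
        lu = make_deforestation(grid, 0.1, 0.3, range(2021, 2031))
        np.testing.assert_array_equal(lu.fraction_at(2050), lu.fraction_at(2030))

    def test_fractions_non_decreasing_per_cell(self):
        grid = make_grid(8, 8)
        lu = make_deforestation(grid, 0.05, 0.4, range(2021, 2041))
        assert np.all(np.diff(lu.fraction, axis=0) >= -1e-12)

    def test_front_advances_from_origin_edge(self):
        grid = make_grid(10, 3)
        lu = make_deforestation(grid, 0.0, 0.3, range(2021, 2031), "x_low")
        final = lu.fraction[-1]
        assert final[grid.x == 0].mean() > final[grid.x == 9].mean()

    def test_end_below_start_rejected(self):
        with pytest.raises(ValueError):
            make_deforestation(make_grid(3, 3), 0.5, 0.2, range(2021, 2031))


class TestPresets:
    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            scenario_preset("business_as_usual")

    def test_ordered_by_drying_severity(self):
        weak = scenario_preset("weak_drying").climate.trend_map_per_decade
        mod = scenario_preset("moderate_drying").climate.trend_map_per_decade
        strong = scenario_preset("strong_drying").climate.trend_map_per_decade
        assert weak == 0.0
        assert abs(strong) > abs(mod) > 0

    def test_deforestation_preset_carries_landuse(self):
        bundle = generate_scenario(
            "strong_drying_deforestation", nx=6, ny=6, seed=0,
            scen_years=range(2020, 2041),
        )
        assert bundle.landuse is not None
        assert bundle.landuse.basin_fraction(bundle.grid)[-1] > 0.2

    def test_monotone_severity_of_final_decade_map(self):
        # noise-free configuration: basin-mean MAP ordering is exact
        means = {}
        for name in ("weak_drying", "moderate_drying", "strong_drying"):
            bundle = generate_scenario(
                name, nx=5, ny=5, seed=2, noise_free_scenario=True,
                scen_years=range(2020, 2101),
            )
            series = hydro_series(bundle.p_scen, bundle.e_scen)
            sel = series.hydro_years >= 2090
            means[name] = series.map[:, sel].mean()
        assert means["weak_drying"] >= means["moderate_drying"] >= means[
            "strong_drying"
        ]


def test_generate_scenario_reproducible():
    b1 = generate_scenario("moderate_drying", nx=4, ny=4, seed=9,
                           scen_years=range(2020, 2041))
    b2 = generate_scenario("moderate_drying", nx=4, ny=4, seed=9,
                           scen_years=range(2020, 2041))
    np.testing.assert_array_equal(b1.p_scen.values, b2.p_scen.values)
    np.testing.assert_array_equal(b1.net.weights, b2.net.weights)
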