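import numpy as np
import pytest

from socassim.errors import InterfaceError
from socassim.evaluate import (
    GridDomain,
    continental_total,
    depth_interval_stock,
    deviation_map,
    eval_metrics,
    fixed_line_r2,
)


@pytest.fixture()
def domain():
    lats = np.arange(40.25, 42.0, 0.5)
    lons = np.arange(-100.25, -98.0, 0.5)
    return GridDomain(lats=lats, lons=lons, mask=np.ones((lats.size, lons.size), bool))


class TestFixedLineR2:
    @pytest.mark.parametrize(
        "obs,pred,expected",
        [
            ([1, 2, 3], [1, 2, 3], 1.0),                 # identity
            ([1, 2, 3], [2, 2, 2], 0.0),                 # null predictor (obs mean)
            ([1, 2, 3], [3, 3, 3], -1.5),                # worse than the mean
        ],
    )
    def test_known_values(self, obs, pred, expected):
        assert fixed_line_r2(obs, pred) == pytest.approx(expected)

    def test_zero_variance_rejected(self):
        with pytest.raises(InterfaceError):
            fixed_line_r2([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestEvalMetrics:
    def test_perfect_prediction(self):
        rep = eval_metrics([1.0, 2.0, 4.0], [1.0, 2.0, 4.0])
        assert rep.r2_fixed == 1.0 and rep.r == pytest.approx(1.0) and rep.rmse == 0.0

    def test_constant_offset(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        rep = eval_metrics(obs, obs + 1.0)
        assert rep.r == pytest.approx(1.0)
        assert rep.rmse == pytest.approx(1.0)

    def test_pooled_rmse_is_weighted_mean_of_group_rmse(self, rng):
        obs = rng.uniform(1, 10, 30)
        pred = obs + rng.normal(0, 1, 30)
        groups = np.array(["a"] * 12 + ["b"] * 18)
        overall, per = eval_metrics(obs, pred, groups=groups)
        pooled_sq = (per["a"].rmse**2 * 12 + per["b"].rmse**2 * 18) / 30
        assert overall.rmse == pytest.approx(np.sqrt(pooled_sq))

    def test_invariant_under_pair_reordering(self, rng):
        obs = rng.uniform(1, 10, 20)
        pred = obs + rng.normal(0, 1, 20)
        perm = rng.permutation(20)
        a = eval_metrics(obs, pred)
        b = eval_metrics(obs[perm], pred[perm])
        assert a.r2_fixed == pytest.approx(b.r2_fixed)
        assert a.rmse == pytest.approx(b.rmse)

    def test_tiny_group_reported_with_missing_statistics(self):
        overall, per = eval_metrics([1, 2, 3], [1, 2, 3], groups=["a", "a", "b"])
        assert per["b"].n == 1
        assert np.isnan(per["b"].r2_fixed)


class TestDepthIntervalStock:
    def test_uniform_concentration(self, grid):
        conc = np.full(grid.n_layers, 10.0)
        assert depth_interval_stock(conc, grid, (0, 0.3)) == pytest.approx(3.0)

    def test_full_column_equals_thickness_sum(self, grid, rng):
        conc = rng.uniform(0, 30, grid.n_layers)
        total = depth_interval_stock(conc, grid, (0, grid.total_depth))
        assert total == pytest.approx(float(np.sum(conc * grid.thickness)), abs=1e-9)

    def test_matches_millimetre_quadrature(self, grid, rng):
        conc = rng.uniform(0, 30, grid.n_layers)
        z = np.arange(0, grid.total_depth, 1e-3) + 5e-4
        piecewise = conc[np.searchsorted(grid.interface_depth, z)]
        for interval in [(0, 0.3), (0.3, 1.0), (1.0, 2.0), (0.17, 2.93)]:
            ours = depth_interval_stock(conc, grid, interval)
            ref = float(np.sum(piecewise[(z >= interval[0]) & (z < interval[1])]) * 1e-3)
            assert ours == pytest.approx(ref, abs=0.05)

    def test_nested_intervals_monotone(self, grid, rng):
        conc = rng.uniform(0, 30, grid.n_layers)
        s30 = depth_interval_stock(conc, grid, (0, 0.3))
        s100 = depth_interval_stock(conc, grid, (0, 1.0))
        s200 = depth_interval_stock(conc, grid, (0, 2.0))
        assert s30 <= s100 <= s200

    def test_interval_beyond_column_truncated(self, grid):
        conc = np.full(grid.n_layers, 1.0)
        assert depth_interval_stock(conc, grid, (0, 50.0)) == pytest.approx(grid.total_depth)

    def test_invalid_interval_rejected(self, grid):
        with pytest.raises(InterfaceError):
            depth_interval_stock(np.ones(grid.n_layers), grid, (1.0, 0.5))


class TestContinentalTotal:
    def test_single_square_metre_unit_conversion(self):
        # 1 kg C m^-2 over 1 m^2 = 1e3 g = 1e-12 Pg
        dom = GridDomain(lats=np.array([0.0]), lons=np.array([0.0]), mask=np.ones((1, 1), bool))
        area = dom.cell_area()[0, 0]
        stock = np.array([[1.0 / area]])  # total mass 1 kg
        assert continental_total(stock, dom) == pytest.approx(1e-12)

    def test_matches_naive_double_loop(self, domain, rng):
        stock = rng.uniform(0, 30, domain.mask.shape)
        area = domain.cell_area()
        naive = 0.0
        for i in range(stock.shape[0]):
            for j in range(stock.shape[1]):
                naive += stock[i, j] * area[i, j]
        assert continental_total(stock, domain) == pytest.approx(naive * 1e3 / 1e15)

    def test_linear_in_uniform_stock(self, domain):
        a = continental_total(np.full(domain.mask.shape, 2.0), domain)
        b = continental_total(np.full(domain.mask.shape, 4.0), domain)
        assert b == pytest.approx(2 * a)


class TestDeviationMap:
    def test_zero_deviation(self):
        obs = np.array([1.0, 2.0, 3.0])
        np.testing.assert_allclose(deviation_map(obs, obs), 0.0)

    def test_quantile_scaling_of_positive_branch(self):
        obs = np.zeros(3)
        mod = np.array([1.0, 2.0, 100.0])
        out = deviation_map(obs, mod)
        q95 = np.quantile([1.0, 2.0, 100.0], 0.95)
        assert out[1] == pytest.approx(min(2.0 / q95, 1.0))

    def test_output_bounded(self, rng):
        obs = rng.uniform(0, 10, 200)
        mod = obs + rng.normal(0, 5, 200)
        out = deviation_map(obs, mod)
        assert np.all((out >= -1) & (out <= 1))


class TestSiteCellAssignment:
    def test_containment_and_boundary_convention(self, domain):
        i, j = domain.cell_index(40.25, -100.25)
        assert (i, j) == (0, 0)
        # edge point belongs to the half-open box it opens: deterministic
        i, j = domain.cell_index(40.5, -100.0)
        assert (i, j) == (1, 1)
        i, j = domain.cell_index(40.49999, -100.00001)
        assert (i, j) == (0, 0)

    def test_every_site_maps_to_one_cell(self, domain, rng):
        for _ in range(50):
            lat = rng.uniform(40.0, 42.0)
            lon = rng.uniform(-100.5, -98.2)
            i, j = domain.cell_index(lat, lon)
            assert abs(domain.lats[i] - lat) <= 0.25 + 1e-9
            assert abs(domain.lons[j] - lon) <= 0.25 + 1e-9

    def test_outside_domain_rejected(self, domain):
        with pytest.raises(InterfaceError):
            domain.cell_index(10.0, 0.0)
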