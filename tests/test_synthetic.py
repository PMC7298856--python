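import numpy as np
import pytest
from scipy import stats

from vectorenm.grids import Grid, GridMismatchError
from vectorenm import synthetic as syn


@pytest.fixture(scope="module")
def grid100():
    return Grid(100, 100, 0.2, -100.0, 0.0)


class TestEnvStack:
    def test_identity_correlation_gives_independent_layers(self, grid100):
        spec = syn.SyntheticSpec(grid=grid100, n_layers=4, correlation=0.0, seed=1)
        X = syn.gen_env_stack(spec).table()
        R = np.corrcoef(X, rowvar=False)
        off = R[~np.eye(4, dtype=bool)]
        assert np.all(np.abs(off) < 0.1)

    def test_strong_correlation_recovered(self, grid100):
        spec = syn.SyntheticSpec(grid=grid100, n_layers=2, correlation=0.95, seed=2)
        X = syn.gen_env_stack(spec).table()
        r = np.corrcoef(X[:, 0], X[:, 1])[0, 1]
        assert 0.85 <= r <= 1.0

    def test_requested_matrix_within_tolerance(self, grid100):
        C = np.array([[1, 0.5, 0.2], [0.5, 1, -0.3], [0.2, -0.3, 1]])
        spec = syn.SyntheticSpec(grid=grid100, n_layers=3, correlation=C, seed=3)
        X = syn.gen_env_stack(spec).table()
        np.testing.assert_allclose(np.corrcoef(X, rowvar=False), C, atol=0.1)

    def test_deterministic_for_seed(self, grid100):
        spec = syn.SyntheticSpec(grid=grid100, n_layers=3, seed=9)
        a = syn.gen_env_stack(spec)
        b = syn.gen_env_stack(spec)
        for n in a.names:
            np.testing.assert_array_equal(a[n], b[n])

    def test_non_psd_correlation_rejected(self, grid100):
        C = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        with pytest.raises(syn.InvalidSpecError):
            syn.SyntheticSpec(grid=grid100, n_layers=3, correlation=C)

    def test_too_few_layers_rejected(self, grid100):
        with pytest.raises(syn.InvalidSpecError):
            syn.SyntheticSpec(grid=grid100, n_layers=1)


class TestFutureStacks:
    def test_counts_and_keys(self, grid100):
        spec = syn.SyntheticSpec(grid=grid100, n_layers=2, n_gcm=20, seed=4)
        base = syn.gen_env_stack(spec)
        fut = syn.gen_future_stacks(base, spec)
        assert len(fut) == 20 * 2 * 2
        gcms = {k[0] for k in fut}
        assert len(gcms) == 20

    def test_zero_shift_zero_noise_equals_baseline(self, grid100):
        spec = syn.SyntheticSpec(
            grid=grid100, n_layers=2, n_gcm=2, gcm_noise_sd=0.0,
            scenario_shifts={("rcp45", "2050"): 0.0}, seed=4,
        )
        base = syn.gen_env_stack(spec)
        fut = syn.gen_future_stacks(base, spec)
        for st in fut.values():
            for n in base.names:
                np.testing.assert_array_equal(st[n], base[n])

    def test_constant_shift_on_one_layer(self, grid100):
        spec = syn.SyntheticSpec(
            grid=grid100, n_layers=2, n_gcm=3, gcm_noise_sd=0.0,
            scenario_shifts={("rcp85", "2070"): [2.0, 0.0]}, seed=4,
        )
        base = syn.gen_env_stack(spec)
        fut = syn.gen_future_stacks(base, spec)
        st = fut[("gcm01", "rcp85", "2070")]
        np.testing.assert_allclose(st[base.names[0]] - base[base.names[0]], 2.0)
        np.testing.assert_allclose(st[base.names[1]], base[base.names[1]])

    def test_mean_anomaly_near_specified_shift(self, grid100):
        sd = 0.3
        spec = syn.SyntheticSpec(
            grid=grid100, n_layers=2, n_gcm=20, gcm_noise_sd=sd,
            scenario_shifts={("rcp45", "2050"): 1.0}, seed=11,
        )
        base = syn.gen_env_stack(spec)
        fut = syn.gen_future_stacks(base, spec)
        anom = np.mean([
            (st[base.names[0]] - base[base.names[0]]).mean() for st in fut.values()
        ])
        assert abs(anom - 1.0) <= 3 * sd / np.sqrt(20)

    def test_grid_mismatch_rejected(self, grid100):
        spec = syn.SyntheticSpec(grid=grid100, n_layers=2, seed=4)
        other = syn.SyntheticSpec(grid=Grid(10, 10, 0.2), n_layers=2, seed=4)
        base = syn.gen_env_stack(other)
        with pytest.raises(GridMismatchError):
            syn.gen_future_stacks(base, spec)


class TestOccurrenceSampling:
    def test_single_hot_cell_takes_all_points(self):
        g = Grid(5, 5, 1.0)
        suit = np.zeros(g.shape)
        suit[2, 3] = 1.0
        truth = syn.TruthSurface(suit, g, np.ones(g.shape, bool), {}, 0.0)
        occ = syn.sample_occurrences(truth, 10, seed=0)
        assert len(occ) == 10
        lon, lat = g.center_of(2, 3)
        assert (occ["longitude"] == lon).all() and (occ["latitude"] == lat).all()

    def test_zero_points(self, truth60):
        assert len(syn.sample_occurrences(truth60, 0)) == 0

    def test_degenerate_truth_raises(self):
        g = Grid(3, 3, 1.0)
        truth = syn.TruthSurface(np.zeros(g.shape), g, np.ones(g.shape, bool), {}, 0.0)
        with pytest.raises(syn.DegenerateTruthError):
            syn.sample_occurrences(truth, 5, seed=0)

    def test_uniform_truth_is_multinomial_uniform(self):
        g = Grid(10, 10, 1.0)
        truth = syn.TruthSurface(np.ones(g.shape), g, np.ones(g.shape, bool), {}, 0.0)
        occ = syn.sample_occurrences(truth, 5000, seed=1)
        counts = np.zeros(100)
        for lon, lat in occ[["longitude", "latitude"]].to_numpy():
            r, c = g.cell_of(lon, lat)
            counts[r * 10 + c] += 1
        p = stats.chisquare(counts).pvalue
        assert p > 0.001

    def test_proportional_sampling_matches_multinomial(self, truth60, grid60):
        occ = syn.sample_occurrences(truth60, 8000, seed=2)
        w = np.nan_to_num(truth60.suitability).ravel()
        counts = np.zeros(w.size)
        for lon, lat in occ[["longitude", "latitude"]].to_numpy():
            r, c = grid60.cell_of(lon, lat)
            counts[r * grid60.ncols + c] += 1
        keep = w > 0
        expected = 8000 * w[keep] / w[keep].sum()
        # pool cells with small expectation for a valid chi-square
        big = expected >= 5
        chi = ((counts[keep][big] - expected[big]) ** 2 / expected[big]).sum()
        chi += (counts[keep][~big].sum() - expected[~big].sum()) ** 2 / max(
            expected[~big].sum(), 1e-9
        )
        dof = big.sum()
        assert stats.chi2.sf(chi, dof) > 0.001


class TestCattleRegions:
    def test_partition_and_skew(self, spec60):
        cattle, regions = syn.gen_cattle_and_regions(spec60, n_regions=3)
        assert cattle.min() >= 0
        assert set(np.unique(regions)) == {1, 2, 3}
        # right-skewed: mean well above median
        assert cattle.mean() > np.median(cattle)

    def test_two_regions_partition_mask(self, spec60):
        _, regions = syn.gen_cattle_and_regions(spec60, n_regions=2)
        assert set(np.unique(regions)) == {1, 2}

    def test_deterministic(self, spec60):
        a = syn.gen_cattle_and_regions(spec60, 2)
        b = syn.gen_cattle_and_regions(spec60, 2)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])
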