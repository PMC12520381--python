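import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from taainv import gr_membrane as gm
from taainv import grf_insults as gi
from taainv.domain import GridSpec
from taainv.exceptions import (CalibrationError, DataError, ParameterError,
                               PipelineError)


class TestGridSpec:
    def test_coords_match_field_flattening(self, grid):
        coords = grid.coords()
        assert coords.shape == (grid.n_theta * grid.n_z, 2)
        # row k of coords corresponds to element k of field.reshape(-1)
        field = np.arange(grid.n_theta * grid.n_z).reshape(grid.shape)
        i, j = 7, 13
        k = np.flatnonzero(field.reshape(-1) == field[i, j])[0]
        assert coords[k, 0] == pytest.approx(grid.theta_hat[i])
        assert coords[k, 1] == pytest.approx(grid.z_hat[j])

    def test_theta_excludes_endpoint(self, grid):
        assert grid.theta[-1] < 2 * np.pi


class TestKernel:
    def test_covariance_is_periodic_in_theta(self, grid, kernel):
        cov = kernel.covariance(grid)
        # node (0, j) and node (n_theta-1, j) are one grid step apart
        # through the wrap, so their covariance equals that of adjacent rows
        j = 5
        a = 0 * grid.n_z + j
        b = (grid.n_theta - 1) * grid.n_z + j
        c = 1 * grid.n_z + j
        assert cov[a, b] == pytest.approx(cov[a, c], rel=1e-12)

    def test_covariance_symmetric_unit_diagonal(self, grid, kernel):
        cov = kernel.covariance(grid)
        assert np.allclose(cov, cov.T)
        assert np.allclose(np.diag(cov), kernel.variance)

    def test_invalid_lengths_rejected(self):
        with pytest.raises(ParameterError):
            gi.GRFKernel(length_theta=0.0)

    def test_sample_variance_matches_kernel(self):
        # Monte-Carlo: many raw (pre-normalization) draws at each node of a
        # small grid must reproduce the kernel's marginal variance.
        grid = GridSpec(n_theta=9, n_z=9)
        kernel = gi.GRFKernel(variance=1.7, length_theta=1.0, length_z=0.25)
        chol = gi._cholesky_factor(grid, kernel)
        rng = np.random.default_rng(42)
        draws = chol @ rng.standard_normal((chol.shape[0], 10_000))
        var = draws.var(axis=1)
        assert abs(var.mean() - kernel.variance) / kernel.variance < 0.05


class TestSampleProfile:
    def test_deterministic_in_seed(self, grid, kernel):
        a = gi.sample_insult_profile(grid, kernel, seed=99)
        b = gi.sample_insult_profile(grid, kernel, seed=99)
        assert np.array_equal(a.field, b.field)

    def test_different_seeds_differ(self, grid, kernel):
        a = gi.sample_insult_profile(grid, kernel, seed=1)
        b = gi.sample_insult_profile(grid, kernel, seed=2)
        assert not np.array_equal(a.field, b.field)

    def test_zero_variance_gives_zero_profile(self, grid):
        k = gi.GRFKernel(variance=0.0, length_z=0.25)
        p = gi.sample_insult_profile(grid, k, seed=3)
        assert p.is_zero

    def test_range_and_end_taper(self, grid, kernel, profile):
        assert profile.field.min() >= 0.0
        assert profile.field.max() == pytest.approx(1.0)
        assert np.all(profile.field[:, 0] == 0.0)
        assert np.all(profile.field[:, -1] == 0.0)

    def test_smoothness_relative_to_correlation_length(self, grid, kernel):
        # discrete gradient stays bounded by the kernel scale: no
        # single-node spikes
        p = gi.sample_insult_profile(grid, kernel, seed=11)
        dtheta = np.abs(np.diff(p.field, axis=0)).max()
        dz = np.abs(np.diff(p.field, axis=1)).max()
        step_theta = 2 * np.pi / grid.n_theta
        step_z = grid.length / (grid.n_z - 1)
        assert dtheta < 4 * step_theta / kernel.length_theta
        assert dz < 4 * step_z / kernel.length_z


class TestNormalizeProfile:
    @pytest.mark.parametrize("raw,floor,expected", [
        ([1.0, 1.0, 1.0], 0.0, [0.0, 0.0, 0.0]),
        ([0.0, 5.0, 10.0], 0.0, [0.0, 0.5, 1.0]),
        ([0.0, 2.0, 10.0], 0.3, [0.0, 0.0, 1.0]),
    ])
    def test_examples(self, raw, floor, expected):
        out = gi.normalize_profile(np.array(raw), floor_frac=floor)
        assert np.allclose(out.field, expected)

    def test_non_finite_rejected(self):
        with pytest.raises(DataError):
            gi.normalize_profile(np.array([0.0, np.nan]))

    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=30),
           st.floats(0.0, 0.9))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_output_always_in_unit_interval(self, raw, floor):
        out = gi.normalize_profile(np.array(raw), floor_frac=floor)
        assert out.field.min() >= 0.0
        if not out.is_zero:
            assert out.field.max() == pytest.approx(1.0)


class TestInsultPair:
    def test_pure_elastic_hits_cap(self, profile):
        pair = gi.make_insult_pair(profile, w=1.0, s=1.0)
        assert pair.theta_ce.max() == pytest.approx(0.48)
        assert np.all(pair.theta_delta == 0.0)

    def test_pure_mechanosensing_hits_cap(self, profile):
        pair = gi.make_insult_pair(profile, w=0.0, s=1.0)
        assert pair.theta_delta.max() == pytest.approx(0.28)
        assert np.all(pair.theta_ce == 0.0)

    def test_even_mixture_arithmetic(self):
        half = gi.InsultProfile(field=np.full((3, 3), 0.5))
        pair = gi.make_insult_pair(half, w=0.5, s=1.0)
        assert pair.theta_ce.max() == pytest.approx(0.12)
        assert pair.theta_delta.max() == pytest.approx(0.07)

    def test_cap_violation_rejected(self, profile):
        with pytest.raises(ParameterError):
            gi.make_insult_pair(profile, w=1.0, s=1.5)

    def test_zero_profile_gives_zero_fields(self):
        zero = gi.InsultProfile(field=np.zeros((3, 3)))
        pair = gi.make_insult_pair(zero, w=0.5, s=1.0)
        assert np.all(pair.theta_ce == 0.0)
        assert np.all(pair.theta_delta == 0.0)


class TestCalibrateScale:
    def test_zero_profile_unreachable(self, wall_params, grid):
        zero = gi.InsultProfile(field=np.zeros(grid.shape))
        with pytest.raises(CalibrationError):
            gi.calibrate_scale(zero, w=0.5, params=wall_params, grid=grid)

    def test_hits_target_and_is_deterministic(self, profile, wall_params,
                                              grid):
        s1 = gi.calibrate_scale(profile, 0.5, wall_params, grid)
        s2 = gi.calibrate_scale(profile, 0.5, wall_params, grid)
        assert s1 == s2
        assert abs(gi._dmax(profile, 0.5, s1, wall_params, grid, 3)
                   - 1.5) <= 0.01


class TestBuildDataset:
    def test_record_count(self, small_records):
        assert len(small_records) == 4 * 2

    def test_counts_for_other_shapes(self, wall_params):
        recs = gi.build_dataset(n_profiles=2, combos=(0.5,), base_seed=3,
                                sim_params=wall_params)
        assert len(recs) == 2

    def test_all_records_calibrated(self, small_records):
        for r in small_records:
            assert abs(r.heat.d.max() - 1.5) <= 0.01

    def test_caps_respected(self, small_records):
        for r in small_records:
            assert r.pair.theta_ce.max() <= 0.48 + 1e-12
            assert r.pair.theta_delta.max() <= 0.28 + 1e-12

    def test_pure_function_of_seed(self, wall_params, small_records):
        again = gi.build_dataset(n_profiles=4, combos=(0.25, 0.75),
                                 base_seed=7, sim_params=wall_params)
        for a, b in zip(small_records, again):
            assert a.record_id == b.record_id
            assert np.array_equal(a.pair.theta_ce, b.pair.theta_ce)
            assert np.array_equal(a.heat.d, b.heat.d)
            assert np.array_equal(a.gray.D, b.gray.D)

    def test_bad_arguments(self, wall_params):
        with pytest.raises(ParameterError):
            gi.build_dataset(n_profiles=0, sim_params=wall_params)
        with pytest.raises(ParameterError):
            gi.build_dataset(n_profiles=1, combos=(), sim_params=wall_params)
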