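import math

import numpy as np
import pytest

from cmbdf.basis import WeightingSpec, weighting_value
from cmbdf.grids import (
    GridSet,
    build_angular_grid,
    build_radial_grid,
    load_gridset,
    lookup,
    save_gridset,
)
from cmbdf.oracle import convolved_value


@pytest.fixture(scope="module")
def radial_grid():
    return build_radial_grid(WeightingSpec(2, "decay_exp", 0), 2, 0.6, x_hi=8.0)


class TestBuildRadial:
    def test_small_sigma_limit_recovers_weighting(self):
        # as sigma -> 0 the Gaussian kernel acts as a delta at interior nodes
        spec = WeightingSpec(2, "decay_exp", 0)
        grid = build_radial_grid(spec, 0, sigma=0.01, x_hi=4.0, dx=0.002)
        x = grid.nodes[200:1800]
        np.testing.assert_allclose(
            grid.values[200:1800], weighting_value(spec, x), rtol=1e-3
        )

    def test_nodes_match_quadrature_oracle(self, radial_grid):
        peak = np.abs(radial_grid.values).max()
        for k in range(40, len(radial_grid.values), 450):
            x = radial_grid.nodes[k]
            ref = convolved_value(radial_grid.spec, 2, 0.6, x)
            if abs(ref) > 1e-10 * peak:
                assert radial_grid.values[k] == pytest.approx(ref, rel=1e-3)
            else:
                assert abs(radial_grid.values[k] - ref) <= 1e-8 * peak

    def test_too_coarse_spacing_refused(self):
        with pytest.raises(ValueError, match="too coarse"):
            build_radial_grid(WeightingSpec(2, "decay_exp", 0), 0, 0.6, 8.0, dx=0.2)

    def test_angular_family_rejected(self):
        with pytest.raises(ValueError):
            build_radial_grid(WeightingSpec(3, "cosine", 0), 0, 0.6, 8.0)

    def test_rebuild_is_bit_identical(self, radial_grid):
        again = build_radial_grid(WeightingSpec(2, "decay_exp", 0), 2, 0.6, x_hi=8.0)
        assert np.array_equal(radial_grid.values, again.values)

    def test_resolution_convergence(self, radial_grid):
        finer = build_radial_grid(
            WeightingSpec(2, "decay_exp", 0), 2, 0.6, x_hi=8.0, dx=0.001
        )
        xs = np.linspace(0.05, 7.5, 57)
        a = lookup(radial_grid, xs)
        b = lookup(finer, xs)
        assert np.abs(a - b).max() < 1e-4 * np.abs(b).max()


class TestBuildAngular:
    def test_sine_family_vanishes_at_origin(self):
        for n in range(2):
            grid = build_angular_grid(WeightingSpec(3, "sine", n), 0, 0.2)
            assert abs(grid.values[0]) < 1e-12 * np.abs(grid.values).max()

    def test_nodes_match_periodic_quadrature(self):
        grid = build_angular_grid(WeightingSpec(3, "cosine", 0), 0, 0.2)
        for k in range(0, 2048, 400):
            ref = convolved_value(grid.spec, 0, 0.2, grid.nodes[k])
            assert grid.values[k] == pytest.approx(ref, rel=1e-3, abs=1e-10)

    def test_wraps_periodically(self):
        grid = build_angular_grid(WeightingSpec(3, "cosine", 1), 1, 0.2)
        assert lookup(grid, 0.0) == pytest.approx(
            lookup(grid, 2 * math.pi), abs=1e-12
        )

    def test_node_count_must_be_power_of_two(self):
        with pytest.raises(ValueError):
            build_angular_grid(WeightingSpec(3, "cosine", 0), 0, 0.2, n_nodes=1000)


class TestLookup:
    def test_exact_node_returns_stored_value(self, radial_grid):
        k = 1234
        for mode in ("cubic", "linear", "nearest"):
            assert lookup(radial_grid, radial_grid.nodes[k], mode) == pytest.approx(
                radial_grid.values[k], rel=1e-12
            )

    def test_linear_midpoint_is_mean_of_bracketing_nodes(self, radial_grid):
        k = 777
        mid = radial_grid.nodes[k] + 0.5 * radial_grid.dx
        expected = 0.5 * (radial_grid.values[k] + radial_grid.values[k + 1])
        assert lookup(radial_grid, mid, "linear") == pytest.approx(expected, rel=1e-12)

    def test_beyond_domain_returns_zero(self, radial_grid):
        assert lookup(radial_grid, radial_grid.x_hi + 1.0) == 0.0

    def test_nan_rejected(self, radial_grid):
        with pytest.raises(ValueError, match="NaN"):
            lookup(radial_grid, float("nan"))

    def test_negative_distance_rejected(self, radial_grid):
        with pytest.raises(ValueError):
            lookup(radial_grid, -0.5)


class TestGridSet:
    def test_complete_for_configuration(self, cfg3, grids3):
        # every (nu, type, n, m) needed by features AND gradients exists
        for nu in (2, 3):
            sigma = cfg3.kernel_sigmas(nu)[0]
            for t in range(2):
                for n in range(cfg3.n_max):
                    for m in range(cfg3.m_max + 2):
                        grids3.get(nu, t, n, m, sigma)
        assert len(grids3) == 2 * 2 * cfg3.n_max * (cfg3.m_max + 2)

    def test_missing_grid_error_names_key(self, grids3):
        with pytest.raises(KeyError, match="nu=4"):
            grids3.get(4, 0, 0, 0, 0.6)

    def test_derivative_identity_on_stored_grids(self, cfg3, grids3):
        # central-difference slope of H_m equals -(1/(sqrt2 sigma)) H_{m+1}
        for (nu, t, n, m, sigma), grid in grids3:
            if m > cfg3.m_max:
                continue
            partner = grids3.get(nu, t, n, m + 1, sigma)
            fd = (grid.values[2:] - grid.values[:-2]) / (2 * grid.dx)
            ref = -partner.values[1:-1] / (math.sqrt(2) * sigma)
            # absolute floor above the O(dx^2) FD truncation error so the
            # relative check only applies away from zero crossings
            floor = 1e-4 * np.abs(ref).max()
            np.testing.assert_allclose(fd, ref, rtol=1e-3, atol=floor)

    def test_hdf5_roundtrip(self, grids3, tmp_path):
        path = tmp_path / "grids.h5"
        save_gridset(grids3, path)
        loaded = load_gridset(path)
        assert len(loaded) == len(grids3)
        for key, grid in grids3:
            other = loaded.get(*key)
            assert np.array_equal(grid.values, other.values)
            assert other.spec == grid.spec
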