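import numpy as np
import pytest

from nucleoquant import (
    TwoChannelModel,
    VoxelStack,
    channel_correlation,
    filter_stack,
    generate_two_channel,
    relative_positional_variance,
    signal_center,
)
from nucleoquant.errors import (
    GeometryError,
    InsufficientDataError,
    UndefinedStatisticError,
)
from nucleoquant.segmentation import FilteredStack


def stack_from_points(points, shape=(9, 21, 21), value=100.0, voxel_size=(1.0, 1.0, 1.0)):
    """FilteredStack whose foreground is exactly the given (z, y, x) points."""
    arr = np.zeros(shape)
    for p, v in points.items():
        arr[p] = v if v is not None else value
    stack = VoxelStack(arr, voxel_size=voxel_size)
    return FilteredStack(source=stack, threshold=0.5, valid_mask=arr > 0.5)


class TestChannelCorrelation:
    def test_identical_channels_give_unit_correlation(self, rng):
        arr = rng.uniform(0, 100, size=(4, 12, 12))
        f = filter_stack(VoxelStack(arr))
        res = channel_correlation(f, f)
        assert res.pearson_r == pytest.approx(1.0, abs=1e-12)

    def test_affine_related_channels_give_unit_correlation(self, rng):
        arr = rng.uniform(1, 100, size=(4, 12, 12))
        a = filter_stack(VoxelStack(arr))
        b = filter_stack(VoxelStack(2.5 * arr + 3.0))
        res = channel_correlation(a, b)
        assert res.pearson_r == pytest.approx(1.0, abs=1e-10)

    def test_shape_mismatch_is_geometry_error(self, rng):
        a = filter_stack(VoxelStack(rng.uniform(0, 9, (2, 5, 5))))
        b = filter_stack(VoxelStack(rng.uniform(0, 9, (2, 6, 6))))
        with pytest.raises(GeometryError):
            channel_correlation(a, b)

    def test_degenerate_variance_is_undefined(self):
        arr_a = np.zeros((1, 3, 3))
        arr_a[0, 0] = 100.0
        arr_b = np.full((1, 3, 3), 42.0)  # constant second channel
        a = FilteredStack(VoxelStack(arr_a), threshold=50.0, valid_mask=arr_a > 50)
        b = FilteredStack(VoxelStack(arr_b), threshold=10.0, valid_mask=arr_b > 10)
        with pytest.raises(UndefinedStatisticError):
            channel_correlation(a, b)

    def test_union_support_sees_exclusion_zones(self):
        # A bright where B is dim and vice versa; the union support keeps
        # the anti-correlated voxels that an intersection rule would drop.
        arr_a = np.zeros((1, 4, 4))
        arr_b = np.zeros((1, 4, 4))
        arr_a[0, :2] = 100.0
        arr_b[0, 2:] = 100.0
        a = stack_from_points({}, shape=(1, 4, 4))
        a = FilteredStack(VoxelStack(arr_a), threshold=50.0, valid_mask=arr_a > 50)
        b = FilteredStack(VoxelStack(arr_b), threshold=50.0, valid_mask=arr_b > 50)
        res = channel_correlation(a, b, support="union")
        assert res.pearson_r == pytest.approx(-1.0, abs=1e-12)
        assert res.n_voxels == 16
        with pytest.raises(InsufficientDataError):
            channel_correlation(a, b, support="intersection")

    def test_shell_pair_less_correlated_than_intermixed(self):
        r = {}
        for geom in ("intermixed", "shell"):
            a, b, _ = generate_two_channel(TwoChannelModel(geometry=geom, seed=5))
            r[geom] = channel_correlation(filter_stack(a), filter_stack(b)).pearson_r
        assert r["shell"] < r["intermixed"]


class TestSignalCenter:
    def test_single_voxel(self):
        f = stack_from_points({(3, 10, 12): 50.0})
        assert signal_center(f) == (3.0, 10.0, 12.0)

    def test_two_equal_masses_balance(self):
        f = stack_from_points({(0, 0, 0): 80.0, (0, 0, 10): 80.0})
        assert signal_center(f) == (0.0, 0.0, 5.0)

    def test_intensity_weighting_shifts_center(self):
        f = stack_from_points({(0, 0, 0): 300.0, (0, 0, 10): 100.0})
        assert signal_center(f, weighted=True)[2] == pytest.approx(2.5)
        assert signal_center(f, weighted=False)[2] == pytest.approx(5.0)

    def test_symmetric_ball_centers_within_tenth_voxel(self):
        a, b, truth = generate_two_channel(
            TwoChannelModel(noise_model="none", psf_sigma=0.0, seed=0)
        )
        c = signal_center(filter_stack(b))
        assert np.allclose(c, truth.center, atol=0.1)

    def test_micron_units_scale_by_voxel_size(self):
        f = stack_from_points({(2, 4, 6): 10.0}, voxel_size=(0.3, 0.1, 0.1))
        c = signal_center(f, units="um")
        assert c == pytest.approx((0.6, 0.4, 0.6))


class TestRelativePositionalVariance:
    def test_two_distance_arithmetic(self):
        f = stack_from_points({(0, 0, 1): 10.0, (0, 0, 3): 10.0})
        d = relative_positional_variance(f, (0, 0, 0), units="voxel")
        assert d.mu == pytest.approx(2.0)
        assert d.sigma2 == pytest.approx(1.0)
        assert d.rpv == pytest.approx(0.5)

    def test_equidistant_shell_has_zero_rpv(self):
        pts = {(0, 0, 4): 9.0, (0, 4, 0): 9.0, (4, 0, 0): 9.0, (0, 0, -4 % 21): None}
        f = stack_from_points({k: v for k, v in pts.items() if v is not None})
        d = relative_positional_variance(f, (0, 0, 0), units="voxel")
        assert d.rpv == pytest.approx(0.0, abs=1e-12)

    def test_uniform_ball_matches_analytic_limit(self):
        # continuum: mu = 3R/4, sigma^2 = 3R^2/80, rpv = R/20
        R, n = 10.0, 31
        zz, yy, xx = np.indices((n, n, n), dtype=float)
        c = (n - 1) / 2
        arr = np.where(
            (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= R**2, 100.0, 0.0
        )
        f = FilteredStack(
            VoxelStack(arr, voxel_size=(1, 1, 1)), threshold=50.0, valid_mask=arr > 50
        )
        d = relative_positional_variance(f, (c, c, c), units="voxel")
        # independent direct-summation oracle over the same lattice
        dist = np.linalg.norm(np.argwhere(arr > 50) - c, axis=1)
        assert d.mu == pytest.approx(dist.mean(), abs=1e-12)
        assert d.rpv == pytest.approx(dist.var() / dist.mean(), abs=1e-12)
        assert d.rpv == pytest.approx(R / 20, abs=0.05)

    def test_rpv_scales_linearly_with_space(self):
        f1 = stack_from_points({(0, 1, 1): 5.0, (0, 3, 4): 5.0, (0, 5, 2): 5.0})
        f2 = stack_from_points(
            {(0, 1, 1): 5.0, (0, 3, 4): 5.0, (0, 5, 2): 5.0},
            voxel_size=(3.0, 3.0, 3.0),
        )
        d1 = relative_positional_variance(f1, (0, 0, 0), units="um")
        d2 = relative_positional_variance(f2, (0, 0, 0), units="um")
        assert d2.rpv == pytest.approx(3.0 * d1.rpv, rel=1e-12)

    def test_voxel_mode_agrees_with_isotropic_physical_mode(self):
        pts = {(1, 2, 3): 7.0, (4, 5, 6): 7.0, (2, 8, 1): 7.0}
        f = stack_from_points(pts, voxel_size=(1.0, 1.0, 1.0))
        dv = relative_positional_variance(f, (0, 0, 0), units="voxel")
        du = relative_positional_variance(f, (0, 0, 0), units="um")
        assert dv.rpv == pytest.approx(du.rpv, rel=1e-12)

    def test_anisotropic_voxels_change_physical_distances(self):
        pts = {(1, 0, 0): 7.0, (0, 0, 3): 7.0}
        f = stack_from_points(pts, voxel_size=(0.3, 0.1, 0.1))
        du = relative_positional_variance(f, (0, 0, 0), units="um")
        assert du.distances == pytest.approx([0.3, 0.3])
        assert du.rpv == pytest.approx(0.0, abs=1e-12)

    def test_single_voxel_signal_is_insufficient(self):
        f = stack_from_points({(2, 2, 2): 5.0})
        with pytest.raises(InsufficientDataError):
            relative_positional_variance(f, (0, 0, 0), units="voxel")

    def test_weighted_variant_concentrates_toward_heavy_voxels(self):
        arr = np.zeros((5, 5, 5))
        arr[2, 2, 2] = 1e6
        arr[2, 2, 4] = 1.0
        f = FilteredStack(VoxelStack(arr), threshold=0.0, valid_mask=arr > 0)
        heavy = relative_positional_variance(
            f, (2, 2, 2), units="voxel", weighted=True
        )
        even = relative_positional_variance(
            f, (2, 2, 2), units="voxel", weighted=False
        )
        assert heavy.mu < even.mu  # nearly all weight at distance zero

    def test_shell_below_intermixed_across_pairs(self):
        wins = 0
        for i in range(10):
            ai, bi, _ = generate_two_channel(
                TwoChannelModel(geometry="intermixed", seed=300 + i)
            )
            as_, bs, _ = generate_two_channel(
                TwoChannelModel(geometry="shell", seed=400 + i)
            )
            fi, fbi = filter_stack(ai), filter_stack(bi)
            fs, fbs = filter_stack(as_), filter_stack(bs)
            ri = relative_positional_variance(
                fi, signal_center(fbi), units="voxel"
            ).rpv
            rs = relative_positional_variance(
                fs, signal_center(fbs), units="voxel"
            ).rpv
            wins += rs < ri
        assert wins == 10
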