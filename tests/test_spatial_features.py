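"""Mean-shift mode seeking, bandwidth estimation, mode-grid encoding and PCA.

The mean-shift implementation is checked against an independent brute-force
iterator (scalar loop, per-seed, tighter tolerance) on random clouds, and
against planted-blob maps where the true mode location is known.
"""

import numpy as np
import pytest

import emgmodes as em
from emgmodes.data_io import ValidationError
from emgmodes.spatial_features import MapPointCloud


def cloud_of(points):
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    dim = pts.shape[1]
    return MapPointCloud(points=pts, transform=np.vstack([np.zeros(dim), np.ones(dim)]))


def brute_force_modes(points, h, tol, max_iter=2000):
    """Independent oracle: plain per-seed flat-kernel iteration + greedy merge."""
    points = np.asarray(points, dtype=float)
    ends = []
    for seed in points:
        y = seed.copy()
        for _ in range(max_iter):
            d = np.sqrt(((points - y) ** 2).sum(axis=1))
            new = points[d <= h].mean(axis=0)
            done = np.sqrt(((new - y) ** 2).sum()) <= tol
            y = new
            if done:
                break
        ends.append(y)
    ends = np.array(ends)
    dens = np.array([(np.sqrt(((points - y) ** 2).sum(axis=1)) <= h).sum() for y in ends])
    modes = []
    # density-descending greedy merge, ties in seed order (shared convention)
    for i in np.argsort(-dens, kind="stable"):
        if all(np.sqrt(((ends[i] - m) ** 2).sum()) > h for m in modes):
            modes.append(ends[i])
    return np.array(modes)


def hausdorff(a, b):
    from scipy.spatial.distance import cdist

    d = cdist(a, b)
    return max(d.min(axis=1).max(), d.min(axis=0).max())


class TestPointCloud:
    def test_shape_one_point_per_pixel(self):
        arr = em.ElectrodeArray(name="a", n_rows=2, n_cols=2)
        amap = em.ActivationMap(values=np.arange(4.0).reshape(2, 2), window_index=0,
                                window_ms=150.0, array=arr)
        cloud = em.to_point_cloud(amap)
        assert cloud.points.shape == (4, 3)

    def test_standardization(self, rng):
        arr = em.ElectrodeArray(name="a", n_rows=4, n_cols=6)
        amap = em.ActivationMap(values=np.abs(rng.standard_normal((4, 6))),
                                window_index=0, window_ms=150.0, array=arr)
        cloud = em.to_point_cloud(amap)
        assert np.all(np.abs(cloud.points.mean(axis=0)) < 1e-9)
        assert np.all(np.abs(cloud.points.var(axis=0) - 1.0) < 1e-6)

    def test_constant_intensity_dimension_centered_not_scaled(self):
        arr = em.ElectrodeArray(name="a", n_rows=3, n_cols=3)
        amap = em.ActivationMap(values=np.full((3, 3), 5.0), window_index=0,
                                window_ms=150.0, array=arr)
        cloud = em.to_point_cloud(amap)
        np.testing.assert_array_equal(cloud.points[:, 2], 0.0)
        assert np.isfinite(cloud.points).all()


class TestBandwidth:
    def test_hand_worked_1d_example(self):
        # points {0,1,2,3}, k=2, factor 0.5: kth distances (2,1,1,2) -> h=0.75
        h = em.estimate_bandwidth(cloud_of([[0.0], [1.0], [2.0], [3.0]]),
                                  em.BandwidthSpec(k_fraction=0.5, factor=0.5))
        assert h == pytest.approx(0.75, abs=0)

    def test_two_points_half_distance(self):
        h = em.estimate_bandwidth(cloud_of([[0.0], [4.0]]),
                                  em.BandwidthSpec(k_fraction=0.5, factor=0.5))
        assert h == pytest.approx(2.0)

    def test_metric_homogeneity(self, rng):
        pts = rng.standard_normal((30, 3))
        spec = em.BandwidthSpec()
        h1 = em.estimate_bandwidth(cloud_of(pts), spec)
        h2 = em.estimate_bandwidth(cloud_of(3.0 * pts), spec)
        assert h2 == pytest.approx(3.0 * h1)

    def test_identical_points_rejected(self):
        with pytest.raises(ValidationError):
            em.estimate_bandwidth(cloud_of([[1.0], [1.0], [1.0]]))


class TestMeanShift:
    def test_isolated_points_are_modes(self):
        ms = em.mean_shift(cloud_of([[0.0], [10.0]]), h=1.0)
        assert ms.n_modes == 2
        assert sorted(ms.modes.ravel()) == [0.0, 10.0]

    def test_two_close_points_merge_at_midpoint(self):
        ms = em.mean_shift(cloud_of([[0.0], [1.0]]), h=2.0)
        assert ms.n_modes == 1
        assert ms.modes[0, 0] == pytest.approx(0.5)

    def test_fixed_point_property(self, rng):
        pts = np.concatenate([rng.normal(0, 0.5, (40, 2)), rng.normal(5, 0.5, (40, 2))])
        cloud = cloud_of(pts)
        h = em.estimate_bandwidth(cloud)
        ms = em.mean_shift(cloud, h)
        for mode in ms.modes:
            d = np.sqrt(((pts - mode) ** 2).sum(axis=1))
            step = pts[d <= h].mean(axis=0) - mode
            assert np.sqrt((step**2).sum()) <= ms.tol + 1e-12

    def test_oracle_equivalence_random_clouds(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            n = int(rng.integers(15, 80))
            pts = rng.standard_normal((n, 3))
            cloud = cloud_of(pts)
            h = em.estimate_bandwidth(cloud)
            ms = em.mean_shift(cloud, h)
            oracle = brute_force_modes(pts, h, ms.tol / 10.0)
            assert hausdorff(ms.modes, oracle) <= 2 * ms.tol

    def test_two_planted_blobs_recovered(self):
        # at the default bandwidth factor the method over-segments (more
        # modes than blobs, matching the reference flat-kernel behaviour);
        # each planted blob must nonetheless be marked by exactly one mode
        rng = np.random.default_rng(7)
        arr = em.ElectrodeArray(name="a", n_rows=8, n_cols=15)
        r, c = np.mgrid[0:8, 0:15]
        centers = [(3, 3), (4, 11)]
        blob = sum(
            5.0 * np.exp(-((r - rr) ** 2 + (c - cc) ** 2) / (2 * 2.0**2))
            for rr, cc in centers
        )
        values = (1.0 + blob) * np.abs(1.0 + 0.04 * rng.standard_normal((8, 15)))
        amap = em.ActivationMap(values=values, window_index=0, window_ms=150.0, array=arr)
        grid = em.mode_grid_for_map(amap)
        found = np.argwhere(grid)
        assert len(found) >= 2
        for rr, cc in centers:
            assert (np.abs(found - [rr, cc]).max(axis=1) <= 1).sum() == 1

    def test_matches_reference_mean_shift_implementation(self):
        # independent cross-check: sklearn's flat-kernel MeanShift finds the
        # same number of cluster centres at the same bandwidth
        from sklearn.cluster import MeanShift

        rng = np.random.default_rng(3)
        arr = em.ElectrodeArray(name="a", n_rows=8, n_cols=15)
        r, c = np.mgrid[0:8, 0:15]
        blob = 5.0 * np.exp(-((r - 3) ** 2 + (c - 7) ** 2) / (2 * 2.0**2))
        values = (1.0 + blob) * np.abs(1.0 + 0.04 * rng.standard_normal((8, 15)))
        amap = em.ActivationMap(values=values, window_index=0, window_ms=150.0, array=arr)
        cloud = em.to_point_cloud(amap)
        for factor in (0.5, 1.0):
            h = em.estimate_bandwidth(cloud, em.BandwidthSpec(factor=factor))
            ours = em.mean_shift(cloud, h)
            ref = MeanShift(bandwidth=h).fit(cloud.points)
            assert ours.n_modes == len(ref.cluster_centers_)

    def test_nonpositive_bandwidth_rejected(self):
        with pytest.raises(ValidationError):
            em.mean_shift(cloud_of([[0.0], [1.0]]), h=0.0)

    def test_mode_count_weakly_increases_as_bandwidth_shrinks(self, rng):
        arr = em.ElectrodeArray(name="a", n_rows=8, n_cols=15)
        r, c = np.mgrid[0:8, 0:15]
        values = (
            6.0 * np.exp(-((r - 2) ** 2 + (c - 3) ** 2) / 4.0)
            + 6.0 * np.exp(-((r - 5) ** 2 + (c - 11) ** 2) / 4.0)
            + np.abs(rng.standard_normal((8, 15)))
        )
        amap = em.ActivationMap(values=values, window_index=0, window_ms=150.0, array=arr)
        cloud = em.to_point_cloud(amap)
        counts = []
        for factor in (1.0, 0.8, 0.6, 0.4, 0.2):
            h = em.estimate_bandwidth(cloud, em.BandwidthSpec(factor=factor))
            counts.append(em.mean_shift(cloud, h).n_modes)
        assert counts[-1] >= counts[0]
        for a, b in zip(counts, counts[1:]):
            assert b >= a - 1  # small non-monotonicity = sampling noise


class TestModeGrid:
    def _cloud_with_identity_transform(self, dim=3):
        return np.vstack([np.zeros(dim), np.ones(dim)])

    def test_mode_exactly_on_electrode(self):
        arr = em.ElectrodeArray(name="a", n_rows=8, n_cols=15)
        ms = em.ModeSet(modes=np.array([[7.0, 3.0, 0.5]]), densities=np.array([1]),
                        h=1.0, tol=1e-3, converged=np.array([True]))
        grid = em.modes_to_grid(ms, self._cloud_with_identity_transform(), arr)
        assert grid[3, 7] == 1 and grid.sum() == 1

    def test_fractional_mode_snaps_to_nearest(self):
        arr = em.ElectrodeArray(name="a", n_rows=8, n_cols=15)
        ms = em.ModeSet(modes=np.array([[7.4, 3.4, 0.0]]), densities=np.array([1]),
                        h=1.0, tol=1e-3, converged=np.array([True]))
        grid = em.modes_to_grid(ms, self._cloud_with_identity_transform(), arr)
        assert grid[3, 7] == 1 and grid.sum() == 1

    def test_collision_leaves_single_entry(self):
        arr = em.ElectrodeArray(name="a", n_rows=8, n_cols=15)
        ms = em.ModeSet(modes=np.array([[7.1, 3.1, 0.0], [6.9, 2.9, 5.0]]),
                        densities=np.array([1, 1]), h=1.0, tol=1e-3,
                        converged=np.array([True, True]))
        grid = em.modes_to_grid(ms, self._cloud_with_identity_transform(), arr)
        assert grid.sum() == 1 and grid[3, 7] == 1

    def test_out_of_grid_mode_clamped(self):
        arr = em.ElectrodeArray(name="a", n_rows=4, n_cols=4)
        ms = em.ModeSet(modes=np.array([[99.0, -5.0, 0.0]]), densities=np.array([1]),
                        h=1.0, tol=1e-3, converged=np.array([True]))
        grid = em.modes_to_grid(ms, self._cloud_with_identity_transform(), arr)
        assert grid[0, 3] == 1


class TestPcaReducer:
    def test_single_axis_data_keeps_one(self, rng):
        t = rng.standard_normal(50)
        X = np.outer(t, [1.0, 2.0, -1.0])
        assert em.fit_reducer(X).n_kept == 1

    def test_cumulative_variance_arithmetic(self, rng):
        # variance fractions (0.50, 0.30, 0.15, 0.05) -> n_kept = 3 at 0.90
        n = 20000
        stds = np.sqrt([0.50, 0.30, 0.15, 0.05])
        X = rng.standard_normal((n, 4)) * stds
        reducer = em.fit_reducer(X, var_threshold=0.90)
        assert reducer.n_kept == 3

    def test_threshold_one_keeps_full_rank(self, rng):
        X = rng.standard_normal((30, 5))
        assert em.fit_reducer(X, var_threshold=1.0).n_kept == 5

    def test_zero_variance_matrix_warns(self):
        with pytest.warns(UserWarning):
            reducer = em.fit_reducer(np.ones((5, 3)))
        assert reducer.n_kept == 0

    def test_kept_components_explain_threshold_variance(self, rng):
        X = rng.standard_normal((100, 10)) * np.linspace(3, 0.1, 10)
        reducer = em.fit_reducer(X, var_threshold=0.90)
        Z = em.apply_reducer(reducer, X)
        recon = Z @ reducer.component_basis + reducer.training_means
        explained = 1 - ((X - recon) ** 2).sum() / ((X - X.mean(0)) ** 2).sum()
        assert explained >= 0.90

    def test_minimality_of_n_kept(self, rng):
        X = rng.standard_normal((100, 10)) * np.linspace(3, 0.1, 10)
        reducer = em.fit_reducer(X, var_threshold=0.90)
        assert reducer.variance_fractions.sum() >= 0.90
        assert reducer.variance_fractions[:-1].sum() < 0.90

    def test_dimension_mismatch_rejected(self, rng):
        reducer = em.fit_reducer(rng.standard_normal((10, 4)))
        with pytest.raises(ValidationError):
            em.apply_reducer(reducer, np.zeros(7))


class TestImsComposition:
    def test_spatial_vector_length_equals_total_channels(self, small_benchmark):
        arrays = small_benchmark.arrays
        maps = []
        rng = np.random.default_rng(0)
        for name in ("biceps", "triceps", "forearm"):
            arr = arrays[name]
            maps.append(em.ActivationMap(
                values=np.abs(rng.standard_normal((arr.n_rows, arr.n_cols))) + 1.0,
                window_index=0, window_ms=150.0, array=arr))
        vec = em.spatial_mode_vector(maps)
        assert vec.size == sum(a.n_channels for a in arrays.values())
        assert set(np.unique(vec)) <= {0, 1}

    def test_ims_length_is_nkept_plus_five(self, small_benchmark, rng):
        arrays = small_benchmark.arrays
        maps = []
        for name in ("biceps", "triceps", "forearm"):
            arr = arrays[name]
            maps.append(em.ActivationMap(
                values=np.abs(rng.standard_normal((arr.n_rows, arr.n_cols))) + 1.0,
                window_index=0, window_ms=150.0, array=arr))
        train = np.array([em.spatial_mode_vector(maps) for _ in range(3)])
        train = train + np.random.default_rng(1).integers(0, 2, train.shape)  # add variance
        reducer = em.fit_reducer(train)
        segmented = [s for m in maps for s in em.segment_map(m)]
        fv = em.extract_ims(maps, segmented, reducer)
        assert fv.values.size == reducer.n_kept + 5
        assert fv.provenance == "IMS"

    def test_identical_maps_give_identical_vectors(self, small_benchmark, rng):
        arrays = small_benchmark.arrays
        maps = []
        for name in ("biceps", "triceps", "forearm"):
            arr = arrays[name]
            maps.append(em.ActivationMap(
                values=np.abs(rng.standard_normal((arr.n_rows, arr.n_cols))) + 1.0,
                window_index=0, window_ms=150.0, array=arr))
        a = em.spatial_mode_vector(maps)
        b = em.spatial_mode_vector(maps)
        np.testing.assert_array_equal(a, b)
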