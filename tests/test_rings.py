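"""Ring construction, space-time maps, summed activation, bands."""

import numpy as np
import pytest

from vsdpop.core import AcquisitionSpec, DffMovie
from vsdpop.rings import (build_rings, normalize_to_center,
                          ring_tc, spacetime_map, spatial_profile,
                          summed_activation)

ACQ = AcquisitionSpec()  # 100 x 100 px, 50 um pitch


class TestBuildRings:
    def test_exactly_40_rings(self):
        rings = build_rings((50, 50), ACQ)
        assert rings.n_rings == 40
        assert rings.labels.max() == 40

    def test_ring1_is_four_edge_neighbors(self):
        rings = build_rings((50, 50), ACQ)
        members = set(map(tuple, np.argwhere(rings.members(1))))
        assert members == {(49, 50), (51, 50), (50, 49), (50, 51)}

    def test_partition_disjoint_and_covering(self):
        """Every pixel with 0 < d <= 2000 um is in exactly one ring."""
        rings = build_rings((50, 50), ACQ)
        d = ACQ.distance_um((50, 50))
        in_range = (d > 0) & (d <= 2000.0)
        total = sum(rings.members(k).sum() for k in range(1, 41))
        assert total == in_range.sum()
        assert (rings.labels[in_range] >= 1).all()
        assert (rings.labels[~in_range] == 0).all()

    def test_interval_rule_brute_force(self):
        """Ring index matches (k-1)*50 < d <= k*50 on every pixel."""
        rings = build_rings((30, 70), ACQ)
        d = ACQ.distance_um((30, 70))
        k = rings.labels
        sel = k > 0
        assert np.all(d[sel] > (k[sel] - 1) * 50.0 - 1e-6)
        assert np.all(d[sel] <= k[sel] * 50.0 + 1e-6)

    def test_center_outside_frame_raises(self):
        with pytest.raises(ValueError):
            build_rings((120, 50), ACQ)


class TestSpaceTimeMap:
    def gaussian_movie(self, sigma_um=500.0, amp=1.0):
        d = ACQ.distance_um((50, 50))
        data = np.zeros((ACQ.n_frames, 100, 100))
        data[ACQ.frame_at(20.0)] = amp * np.exp(-d ** 2 / (2 * sigma_um ** 2))
        return DffMovie(data=data, acq=ACQ)

    def test_gaussian_ring_means_decrease_with_distance(self):
        movie = self.gaussian_movie()
        rings = build_rings((50, 50), ACQ)
        stm = spacetime_map(movie, rings)
        col = stm.values[:, stm.frame_index(20.0)]
        assert np.all(np.diff(col) < 0)

    def test_constant_movie_constant_map(self):
        movie = DffMovie(data=np.full((ACQ.n_frames, 100, 100), 0.3), acq=ACQ)
        rings = build_rings((50, 50), ACQ)
        stm = spacetime_map(movie, rings)
        np.testing.assert_allclose(stm.values, 0.3)
        np.testing.assert_allclose(stm.center, 0.3)

    def test_matches_bruteforce_oracle_small_movie(self):
        acq = AcquisitionSpec(height_px=20, width_px=20, n_frames=6,
                              onset_frame=2)
        rng = np.random.default_rng(1)
        data = rng.normal(size=(6, 20, 20))
        movie = DffMovie(data=data, acq=acq)
        rings = build_rings((10, 10), acq, max_radius_um=500.0)
        stm = spacetime_map(movie, rings)
        d = acq.distance_um((10, 10))
        for k in range(1, rings.n_rings + 1):
            mask = (d > (k - 1) * 50.0) & (d <= k * 50.0 + 1e-9)
            for f in range(6):
                expected = data[f][mask].mean() if mask.any() else np.nan
                got = stm.values[k - 1, f]
                if np.isnan(expected):
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(expected)

    def test_center_is_mean_of_rings_1_to_5(self):
        movie = self.gaussian_movie()
        rings = build_rings((50, 50), ACQ)
        stm = spacetime_map(movie, rings)
        k = stm.frame_index(20.0)
        assert stm.center[k] == pytest.approx(np.mean(stm.values[:5, k]))


class TestNormalizeToCenter:
    def test_center_forced_to_one(self):
        movie = TestSpaceTimeMap().gaussian_movie()
        rings = build_rings((50, 50), ACQ)
        stm = normalize_to_center(spacetime_map(movie, rings))
        assert stm.center[stm.frame_index(20.0)] == pytest.approx(1.0)

    def test_scale_invariance(self):
        movie = TestSpaceTimeMap().gaussian_movie()
        rings = build_rings((50, 50), ACQ)
        a = normalize_to_center(spacetime_map(movie, rings))
        scaled = DffMovie(data=movie.data * 12.0, acq=ACQ)
        b = normalize_to_center(spacetime_map(scaled, rings))
        np.testing.assert_allclose(a.values, b.values, equal_nan=True)


class TestSummedActivation:
    def unit_map(self, value=1.0):
        movie = DffMovie(data=np.full((ACQ.n_frames, 100, 100), value), acq=ACQ)
        rings = build_rings((50, 50), ACQ)
        return spacetime_map(movie, rings)

    def test_zero_map(self):
        assert summed_activation(self.unit_map(0.0)) == 0.0

    def test_unit_map_window_cardinality(self):
        # 40 rings x 9 frames (t = 20..100 ms inclusive at 10 ms sampling)
        assert summed_activation(self.unit_map()) == pytest.approx(360.0)

    def test_linearity(self):
        assert summed_activation(self.unit_map(2.0)) == pytest.approx(
            2.0 * summed_activation(self.unit_map(1.0)))

    def test_empty_window_raises(self):
        with pytest.raises(ValueError):
            summed_activation(self.unit_map(), t_from_ms=500.0, t_to_ms=600.0)


class TestSpatialProfileAndBands:
    def test_gaussian_profile_matches_ring_averaged_closed_form(self):
        sigma = 500.0
        movie = TestSpaceTimeMap().gaussian_movie(sigma_um=sigma)
        rings = build_rings((50, 50), ACQ)
        stm = spacetime_map(movie, rings)
        dist, prof = spatial_profile(stm, t_ms=20.0)
        d = ACQ.distance_um((50, 50))
        for k in (5, 10, 20, 30):
            mask = rings.members(k)
            expected = np.exp(-d[mask] ** 2 / (2 * sigma ** 2)).mean()
            assert prof[k - 1] == pytest.approx(expected, rel=0.02)

    def test_flat_map_flat_profile(self):
        stm = TestSummedActivation().unit_map(0.7)
        _, prof = spatial_profile(stm, t_ms=20.0)
        np.testing.assert_allclose(prof, 0.7)

    def test_normalized_profile_below_center(self):
        movie = TestSpaceTimeMap().gaussian_movie()
        rings = build_rings((50, 50), ACQ)
        stm = normalize_to_center(spacetime_map(movie, rings))
        _, prof = spatial_profile(stm, t_ms=20.0)
        assert np.all(prof[5:] <= 1.0)

    def test_band_ring1_is_elementary_rings_4_to_7(self):
        rings = build_rings((50, 50), ACQ)
        np.testing.assert_array_equal(rings.band_indices("ring1"), [4, 5, 6, 7])
        np.testing.assert_array_equal(rings.band_indices("ring2"), [15, 16, 17, 18])
        np.testing.assert_array_equal(rings.band_indices("ring3"), [26, 27, 28, 29])

    def test_constant_map_constant_band_tc(self):
        stm = TestSummedActivation().unit_map(0.4)
        rings = build_rings((50, 50), ACQ)
        tc = ring_tc(stm, "ring2", rings)
        np.testing.assert_allclose(tc.values, 0.4)

    def test_distal_band_weaker_than_central_on_gaussian(self):
        movie = TestSpaceTimeMap().gaussian_movie()
        rings = build_rings((50, 50), ACQ)
        stm = spacetime_map(movie, rings)
        tc1 = ring_tc(stm, "ring1", rings)
        tc3 = ring_tc(stm, "ring3", rings)
        assert tc3.at(20.0) < tc1.at(20.0)

    def test_unknown_band_raises(self):
        rings = build_rings((50, 50), ACQ)
        with pytest.raises(ValueError):
            ring_tc(TestSummedActivation().unit_map(), "ring9", rings)
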