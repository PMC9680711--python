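"""Moment/cumulant reconstruction and photobleaching correction."""

import numpy as np
import pytest

import sofikit as sk
from sofikit.reconstruction import bleach_schedule, cumulants_over_blocks

from oracles import bell_cumulants_from_moments, brute_central_moment


def step_pixel_movie():
    """Single pixel with series {0, 0, 1, 1}: hand-computable moments."""
    return sk.Movie(np.array([0.0, 0.0, 1.0, 1.0]).reshape(4, 1, 1))


class TestAverageImage:
    def test_constant_movie(self):
        assert np.array_equal(sk.average_image(np.full((5, 3, 3), 7.0)),
                              np.full((3, 3), 7.0))

    def test_two_frame_mean(self):
        movie = np.array([0.0, 2.0]).reshape(2, 1, 1)
        assert sk.average_image(movie)[0, 0] == 1.0

    def test_matches_frame_by_frame_summation(self, random_movie):
        total = np.zeros(random_movie.frame_shape)
        for frame in random_movie.frames:
            total = total + frame
        assert np.abs(sk.average_image(random_movie) - total / 50).max() <= 1e-12

    def test_frame_range_is_half_open(self, random_movie):
        sub = sk.average_image(random_movie, frame_range=(0, 10))
        assert np.allclose(sub, random_movie.frames[:10].mean(axis=0))

    def test_empty_selection_rejected(self, random_movie):
        with pytest.raises(ValueError, match=r"\[5, 5\)"):
            sk.average_image(random_movie, frame_range=(5, 5))


class TestMomentImage:
    def test_first_centered_moment_is_zero(self, random_movie):
        assert np.array_equal(sk.moment_image(random_movie, 1),
                              np.zeros(random_movie.frame_shape))

    @pytest.mark.parametrize("order, expected", [(2, 0.25), (3, 0.0), (4, 0.0625)])
    def test_step_pixel_hand_values(self, order, expected):
        assert sk.moment_image(step_pixel_movie(), order)[0, 0] == pytest.approx(expected)

    def test_order4_matches_brute_force_loop(self, rng):
        series = rng.normal(size=1000)
        movie = sk.Movie(series.reshape(-1, 1, 1))
        expected = brute_central_moment(series, 4)
        assert sk.moment_image(movie, 4)[0, 0] == pytest.approx(expected, rel=1e-10)

    def test_invalid_order_and_frame_count(self):
        with pytest.raises(ValueError, match="order"):
            sk.moment_image(step_pixel_movie(), 0)
        with pytest.raises(ValueError, match="frames"):
            sk.moment_image(np.zeros((1, 2, 2)), 2)


class TestMomentSet:
    def test_contains_all_orders_and_average(self, random_movie):
        mset = sk.calc_moments_set(random_movie, 4)
        assert set(mset.order_to_image) == {1, 2, 3, 4}
        assert np.allclose(mset.average, sk.average_image(random_movie))

    def test_each_order_equals_direct_moment_image(self, random_movie):
        mset = sk.calc_moments_set(random_movie, 6)
        for n in range(1, 7):
            assert np.array_equal(mset[n], sk.moment_image(random_movie, n))

    def test_bernoulli_variance(self, rng):
        # Bernoulli(0.3) marginal: variance rho(1-rho) = 0.21
        series = (rng.random(100_000) < 0.3).astype(float)
        mset = sk.calc_moments_set(sk.Movie(series.reshape(-1, 1, 1)), 2)
        se = np.sqrt(0.21 * (1 - 0.21) / len(series))  # conservative scale
        assert abs(mset[2][0, 0] - 0.21) < 3 * 3 * se


class TestCumulantsFromMoments:
    def test_low_orders_equal_centered_moments(self, random_movie):
        mset = sk.calc_moments_set(random_movie, 3)
        cset = sk.cumulants_from_moments(mset)
        assert np.array_equal(cset[2], mset[2])
        assert np.array_equal(cset[3], mset[3])

    def test_step_pixel_fourth_cumulant_by_hand(self):
        # G2 = 0.25, G4 = 0.0625 -> k4 = 0.0625 - 3 * 0.25^2 = -0.125,
        # which equals omega_4(0.5) = rho(1-rho)(1-6rho+6rho^2) at rho = 0.5
        cset = sk.cumulants_from_moments(sk.calc_moments_set(step_pixel_movie(), 4))
        assert cset[4][0, 0] == pytest.approx(-0.125)

    def test_matches_bell_polynomial_oracle_to_order8(self, rng):
        movie = sk.Movie(rng.lognormal(mean=0.0, sigma=0.5, size=(400, 4, 5)))
        mset = sk.calc_moments_set(movie, 8)
        cset = sk.cumulants_from_moments(mset)
        oracle = bell_cumulants_from_moments(
            np.stack([mset[n] for n in range(1, 9)])
        )
        for n in range(2, 9):
            scale = np.abs(oracle[n - 1]).max()
            assert np.abs(cset[n] - oracle[n - 1]).max() <= 1e-9 * scale

    def test_missing_order_reported(self):
        broken = sk.MomentSet(order_to_image={1: np.zeros((2, 2)), 3: np.zeros((2, 2))},
                              average=np.zeros((2, 2)), highest_order=3)
        with pytest.raises(ValueError, match="order 2"):
            sk.cumulants_from_moments(broken)


class TestMomentsFromCumulants:
    def test_roundtrip_is_identity(self, random_movie):
        mset = sk.calc_moments_set(random_movie, 8)
        back = sk.moments_from_cumulants(sk.cumulants_from_moments(mset))
        for n in range(2, 9):
            scale = max(np.abs(mset[n]).max(), 1e-300)
            assert np.abs(back[n] - mset[n]).max() <= 1e-10 * scale

    def test_all_zero_cumulants_give_zero_moments(self):
        zeros = {n: np.zeros((3, 3)) for n in range(1, 6)}
        back = sk.moments_from_cumulants(sk.CumulantSet(zeros, highest_order=5))
        for n in range(1, 6):
            assert np.array_equal(back[n], np.zeros((3, 3)))

    def test_gaussian_fourth_moment(self):
        # centered with k2 = 1, all else 0 -> G4 = 3 (Gaussian)
        cums = {n: np.zeros((1, 1)) for n in range(1, 5)}
        cums[2] = np.ones((1, 1))
        back = sk.moments_from_cumulants(sk.CumulantSet(cums, highest_order=4))
        assert back[4][0, 0] == pytest.approx(3.0)


class TestTotalSignal:
    def test_constant_movie(self):
        assert np.array_equal(sk.total_signal(np.full((5, 4, 4), 2.0)),
                              np.full(5, 32.0))

    def test_single_pixel_is_identity(self, rng):
        series = rng.random(20)
        assert np.array_equal(sk.total_signal(series.reshape(-1, 1, 1)), series)

    def test_matches_per_frame_summation(self, random_movie):
        expected = np.array([f.sum() for f in random_movie.frames])
        assert np.array_equal(sk.total_signal(random_movie), expected)


class TestSmoothMonotone:
    def test_window_one_keeps_decreasing_series(self):
        series = np.linspace(100.0, 1.0, 50)
        assert np.array_equal(sk.smooth_monotone(series, 1), series)

    def test_noisy_decay_becomes_monotone(self, rng):
        t = np.arange(2000)
        series = 1000 * np.exp(-t / 800) + rng.normal(0, 20, size=2000)
        smoothed = sk.smooth_monotone(series, 251)
        assert np.all(np.diff(smoothed) <= 0)

    def test_constant_series_is_fixed_point(self):
        series = np.full(100, 5.0)
        assert np.allclose(sk.smooth_monotone(series, 21), series)

    @pytest.mark.parametrize("window", [2, 4, 101])
    def test_invalid_windows_rejected(self, window):
        with pytest.raises(ValueError):
            sk.smooth_monotone(np.linspace(10, 1, 50), window)


class TestBleachBlocks:
    def test_shallow_decay_gives_single_block(self):
        smoothed = np.linspace(100.0, 99.0, 500)  # 1% total decay
        schedule = sk.bleach_blocks(smoothed, fbc=0.04)
        assert schedule.blocks == [(0, 500)]

    def test_geometric_decay_boundary_by_direct_scan(self):
        t = np.arange(2000)
        smoothed = 100.0 * 0.96 ** (t / 1000.0)
        schedule = sk.bleach_blocks(smoothed, fbc=0.04)
        expected_boundary = int(np.nonzero(smoothed < 96.0)[0][0])
        assert len(schedule.blocks) == 2
        assert schedule.blocks[0] == (0, expected_boundary)
        assert schedule.blocks[1] == (expected_boundary, 2000)

    def test_constant_series_gives_single_block(self):
        schedule = sk.bleach_blocks(np.full(100, 10.0), fbc=0.5)
        assert schedule.blocks == [(0, 100)]

    @pytest.mark.parametrize("fbc", [0.0, 1.0, -0.1, 2.0])
    def test_fbc_outside_unit_interval_rejected(self, fbc):
        with pytest.raises(ValueError, match="fbc"):
            sk.bleach_blocks(np.linspace(10, 1, 50), fbc=fbc)

    def test_blocks_cover_all_frames(self, rng):
        smoothed = sk.smooth_monotone(
            1000 * np.exp(-np.arange(3000) / 600.0) + rng.normal(0, 5, 3000), 101)
        schedule = sk.bleach_blocks(smoothed, fbc=0.05)
        spans = np.concatenate([np.arange(a, b) for a, b in schedule.blocks])
        assert np.array_equal(spans, np.arange(3000))


class TestCorrectBleaching:
    def test_single_block_degenerates_to_plain_reconstruction(self, random_movie):
        # no bleaching trend -> one block -> identical to the direct path
        corrected = sk.correct_bleaching(random_movie, fbc=0.9,
                                         smooth_kernel=49, highest_order=4)
        plain = sk.cumulants_from_moments(sk.calc_moments_set(random_movie, 4))
        schedule = bleach_schedule(random_movie, fbc=0.9, smooth_kernel=49)
        assert schedule.n_blocks == 1
        for n in range(1, 5):
            assert np.allclose(corrected[n], plain[n])

    def test_bleaching_scene_returns_finite_orders(self, rng):
        field = sk.semicircle_field(n_emitters=11, radius=8.0, center=(12.0, 16.0),
                                    bleach_lifetime=1500.0)
        movie, _ = sk.simulate_movie(field, sk.PsfModel(sigma=1.5), 2000, (16, 32),
                                     seed=rng)
        cset = sk.correct_bleaching(movie, fbc=0.04, smooth_kernel=251,
                                    highest_order=7)
        assert set(cset.order_to_image) == set(range(1, 8))
        for n in range(1, 8):
            assert np.all(np.isfinite(cset[n]))

    def test_statistically_identical_blocks_match_single_block(self, rng):
        # stationary movie split in two at the midpoint: block-averaged
        # cumulants agree with the whole-movie ones within Monte-Carlo error
        series = (rng.random(40_000) < 0.4).astype(float)
        movie = sk.Movie(series.reshape(-1, 1, 1))
        split = cumulants_over_blocks(movie, [(0, 20_000), (20_000, 40_000)], 3)
        whole = sk.cumulants_from_moments(sk.calc_moments_set(movie, 3))
        se3 = np.sqrt(20.0 / 20_000)  # coarse upper bound on SE of k3-hat
        assert abs(split[3][0, 0] - whole[3][0, 0]) < 3 * se3

    def test_short_block_reported(self, random_movie):
        with pytest.raises(ValueError, match="block 1"):
            cumulants_over_blocks(random_movie, [(0, 49), (49, 50)], 2)


class TestCumulantProperties:
    def test_additivity_under_independence(self, rng):
        """Cumulant images of a sum of independent movies add."""
        psf = sk.PsfModel(sigma=1.5)
        f1 = sk.EmitterField(positions=[(8.0, 8.0)], brightness=80.0, on_ratio=0.3)
        f2 = sk.EmitterField(positions=[(8.0, 9.0)], brightness=60.0, on_ratio=0.7)
        m1, _ = sk.simulate_movie(f1, psf, 30_000, (17, 17), seed=rng)
        m2, _ = sk.simulate_movie(f2, psf, 30_000, (17, 17), seed=rng)
        both = sk.Movie(m1.frames + m2.frames)

        def k4(movie):
            return sk.cumulants_from_moments(sk.calc_moments_set(movie, 4))[4]

        peak = np.unravel_index(np.argmax(np.abs(k4(both))), (17, 17))
        total, parts = k4(both)[peak], (k4(m1) + k4(m2))[peak]
        scale = 80.0**4 * 0.06  # omega_4 scale at the peak
        assert abs(total - parts) < 0.1 * abs(scale)

    def test_third_order_sign_tracks_on_ratio(self, rng):
        """k3 > 0 below rho = 0.5, < 0 above, ~0 at 0.5 (cusp driver)."""
        psf = sk.PsfModel(sigma=1.5)
        peaks = {}
        for rho in (0.25, 0.5, 0.75):
            field = sk.EmitterField(positions=[(8.0, 8.0)], brightness=100.0,
                                    on_ratio=rho)
            movie, _ = sk.simulate_movie(field, psf, 20_000, (17, 17), seed=rng)
            cset = sk.cumulants_from_moments(sk.calc_moments_set(movie, 3))
            peaks[rho] = cset[3][8, 8] / 100.0**3
        assert peaks[0.25] > 0
        assert peaks[0.75] < 0
        assert abs(peaks[0.5]) < 0.25 * peaks[0.25]
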