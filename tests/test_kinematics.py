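import numpy as np
import pytest

from asymdiv.errors import AsymdivError
from asymdiv.io_core import MovieStack, RegionBox
from asymdiv.kinematics import (
    asymmetry_index,
    average_velocity,
    build_kymograph,
    classify_asymmetry,
    compute_asymmetry,
    daughter_intensity_sums,
    telophase_position,
)
from asymdiv.registration import CellRegistration
from asymdiv.tracking import Spot, Track


def make_registration(n_frames=11, t0=5, ant=(5.0, 2.0), post=(5.0, 8.0)):
    reg = CellRegistration(np.tile(ant, (n_frames, 1)), np.tile(post, (n_frames, 1)),
                           frame_interval_s=12.0)
    reg.t0 = t0
    return reg


def track_from_s(s_values, reg, track_id=0):
    """Build a track whose projected coordinate at frame t is s_values[t]."""
    spots = []
    for t, s in enumerate(s_values):
        if s is None:
            continue
        p = reg.anterior_um[t] + s * (reg.posterior_um[t] - reg.anterior_um[t])
        spots.append(Spot(frame=t, channel=0, position_um=p, peak_intensity=1, score=1))
    return Track(track_id=track_id, spots=spots)


class TestKymograph:
    def test_single_fixed_endosome_gives_unit_rows(self):
        reg = make_registration()
        tr = track_from_s([0.5] * 11, reg)
        kymo = build_kymograph([tr], reg, window_frames=3, n_bins=10)
        assert kymo.values.shape == (7, 10)
        for row in kymo.values:
            assert row.sum() == pytest.approx(1.0)
            assert row.max() == pytest.approx(1.0)
            assert np.argmax(row) == 5

    def test_two_endosomes_split_the_row(self):
        reg = make_registration()
        tracks = [track_from_s([0.1] * 11, reg, 0), track_from_s([0.9] * 11, reg, 1)]
        kymo = build_kymograph(tracks, reg, window_frames=2, n_bins=10)
        for row in kymo.values:
            assert sorted(row[row > 0]) == [0.5, 0.5]

    def test_rows_match_bruteforce_histogram(self, rng):
        reg = make_registration()
        tracks = [track_from_s(rng.uniform(-0.2, 1.2, 11), reg, i) for i in range(6)]
        kymo = build_kymograph(tracks, reg, window_frames=4, n_bins=13)
        edges = np.linspace(0, 1, 14)
        for row, frame in zip(kymo.values, kymo.frames):
            ss = []
            for tr in tracks:
                spot = tr.spot_at(int(frame))
                s = (spot.position_um - reg.anterior_um[frame]) @ np.array([0.0, 1.0]) / 6.0
                ss.append(min(max(s, 0.0), 1.0))
            expected = np.zeros(13)
            for s in ss:
                b = min(int(s * 13), 12)
                expected[b] += 1 / len(ss)
            np.testing.assert_allclose(row, expected, atol=1e-12)

    def test_rows_with_endosomes_sum_to_one_else_zero(self, rng):
        reg = make_registration()
        svals = [rng.uniform(0, 1, 11).tolist() for _ in range(3)]
        for sv in svals:
            sv[2] = None  # nobody at frame 2... (per-track missing frames)
        tracks = [track_from_s(sv, reg, i) for i, sv in enumerate(svals)]
        kymo = build_kymograph(tracks, reg, window_frames=4, n_bins=20)
        for row, frame in zip(kymo.values, kymo.frames):
            if frame == 2:
                assert row.sum() == 0.0
            else:
                assert row.sum() == pytest.approx(1.0, abs=1e-9)

    def test_window_truncation_warns(self):
        reg = make_registration(n_frames=8, t0=2)
        tr = track_from_s([0.5] * 8, reg)
        with pytest.warns(UserWarning, match="truncat"):
            kymo = build_kymograph([tr], reg, window_frames=5)
        assert kymo.truncated


class TestTelophasePosition:
    def test_all_posterior_gives_one(self):
        reg = make_registration(n_frames=40, t0=10)
        tracks = [track_from_s([1.0] * 40, reg, i) for i in range(3)]
        assert telophase_position(tracks, reg, 4.0) == pytest.approx(1.0)

    def test_mean_of_two_positions(self):
        reg = make_registration(n_frames=40, t0=10)
        tracks = [track_from_s([0.2] * 40, reg, 0), track_from_s([0.8] * 40, reg, 1)]
        assert telophase_position(tracks, reg, 4.0) == pytest.approx(0.5)

    def test_no_endosomes_is_an_error(self):
        reg = make_registration(n_frames=40, t0=10)
        with pytest.raises(AsymdivError):
            telophase_position([], reg, 4.0)


class TestVelocity:
    def test_constant_step_arithmetic(self):
        # 0.2 um per 12 s frame = 1.0 um/min
        reg = make_registration(n_frames=11, t0=5)
        spots = [Spot(frame=t, channel=0, position_um=(5.0, 2.0 + 0.2 * t),
                      peak_intensity=1, score=1) for t in range(11)]
        v = average_velocity([Track(0, spots)], reg, (-1.0, 1.0))
        assert v.speed_um_min == pytest.approx(1.0)
        assert v.axial_um_min == pytest.approx(1.0)

    def test_stationary_is_zero(self):
        reg = make_registration()
        tr = track_from_s([0.4] * 11, reg)
        assert average_velocity([tr], reg).speed_um_min == 0.0

    def test_gap_steps_divide_by_elapsed_time(self):
        reg = make_registration(n_frames=11, t0=5)
        spots = [Spot(frame=t, channel=0, position_um=(5.0, 2.0 + 0.2 * t),
                      peak_intensity=1, score=1) for t in (0, 1, 3)]
        v = average_velocity([Track(0, spots)], reg, (-1.0, 0.0))
        # both steps have speed 0.2 um / 0.2 min and 0.4 um / 0.4 min = 1.0
        assert v.speed_um_min == pytest.approx(1.0)

    def test_empty_window_is_an_error(self):
        reg = make_registration()
        with pytest.raises(AsymdivError):
            average_velocity([], reg)


class TestAsymmetryIndex:
    def test_fifty_percent_more_equals_threshold(self):
        assert asymmetry_index(1.5, 1.0) == pytest.approx(0.2)

    def test_equal_sums_are_symmetric(self):
        assert asymmetry_index(3.7, 3.7) == 0.0

    def test_absolute_asymmetry(self):
        assert asymmetry_index(5.0, 0.0) == 1.0
        assert asymmetry_index(0.0, 5.0) == -1.0

    def test_both_zero_is_undefined(self):
        with pytest.raises(AsymdivError):
            asymmetry_index(0.0, 0.0)

    def test_negative_sum_rejected(self):
        with pytest.raises(ValueError):
            asymmetry_index(-1.0, 1.0)


class TestClassification:
    @pytest.mark.parametrize("x,label", [
        (0.2, "posterior"), (0.19, "symmetric"), (-0.2, "anterior"),
        (-0.19, "symmetric"), (1.0, "posterior"), (-1.0, "anterior"), (0.0, "symmetric"),
    ])
    def test_threshold_boundaries(self, x, label):
        assert classify_asymmetry(x) == label

    def test_threshold_must_be_in_unit_interval(self):
        with pytest.raises(ValueError):
            classify_asymmetry(0.5, threshold=0.0)


def make_test_movie(img):
    data = np.asarray(img, float)[None, None, None]
    return MovieStack(data, (1.0, 0.2, 0.2), 0.0, ["endosome"])


class TestDaughterSums:
    def test_all_posterior_signal_gives_index_one(self):
        img = np.zeros((20, 20))
        img[10, 15] = 100.0  # x = 3.0 um, posterior of midplane
        movie = make_test_movie(img)
        reg = make_registration(n_frames=1, t0=0, ant=(2.0, 1.0), post=(2.0, 3.0))
        res = compute_asymmetry(movie, reg, 0, 0)
        assert res.index == pytest.approx(1.0)
        assert res.label == "posterior"

    def test_mirror_symmetric_frame_is_exactly_symmetric(self):
        img = np.zeros((20, 20))
        img[4:8, 4] = 50.0
        img[4:8, 15] = 50.0  # mirror about x between columns 9 and 10
        movie = make_test_movie(img)
        # midplane at x = 1.9 um: midpoint of columns 9,10 (pixel size 0.2)
        reg = make_registration(n_frames=1, t0=0, ant=(2.0, 0.9), post=(2.0, 2.9))
        res = compute_asymmetry(movie, reg, 0, 0)
        assert res.index == pytest.approx(0.0, abs=1e-6)

    def test_sums_match_bruteforce_halfplane_sums(self, rng):
        img = rng.uniform(0, 50, (16, 24))
        movie = make_test_movie(img)
        blank = RegionBox((0, 0), (4, 4))
        reg = make_registration(n_frames=1, t0=0, ant=(1.6, 1.0), post=(1.6, 3.0))
        sa, sp = daughter_intensity_sums(movie, reg, 0, 0, blank)
        sub = np.clip(img - img[:4, :4].mean(), 0, None)
        mid_x = 2.0  # um; pixels exactly on the plane are shared half-half
        exp_post = sum(sub[y, x] * (1.0 if x * 0.2 > mid_x else 0.5 if x * 0.2 == mid_x else 0.0)
                       for y in range(16) for x in range(24))
        exp_ant = sum(sub[y, x] * (1.0 if x * 0.2 < mid_x else 0.5 if x * 0.2 == mid_x else 0.0)
                      for y in range(16) for x in range(24))
        assert sp == pytest.approx(exp_post, rel=1e-12)
        assert sa == pytest.approx(exp_ant, rel=1e-12)

    def test_axis_reversal_negates_index(self, rng):
        img = rng.uniform(0, 50, (16, 24))
        movie = make_test_movie(img)
        fwd = make_registration(n_frames=1, t0=0, ant=(1.6, 1.0), post=(1.6, 3.0))
        rev = make_registration(n_frames=1, t0=0, ant=(1.6, 3.0), post=(1.6, 1.0))
        ra = compute_asymmetry(movie, fwd, 0, 0)
        rb = compute_asymmetry(movie, rev, 0, 0)
        assert ra.index == pytest.approx(-rb.index, abs=1e-6)
        swap = {"posterior": "anterior", "anterior": "posterior", "symmetric": "symmetric"}
        assert rb.label == swap[ra.label]
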