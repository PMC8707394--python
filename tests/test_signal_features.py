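"""Unit and property tests of the seven-channel feature pipeline."""

from datetime import datetime, timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from actibed.signal_features import (
    Activity,
    AccelCSVError,
    CHANNEL_NAMES,
    TriaxialRecording,
    build_features,
    classify_activity,
    classify_lying,
    encode,
    frame_windows,
    inclination_deg,
    read_accel_csv,
    resample,
    sd_longitudinal,
    time_bin_level,
)
from conftest import START, constant_recording


# ---------------------------------------------------------------- CSV reader

def _write_csv(path, rows, header="timestamp,ax,ay,az"):
    path.write_text(header + "\n" + "\n".join(rows) + "\n")
    return path


class TestReadAccelCSV:
    def test_well_formed_50hz(self, tmp_path):
        rows = [
            f"2018-10-01T20:00:{s:09.6f},0.1,0.2,0.9"
            for s in (0.0, 0.02, 0.04)
        ]
        rec = read_accel_csv(_write_csv(tmp_path / "a.csv", rows), site="hip")
        assert len(rec) == 3
        assert rec.sample_rate == pytest.approx(50.0, rel=1e-6)
        assert rec.start_time == datetime(2018, 10, 1, 20, 0, 0)
        assert rec.samples[0] == pytest.approx([0.1, 0.2, 0.9])

    def test_missing_column_named_in_error(self, tmp_path):
        p = _write_csv(tmp_path / "a.csv", ["2018-10-01T20:00:00,0.1,0.9"],
                       header="timestamp,ay,az")
        with pytest.raises(AccelCSVError, match="'ax'"):
            read_accel_csv(p, site="hip")

    def test_non_monotone_rejected_with_line(self, tmp_path):
        rows = [
            "2018-10-01T20:00:00.00,0,0,1",
            "2018-10-01T20:00:00.02,0,0,1",
            "2018-10-01T20:00:00.01,0,0,1",
        ]
        with pytest.raises(AccelCSVError, match="line 4"):
            read_accel_csv(_write_csv(tmp_path / "a.csv", rows), site="hip")

    def test_gap_flagged(self, tmp_path):
        times = [0.0, 0.02, 0.04, 0.2, 0.22]  # 0.16 s gap > 2 periods
        rows = [f"2018-10-01T20:00:{s:09.6f},0,0,1" for s in times]
        rec = read_accel_csv(_write_csv(tmp_path / "a.csv", rows), site="hip")
        assert rec.gap_indices == [2]

    def test_sensor_range_clipped(self):
        rec = constant_recording("hip", (12.0, -9.0, 0.0), seconds=1)
        assert rec.samples[:, 0].max() == 8.0
        assert rec.samples[:, 1].min() == -8.0


# ----------------------------------------------------------------- resample

class TestResample:
    def test_constant_signal(self):
        rec = constant_recording("hip", (1.0, 0.0, 0.0), seconds=10, hz=50)
        out = resample(rec, 30)
        assert out.sample_rate == 30
        assert len(out) == 300  # grid spans [0, 9.98] s -> floor(9.98*30)+1
        assert np.allclose(out.samples, [1.0, 0.0, 0.0])
        assert out.start_time == rec.start_time

    def test_identity_at_target_rate(self):
        rec = constant_recording("hip", (0.0, 1.0, 0.0), seconds=4, hz=30)
        assert resample(rec, 30) is rec

    def test_linear_ramp_closed_form(self):
        hz, seconds = 50.0, 4.0
        t_src = np.arange(int(hz * seconds)) / hz
        samples = np.column_stack([0.01 * t_src, np.ones_like(t_src), np.zeros_like(t_src)])
        rec = TriaxialRecording("hip", START, hz, samples)
        out = resample(rec, 30)
        t_new = np.arange(len(out)) / 30.0
        assert np.allclose(out.samples[:, 0], 0.01 * t_new, atol=1e-12)

    def test_rejects_bad_rate(self):
        rec = constant_recording("hip", (1, 0, 0), seconds=1)
        with pytest.raises(ValueError):
            resample(rec, 0)


# ------------------------------------------------------------------ windows

class TestFrameWindows:
    @pytest.mark.parametrize("n,expected", [(300, 9), (60, 1), (59, 0), (0, 0), (90, 2)])
    def test_counts(self, n, expected):
        rec = TriaxialRecording("hip", START, 30.0, np.ones((n, 3)))
        assert len(frame_windows(rec)) == expected

    def test_center_times_one_second_apart(self):
        rec = TriaxialRecording("hip", START, 30.0, np.ones((300, 3)))
        centers = [w.center_time for w in frame_windows(rec)]
        assert centers[0] == START + timedelta(seconds=1)
        assert all(
            (b - a) == timedelta(seconds=1) for a, b in zip(centers, centers[1:])
        )

    @given(n=st.integers(0, 2000))
    @settings(max_examples=40, deadline=None)
    def test_count_formula(self, n):
        rec = TriaxialRecording("hip", START, 30.0, np.zeros((n, 3)))
        expected = 0 if n < 60 else (n - 60) // 30 + 1
        assert len(frame_windows(rec)) == expected


# ----------------------------------------------------- per-window primitives

class TestWindowPrimitives:
    @pytest.mark.parametrize(
        "vector,expected",
        [((1, 0, 0), 0.0), ((0, 1, 0), 90.0), ((-1, 0, 0), 180.0), ((1, 1, 0), 45.0)],
    )
    def test_inclination(self, vector, expected):
        win = np.tile(np.asarray(vector, float), (60, 1))
        assert inclination_deg(win) == pytest.approx(expected, abs=1e-9)

    def test_inclination_zero_vector_is_missing(self):
        assert np.isnan(inclination_deg(np.zeros((60, 3))))

    @given(scale=st.floats(1e-3, 1e3), theta=st.floats(1.0, 179.0))
    @settings(max_examples=50, deadline=None)
    def test_inclination_scale_invariant(self, scale, theta):
        v = np.array([np.cos(np.radians(theta)), np.sin(np.radians(theta)), 0.0])
        win = np.tile(v, (60, 1))
        assert inclination_deg(win * scale) == pytest.approx(
            inclination_deg(win), abs=1e-6
        )

    def test_sd_constant_window_is_zero(self):
        assert sd_longitudinal(np.ones((60, 3))) == 0.0

    def test_sd_alternating_hand_value(self):
        win = np.zeros((60, 3))
        win[::2, 0], win[1::2, 0] = 0.1, -0.1
        assert sd_longitudinal(win) == pytest.approx(0.1, abs=1e-15)

    def test_sd_matches_two_pass_oracle(self):
        rng = np.random.default_rng(11)
        win = rng.normal(size=(60, 3))
        x = win[:, 0]
        oracle = np.sqrt(np.sum((x - x.mean()) ** 2) / len(x))
        assert sd_longitudinal(win) == pytest.approx(oracle, abs=1e-12)


# -------------------------------------------------------------- classifiers

class TestClassifiers:
    @pytest.mark.parametrize(
        "incl,tsd,hsd,expected",
        [
            (90.0, 0.005, 0.005, Activity.SITTING),
            (10.0, 0.005, 0.005, Activity.UPRIGHT),
            (10.0, 0.300, 0.250, Activity.UPRIGHT),  # moving, same encoded level
            (90.0, 0.300, 0.250, Activity.OTHER),
        ],
    )
    def test_activity(self, incl, tsd, hsd, expected):
        assert classify_activity(incl, tsd, hsd) is expected

    @pytest.mark.parametrize(
        "hip,activity,expected",
        [
            (70.0, Activity.SITTING, True),
            (60.0, Activity.SITTING, False),
            (65.0, Activity.SITTING, False),  # strict inequality
            (70.0, Activity.UPRIGHT, False),
            (70.0, Activity.OTHER, False),
        ],
    )
    def test_lying(self, hip, activity, expected):
        assert classify_lying(hip, activity) is expected

    def test_lying_flips_just_above_65(self):
        assert not classify_lying(65.0, Activity.SITTING)
        assert classify_lying(np.nextafter(65.0, 180.0), Activity.SITTING)


# ----------------------------------------------------------------- encoding

class TestEncoding:
    @pytest.mark.parametrize(
        "clock,expected",
        [("02:00", -1.0), ("04:00", -0.6), ("23:59", 1.0), ("00:00", -1.0),
         ("11:59", -0.2), ("12:00", 0.2), ("20:00", 1.0)],
    )
    def test_time_bins(self, clock, expected):
        h, m = map(int, clock.split(":"))
        assert time_bin_level(datetime(2018, 10, 1, h, m)) == expected

    @pytest.mark.parametrize(
        "value,kind,expected",
        [
            (0.0, "inclination", 0.0),
            (180.0, "inclination", 1.0),
            (90.0, "inclination", 0.5),
            (0.0, "sd", -1.0),
            (0.25, "sd", 0.0),
            (0.5, "sd", 1.0),
            (2.0, "sd", 1.0),  # saturates
            (True, "lying", 1.0),
            (False, "lying", -1.0),
            (Activity.OTHER, "activity", -1.0),
        ],
    )
    def test_encode(self, value, kind, expected):
        assert encode(value, kind) == pytest.approx(expected)

    @pytest.mark.parametrize("value,kind", [(200, "inclination"), (-0.1, "sd"), (5, "activity")])
    def test_encode_rejects_out_of_domain(self, value, kind):
        with pytest.raises(ValueError):
            encode(value, kind)


# ------------------------------------------------------------ full pipeline

class TestBuildFeatures:
    def test_frame_count_60s_pair(self, lying_pair):
        features = build_features(*lying_pair)
        assert len(features) == 59
        times = features.frame_times()
        assert times[1] - times[0] == timedelta(seconds=1)

    def test_lying_pair_channels(self, lying_features):
        assert np.all(lying_features.channels["Lying"] == 1.0)
        assert np.all(lying_features.channels["Activity"] == 0.0)
        assert np.all(lying_features.channels["Hip-Inclination"] == pytest.approx(0.5))

    def test_upright_pair_not_lying(self, upright_pair):
        features = build_features(*upright_pair)
        assert np.all(features.channels["Lying"] == -1.0)
        assert np.all(features.channels["Activity"] == 1.0)

    def test_channel_order_fixed(self, lying_features):
        assert tuple(lying_features.channels) == CHANNEL_NAMES

    def test_no_overlap_rejected(self):
        hip = constant_recording("hip", (1, 0, 0), seconds=10)
        thigh = constant_recording(
            "thigh", (1, 0, 0), seconds=10, start=START + timedelta(hours=1)
        )
        with pytest.raises(ValueError, match="overlap"):
            build_features(hip, thigh)

    def test_all_values_in_range_random_inputs(self):
        rng = np.random.default_rng(5)
        n = 50 * 120
        hip = TriaxialRecording("hip", START, 50.0, rng.normal(0, 2, (n, 3)))
        thigh = TriaxialRecording("thigh", START, 50.0, rng.normal(0, 2, (n, 3)))
        vals = build_features(hip, thigh).values()
        finite = vals[np.isfinite(vals)]
        assert finite.min() >= -1.0 and finite.max() <= 1.0

    def test_lying_implies_sitting_random_inputs(self):
        rng = np.random.default_rng(6)
        n = 50 * 120
        hip = TriaxialRecording("hip", START, 50.0, rng.normal(0, 1, (n, 3)))
        thigh = TriaxialRecording("thigh", START, 50.0, rng.normal(0, 1, (n, 3)))
        f = build_features(hip, thigh)
        lying = f.channels["Lying"] == 1.0
        assert np.all(f.channels["Activity"][lying] == 0.0)

    def test_deterministic(self, lying_pair):
        a = build_features(*lying_pair)
        b = build_features(*lying_pair)
        for name in CHANNEL_NAMES:
            np.testing.assert_array_equal(a.channels[name], b.channels[name])
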