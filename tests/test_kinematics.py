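"""Crank geometry, leg IK, filtering, revolution segmentation, storage I/O."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cyclesim import io as stoio
from cyclesim.kinematics import (
    CrankGeometry,
    ReachabilityError,
    TimeGrid,
    dual_pass_butterworth,
    forward_kinematics,
    leg_inverse_kinematics,
    pedal_position,
    recreational_geometry,
    segment_revolutions,
)


class TestButterworth:
    def test_dc_gain_unity(self):
        x = np.full(500, 3.7)
        y = dual_pass_butterworth(x, fs=100.0, fc=6.0)
        assert np.allclose(y, x, atol=1e-10)

    def test_cutoff_gain_half(self):
        # two -3 dB passes: amplitude ratio 0.5 at the cutoff frequency
        fs, fc = 200.0, 6.0
        t = np.arange(0, 60, 1 / fs)
        x = np.sin(2 * np.pi * fc * t)
        y = dual_pass_butterworth(x, fs, fc)
        core = slice(len(t) // 4, 3 * len(t) // 4)
        gain = np.max(np.abs(y[core]))
        assert gain == pytest.approx(0.5, abs=0.02)

    def test_zero_lag(self):
        fs, fc = 200.0, 6.0
        t = np.arange(0, 30, 1 / fs)
        x = np.sin(2 * np.pi * (fc / 10) * t)
        y = dual_pass_butterworth(x, fs, fc)
        core = slice(len(t) // 4, 3 * len(t) // 4)
        xc, yc = x[core] - x[core].mean(), y[core] - y[core].mean()
        lags = np.arange(-20, 21)
        cc = [np.dot(xc, np.roll(yc, k)) for k in lags]
        assert lags[int(np.argmax(cc))] == 0

    def test_idempotent_on_bandlimited_signal(self):
        fs, fc = 200.0, 6.0
        t = np.arange(0, 30, 1 / fs)
        x = np.sin(2 * np.pi * 1.0 * t) + 0.3 * np.cos(2 * np.pi * 1.4 * t)
        y1 = dual_pass_butterworth(x, fs, fc)
        y2 = dual_pass_butterworth(y1, fs, fc)
        core = slice(len(t) // 4, 3 * len(t) // 4)
        rms = lambda v: np.sqrt(np.mean(v**2))  # noqa: E731
        assert abs(rms(y2[core]) - rms(y1[core])) / rms(y1[core]) < 0.01

    def test_errors(self):
        with pytest.raises(ValueError):
            dual_pass_butterworth(np.zeros(100), fs=10.0, fc=6.0)
        with pytest.raises(ValueError):
            dual_pass_butterworth(np.zeros(5), fs=100.0, fc=6.0)


class TestPedalPosition:
    def test_tdc_and_bdc(self):
        geom = CrankGeometry(crank_length=0.1725)
        x, y = pedal_position(0.0, geom)
        assert (x, y) == pytest.approx((0.0, 0.1725))
        x, y = pedal_position(math.pi, geom)
        assert (x, y) == pytest.approx((0.0, -0.1725), abs=1e-12)

    @given(st.floats(-20.0, 20.0))
    def test_circle_invariant(self, theta):
        geom = CrankGeometry(crank_length=0.1725, crank_axis=(0.1, -0.2))
        x, y = pedal_position(theta, geom)
        assert math.hypot(x - 0.1, y + 0.2) == pytest.approx(0.1725)


class TestLegInverseKinematics:
    def _setup(self, height=1.75):
        geom = recreational_geometry(height)
        thigh, shank, lever = 0.245 * height, 0.246 * height, 0.0835 * height
        return geom, thigh, shank, lever

    def test_full_extension_boundary(self):
        geom, thigh, shank, _ = self._setup()
        hx, hy = geom.saddle_position
        # ankle target at the edge of the reachable annulus (zero foot lever
        # makes the pedal coincide with the ankle target)
        d = (thigh + shank) * (1.0 - 1e-9)
        hip, knee = leg_inverse_kinematics((hx, hy - d), 0.0, geom, thigh, shank, 0.0)
        assert knee == pytest.approx(0.0, abs=1e-3)
        assert hip == pytest.approx(0.0, abs=1e-3)

    def test_round_trip_over_revolution(self):
        geom, thigh, shank, lever = self._setup()
        th = np.linspace(0, 2 * np.pi, 721)
        qa = geom.ankle_profile(th)
        px, py = pedal_position(th, geom)
        hip, knee = leg_inverse_kinematics((px, py), qa, geom, thigh, shank, lever)
        assert np.all(knee >= 0.0)
        rx, ry = forward_kinematics(hip, knee, qa, geom, thigh, shank, lever)
        assert np.max(np.hypot(rx - px, ry - py)) < 1e-9

    def test_round_trip_all_cohort_statures(self):
        from cyclesim.synth import TABLE1_ROWS
        for row in TABLE1_ROWS:
            geom, thigh, shank, lever = self._setup(row[1] / 100.0)
            th = np.linspace(0, 2 * np.pi, 181)
            qa = geom.ankle_profile(th)
            px, py = pedal_position(th, geom)
            hip, knee = leg_inverse_kinematics((px, py), qa, geom, thigh, shank, lever)
            rx, ry = forward_kinematics(hip, knee, qa, geom, thigh, shank, lever)
            assert np.max(np.hypot(rx - px, ry - py)) < 1e-9

    def test_knee_flexion_peaks_near_tdc(self):
        geom, thigh, shank, lever = self._setup()
        th = np.linspace(0, 2 * np.pi, 721)
        qa = geom.ankle_profile(th)
        px, py = pedal_position(th, geom)
        _, knee = leg_inverse_kinematics((px, py), qa, geom, thigh, shank, lever)
        peak = math.degrees(th[int(np.argmax(knee))])
        assert peak < 30.0 or peak > 330.0

    def test_unreachable_reports_crank_angle(self):
        geom, thigh, shank, lever = self._setup()
        with pytest.raises(ReachabilityError, match="crank angle"):
            leg_inverse_kinematics((np.array([0.0]), np.array([-2.0])), 0.0, geom,
                                   thigh, shank, lever, crank_angle=np.array([1.0]))


class TestSegmentRevolutions:
    def test_uniform_80rpm(self):
        fs = 112.5
        t = np.arange(0, 3 * 60 / 80, 1 / fs)
        th = 80 / 60 * 2 * np.pi * t
        wins = segment_revolutions(th)
        assert len(wins) == 2  # third revolution ends one sample short of 2.25 s
        for i0, i1 in wins:
            assert (t[i1] - t[i0]) == pytest.approx(60 / 80, abs=1.5 / fs)

    def test_partial_start_excluded(self):
        th = np.linspace(np.pi, 5 * np.pi, 400)  # starts mid-revolution
        wins = segment_revolutions(th)
        assert len(wins) == 1
        i0, i1 = wins[0]
        assert th[i0] == pytest.approx(2 * np.pi, abs=np.diff(th)[0])

    def test_windows_cover_complete_revolutions_once(self):
        rng = np.random.default_rng(3)
        t = np.cumsum(rng.uniform(0.5, 1.5, 900)) * 0.01
        th = 7.5 * t  # strictly increasing, irregular sampling
        wins = segment_revolutions(th)
        # brute-force oracle: count integer-2*pi multiples interior to range
        k0 = math.ceil(th[0] / (2 * np.pi))
        k1 = math.floor(th[-1] / (2 * np.pi))
        assert len(wins) == (k1 - k0)
        for (a0, a1), (b0, b1) in zip(wins, wins[1:]):
            assert a1 == b0  # contiguous, non-overlapping

    def test_less_than_one_revolution(self):
        with pytest.raises(ValueError):
            segment_revolutions(np.linspace(0.1, 5.0, 50))


class TestTimeGrid:
    def test_validation(self):
        TimeGrid(0.0, 1.0, 21, cadence=80.0).validate()
        with pytest.raises(ValueError):
            TimeGrid(0.0, 0.5, 21, cadence=80.0).validate()  # shorter than a rev
        with pytest.raises(ValueError):
            TimeGrid(0.0, 1.0, 5, cadence=80.0).validate()


class TestStorageIO:
    def test_round_trip_full_precision(self, tmp_path):
        rng = np.random.default_rng(0)
        t = np.sort(rng.uniform(0, 10, 57))
        cols = {"a": rng.normal(size=57), "b/col": rng.normal(size=57) * 1e-7}
        path = tmp_path / "x.sto"
        stoio.write_sto(path, "trial", t, cols)
        name, t2, cols2, indeg = stoio.read_sto(path)
        assert name == "trial" and not indeg
        assert np.array_equal(t, t2)
        for k in cols:
            assert np.array_equal(cols[k], cols2[k])

    def test_degrees_normalized_to_radians(self, tmp_path):
        t = np.linspace(0, 1, 11)
        path = tmp_path / "deg.mot"
        stoio.write_sto(path, "angles", t, {"knee": np.full(11, 90.0)}, in_degrees=True)
        _, _, cols, indeg = stoio.read_sto(path)
        assert indeg
        assert np.allclose(cols["knee"], math.pi / 2)

    def test_truncated_header_errors(self, tmp_path):
        path = tmp_path / "bad.sto"
        path.write_text("name\nnRows=3\nnColumns=2\n")
        with pytest.raises(stoio.StorageParseError, match="endheader"):
            stoio.read_sto(path)

    def test_bad_row_reports_line(self, tmp_path):
        path = tmp_path / "bad2.sto"
        path.write_text("n\nnRows=1\nnColumns=2\ninDegrees=no\nendheader\n"
                        "time\tx\n0.0\toops\n")
        with pytest.raises(stoio.StorageParseError, match="line 7"):
            stoio.read_sto(path)
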