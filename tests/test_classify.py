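"""Classifier internals against brute-force and closed-form oracles."""

import numpy as np
import pytest

from morus import classify, io as mio
from morus.config import ClassifierParams


def _trace(ax, ay=None, az=None, rate=50.0, t=None):
    ax = np.asarray(ax, float)
    ay = np.zeros_like(ax) if ay is None else np.asarray(ay, float)
    az = np.ones_like(ax) if az is None else np.asarray(az, float)
    t = np.arange(len(ax)) / rate if t is None else np.asarray(t, float)
    return mio.AccelTrace("b", t, ax, ay, az, rate_hz=rate)


def brute_running(x, half, bounds):
    """Direct O(n * w) centred running mean / population SD oracle."""
    mean = np.empty_like(x)
    sd = np.empty_like(x)
    for s, e in bounds:
        for i in range(s, e):
            h = min(half, i - s, e - 1 - i)
            w = x[i - h:i + h + 1]
            mean[i] = w.mean()
            sd[i] = w.std(ddof=0)
    return mean, sd


class TestRunningStats:
    def test_matches_brute_force_single_segment(self, rng):
        x = rng.normal(size=400)
        tr = _trace(x)
        st = classify.running_stats(tr, window_s=2.0)
        half = 50
        m, s = brute_running(x, half, tr.segment_bounds())
        np.testing.assert_allclose(st.mean_x, m, atol=1e-10)
        np.testing.assert_allclose(st.sd_x, s, atol=1e-10)

    def test_matches_brute_force_across_gap(self, rng):
        x = rng.normal(size=300)
        t = np.concatenate([np.arange(120) / 50.0,
                            5.0 + np.arange(180) / 50.0])
        tr = _trace(x, t=t)
        assert tr.n_segments == 2
        st = classify.running_stats(tr, window_s=2.0)
        m, s = brute_running(x, 50, tr.segment_bounds())
        np.testing.assert_allclose(st.mean_x, m, atol=1e-10)
        # cumulative-sum SD carries ~1e-7 cancellation noise at edge windows
        np.testing.assert_allclose(st.sd_x, s, atol=1e-6)

    def test_constant_signal_zero_sd(self):
        tr = _trace(np.full(200, 0.3))
        st = classify.running_stats(tr, window_s=2.0)
        np.testing.assert_allclose(st.mean_x, 0.3)
        np.testing.assert_allclose(st.sd_x, 0.0, atol=1e-6)

    def test_short_segment_flagged_unusable(self):
        t = np.concatenate([np.arange(10) / 50.0, 5.0 + np.arange(200) / 50.0])
        tr = _trace(np.zeros(210), t=t)
        st = classify.running_stats(tr, window_s=2.0)
        assert not st.usable[:10].any()
        assert st.usable[10:].all()


class TestPitch:
    def test_level_posture_is_zero(self):
        tr = _trace(np.zeros(300))
        pitch = classify.compute_pitch(tr)
        np.testing.assert_allclose(pitch, 0.0, atol=1e-9)

    def test_known_inclination(self):
        # static (0.5, 0, sqrt(3)/2) -> arcsin(0.5) = 30 degrees head-up
        tr = _trace(np.full(300, 0.5), az=np.full(300, np.sqrt(3) / 2))
        pitch = classify.compute_pitch(tr)
        np.testing.assert_allclose(pitch[60:-60], 30.0, atol=1e-6)

    def test_head_down_negative(self):
        tr = _trace(np.full(300, -1.0), az=np.zeros(300))
        pitch = classify.compute_pitch(tr)
        np.testing.assert_allclose(pitch[60:-60], -90.0, atol=1e-6)

    def test_zero_static_vector_carries_forward(self):
        ax = np.full(300, 0.6)
        az = np.full(300, 0.8)
        tr = _trace(ax, az=az)
        # force a zero static window in the middle
        tr.ax[140:160] = 0.0
        tr.az[140:160] = 0.0
        pitch = classify.compute_pitch(tr)
        assert np.isfinite(pitch).all()


class TestDiveTypeSplit:
    def test_below_split_is_plunge(self):
        assert classify.classify_dive_type(4.99) == "plunge"

    def test_boundary_is_pursuit(self):
        assert classify.classify_dive_type(5.0) == "pursuit"

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            classify.classify_dive_type(0.0)


class TestDetection:
    def _synthetic_dive_trace(self, rng, dive=(30.0, 33.0), rate=50.0,
                              n_s=120):
        """Rest everywhere except a head-down high-variance dive burst and
        a post-dive heave burst (take-off)."""
        n = int(n_s * rate)
        ax = rng.normal(0, 0.05, n)
        ay = rng.normal(0, 0.05, n)
        az = 1.0 + rng.normal(0, 0.05, n)
        d0, d1 = int(dive[0] * rate), int(dive[1] * rate)
        ax[d0:d1] = -0.5 + rng.normal(0, 1.6, d1 - d0)
        az[d0:d1] = 0.8 + rng.normal(0, 1.0, d1 - d0)
        # surfacing overshoot then decay (detectable pitch extremum)
        h1 = d1 + int(1.0 * rate)
        r1 = h1 + int(6.0 * rate)
        ax[d1:h1] += 0.9
        ax[h1:r1] += 0.9 * np.linspace(1, 0, r1 - h1)
        # take-off burst
        t0, t1 = h1, h1 + int(3.0 * rate)
        az[t0:t1] = 1.0 + rng.normal(0, 2.5, t1 - t0)
        ax[t0:t1] += rng.normal(0, 1.2, t1 - t0)
        return _trace(ax, ay, az, rate=rate)

    def test_single_dive_detected_with_takeoff(self, rng):
        tr = self._synthetic_dive_trace(rng)
        dives, takeoffs = classify.classify_events(tr)
        assert len(dives) == 1
        assert abs(dives[0].start_s - 30.0) < 1.5
        assert dives[0].dive_type == "plunge"
        assert len(takeoffs) == 1
        assert takeoffs[0].linked_id == dives[0].event_id
        assert takeoffs[0].start_s >= dives[0].end_s

    def test_no_takeoff_is_flagged(self, rng):
        tr = self._synthetic_dive_trace(rng)
        # silence everything after the surfacing overshoot
        cut = int(35.0 * tr.rate_hz)
        tr.ax[cut:] = np.random.default_rng(0).normal(0, 0.05, len(tr) - cut)
        tr.az[cut:] = 1.0 + np.random.default_rng(1).normal(
            0, 0.05, len(tr) - cut)
        dives, takeoffs = classify.classify_events(tr)
        assert len(dives) == 1 and len(takeoffs) == 0
        assert "no_takeoff" in dives[0].flags

    def test_quiet_trace_has_no_events(self, rng):
        tr = _trace(rng.normal(0, 0.05, 5000))
        dives, takeoffs = classify.classify_events(tr)
        assert dives == [] and takeoffs == []

    def test_dive_end_modes_agree_on_clean_extremum(self, rng):
        tr = self._synthetic_dive_trace(rng)
        off = classify.detect_dives(tr, ClassifierParams(
            dive_end_mode="offset"))
        ser = classify.detect_dives(tr, ClassifierParams(
            dive_end_mode="series"))
        assert len(off) == len(ser) == 1
        assert abs(off[0].end_s - ser[0].end_s) < 1.5


class TestBehaviourEvent:
    def test_end_before_start_rejected(self):
        with pytest.raises(ValueError):
            classify.BehaviourEvent("b", "dive", 10.0, 9.0)

    def test_takeoff_with_dive_type_rejected(self):
        with pytest.raises(ValueError):
            classify.BehaviourEvent("b", "takeoff", 0.0, 1.0,
                                    dive_type="plunge")


class TestTdrValidation:
    def _depth(self, starts, dur=3.0, rate=4.0):
        ts, ds = [], []
        for s in starts:
            tt = s + np.arange(int(dur * rate)) / rate
            ts.append(tt)
            ds.append(np.full(len(tt), 2.0))
        return mio.DepthTrace("b", np.concatenate(ts), np.concatenate(ds),
                              rate_hz=rate)

    def _dives(self, starts):
        return [classify.BehaviourEvent("b", "dive", s, s + 2.0, "plunge", i)
                for i, s in enumerate(starts)]

    def test_perfect_match(self):
        rep = classify.validate_against_tdr(self._dives([100, 200, 300]),
                                            self._depth([100, 200, 300]))
        assert rep.n_matched == 3 and rep.match_rate == 1.0
        np.testing.assert_allclose(rep.offsets_s, 0.0)

    def test_one_to_one_no_double_matching(self):
        # two accel dives near one TDR dive: only one may claim it
        rep = classify.validate_against_tdr(self._dives([100, 103]),
                                            self._depth([101]))
        assert rep.n_matched == 1
        assert len(rep.unmatched_accel) == 1

    def test_beyond_tolerance_unmatched(self):
        rep = classify.validate_against_tdr(self._dives([100]),
                                            self._depth([106]))
        assert rep.n_matched == 0

    def test_greedy_prefers_smaller_offset(self):
        rep = classify.validate_against_tdr(self._dives([100]),
                                            self._depth([101, 104]))
        assert rep.n_matched == 1
        np.testing.assert_allclose(rep.offsets_s, [1.0])

    def test_clock_offset_applied(self):
        rep = classify.validate_against_tdr(self._dives([92]),
                                            self._depth([100]),
                                            time_offset_s=8.0)
        assert rep.n_matched == 1

    def test_empty_tdr_warns(self):
        depth = mio.DepthTrace("b", np.array([0.0]), np.array([0.2]))
        rep = classify.validate_against_tdr(self._dives([10]), depth)
        assert rep.n_matched == 0 and rep.warning is not None

    def test_tdr_starts_on_trigger_crossing(self):
        # depth ramps through the 0.5 m trigger within one segment
        t = np.arange(20) / 4.0
        d = np.concatenate([np.linspace(0.0, 0.4, 5),
                            np.linspace(0.6, 3.0, 15)])
        starts = classify.tdr_dive_starts(mio.DepthTrace("b", t, d))
        assert len(starts) == 1
        assert starts[0] == t[5]
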