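"""Agreement statistics, response-time detectors, spike segmentation,
IAH grading — including brute-force definitional oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from gastrosim import analysis
from gastrosim.analysis import (IahGrade, bland_altman,
                                bland_altman_from_stats, classify_iah,
                                response_time_spike, response_time_step,
                                segment_spikes, summarize_steady_state)
from gastrosim.logio import LogRecord


class TestBlandAltman:
    def test_hand_computed_triple(self):
        res = bland_altman([1.0, 2.0, 3.0])
        assert res.mean_diff == pytest.approx(2.0)
        assert res.sd == pytest.approx(1.0)
        assert res.se == pytest.approx(0.5774, abs=1e-4)
        assert res.loa_lower == pytest.approx(0.04)
        assert res.loa_upper == pytest.approx(3.96)

    def test_all_zero_differences(self):
        res = bland_altman([0.0] * 10)
        assert (res.mean_diff, res.sd, res.se) == (0.0, 0.0, 0.0)
        assert (res.loa_lower, res.loa_upper) == (0.0, 0.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0])

    def test_limits_identity(self, rng):
        d = rng.normal(0, 1, 50)
        res = bland_altman(d)
        assert res.loa_upper - res.loa_lower \
            == pytest.approx(2 * 1.96 * res.sd, abs=1e-9)
        assert res.se == pytest.approx(res.sd / np.sqrt(res.n), abs=1e-12)

    def test_from_stats_matches_from_data(self, rng):
        d = rng.normal(0.2, 1.4, 24)
        a = bland_altman(d)
        b = bland_altman_from_stats(a.mean_diff, a.sd, a.n)
        assert a == b


class TestResponseTimeStep:
    def test_constant_trace_satisfies_first_window(self):
        rt = response_time_step([10.0] * 8, 10.0)
        assert rt == 4.0  # last sample of the first 5-window at unit cadence

    def test_hand_computed_moving_average(self):
        # first qualifying 5-mean is 9.7, ending at the 6th sample (t=5 s)
        trace = [8.0, 9.0, 9.6, 9.8, 10.0, 10.1]
        assert response_time_step(trace, 10.0, band=0.5) == 5.0

    def test_never_entering_band_returns_none(self):
        assert response_time_step([0.0] * 10, 10.0) is None

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            response_time_step([10.0] * 4, 10.0)

    def test_tightening_band_never_decreases_time(self, rng):
        trace = list(10.0 + np.linspace(5, 0, 40) * rng.uniform(0.5, 1, 40))
        wide = response_time_step(trace, 10.0, band=1.0)
        narrow = response_time_step(trace, 10.0, band=0.3)
        if narrow is not None:
            assert wide is not None and wide <= narrow

    def test_uses_log_record_times(self):
        records = [LogRecord(2.0 + 0.5 * i, 10.0, 0.0) for i in range(6)]
        assert response_time_step(records, 10.0) == pytest.approx(2.0)


class TestResponseTimeSpike:
    def test_whole_segment_inside_band(self):
        assert response_time_spike([10.0, 10.05, 9.95], 10.0) == 0.0

    def test_suffix_scan_example(self):
        seg = [10.5, 10.2, 10.05, 10.02, 10.01]
        assert response_time_spike(seg, 10.0, tol=0.1) == 2.0

    def test_segment_ending_outside_band(self):
        assert response_time_spike([10.0, 10.0, 10.5], 10.0) is None

    def test_empty_segment_rejected(self):
        with pytest.raises(ValueError):
            response_time_spike([], 10.0)


def _make_log(motor, pressure=None, dt=1.0):
    pressure = pressure if pressure is not None else [10.0] * len(motor)
    return [LogRecord(i * dt, p, m)
            for i, (p, m) in enumerate(zip(pressure, motor))]


class TestSegmentSpikes:
    def test_quiet_log_has_no_segments(self):
        assert segment_spikes(_make_log([0.0] * 20)) == []

    def test_three_bursts_give_two_segments(self):
        motor = [0] * 5 + [255] + [0] * 5 + [255] + [0] * 5 + [255] + [0] * 5
        segs = segment_spikes(_make_log([float(m) for m in motor]))
        assert len(segs) == 2
        assert segs[0].start == 11.0 and segs[1].start == 17.0

    def test_first_segment_excluded(self):
        motor = [0.0] * 3 + [255.0] + [0.0] * 10
        assert segment_spikes(_make_log(motor)) == []

    def test_debounce_merges_rapid_recrossings(self):
        # two crossings 0.5 s apart count as one burst
        motor = [0.0, 255.0, 0.0, 255.0] + [0.0] * 10 + [255.0] + [0.0] * 5
        segs = segment_spikes(_make_log(motor, dt=0.5))
        assert len(segs) == 1

    def test_negative_bursts_detected_by_magnitude(self):
        motor = [0.0] * 3 + [-255.0] + [0.0] * 8 + [-255.0] + [0.0] * 8
        segs = segment_spikes(_make_log(motor))
        assert len(segs) == 1

    def test_empty_log_rejected(self):
        with pytest.raises(ValueError):
            segment_spikes([])


class TestSteadySummary:
    def test_constant_at_setpoint(self):
        s = summarize_steady_state([10.0] * 10, 10.0)
        assert s.steady_state_error == 0.0 and s.sd == 0.0

    def test_symmetric_triple(self):
        s = summarize_steady_state([9.0, 10.0, 11.0], 10.0)
        assert s.mean == 10.0 and s.sd == pytest.approx(1.0)
        assert s.steady_state_error == 0.0
        assert s.ci95[0] < s.mean < s.ci95[1]

    def test_se_consistency(self, rng):
        p = rng.normal(10, 0.5, 100)
        s = summarize_steady_state(p, 10.0)
        assert s.se * np.sqrt(100) == pytest.approx(s.sd, abs=1e-12)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            summarize_steady_state([10.0], 10.0)


class TestIahGrading:
    @pytest.mark.parametrize("pressure,grade", [
        (0.0, IahGrade.NONE), (11.99, IahGrade.NONE),
        (12.0, IahGrade.I), (15.99, IahGrade.I),
        (16.0, IahGrade.II), (20.99, IahGrade.II),
        (21.0, IahGrade.III), (25.0, IahGrade.III),
        (25.01, IahGrade.IV), (100.0, IahGrade.IV),
    ])
    def test_wsacs_boundaries(self, pressure, grade):
        assert classify_iah(pressure) is grade

    @given(st.floats(min_value=-5, max_value=40),
           st.floats(min_value=0, max_value=10))
    def test_monotone_in_pressure(self, p, delta):
        order = [IahGrade.NONE, IahGrade.I, IahGrade.II, IahGrade.III,
                 IahGrade.IV]
        assert order.index(classify_iah(p + delta)) \
            >= order.index(classify_iah(p))


# --- brute-force definitional oracles (shared with the acceptance suite) ---

def oracle_bland_altman(d):
    n = len(d)
    mean = sum(d) / n
    sd = (sum((x - mean) ** 2 for x in d) / (n - 1)) ** 0.5
    return mean, sd, sd / n ** 0.5, mean - 1.96 * sd, mean + 1.96 * sd


def oracle_response_time_step(values, times, target, band, window):
    for i in range(window - 1, len(values)):
        win = values[i - window + 1:i + 1]
        if abs(sum(win) / window - target) <= band:
            return times[i] - times[0]
    return None


def oracle_response_time_spike(values, times, target, tol):
    for i in range(len(values)):
        if all(abs(v - target) <= tol for v in values[i:]):
            return times[i] - times[0]
    return None


def oracle_segment_starts(motor, times, threshold, debounce):
    crossings = []
    for i, m in enumerate(motor):
        rises = abs(m) > threshold and (i == 0 or abs(motor[i - 1]) <= threshold)
        if rises and (not crossings or times[i] - times[crossings[-1]] > debounce):
            crossings.append(i)
    return [times[i] for i in crossings[1:]]  # first burst excluded


def test_bland_altman_matches_oracle(rng):
    for _ in range(200):
        d = list(rng.normal(rng.uniform(-1, 1), rng.uniform(0.1, 2),
                            rng.integers(2, 40)))
        res = bland_altman(d)
        om, osd, ose, olo, ohi = oracle_bland_altman(d)
        assert res.mean_diff == pytest.approx(om, abs=1e-12)
        assert res.sd == pytest.approx(osd, abs=1e-12)
        assert res.se == pytest.approx(ose, abs=1e-12)
        assert res.loa_lower == pytest.approx(olo, abs=1e-12)
        assert res.loa_upper == pytest.approx(ohi, abs=1e-12)


def test_response_detectors_match_oracles(rng):
    for _ in range(200):
        n = int(rng.integers(5, 60))
        values = list(10.0 + rng.normal(0, 0.5, n))
        times = list(np.cumsum(rng.uniform(0.04, 0.06, n)))
        records = [LogRecord(t, v, 0.0) for t, v in zip(times, values)]
        assert response_time_step(records, 10.0) \
            == oracle_response_time_step(values, times, 10.0, 0.5, 5)
        assert response_time_spike(records, 10.0) \
            == oracle_response_time_spike(values, times, 10.0, 0.1)


def test_segmentation_matches_oracle(rng):
    for _ in range(200):
        n = int(rng.integers(10, 120))
        motor = list(np.where(rng.random(n) < 0.15,
                              rng.choice([-255.0, 255.0], n), 0.0))
        times = list(np.arange(n) * 0.5)
        records = [LogRecord(t, 10.0, m) for t, m in zip(times, motor)]
        segs = segment_spikes(records)
        assert [s.start for s in segs] \
            == oracle_segment_starts(motor, times, 50.0, 1.0)
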