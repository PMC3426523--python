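"""Requirement metrics on synthetic calcium traces."""

import numpy as np
import pytest

from awcsim import metrics
from awcsim.stimulus import StimulusProtocol
from conftest import make_trace

REMOVAL = 310.0  # 10-s baseline + 300-s pulse


def gaussian_trace(peak_delay=5.0, amplitude=0.2, rest=0.05, width=3.0):
    t = np.arange(0.0, 400.0, 0.05)
    ca = rest + amplitude * np.exp(-((t - REMOVAL - peak_delay) / width) ** 2)
    ca[t <= REMOVAL] = rest
    return make_trace(t, ca, resting_ca=rest)


class TestTimeToPeak:
    def test_constructed_maximum_recovered(self):
        trace = gaussian_trace(peak_delay=5.0)
        ttp, found = metrics.time_to_peak(trace, REMOVAL)
        assert found and ttp == pytest.approx(5.0, abs=0.1)

    def test_flat_trace_flagged_no_peak(self):
        t = np.arange(0.0, 400.0, 0.1)
        trace = make_trace(t, np.full(t.size, 0.05))
        ttp, found = metrics.time_to_peak(trace, REMOVAL)
        assert not found and ttp == metrics.PEAK_SEARCH_WINDOW_S

    def test_short_trace_raises(self):
        t = np.arange(0.0, 320.0, 0.1)
        trace = make_trace(t, np.full(t.size, 0.05))
        with pytest.raises(metrics.TraceRangeError):
            metrics.time_to_peak(trace, REMOVAL)


class TestRiseLatency:
    def test_ramp_crosses_one_percent_threshold(self):
        t = np.arange(0.0, 400.0, 0.05)
        ca = np.full(t.size, 0.05)
        ramp = (t > REMOVAL) & (t <= REMOVAL + 50.0)
        ca[ramp] = 0.05 + (t[ramp] - REMOVAL) * 0.002  # linear, peak +0.1
        ca[t > REMOVAL + 50.0] = 0.15
        trace = make_trace(t, ca)
        lat, found = metrics.rise_latency(trace, REMOVAL)
        # crosses 1 % of the 0.1-µM range after 0.5 s of a 50-s ramp
        assert found and lat == pytest.approx(0.5, abs=0.1)

    def test_flat_trace_flagged_no_rise(self):
        t = np.arange(0.0, 400.0, 0.1)
        trace = make_trace(t, np.full(t.size, 0.05))
        _, found = metrics.rise_latency(trace, REMOVAL)
        assert not found


class TestReturnToBaseline:
    def test_gaussian_reenters_band(self):
        trace = gaussian_trace(peak_delay=5.0, amplitude=0.2, width=8.0)
        ret, found = metrics.return_to_baseline(trace, REMOVAL)
        # analytic: 0.2·exp(-(dt/8)²) < 5 % of 0.05 → dt ≈ 8·sqrt(ln 80)
        expected = 5.0 + 8.0 * np.sqrt(np.log(0.2 / 0.0025))
        assert found and ret == pytest.approx(expected, abs=0.5)

    def test_never_returning_trace_flagged(self):
        t = np.arange(0.0, 400.0, 0.05)
        ca = np.where(t > REMOVAL, 0.2, 0.05)
        trace = make_trace(t, ca)
        ret, found = metrics.return_to_baseline(trace, REMOVAL)
        assert not found and np.isinf(ret)


class TestInvariances:
    def test_metrics_invariant_to_time_shift(self):
        trace = gaussian_trace()
        shifted = make_trace(trace.t + 37.0, trace.ca,
                             protocol=StimulusProtocol(((47.0, 300.0),)))
        for fn in (metrics.time_to_peak, metrics.rise_latency):
            v0, _ = fn(trace, REMOVAL)
            v1, _ = fn(shifted, REMOVAL + 37.0)
            assert v1 == pytest.approx(v0, abs=1e-9)


class TestEvaluateRequirements:
    @staticmethod
    def _result_set(peaks=(0.1, 0.2, 0.3)):
        results = {}
        for mins, peak in zip((1, 3, 5), peaks):
            dur = 60.0 * mins
            proto = StimulusProtocol(((10.0, dur),), name=f"pulse{mins}min")
            t = np.arange(0.0, proto.duration, 0.05)
            removal = 10.0 + dur
            rest = 0.05
            ca = np.full(t.size, rest)
            stim = (t > 10.0) & (t <= removal)
            ca[stim] = rest * 0.5
            post = t > removal
            ca[post] = rest + (peak - rest) * np.exp(-((t[post] - removal - 5) / 6.0) ** 2)
            ca[(t > removal) & (t <= removal + 0.2)] = rest * 0.5
            results[proto.name] = make_trace(t, ca, rest, proto)
        # paired protocol: suppressed second response
        proto = StimulusProtocol(((10.0, 300.0), (320.0, 20.0)), name="pulse5min_second10s")
        t = np.arange(0.0, proto.duration, 0.05)
        ca = np.interp(t, results["pulse5min"].t, results["pulse5min"].ca)
        second = (t > 320.0) & (t <= 340.0)
        ca[second] = 0.02
        results[proto.name] = make_trace(t, ca, 0.05, proto)
        return results

    def test_monotonic_peaks_detected(self):
        rep = metrics.evaluate_requirements(self._result_set())
        assert rep.monotonic_peaks
        assert rep.second_stimulus_decrease

    def test_non_monotonic_peaks_detected(self):
        rep = metrics.evaluate_requirements(self._result_set(peaks=(0.3, 0.2, 0.25)))
        assert not rep.monotonic_peaks
        assert not rep.overall_pass

    def test_flat_traces_fail_each_criterion_with_full_report(self):
        results = {}
        for mins in (1, 3, 5):
            proto = StimulusProtocol(((10.0, 60.0 * mins),), name=f"pulse{mins}min")
            t = np.arange(0.0, proto.duration, 0.1)
            results[proto.name] = make_trace(t, np.full(t.size, 0.05), 0.05, proto)
        proto = StimulusProtocol(((10.0, 300.0), (320.0, 20.0)), name="pulse5min_second10s")
        t = np.arange(0.0, proto.duration, 0.1)
        results[proto.name] = make_trace(t, np.full(t.size, 0.05), 0.05, proto)
        rep = metrics.evaluate_requirements(results)
        assert not rep.overall_pass
        assert not rep.on_stimulus_decrease
        assert not rep.rise_within_limit
        assert not rep.peak_within_limit
        assert not rep.return_within_band
        assert not rep.monotonic_peaks
        d = rep.to_dict()
        assert {"rise_latency_s", "time_to_peak_s", "peak_ca_uM"} <= set(d)

    def test_missing_protocol_reported(self):
        results = self._result_set()
        del results["pulse3min"]
        with pytest.raises(ValueError, match="pulse3min"):
            metrics.evaluate_requirements(results)
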