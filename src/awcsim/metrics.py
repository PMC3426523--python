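"""Physiological-requirement metrics on [Ca²⁺] traces.

Three requirements define a physiologically acceptable model:

1. [Ca²⁺] decreases during odor stimulation, rises within 1 s of odor
   removal, peaks within 10 s, and returns to baseline at about 40 s
   (accepted band 25–60 s, since no tolerance is published for the
   "approximately 40 s" figure).
2. The post-removal [Ca²⁺] peak grows strictly with stimulus duration
   between 1 and 5 minutes.
3. A second stimulus delivered during the post-removal transient drives
   [Ca²⁺] back down while it is applied.

All metrics operate on free calcium, not on the fluorescence readout, and
are invariant to uniform time shifts of the trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import SimulationResult

__all__ = [
    "RequirementReport",
    "time_to_peak",
    "rise_latency",
    "return_to_baseline",
    "on_stimulus_decrease",
    "second_stimulus_decrease",
    "evaluate_requirements",
]

PEAK_SEARCH_WINDOW_S = 60.0
RISE_FRACTION = 0.01          # rise threshold: 1 % of (peak − value at removal)
RISE_PERSISTENCE_S = 0.5      # anti-noise hysteresis
BASELINE_BAND = 0.05          # ±5 % of resting [Ca²⁺]
BASELINE_PERSISTENCE_S = 5.0
RETURN_BAND_S = (25.0, 60.0)  # accepted return-to-baseline window
RISE_LIMIT_S = 1.0
PEAK_LIMIT_S = 10.0


class TraceRangeError(ValueError):
    """Trace does not cover the analysis window."""


def _window(trace: SimulationResult, removal_t: float) -> tuple[np.ndarray, np.ndarray]:
    if trace.t[-1] < removal_t + PEAK_SEARCH_WINDOW_S:
        raise TraceRangeError(
            f"trace ends at {trace.t[-1]:.1f} s, needs {PEAK_SEARCH_WINDOW_S:.0f} s past "
            f"removal at {removal_t:.1f} s")
    mask = (trace.t > removal_t) & (trace.t <= removal_t + PEAK_SEARCH_WINDOW_S)
    return trace.t[mask], trace.ca[mask]


def time_to_peak(trace: SimulationResult, removal_t: float) -> tuple[float, bool]:
    """Time (s) from stimulus removal to the [Ca²⁺] maximum in the following
    60 s.  Returns (time, found); a flat trace reports the 60-s cap with
    ``found=False``.  Ties break to the earliest sample."""
    tw, ca = _window(trace, removal_t)
    k = int(np.argmax(ca))
    ca0 = float(np.interp(removal_t, trace.t, trace.ca))
    if ca[k] <= ca0 * (1.0 + 1e-9):
        return PEAK_SEARCH_WINDOW_S, False
    return float(tw[k] - removal_t), True


def rise_latency(trace: SimulationResult, removal_t: float) -> tuple[float, bool]:
    """First time after removal at which [Ca²⁺] exceeds its value at removal
    by 1 % of (peak − value-at-removal) and stays above for 0.5 s."""
    tw, ca = _window(trace, removal_t)
    ca0 = float(np.interp(removal_t, trace.t, trace.ca))
    peak = float(ca.max())
    if peak <= ca0 * (1.0 + 1e-9):
        return PEAK_SEARCH_WINDOW_S, False
    thr = ca0 + RISE_FRACTION * (peak - ca0)
    above = ca > thr
    for i in np.flatnonzero(above):
        persist = (tw >= tw[i]) & (tw <= tw[i] + RISE_PERSISTENCE_S)
        if above[persist].all():
            return float(tw[i] - removal_t), True
    return PEAK_SEARCH_WINDOW_S, False


def return_to_baseline(trace: SimulationResult, removal_t: float,
                       resting_ca: float | None = None) -> tuple[float, bool]:
    """First time after the post-removal peak at which [Ca²⁺] re-enters the
    ±5 %-of-resting band and stays inside it for at least 5 s."""
    resting = trace.resting_ca if resting_ca is None else resting_ca
    t_peak, found = time_to_peak(trace, removal_t)
    if not found:
        return np.inf, False
    lo, hi = resting * (1 - BASELINE_BAND), resting * (1 + BASELINE_BAND)
    mask = trace.t > removal_t + t_peak
    tw, ca = trace.t[mask], trace.ca[mask]
    inside = (ca >= lo) & (ca <= hi)
    for i in np.flatnonzero(inside):
        persist = (tw >= tw[i]) & (tw <= tw[i] + BASELINE_PERSISTENCE_S)
        if persist.any() and inside[persist].all() and tw[-1] >= tw[i] + BASELINE_PERSISTENCE_S:
            return float(tw[i] - removal_t), True
    return np.inf, False


def on_stimulus_decrease(trace: SimulationResult) -> bool:
    """[Ca²⁺] falls below its pre-stimulus baseline during the (first)
    stimulus and is still below baseline at stimulus end."""
    onset, dur = trace.protocol.pulses[0]
    pre = trace.ca[trace.t < onset]
    baseline = float(pre.mean()) if pre.size else trace.resting_ca
    during = (trace.t > onset) & (trace.t <= onset + dur)
    ca_end = float(np.interp(onset + dur, trace.t, trace.ca))
    return bool(trace.ca[during].min() < baseline * 0.99 and ca_end < baseline)


def second_stimulus_decrease(paired: SimulationResult,
                             unpaired: SimulationResult) -> bool:
    """[Ca²⁺] decreases during the second pulse of a paired protocol, and
    ends it below the level the unpaired recovery would have had.

    The second criterion captures suppression relative to the ongoing
    post-removal transient of the corresponding single-pulse protocol, whose
    first pulse must match the paired protocol's first pulse.
    """
    if len(paired.protocol.pulses) < 2:
        raise ValueError("paired protocol must contain a second pulse")
    if paired.protocol.pulses[0] != unpaired.protocol.pulses[0]:
        raise ValueError("unpaired reference must share the first pulse")
    onset2, dur2 = paired.protocol.pulses[1]
    end2 = onset2 + dur2
    ca_start = float(np.interp(onset2, paired.t, paired.ca))
    ca_end = float(np.interp(end2, paired.t, paired.ca))
    ca_unpaired_end = float(np.interp(end2, unpaired.t, unpaired.ca))
    return bool(ca_end < ca_start and ca_end < ca_unpaired_end)


@dataclass
class RequirementReport:
    """Per-protocol metrics plus the pass/fail verdicts of the three
    physiological requirements."""

    rise_latency_s: dict[str, float] = field(default_factory=dict)
    time_to_peak_s: dict[str, float] = field(default_factory=dict)
    peak_ca_uM: dict[str, float] = field(default_factory=dict)
    return_to_baseline_s: float = np.inf
    on_stimulus_decrease: bool = False
    rise_within_limit: bool = False
    peak_within_limit: bool = False
    return_within_band: bool = False
    monotonic_peaks: bool = False
    second_stimulus_decrease: bool = False
    overall_pass: bool = False

    def to_dict(self) -> dict:
        out = {}
        for key, val in self.__dict__.items():
            if isinstance(val, dict):
                out[key] = {k: float(v) for k, v in val.items()}
            elif isinstance(val, (bool, np.bool_)):
                out[key] = bool(val)
            else:
                out[key] = float(val)
        return out


_SINGLE = ("pulse1min", "pulse3min", "pulse5min")


def evaluate_requirements(results: dict[str, SimulationResult]) -> RequirementReport:
    """Evaluate the three requirements on a set of simulated protocols.

    ``results`` must contain the three single-pulse protocols and at least
    one paired protocol (keyed by protocol name); the return-to-baseline
    criterion is measured on the 5-min protocol.
    """
    for name in _SINGLE:
        if name not in results:
            raise ValueError(f"missing required protocol {name!r}")
    paired_names = [n for n, r in results.items() if len(r.protocol.pulses) > 1]
    if not paired_names:
        raise ValueError("need at least one paired protocol")

    rep = RequirementReport()
    decrease_ok, rise_ok, peak_ok = [], [], []
    for name in _SINGLE:
        res = results[name]
        removal = res.protocol.removal_times[0]
        lat, lat_found = rise_latency(res, removal)
        ttp, ttp_found = time_to_peak(res, removal)
        rep.rise_latency_s[name] = lat
        rep.time_to_peak_s[name] = ttp
        _, ca_win = _window(res, removal)
        rep.peak_ca_uM[name] = float(ca_win.max())
        decrease_ok.append(on_stimulus_decrease(res))
        rise_ok.append(lat_found and lat <= RISE_LIMIT_S)
        peak_ok.append(ttp_found and ttp <= PEAK_LIMIT_S)

    ret, ret_found = return_to_baseline(results["pulse5min"],
                                        results["pulse5min"].protocol.removal_times[0])
    rep.return_to_baseline_s = ret
    rep.on_stimulus_decrease = all(decrease_ok)
    rep.rise_within_limit = all(rise_ok)
    rep.peak_within_limit = all(peak_ok)
    rep.return_within_band = bool(ret_found and RETURN_BAND_S[0] <= ret <= RETURN_BAND_S[1])
    peaks = [rep.peak_ca_uM[n] for n in _SINGLE]
    rep.monotonic_peaks = bool(peaks[0] < peaks[1] < peaks[2])

    second_ok = []
    for name in paired_names:
        res = results[name]
        first_dur = res.protocol.pulses[0][1]
        single_name = f"pulse{int(first_dur) // 60}min"
        if single_name not in results:
            raise ValueError(f"paired protocol {name!r} needs its single-pulse "
                             f"reference {single_name!r}")
        second_ok.append(second_stimulus_decrease(res, results[single_name]))
    rep.second_stimulus_decrease = all(second_ok)

    rep.overall_pass = bool(
        rep.on_stimulus_decrease and rep.rise_within_limit and rep.peak_within_limit
        and rep.return_within_band and rep.monotonic_peaks and rep.second_stimulus_decrease
    )
    return rep
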