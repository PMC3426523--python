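"""Odor stimulation protocols: piecewise-constant pulse trains.

The reference protocols are the imaging protocols this model is judged
against: single odor pulses of 1, 3 and 5 minutes, and paired protocols in
which a 20-s second pulse follows the first by 10 or 30 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["StimulusProtocol", "reference_protocols"]

BASELINE_MARGIN_S = 10.0   # quiet time simulated before the first pulse
POST_WINDOW_S = 90.0       # time simulated past the last pulse


@dataclass(frozen=True)
class StimulusProtocol:
    """A sorted list of non-overlapping (onset_s, duration_s) odor pulses."""

    pulses: tuple[tuple[float, float], ...]
    amplitude: float = 1.0
    duration: float | None = None  # total simulated time; derived if None
    name: str = ""

    def __post_init__(self) -> None:
        prev_end = -1.0
        for onset, dur in self.pulses:
            if onset < 0 or dur <= 0:
                raise ValueError("pulse onsets must be >= 0 and durations > 0")
            if onset < prev_end:
                raise ValueError("pulses must be sorted and non-overlapping")
            prev_end = onset + dur
        if self.duration is None:
            object.__setattr__(self, "duration", prev_end + POST_WINDOW_S if self.pulses else POST_WINDOW_S)

    def odor_level(self, t: float) -> float:
        """Odor amplitude at time ``t`` (right-continuous at pulse onsets)."""
        if t < 0:
            raise ValueError("t must be >= 0")
        for onset, dur in self.pulses:
            if onset <= t < onset + dur:
                return self.amplitude
        return 0.0

    @property
    def edges(self) -> tuple[float, ...]:
        """All stimulus on/off switching times, sorted."""
        out: list[float] = []
        for onset, dur in self.pulses:
            out.extend((onset, onset + dur))
        return tuple(out)

    @property
    def removal_times(self) -> tuple[float, ...]:
        return tuple(onset + dur for onset, dur in self.pulses)


def _single(duration_s: float) -> StimulusProtocol:
    return StimulusProtocol(
        ((BASELINE_MARGIN_S, duration_s),),
        name=f"pulse{int(duration_s) // 60}min",
    )

def _paired(first_s: float, gap_s: float, second_s: float = 20.0) -> StimulusProtocol:
    first_end = BASELINE_MARGIN_S + first_s
    return StimulusProtocol(
        ((BASELINE_MARGIN_S, first_s), (first_end + gap_s, second_s)),
        name=f"pulse{int(first_s) // 60}min_second{int(gap_s)}s",
    )


def reference_protocols() -> dict[str, StimulusProtocol]:
    """The seven stimulation protocols used throughout: 1/3/5-min single
    pulses and {1, 5}-min first pulses followed by a 20-s pulse after a
    10- or 30-s gap, each preceded by a 10-s baseline."""
    protocols = [
        _single(60.0), _single(180.0), _single(300.0),
        _paired(60.0, 10.0), _paired(60.0, 30.0),
        _paired(300.0, 10.0), _paired(300.0, 30.0),
    ]
    return {p.name: p for p in protocols}
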