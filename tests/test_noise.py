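"""Random pulse-train generation and the sensitivity classifier."""

import numpy as np
import pytest

from awcsim.engine import run_simulation
from awcsim.network import build_network
from awcsim.noise import (GAP_RANGE_S, WIDTH_RANGE_S, NoiseTrain,
                          _NoiseModifier, classify_sensitivity,
                          generate_pulse_train, simulate_with_noise)
from awcsim.params import ParameterSet
from awcsim.stimulus import StimulusProtocol
from conftest import make_trace


class TestPulseTrain:
    def test_zero_magnitude_heights_equal_base(self):
        train = generate_pulse_train("EC50_CNG", 2.0, 0.0, seed=1, duration=200.0)
        assert all(r == 0.0 for _, _, r in train.pulses)
        assert all(train.factor_at(s + 0.5 * w) == 1.0 for s, w, _ in train.pulses)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_widths_and_gaps_within_stated_ranges(self, seed):
        train = generate_pulse_train("EC50_CNG", 2.0, 1.0, seed, duration=500.0)
        prev_end = None
        for start, width, r in train.pulses:
            assert WIDTH_RANGE_S[0] <= width <= WIDTH_RANGE_S[1]
            assert -1.0 <= r <= 1.0
            if prev_end is not None:
                assert GAP_RANGE_S[0] <= start - prev_end <= GAP_RANGE_S[1]
            prev_end = start + width

    def test_deterministic_given_seed(self):
        a = generate_pulse_train("GTP", None, 0.5, seed=7, duration=300.0)
        b = generate_pulse_train("GTP", None, 0.5, seed=7, duration=300.0)
        assert a == b

    def test_mean_pulse_height_unbiased(self):
        """Monte-Carlo: symmetric noise leaves the mean height at the base."""
        heights = []
        seed = 0
        while len(heights) < 10_000:
            train = generate_pulse_train("EC50_CNG", 1.0, 1.0, seed, duration=5_000.0)
            heights.extend(1.0 + r for _, _, r in train.pulses)
            seed += 1
        assert np.mean(heights) == pytest.approx(1.0, abs=0.01)

    def test_invalid_trains_rejected(self):
        with pytest.raises(ValueError):
            NoiseTrain("GTP", None, 1.0, 0, ((0.5, 9.0, 0.0),), 100.0)  # width
        with pytest.raises(ValueError):
            NoiseTrain("GTP", None, 0.5, 0, ((0.5, 2.0, 0.9),), 100.0)  # |R| > m
        with pytest.raises(ValueError):
            generate_pulse_train("GTP", None, 1.5, 0, 100.0)  # m > 1


@pytest.fixture(scope="module")
def sim_setup():
    p = ParameterSet()
    net = build_network(p)
    proto = StimulusProtocol(((10.0, 30.0),), duration=80.0)
    baseline = run_simulation(net, p, proto)
    return p, net, proto, baseline


class TestSimulateWithNoise:
    def test_zero_magnitude_is_bitwise_noop(self, sim_setup):
        """With identical solver segmentation a zero-magnitude train must
        not change any output bit."""
        p, net, proto, baseline = sim_setup
        train = generate_pulse_train("EC50_CNG", p["EC50_CNG"], 0.0, 3, proto.duration)
        mod = _NoiseModifier([train], baseline)
        segmented = run_simulation(net, p, proto,
                                   resting_state=baseline.resting_state,
                                   modifiers=[mod])
        perturbed = simulate_with_noise(net, p, train, proto, baseline)
        assert np.array_equal(segmented.y, perturbed.y)

    def test_noise_on_inactive_reaction_has_no_effect(self, sim_setup):
        """A rate constant whose reactants are absent (odor unbinding with no
        odor applied) has zero sensitivity."""
        p, net, _, _ = sim_setup
        quiet = StimulusProtocol((), duration=80.0)
        base = run_simulation(net, p, quiet)
        train = generate_pulse_train("K_m1_odor_R", p["K_m1_odor_R"], 1.0, 5, 80.0)
        pert = simulate_with_noise(net, p, train, quiet, base)
        res = classify_sensitivity(base, pert, base.resting_ca, "K_m1_odor_R", 1.0)
        assert res.max_deviation_uM < 1e-9
        assert not res.sensitive

    def test_unknown_target_rejected(self, sim_setup):
        p, net, proto, baseline = sim_setup
        train = generate_pulse_train("not_a_thing", 1.0, 0.5, 0, proto.duration)
        with pytest.raises(KeyError):
            simulate_with_noise(net, p, train, proto, baseline)


class TestClassifier:
    def test_identical_traces_insensitive(self):
        t = np.arange(0.0, 100.0, 0.1)
        ca = 0.05 + 0.01 * np.sin(t / 5.0)
        a = make_trace(t, ca)
        b = make_trace(t, ca.copy())
        res = classify_sensitivity(a, b, resting_ca=0.05)
        assert res.max_deviation_uM == 0.0 and not res.sensitive

    def test_ten_percent_offset_is_sensitive_and_upward(self):
        t = np.arange(0.0, 100.0, 0.1)
        ca = np.full(t.size, 0.05)
        pert = ca.copy()
        pert[(t > 40) & (t < 41)] = 0.055  # +10 % of rest for 1 s
        res = classify_sensitivity(make_trace(t, ca), make_trace(t, pert),
                                   resting_ca=0.05)
        assert res.sensitive
        assert res.upward_dominant
        assert res.deviation_pct_of_rest == pytest.approx(10.0)

    def test_five_percent_rule_boundary(self):
        t = np.arange(0.0, 100.0, 0.1)
        ca = np.full(t.size, 0.05)
        pert = ca.copy()
        pert[500] = 0.05 + 0.049 * 0.05
        res = classify_sensitivity(make_trace(t, ca), make_trace(t, pert), 0.05)
        assert not res.sensitive
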