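"""Event-loop semantics: firing, rescheduling, sampling, continuation."""

import math

import numpy as np
import pytest

from actinet.engine import (
    FiringSchedule,
    ScheduleEntry,
    SimulationState,
    apply_firing,
    continue_from,
    reschedule,
    simulate,
    TimeSeries,
)
from actinet.fixtures import build_mek_erk
from actinet.netmodel import (
    ACTIVATION,
    INHIBITION,
    Network,
    S1_REACTANT,
    S2_REACTANT_SUBSTRATE,
)


class TestSimulate:
    def test_linear_ramp_oracle(self, ramp_network):
        """S1 at rate 0.1, L=10: level(t) = floor(t) until saturation at 10."""
        s = simulate(ramp_network, 12, mode="center", sample_step=0.25)
        levels = np.round(s.activity("B") / 10).astype(int)
        expected = np.minimum(np.floor(s.times + 1e-9), 10).astype(int)
        assert np.array_equal(levels, expected)

    def test_zero_rate_network_constant(self, two_node):
        net = two_node.set_initial_level("A", 0)  # source inactive forever
        s = simulate(net, 50, mode="center")
        assert np.all(s.activity("B") == 0.0)
        assert np.all(s.activity("A") == 0.0)

    def test_first_sample_is_initial_state(self, two_node):
        s = simulate(two_node, 10, mode="uniform", seed=5)
        assert s.activity("A")[0] == 100.0 and s.activity("B")[0] == 0.0

    def test_values_stay_on_percent_scale(self, two_node):
        s = simulate(two_node, 50, mode="uniform", seed=2)
        v = s.frame.to_numpy()
        assert v.min() >= 0.0 and v.max() <= 100.0

    @pytest.mark.parametrize("mode", ["center", "uniform", "lo", "hi"])
    def test_reproducible_for_fixed_inputs(self, two_node, mode):
        a = simulate(two_node, 20, mode=mode, seed=7)
        b = simulate(two_node, 20, mode=mode, seed=7)
        assert a == b

    def test_different_seeds_differ_in_uniform_mode(self):
        net = build_mek_erk(levels=50)
        a = simulate(net, 500, mode="uniform", seed=1)
        b = simulate(net, 500, mode="uniform", seed=2)
        assert not (a == b)

    def test_mek_erk_interval_bounds(self):
        """Every step latency of the clocked toy lies inside [18, 20]."""
        net = build_mek_erk(levels=20)
        s = simulate(net, 500, mode="uniform", seed=11, record_events=True)
        changed = [e for e in s.events if e.level_changed]
        assert changed
        for e in changed:
            assert e.lo - 1e-9 <= e.latency <= e.hi + 1e-9
            assert e.lo == pytest.approx(18.0) and e.hi == pytest.approx(20.0)

    def test_invalid_network_rejected(self):
        from actinet.netmodel import Interaction, Node

        bad = Network(nodes=(Node("A"),), interactions=(Interaction("x", ("A",), "Z", ACTIVATION, S1_REACTANT, 1.0),))
        with pytest.raises(ValueError, match="invalid network"):
            simulate(bad, 10)

    def test_nonpositive_duration_rejected(self, two_node):
        with pytest.raises(ValueError, match="duration"):
            simulate(two_node, 0)

    def test_disabled_node_level_frozen(self, two_node):
        net = two_node.set_initial_level("B", 40).set_enabled("B", False)
        s = simulate(net, 20, mode="center")
        assert np.all(s.activity("B") == 40.0)


class TestApplyFiring:
    def _setup(self):
        net = Network().add_node("T", levels=10, initial_level=3)
        net = net.add_node("S", levels=10, initial_level=10)
        act = net.add_interaction("S", "T", ACTIVATION, S1_REACTANT, k=1.0, id="up")
        inh = act.add_interaction("S", "T", INHIBITION, S1_REACTANT, k=1.0, id="down")
        return inh

    def test_activation_steps_up(self):
        net = self._setup()
        state = SimulationState(0.0, {"T": 3, "S": 10})
        assert apply_firing(state, net.interaction("up"), net).levels["T"] == 4

    def test_clamped_at_bounds(self):
        net = self._setup()
        top = SimulationState(0.0, {"T": 10, "S": 10})
        bottom = SimulationState(0.0, {"T": 0, "S": 10})
        assert apply_firing(top, net.interaction("up"), net).levels["T"] == 10
        assert apply_firing(bottom, net.interaction("down"), net).levels["T"] == 0


class TestReschedule:
    def _net(self):
        return (
            Network()
            .add_node("A", levels=10, initial_level=10)
            .add_node("B", levels=10, initial_level=0)
            .add_interaction("A", "B", ACTIVATION, S1_REACTANT, k=0.1, uncertainty=0.0, id="A->B")
        )

    def test_untouched_without_changed_nodes(self):
        net = self._net()
        sched = FiringSchedule({"A->B": ScheduleEntry(time=1.0, start=0.0, dt=1.0, lo=1.0, hi=1.0)})
        state = SimulationState(0.5, {"A": 10, "B": 0})
        out = reschedule(sched, net, state, [], mode="center")
        assert out.entries["A->B"].time == 1.0

    def test_rate_halved_doubles_remaining_wait(self):
        net = self._net()
        sched = FiringSchedule({"A->B": ScheduleEntry(time=1.0, start=0.0, dt=1.0, lo=1.0, hi=1.0)})
        state = SimulationState(0.5, {"A": 5, "B": 0})  # source halved mid-step
        out = reschedule(sched, net, state, ["A"], mode="center")
        assert out.entries["A->B"].time == pytest.approx(0.5 + 0.5 * 2.0)

    def test_source_dropping_to_zero_parks_entry(self):
        net = self._net()
        sched = FiringSchedule({"A->B": ScheduleEntry(time=1.0, start=0.0, dt=1.0, lo=1.0, hi=1.0)})
        state = SimulationState(0.5, {"A": 0, "B": 0})
        out = reschedule(sched, net, state, ["A"], mode="center")
        assert math.isinf(out.entries["A->B"].time)


class TestContinueFrom:
    def test_time_zero_recovers_initial_network(self, two_node):
        s = simulate(two_node, 10, mode="center")
        assert continue_from(s, 0.0, two_node) == two_node

    def test_splice_consistency_in_center_mode(self):
        """Restarting at a step instant reproduces the tail of a full run.

        The copy point must coincide with a firing instant because the
        continuation resets every automaton's clock; mek_erk steps every
        19 tu in center mode, so t = 190 is both a grid and a step time.
        """
        net = build_mek_erk(levels=20)  # full traversal 380 tu
        full = simulate(net, 380, mode="center", sample_step=19.0)
        half = continue_from(full, 190.0, net)
        tail = simulate(half, 190, mode="center", sample_step=19.0)
        np.testing.assert_allclose(
            tail.activity("ERK"), full.activity("ERK")[10:], atol=1e-9
        )

    def test_disabled_node_keeps_stored_level(self, two_node):
        net = two_node.set_initial_level("B", 7).set_enabled("B", False)
        s = simulate(net, 10, mode="center")
        out = continue_from(s, 10.0, net)
        assert out.node("B").initial_level == 7 and not out.node("B").enabled

    def test_outside_span_rejected(self, two_node):
        s = simulate(two_node, 10, mode="center")
        with pytest.raises(ValueError, match="span"):
            continue_from(s, 11.0, two_node)


class TestTimeSeriesCsv:
    def test_roundtrip(self, two_node, tmp_path):
        s = simulate(two_node, 10, mode="uniform", seed=3)
        p = tmp_path / "out.csv"
        s.to_csv(p)
        back = TimeSeries.from_csv(p)
        np.testing.assert_allclose(back.times, s.times, atol=1e-4)  # %.6g format
        np.testing.assert_allclose(back.activity("B"), s.activity("B"), atol=1e-3)

    def test_byte_identical_rewrites(self, two_node, tmp_path):
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        simulate(two_node, 10, mode="uniform", seed=3).to_csv(a)
        simulate(two_node, 10, mode="uniform", seed=3).to_csv(b)
        assert a.read_bytes() == b.read_bytes()


class TestOrGateSemantics:
    def test_parallel_edges_activate_faster_than_either_alone(self):
        def build(edges):
            net = Network()
            for n in ("A", "B", "C"):
                net = net.add_node(n, levels=50, initial_level=50 if n != "C" else 0)
            for src in edges:
                net = net.add_interaction(src, "C", ACTIVATION, S2_REACTANT_SUBSTRATE, k=0.2, uncertainty=0.0, id=f"{src}->C")
            return net

        def t_half(net):
            s = simulate(net, 60, mode="center", sample_step=0.1)
            idx = np.argmax(s.activity("C") >= 50.0)
            return s.times[idx]

        t_both = t_half(build(["A", "B"]))
        t_a = t_half(build(["A"]))
        assert t_both < t_a

    def test_time_to_half_nonincreasing_in_k(self):
        times = []
        for k in (0.1, 0.2, 0.4, 0.8):
            net = (
                Network()
                .add_node("A", levels=100, initial_level=100)
                .add_node("B", levels=100, initial_level=0)
                .add_interaction("A", "B", ACTIVATION, S2_REACTANT_SUBSTRATE, k=k, uncertainty=0.0)
            )
            s = simulate(net, 100, mode="center", sample_step=0.05)
            times.append(s.times[np.argmax(s.activity("B") >= 50.0)])
        assert all(b <= a for a, b in zip(times, times[1:]))
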