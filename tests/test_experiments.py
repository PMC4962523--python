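"""Protocols and comparison utilities: knock-outs, sweeps, oscillation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from actinet.engine import TimeSeries, simulate
from actinet.experiments import (
    ReferenceData,
    complement_percent,
    detect_oscillation,
    downstream_interactions,
    fit_score,
    knockout,
    normalize_to_max,
    parameter_sweep,
    phase_difference,
)
from actinet.fixtures import build_mek_erk, synthetic_reference
from actinet.netmodel import ACTIVATION, Network, S2_REACTANT_SUBSTRATE


def _series_from_arrays(times, **cols) -> TimeSeries:
    frame = pd.DataFrame(cols, index=pd.Index(times, name="time"))
    return TimeSeries(frame)


class TestKnockout:
    def test_knockout_disables_listed_nodes(self):
        net = build_mek_erk()
        out = knockout(net, ["MEK"])
        assert not out.node("MEK").enabled and out.node("ERK").enabled

    def test_mek_knockout_freezes_erk(self):
        net = knockout(build_mek_erk(levels=10), ["MEK"])
        s = simulate(net, 500, mode="center")
        assert np.all(s.activity("ERK") == 0.0)

    def test_sink_knockout_leaves_upstream_untouched(self):
        net = build_mek_erk(levels=10)
        base = simulate(net, 200, mode="center")
        ko = simulate(knockout(net, ["ERK"]), 200, mode="center")
        np.testing.assert_array_equal(base.activity("MEK"), ko.activity("MEK"))

    def test_unknown_node_rejected(self):
        with pytest.raises(KeyError):
            knockout(build_mek_erk(), ["ghost"])


class TestFitScore:
    def test_series_against_itself_is_zero(self, two_node):
        s = simulate(two_node, 50, mode="center")
        ref = ReferenceData(s.frame.copy())
        assert fit_score(s, ref) == 0.0

    def test_constant_offset_squared(self):
        s = _series_from_arrays([0.0, 1.0, 2.0], X=[0.0, 0.0, 0.0])
        ref = ReferenceData(pd.DataFrame({"X": [100.0, 100.0, 100.0]}, index=pd.Index([0.0, 1.0, 2.0], name="time")))
        assert fit_score(s, ref) == pytest.approx(10000.0)

    def test_perfectly_matching_extra_column_leaves_score_unchanged(self):
        t = [0.0, 1.0, 2.0]
        s = _series_from_arrays(t, X=[0.0, 0.0, 0.0], Y=[5.0, 6.0, 7.0])
        ref1 = ReferenceData(pd.DataFrame({"X": [10.0] * 3}, index=pd.Index(t, name="time")))
        ref2 = ReferenceData(pd.DataFrame({"X": [10.0] * 3, "Y": [5.0, 6.0, 7.0]}, index=pd.Index(t, name="time")))
        assert fit_score(s, ref2) == pytest.approx(fit_score(s, ref1) / 2)

    def test_no_shared_columns_rejected(self):
        s = _series_from_arrays([0.0, 1.0], X=[0.0, 1.0])
        ref = ReferenceData(pd.DataFrame({"Z": [1.0, 2.0]}, index=pd.Index([0.0, 1.0], name="time")))
        with pytest.raises(ValueError, match="shared"):
            fit_score(s, ref)


class TestParameterSweep:
    @pytest.fixture
    def sweep_net(self):
        return (
            Network(time_unit="tu")
            .add_node("S", levels=100, initial_level=100)
            .add_node("T", levels=100, initial_level=0)
            .add_interaction("S", "T", ACTIVATION, S2_REACTANT_SUBSTRATE, k=1.0, uncertainty=0.0, id="S->T")
        )

    def test_single_point_grid(self, sweep_net):
        ref = synthetic_reference(sweep_net, {"S->T": 0.05}, sample_times=np.linspace(0, 60, 13))
        res = parameter_sweep(sweep_net, {"S->T": [0.05]}, ref)
        assert len(res.ranking) == 1 and res.best[0] == {"S->T": 0.05}

    def test_noiseless_recovery_ranks_truth_first(self, sweep_net):
        k_star = 0.05
        grid = list(np.round(np.linspace(0.01, 0.2, 20), 4))
        assert round(k_star, 4) in grid
        ref = synthetic_reference(sweep_net, {"S->T": k_star}, sample_times=np.linspace(0, 60, 13), nodes=["T"])
        res = parameter_sweep(sweep_net, {"S->T": grid}, ref)
        assert res.best[0]["S->T"] == pytest.approx(k_star)
        assert res.best[1] == pytest.approx(0.0, abs=1e-9)

    def test_score_unimodal_around_truth(self, sweep_net):
        grid = list(np.round(np.linspace(0.01, 0.2, 20), 4))
        ref = synthetic_reference(sweep_net, {"S->T": 0.05}, sample_times=np.linspace(0, 60, 13), nodes=["T"])
        res = parameter_sweep(sweep_net, {"S->T": grid}, ref)
        by_k = {a["S->T"]: sc for a, sc in res.ranking}
        scores = [by_k[k] for k in grid]
        trough = int(np.argmin(scores))
        assert all(a >= b for a, b in zip(scores[:trough], scores[1 : trough + 1]))
        assert all(a <= b for a, b in zip(scores[trough:], scores[trough + 1 :]))

    def test_ranking_ascending(self, sweep_net):
        ref = synthetic_reference(sweep_net, {"S->T": 0.05}, sample_times=np.linspace(0, 60, 7))
        res = parameter_sweep(sweep_net, {"S->T": [0.02, 0.05, 0.1]}, ref)
        scores = [sc for _, sc in res.ranking]
        assert scores == sorted(scores)

    def test_unknown_interaction_or_empty_grid_rejected(self, sweep_net):
        ref = synthetic_reference(sweep_net, sample_times=[0.0, 10.0])
        with pytest.raises(KeyError):
            parameter_sweep(sweep_net, {"ghost": [1.0]}, ref)
        with pytest.raises(ValueError, match="empty"):
            parameter_sweep(sweep_net, {}, ref)


class TestNormalisation:
    def test_column_scaled_to_max_100(self):
        raw = pd.DataFrame({"A": [2.0, 4.0, 8.0]}, index=pd.Index([0.0, 1.0, 2.0], name="time"))
        out = normalize_to_max(raw)
        assert list(out.table["A"]) == [25.0, 50.0, 100.0]

    def test_columns_scaled_independently(self):
        raw = pd.DataFrame(
            {"A": [1.0, 2.0], "B": [10.0, 40.0]}, index=pd.Index([0.0, 1.0], name="time")
        )
        out = normalize_to_max(raw)
        assert list(out.table["A"]) == [50.0, 100.0]
        assert list(out.table["B"]) == [25.0, 100.0]

    def test_already_normalised_unchanged(self):
        raw = pd.DataFrame({"A": [50.0, 100.0]}, index=pd.Index([0.0, 1.0], name="time"))
        assert list(normalize_to_max(raw).table["A"]) == [50.0, 100.0]

    def test_all_zero_column_rejected(self):
        raw = pd.DataFrame({"A": [0.0, 0.0]}, index=pd.Index([0.0, 1.0], name="time"))
        with pytest.raises(ValueError, match="positive maximum"):
            normalize_to_max(raw)

    @pytest.mark.parametrize("col,expected", [([30.0], [70.0]), ([0.0, 100.0], [100.0, 0.0])])
    def test_complement_percent(self, col, expected):
        assert list(complement_percent(col)) == expected

    @given(st.lists(st.floats(min_value=0, max_value=100), min_size=1, max_size=20))
    def test_complement_is_involution(self, col):
        np.testing.assert_allclose(complement_percent(complement_percent(col)), col, atol=1e-7)

    def test_complement_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            complement_percent([120.0])


class TestOscillationMetrics:
    def _sinusoid(self, period=24.0, amplitude=40.0, days=5, step=0.1, phase=0.0):
        t = np.arange(0, days * 24 + step / 2, step)
        v = 50 + amplitude * np.sin(2 * np.pi * (t - phase) / period)
        return t, np.clip(v, 0, 100)

    def test_constant_series_not_oscillating(self):
        t = np.arange(0, 100, 0.5)
        s = _series_from_arrays(t, X=np.full_like(t, 42.0))
        assert detect_oscillation(s, "X") is None

    def test_sinusoid_period_and_amplitude_recovered(self):
        t, v = self._sinusoid(period=24.0, amplitude=40.0, step=0.1)
        s = _series_from_arrays(t, X=v)
        period, amplitude = detect_oscillation(s, "X")
        assert period == pytest.approx(24.0, abs=0.2)
        assert amplitude == pytest.approx(80.0, rel=0.05)  # peak-to-trough

    def test_phase_difference_of_identical_signals_is_zero(self):
        t, v = self._sinusoid()
        s = _series_from_arrays(t, X=v, Y=v.copy())
        assert np.allclose(phase_difference(s, "X", "Y"), 0.0)

    def test_phase_difference_recovers_known_offset(self):
        t, a = self._sinusoid(phase=0.0)
        _, b = self._sinusoid(phase=6.0)
        s = _series_from_arrays(t, X=a, Y=b)
        offs = phase_difference(s, "X", "Y")
        assert np.allclose(offs, 6.0, atol=0.3)

    def test_non_oscillating_input_rejected(self):
        t, v = self._sinusoid()
        s = _series_from_arrays(t, X=v, Y=np.full_like(t, 10.0))
        with pytest.raises(ValueError, match="oscillate"):
            phase_difference(s, "X", "Y")

    def test_quantisation_twin_peaks_merged(self):
        """Equal-height peaks a level apart on a plateau count as one."""
        t = np.arange(0, 100, 0.5)
        v = 50 + 30 * np.sin(2 * np.pi * t / 24)
        v = np.round(v)  # quantise to integer levels
        v[40] += 1.0  # wobble on a plateau
        s = _series_from_arrays(t, X=v)
        period, _ = detect_oscillation(s, "X", transient_fraction=0.0)
        assert period == pytest.approx(24.0, abs=0.5)


class TestDownstreamInteractions:
    def test_reachable_edges_only(self):
        net = (
            Network()
            .add_node("A", 10, 10)
            .add_node("B", 10, 0)
            .add_node("C", 10, 0)
            .add_node("D", 10, 10)
            .add_interaction("A", "B", ACTIVATION, S2_REACTANT_SUBSTRATE, k=1, id="A->B")
            .add_interaction("B", "C", ACTIVATION, S2_REACTANT_SUBSTRATE, k=1, id="B->C")
            .add_interaction("D", "A", ACTIVATION, S2_REACTANT_SUBSTRATE, k=1, id="D->A")
        )
        assert set(downstream_interactions(net, "B")) == {"B->C"}
        assert set(downstream_interactions(net, "A")) == {"A->B", "B->C"}
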