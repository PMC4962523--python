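"""Two-node MEK -> ERK toy: the minimal timed-automaton example.

MEK is persistently fully active (no inputs); a single S1 activation edge
drives ERK upward one level at a time.  The rate constant is chosen so
that one ERK level step has an expected latency of 19 time units, and the
uncertainty is 1/19, which puts the admissible firing window at exactly
18 < t < 20: the guard/invariant bracket of the classic illustration of a
biochemical step as a clocked automaton transition.
"""

from __future__ import annotations

from ..netmodel import ACTIVATION, DEFAULT_LEVELS, Network, S1_REACTANT

#: Expected single-step latency (time units) and window half-width.
STEP_LATENCY = 19.0
STEP_UNCERTAINTY = 1.0 / 19.0


def build_mek_erk(levels: int = DEFAULT_LEVELS) -> Network:
    """MEK (fully active, constant) activates ERK (initially inactive).

    ``levels`` sets ERK's granularity; the rate is scaled so that a single
    level step always takes 19 time units in expectation (window
    [18, 20]), and a full 0 -> L traversal takes ``19 * levels``.
    """
    k = 1.0 / (STEP_LATENCY * levels)
    net = Network(time_unit="tu")
    net = net.add_node("MEK", levels=levels, initial_level=levels)
    net = net.add_node("ERK", levels=levels, initial_level=0)
    net = net.add_interaction(
        "MEK", "ERK", ACTIVATION, S1_REACTANT, k=k, uncertainty=STEP_UNCERTAINTY, id="MEK->ERK"
    )
    return net
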