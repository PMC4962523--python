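"""Rate laws, firing-time conversion, and the deterministic ODE drift.

Each interaction has one of three rate-law shapes ("scenarios"), all
linear in the rate constant ``k`` and bilinear at most in the activity
fractions involved:

* ``S1_REACTANT``      — r = k * a                (source activity only)
* ``S2_REACTANT_SUBSTRATE`` — activation r = k * a * (1 - y), inhibition
  r = k * a * y, where ``y`` is the target's active fraction: the step can
  only proceed on the part of the target pool still available to it.
* ``AND``              — r = k * a1 * a2          (two-source product gate)

Rates are fractions of the target's full activity range per model time
unit.  A single level step of a target with granularity ``L`` therefore
has expected latency ``Δt = (1 / L) / r``: traversing the whole range at
constant rate ``r`` takes ``1 / r`` regardless of ``L`` (granularity
invariance).  Nondeterminism enters through the firing window
``[Δt (1 - u), Δt (1 + u)]`` — the guard and location-invariant bounds of
the underlying timed automaton's clock.

The signed sum of incoming rates, :func:`net_drift`, is the right-hand
side of the piecewise-smooth ODE that the discrete simulation approaches
as ``L`` grows; the test-suite's numerical-integration oracle integrates
exactly this function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .netmodel import (
    ACTIVATION,
    AND,
    Interaction,
    Network,
    S1_REACTANT,
    S2_REACTANT_SUBSTRATE,
)

__all__ = [
    "FiringInterval",
    "NEVER",
    "scenario_rate",
    "step_time",
    "firing_interval",
    "activity_fractions",
    "net_drift",
]


@dataclass(frozen=True)
class FiringInterval:
    """Admissible clock window ``[lo, hi]`` for the next level step.

    ``lo = Δt (1 - u)`` is the guard (earliest firing), ``hi = Δt (1 + u)``
    the invariant (latest).  The distinguished value :data:`NEVER`
    (``lo = hi = inf``) marks an interaction whose current rate is zero.
    """

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.is_never:
            if self.lo < 0 or self.hi < self.lo:
                raise ValueError(f"invalid firing interval [{self.lo}, {self.hi}]")

    @property
    def is_never(self) -> bool:
        return math.isinf(self.lo)

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lo + self.hi)


#: Firing interval of a zero-rate interaction.
NEVER = FiringInterval(math.inf, math.inf)


def _check_fraction(value: float, what: str) -> float:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{what} activity fraction {value} outside [0, 1]")
    return value


def scenario_rate(interaction: Interaction, fractions: Mapping[str, float]) -> float:
    """Current rate of *interaction* given node activity fractions.

    ``fractions`` must supply an activity fraction in [0, 1] for every
    source and for the target; disabled sources must be reported as 0 by
    the caller (see :func:`activity_fractions`).
    """
    srcs = [_check_fraction(fractions[s], f"source {s!r}") for s in interaction.sources]
    y = _check_fraction(fractions[interaction.target], f"target {interaction.target!r}")
    k = interaction.k
    if interaction.scenario == S1_REACTANT:
        return k * srcs[0]
    if interaction.scenario == AND:
        return k * srcs[0] * srcs[1]
    # S2: the step acts on the part of the target pool it can still convert
    avail = (1.0 - y) if interaction.sign == ACTIVATION else y
    return k * srcs[0] * avail


def step_time(rate: float, target_levels: int) -> float:
    """Expected time for one level step of a target with ``target_levels``.

    Zero rate maps to ``inf`` (never fires).
    """
    if rate < 0:
        raise ValueError(f"negative rate {rate}")
    if target_levels < 1:
        raise ValueError(f"target_levels must be >= 1, got {target_levels}")
    if rate == 0.0:
        return math.inf
    return (1.0 / target_levels) / rate


def firing_interval(dt: float, u: float) -> FiringInterval:
    """Window ``[dt (1 - u), dt (1 + u)]``; ``inf`` passes through as NEVER."""
    if not 0 <= u < 1:
        raise ValueError(f"uncertainty must lie in [0, 1), got {u}")
    if math.isinf(dt):
        return NEVER
    if dt <= 0:
        raise ValueError(f"expected step time must be positive, got {dt}")
    return FiringInterval(dt * (1.0 - u), dt * (1.0 + u))


def activity_fractions(network: Network, levels: Mapping[str, int]) -> dict[str, float]:
    """Per-node active fractions, with disabled nodes forced to 0.

    Disabled nodes retain their stored level but contribute no activity to
    any interaction they source (knock-out semantics).
    """
    out: dict[str, float] = {}
    for node in network.nodes:
        lvl = levels.get(node.name, node.initial_level)
        out[node.name] = (lvl / node.levels) if node.enabled else 0.0
    return out


def net_drift(node_name: str, network: Network, fractions: Mapping[str, float]) -> float:
    """Signed sum of incoming interaction rates: d(activity)/dt.

    Activations count positive, inhibitions negative; interactions are
    additive ("OR" gates are simply parallel edges).  Interactions whose
    target is disabled never fire and contribute nothing.
    """
    node = network.node(node_name)
    if not node.enabled:
        return 0.0
    total = 0.0
    for inter in network.interactions:
        if inter.target != node_name:
            continue
        r = scenario_rate(inter, fractions)
        total += r if inter.sign == ACTIVATION else -r
    return total
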