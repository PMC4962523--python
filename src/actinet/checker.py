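"""Bounded reachability over the discretised state space.

Because activity levels are finite and firing times can be quantised to a
tick grid, the set of behaviours of a network within a time horizon is a
finite transition system and can be searched exhaustively.  The checker
answers queries of the form "can NODE reach a level satisfying CMP BOUND
within TIME" by exploring *all* admissible firing-time choices: every
pending interaction may fire at any tick-aligned instant inside its
``[lo, hi]`` window, not just at one scheduler's choice.  A positive
answer comes with a minimal-time witness trace that replays through the
engine's firing rule.

The tick quantisation makes the search an under-approximation of the
continuous semantics (firings strictly between grid points are not
represented); the default tick — a quarter of the smallest guard bound
among enabled interactions — keeps the grid finer than any single step.
The search is Dijkstra-style on elapsed time, memoised on (levels,
pending countdowns), and guarded by a configurable state budget.
"""

from __future__ import annotations

import heapq
import itertools
import math
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

from .engine import SimulationState, apply_firing
from .kinetics import activity_fractions, scenario_rate, step_time
from .netmodel import Network

__all__ = [
    "ReachabilityQuery",
    "Witness",
    "TraceStep",
    "StateBudgetExceeded",
    "parse_query",
    "default_tick",
    "check_reachability",
    "dose_search",
]

COMPARATORS = ("<=", ">=", "==")


class StateBudgetExceeded(RuntimeError):
    """The reachability search hit its state-count budget."""


@dataclass(frozen=True)
class ReachabilityQuery:
    """Can *node* reach activity CMP *bound* (0-100) within *horizon*?"""

    node: str
    comparator: str
    bound: float  # activity on the 0-100 scale
    horizon: float

    def __post_init__(self) -> None:
        if self.comparator not in COMPARATORS:
            raise ValueError(f"comparator must be one of {COMPARATORS}, got {self.comparator!r}")
        if not 0 <= self.bound <= 100:
            raise ValueError(f"bound must lie in [0, 100], got {self.bound}")
        if not self.horizon > 0:
            raise ValueError(f"horizon must be positive, got {self.horizon}")

    def satisfied(self, level: int, levels_max: int) -> bool:
        pct = level * 100.0 / levels_max
        if self.comparator == "<=":
            return pct <= self.bound + 1e-9
        if self.comparator == ">=":
            return pct >= self.bound - 1e-9
        return abs(pct - self.bound) < 1e-9


_QUERY_RE = re.compile(r"^\s*(\S+)\s*(<=|>=|==|=)\s*([0-9.]+)\s+within\s+([0-9.eE+-]+)\s*$")


def parse_query(text: str) -> ReachabilityQuery:
    """Parse the mini-syntax ``"NODE >= LEVEL within TIME"``."""
    m = _QUERY_RE.match(text)
    if not m:
        raise ValueError(
            f"cannot parse query {text!r}; expected 'NODE <=|>=|== LEVEL within TIME'"
        )
    node, cmp_, bound, horizon = m.groups()
    if cmp_ == "=":
        cmp_ = "=="
    return ReachabilityQuery(node, cmp_, float(bound), float(horizon))


@dataclass(frozen=True)
class TraceStep:
    time: float
    interaction_id: str
    levels: dict[str, int]


@dataclass(frozen=True)
class Witness:
    """Outcome of a reachability check, with a replayable trace if found."""

    reachable: bool
    trace: tuple[TraceStep, ...] = ()
    states_explored: int = 0


def default_tick(network: Network) -> float:
    """A quarter of the smallest guard bound among enabled interactions.

    Computed from each interaction's fastest achievable rate (all activity
    fractions at 1), which bounds its guard ``lo`` from below.
    """
    lo_min = math.inf
    for it in network.interactions:
        node = network.node(it.target)
        if not node.enabled:
            continue
        if any(not network.node(s).enabled for s in it.sources):
            continue
        dt = step_time(it.k, node.levels)  # fastest: all fractions 1
        lo = dt * (1.0 - it.uncertainty)
        lo_min = min(lo_min, lo)
    if not math.isfinite(lo_min):
        raise ValueError("no enabled interaction can ever fire; tick undefined")
    return lo_min / 4.0


def _draw_range(dt: float, u: float, tick: float) -> range:
    """Tick counts admissible in [dt(1-u), dt(1+u)]; at least one draw."""
    lo = dt * (1.0 - u)
    hi = dt * (1.0 + u)
    c_lo = max(1, math.ceil(lo / tick - 1e-9))
    c_hi = max(c_lo, math.floor(hi / tick + 1e-9))
    return range(c_lo, c_hi + 1)


def check_reachability(
    network: Network,
    query: ReachabilityQuery,
    tick: float | None = None,
    max_states: int = 200_000,
) -> Witness:
    """Exhaustively decide *query* under tick-quantised firing times.

    Returns a :class:`Witness` whose trace (if reachable) is the earliest
    satisfying run at this quantisation.  Raises
    :class:`StateBudgetExceeded` when the memoised search would exceed
    *max_states* distinct states.
    """
    violations = network.validate()
    if violations:
        raise ValueError("invalid network: " + "; ".join(violations))
    network.node(query.node)
    if tick is None:
        tick = default_tick(network)
    if not tick > 0:
        raise ValueError(f"tick must be positive, got {tick}")
    horizon_ticks = int(round(query.horizon / tick))
    if abs(horizon_ticks * tick - query.horizon) > 1e-6 * max(1.0, query.horizon):
        raise ValueError(f"tick {tick} does not divide the horizon {query.horizon}")

    names = network.node_names()
    node_of = {n.name: n for n in network.nodes}
    q_idx = names.index(query.node)
    q_levels = node_of[query.node].levels
    inters = network.interactions
    m = len(inters)
    tgt_idx = [names.index(it.target) for it in inters]

    def rates(levels: tuple[int, ...]) -> list[float]:
        fr = activity_fractions(network, dict(zip(names, levels)))
        out = []
        for it in inters:
            if not node_of[it.target].enabled:
                out.append(0.0)
            else:
                out.append(scenario_rate(it, fr))
        return out

    def dts(levels: tuple[int, ...]) -> list[float]:
        return [step_time(r, node_of[inters[j].target].levels) for j, r in enumerate(rates(levels))]

    init_levels = tuple(n.initial_level for n in network.nodes)
    if query.satisfied(init_levels[q_idx], q_levels):
        return Witness(reachable=True, trace=(), states_explored=0)

    # countdown options for each interaction in the initial state
    init_dts = dts(init_levels)
    option_sets: list[Sequence[int | None]] = []
    for j in range(m):
        if math.isinf(init_dts[j]):
            option_sets.append((None,))
        else:
            option_sets.append(tuple(_draw_range(init_dts[j], inters[j].uncertainty, tick)))

    best: dict[tuple, int] = {}
    counter = itertools.count()
    heap: list = []
    for combo in itertools.product(*option_sets):
        state = (init_levels, combo)
        if state not in best or best[state] > 0:
            best[state] = 0
            heapq.heappush(heap, (0, next(counter), state, None, None))

    parents: dict[tuple, tuple] = {}
    explored = 0
    while heap:
        elapsed, _, state, parent, fired = heapq.heappop(heap)
        if best.get(state, math.inf) < elapsed:
            continue
        if state not in parents and parent is not None:
            parents[state] = (parent, fired, elapsed)
        explored += 1
        if explored > max_states:
            raise StateBudgetExceeded(
                f"reachability search exceeded {max_states} states at elapsed {elapsed * tick}"
            )
        levels, cds = state
        pending = [(cd, j) for j, cd in enumerate(cds) if cd is not None]
        if not pending:
            continue
        m_cd = min(cd for cd, _ in pending)
        t_next = elapsed + m_cd
        if t_next > horizon_ticks:
            continue
        old_dts = dts(levels)
        for cd, j in pending:
            if cd != m_cd:
                continue
            new_levels = list(levels)
            it = inters[j]
            tgt = tgt_idx[j]
            L = node_of[it.target].levels
            delta = 1 if it.sign == "activation" else -1
            new_levels[tgt] = min(max(new_levels[tgt] + delta, 0), L)
            new_levels = tuple(new_levels)
            sat = query.satisfied(new_levels[q_idx], q_levels)
            new_dts = dts(new_levels)
            # per-interaction countdown options after this firing
            opts: list[Sequence[int | None]] = []
            for i2 in range(m):
                if i2 == j:
                    if math.isinf(new_dts[i2]):
                        opts.append((None,))
                    else:
                        opts.append(tuple(_draw_range(new_dts[i2], inters[i2].uncertainty, tick)))
                    continue
                cd2 = cds[i2]
                if cd2 is None:
                    if math.isinf(new_dts[i2]):
                        opts.append((None,))
                    else:  # rate rose from zero: fresh draws
                        opts.append(tuple(_draw_range(new_dts[i2], inters[i2].uncertainty, tick)))
                    continue
                rem = cd2 - m_cd
                if math.isinf(new_dts[i2]):
                    opts.append((None,))
                elif new_dts[i2] != old_dts[i2]:  # rescale remaining wait
                    factor = new_dts[i2] / old_dts[i2]
                    opts.append((max(0, round(rem * factor)),))
                else:
                    opts.append((rem,))
            for combo in itertools.product(*opts):
                succ = (new_levels, combo)
                if best.get(succ, math.inf) <= t_next:
                    continue
                best[succ] = t_next
                parents[succ] = (state, it.id, t_next)
                if sat:
                    # reconstruct the witness trace
                    steps: list[TraceStep] = []
                    cur = succ
                    while cur in parents:
                        prev, iid, at = parents[cur]
                        steps.append(TraceStep(at * tick, iid, dict(zip(names, cur[0]))))
                        cur = prev
                    steps.reverse()
                    return Witness(reachable=True, trace=tuple(steps), states_explored=explored)
                heapq.heappush(heap, (t_next, next(counter), succ, state, it.id))
    return Witness(reachable=False, trace=(), states_explored=explored)


def dose_search(
    network: Network,
    stimulus_nodes: Sequence[str],
    dose_grid: Mapping[str, Sequence[float]] | Sequence[Sequence[float]],
    query: ReachabilityQuery,
    tick: float | None = None,
    max_states: int = 200_000,
) -> list[tuple[dict[str, float], Witness]]:
    """Search stimulus-dose combinations for ones that satisfy *query*.

    ``dose_grid`` maps each stimulus node to its candidate initial
    activity fractions (or is a list of per-node fraction lists in the
    order of *stimulus_nodes*).  Every combination is checked; the
    satisfying ones are returned with their witnesses.
    """
    for n in stimulus_nodes:
        network.node(n)
    if isinstance(dose_grid, Mapping):
        per_node = [list(dose_grid[n]) for n in stimulus_nodes]
    else:
        per_node = [list(v) for v in dose_grid]
        if len(per_node) != len(stimulus_nodes):
            raise ValueError("dose_grid length does not match stimulus_nodes")
    hits: list[tuple[dict[str, float], Witness]] = []
    for combo in itertools.product(*per_node):
        doses = dict(zip(stimulus_nodes, combo))
        net = network
        for name, frac in doses.items():
            net = net.set_initial_fraction(name, frac)
        wit = check_reachability(net, query, tick=tick, max_states=max_states)
        if wit.reachable:
            hits.append((doses, wit))
    return hits
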