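"""Discrete-event simulation of activity-level networks.

Every interaction behaves as a small timed automaton: while its rate is
positive it holds a pending level step whose clock must fire inside the
window ``[Δt (1 - u), Δt (1 + u)]`` around the expected step time.  The
engine keeps one pending firing per interaction in a priority queue,
repeatedly pops the earliest (ties broken by interaction id), applies a
single ±1 level step to the target (clamped at the bounds), resets the
fired automaton's clock, and *rescales* the remaining wait of every other
pending firing whose rate inputs changed — preserving each one's elapsed
progress fraction, so that a rate that halves midway through a step
doubles the remaining wait.

Firing-time draws come in four modes:

* ``center``  — deterministic midpoint ``Δt`` (the piecewise-linear
  ODE-approximation semantics);
* ``uniform`` — a seeded uniform sample from ``[lo, hi]`` (the
  nondeterministic timed-automata semantics, resolved randomly);
* ``lo`` / ``hi`` — the extreme schedulers (earliest/latest firing).

Simulations are reproducible: identical (network, duration, mode, seed,
sample_step) yield identical trajectories.
"""

from __future__ import annotations

import hashlib
import heapq
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .netmodel import (
    ACTIVATION,
    AND,
    Interaction,
    Network,
    S1_REACTANT,
    S2_REACTANT_SUBSTRATE,
)

__all__ = [
    "MODES",
    "SimulationState",
    "ScheduleEntry",
    "FiringSchedule",
    "EventRecord",
    "TimeSeries",
    "simulate",
    "apply_firing",
    "reschedule",
    "continue_from",
]

MODES = ("center", "uniform", "lo", "hi")

#: Default number of sample intervals on the output grid (a 24 h run is
#: sampled every 6 min).
DEFAULT_SAMPLE_INTERVALS = 240


@dataclass(frozen=True)
class SimulationState:
    """Instantaneous snapshot: clock time plus every node's level."""

    time: float
    levels: dict[str, int]


@dataclass
class ScheduleEntry:
    """Pending firing of one interaction.

    ``time`` is the absolute scheduled firing instant (``inf`` = never);
    ``start`` the instant the automaton's clock was last reset; ``dt`` the
    expected step time under the rates in force when the entry was last
    (re)scaled; ``lo``/``hi`` the admissible window relative to ``start``
    (rescaled together with the remaining wait when rates change).
    """

    time: float
    start: float
    dt: float
    lo: float
    hi: float
    rescaled: bool = False

    @property
    def is_never(self) -> bool:
        return math.isinf(self.time)


@dataclass
class FiringSchedule:
    """Map interaction id -> pending :class:`ScheduleEntry`."""

    entries: dict[str, ScheduleEntry] = field(default_factory=dict)

    def copy(self) -> "FiringSchedule":
        return FiringSchedule({k: ScheduleEntry(**vars(v)) for k, v in self.entries.items()})


@dataclass(frozen=True)
class EventRecord:
    """One firing, as logged when ``record_events=True``."""

    time: float
    interaction_id: str
    latency: float  # time since the automaton's last clock reset
    lo: float
    hi: float
    rescaled: bool  # True if the wait was rescaled since the reset
    target: str
    new_level: int
    level_changed: bool


class TimeSeries:
    """Sampled activity trajectories on a uniform grid, 0-100 scale."""

    def __init__(self, frame: pd.DataFrame, metadata: dict | None = None, events: list[EventRecord] | None = None):
        self.frame = frame
        self.metadata = dict(metadata or {})
        self.events = events

    # -- access ------------------------------------------------------------

    @property
    def times(self) -> np.ndarray:
        return self.frame.index.to_numpy(dtype=float)

    @property
    def node_names(self) -> list[str]:
        return list(self.frame.columns)

    def activity(self, node: str) -> np.ndarray:
        return self.frame[node].to_numpy(dtype=float)

    def value_at(self, node: str, times: float | Sequence[float]) -> np.ndarray:
        """Linearly interpolated activity of *node* at arbitrary times."""
        return np.interp(np.asarray(times, dtype=float), self.times, self.activity(node))

    def levels_at(self, time: float, network: Network) -> dict[str, int]:
        """Integer levels at the nearest grid point <= *time*."""
        t = self.times
        if time < t[0] - 1e-9 or time > t[-1] + 1e-9:
            raise ValueError(f"time {time} outside series span [{t[0]}, {t[-1]}]")
        idx = int(np.searchsorted(t, time + 1e-9) - 1)
        idx = max(idx, 0)
        row = self.frame.iloc[idx]
        return {n.name: int(round(row[n.name] / 100.0 * n.levels)) for n in network.nodes}

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, TimeSeries)
            and self.frame.shape == other.frame.shape
            and bool(self.frame.equals(other.frame))
        )

    # -- CSV dialect: comma-separated, '.' decimal, header row -------------

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index_label="time", float_format="%.6g")

    @classmethod
    def from_csv(cls, path) -> "TimeSeries":
        frame = pd.read_csv(path, index_col="time")
        return cls(frame)


# ---------------------------------------------------------------------------
# runtime
# ---------------------------------------------------------------------------


def network_hash(network: Network) -> str:
    return hashlib.md5(repr((network.nodes, network.interactions, network.time_unit)).encode()).hexdigest()[:12]


class _Runtime:
    """Mutable simulation state: levels, schedule arrays, event heap."""

    def __init__(
        self,
        network: Network,
        mode: str,
        rng: np.random.Generator | None,
        levels: Mapping[str, int] | None = None,
        now: float = 0.0,
    ):
        if mode not in MODES:
            raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
        self.network = network
        self.mode = mode
        self.rng = rng
        self.now = now

        self.names = [n.name for n in network.nodes]
        self.idx = {name: i for i, name in enumerate(self.names)}
        self.L = [n.levels for n in network.nodes]
        self.inv_L = [1.0 / n.levels for n in network.nodes]
        self.enabled = [n.enabled for n in network.nodes]
        if levels is None:
            self.levels = [n.initial_level for n in network.nodes]
        else:
            self.levels = [int(levels[n.name]) for n in network.nodes]

        inters = network.interactions
        self.iids = [it.id for it in inters]
        self.src = [tuple(self.idx[s] for s in it.sources) for it in inters]
        self.tgt = [self.idx[it.target] for it in inters]
        self.delta = [1 if it.sign == ACTIVATION else -1 for it in inters]
        self.scen = [it.scenario for it in inters]
        self.k = [it.k for it in inters]
        self.u = [it.uncertainty for it in inters]

        # node index -> interactions whose *rate* depends on that node
        self.deps: list[list[int]] = [[] for _ in self.names]
        for j, it in enumerate(inters):
            dep = set(self.src[j])
            if it.scenario == S2_REACTANT_SUBSTRATE:
                dep.add(self.tgt[j])
            for d in dep:
                self.deps[d].append(j)

        m = len(inters)
        self.time_s = [math.inf] * m
        self.start_s = [now] * m
        self.dt_s = [math.inf] * m
        self.lo_s = [math.inf] * m
        self.hi_s = [math.inf] * m
        self.rescaled_s = [False] * m
        self.version = [0] * m
        self.heap: list[tuple[float, str, int, int]] = []

    # -- rates -------------------------------------------------------------

    def rate(self, j: int) -> float:
        tgt = self.tgt[j]
        if not self.enabled[tgt]:
            return 0.0
        src = self.src[j]
        i0 = src[0]
        a0 = self.levels[i0] * self.inv_L[i0] if self.enabled[i0] else 0.0
        if a0 == 0.0:
            return 0.0
        scen = self.scen[j]
        if scen == S1_REACTANT:
            return self.k[j] * a0
        if scen == AND:
            i1 = src[1]
            a1 = self.levels[i1] * self.inv_L[i1] if self.enabled[i1] else 0.0
            return self.k[j] * a0 * a1
        y = self.levels[tgt] * self.inv_L[tgt]
        avail = (1.0 - y) if self.delta[j] > 0 else y
        return self.k[j] * a0 * avail

    # -- scheduling --------------------------------------------------------

    def _draw(self, dt: float, u: float) -> tuple[float, float, float]:
        lo = dt * (1.0 - u)
        hi = dt * (1.0 + u)
        if self.mode == "center":
            w = dt
        elif self.mode == "lo":
            w = lo
        elif self.mode == "hi":
            w = hi
        else:
            w = lo + (hi - lo) * self.rng.random() if hi > lo else dt
        return w, lo, hi

    def fresh(self, j: int) -> None:
        """Schedule *j* anew from the current instant (clock reset)."""
        self.version[j] += 1
        r = self.rate(j)
        if r <= 0.0:
            self.time_s[j] = math.inf
            self.dt_s[j] = math.inf
            return
        dt = self.inv_L[self.tgt[j]] / r
        w, lo, hi = self._draw(dt, self.u[j])
        self.time_s[j] = self.now + w
        self.start_s[j] = self.now
        self.dt_s[j] = dt
        self.lo_s[j] = lo
        self.hi_s[j] = hi
        self.rescaled_s[j] = False
        heapq.heappush(self.heap, (self.time_s[j], self.iids[j], j, self.version[j]))

    def rescale(self, j: int) -> None:
        """Adapt *j*'s pending wait to its new rate, preserving progress."""
        r = self.rate(j)
        was_never = math.isinf(self.time_s[j])
        if r <= 0.0:
            if not was_never:
                self.version[j] += 1
                self.time_s[j] = math.inf
                self.dt_s[j] = math.inf
            return
        if was_never:
            self.fresh(j)
            return
        dt_new = self.inv_L[self.tgt[j]] / r
        factor = dt_new / self.dt_s[j]
        if factor == 1.0:
            return
        rem = max(self.time_s[j] - self.now, 0.0)
        self.version[j] += 1
        self.time_s[j] = self.now + rem * factor
        self.dt_s[j] = dt_new
        self.lo_s[j] *= factor
        self.hi_s[j] *= factor
        self.rescaled_s[j] = True
        heapq.heappush(self.heap, (self.time_s[j], self.iids[j], j, self.version[j]))

    def schedule_all(self) -> None:
        for j in range(len(self.iids)):
            self.fresh(j)

    def load_schedule(self, schedule: FiringSchedule) -> None:
        for j, iid in enumerate(self.iids):
            e = schedule.entries[iid]
            self.version[j] += 1
            self.time_s[j] = e.time
            self.start_s[j] = e.start
            self.dt_s[j] = e.dt
            self.lo_s[j] = e.lo
            self.hi_s[j] = e.hi
            self.rescaled_s[j] = e.rescaled
            if not math.isinf(e.time):
                heapq.heappush(self.heap, (e.time, iid, j, self.version[j]))

    def snapshot(self) -> FiringSchedule:
        return FiringSchedule(
            {
                iid: ScheduleEntry(
                    time=self.time_s[j],
                    start=self.start_s[j],
                    dt=self.dt_s[j],
                    lo=self.lo_s[j],
                    hi=self.hi_s[j],
                    rescaled=self.rescaled_s[j],
                )
                for j, iid in enumerate(self.iids)
            }
        )

    # -- event loop --------------------------------------------------------

    def pop_event(self) -> int | None:
        """Earliest valid pending firing, or None when nothing is pending."""
        while self.heap:
            t, _, j, ver = self.heap[0]
            if ver != self.version[j] or math.isinf(self.time_s[j]):
                heapq.heappop(self.heap)
                continue
            return j
        return None

    def fire(self, j: int, record: list[EventRecord] | None) -> None:
        """Advance to *j*'s firing time and apply its level step."""
        t = self.time_s[j]
        heapq.heappop(self.heap)
        self.now = t
        tgt = self.tgt[j]
        old = self.levels[tgt]
        new = min(max(old + self.delta[j], 0), self.L[tgt])
        changed = new != old
        self.levels[tgt] = new
        if record is not None:
            record.append(
                EventRecord(
                    time=t,
                    interaction_id=self.iids[j],
                    latency=t - self.start_s[j],
                    lo=self.lo_s[j],
                    hi=self.hi_s[j],
                    rescaled=self.rescaled_s[j],
                    target=self.names[tgt],
                    new_level=new,
                    level_changed=changed,
                )
            )
        self.fresh(j)  # clock reset on the fired automaton
        if changed:
            for dep in self.deps[tgt]:
                if dep != j:
                    self.rescale(dep)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def simulate(
    network: Network,
    duration: float,
    mode: str = "uniform",
    seed: int = 0,
    sample_step: float | None = None,
    record_events: bool = False,
) -> TimeSeries:
    """Run the network for *duration* time units and sample its activities.

    Returns a :class:`TimeSeries` on the uniform grid with spacing
    ``sample_step`` (default ``duration / 240``), activities on the 0-100
    scale.  Deterministic for fixed (network, duration, mode, seed,
    sample_step).
    """
    violations = network.validate()
    if violations:
        raise ValueError("invalid network: " + "; ".join(violations))
    if not duration > 0:
        raise ValueError(f"duration must be positive, got {duration}")
    if sample_step is None:
        sample_step = duration / DEFAULT_SAMPLE_INTERVALS
    if not sample_step > 0:
        raise ValueError(f"sample_step must be positive, got {sample_step}")

    rng = np.random.default_rng(seed) if mode == "uniform" else None
    rt = _Runtime(network, mode, rng)
    rt.schedule_all()

    n_samples = int(math.floor(duration / sample_step + 1e-9)) + 1
    times = np.arange(n_samples) * sample_step
    n_nodes = len(rt.names)
    data = np.empty((n_samples, n_nodes), dtype=float)
    scale = np.array([100.0 * v for v in rt.inv_L])

    events: list[EventRecord] | None = [] if record_events else None
    cursor = 0  # next sample row to fill
    while True:
        j = rt.pop_event()
        t_next = rt.time_s[j] if j is not None else math.inf
        if t_next > duration:
            break
        # flush samples strictly before the event; events at exactly a grid
        # time are applied first, so samples reflect state at their instant
        while cursor < n_samples and times[cursor] < t_next - 1e-12:
            data[cursor] = np.array(rt.levels) * scale
            cursor += 1
        rt.fire(j, events)
    while cursor < n_samples:
        data[cursor] = np.array(rt.levels) * scale
        cursor += 1

    frame = pd.DataFrame(data, index=pd.Index(times, name="time"), columns=rt.names)
    meta = {
        "seed": seed,
        "mode": mode,
        "network_hash": network_hash(network),
        "sample_step": sample_step,
        "duration": duration,
        "time_unit": network.time_unit,
    }
    return TimeSeries(frame, meta, events)


def apply_firing(state: SimulationState, interaction: Interaction, network: Network) -> SimulationState:
    """One level step of *interaction* applied to *state* (time unchanged).

    Activation adds one level, inhibition removes one, clamped to the
    target's ``[0, L]``.
    """
    node = network.node(interaction.target)
    levels = dict(state.levels)
    delta = 1 if interaction.sign == ACTIVATION else -1
    levels[node.name] = min(max(levels[node.name] + delta, 0), node.levels)
    return SimulationState(time=state.time, levels=levels)


def reschedule(
    schedule: FiringSchedule,
    network: Network,
    state: SimulationState,
    changed_nodes: Iterable[str],
    mode: str = "center",
    rng: np.random.Generator | None = None,
) -> FiringSchedule:
    """Adapt pending firings to a change of the listed nodes' levels.

    Only interactions whose rate inputs intersect *changed_nodes* are
    touched; each has its remaining wait rescaled by the ratio of new to
    old expected step time (preserving elapsed progress).  A rate falling
    to zero parks the entry at NEVER; a rate rising from zero gets a fresh
    draw starting at ``state.time``.
    """
    changed = set(changed_nodes)
    unknown = changed - set(network.node_names())
    if unknown:
        raise KeyError(f"changed nodes not in network: {sorted(unknown)}")
    rt = _Runtime(network, mode, rng, levels=state.levels, now=state.time)
    rt.load_schedule(schedule)
    touched: set[int] = set()
    for name in changed:
        touched.update(rt.deps[rt.idx[name]])
    for j in sorted(touched):
        rt.rescale(j)
    return rt.snapshot()


def continue_from(series: TimeSeries, time_point: float, network: Network) -> Network:
    """State-copy continuation: make a trajectory point the new start.

    Each enabled node's ``initial_level`` is set to its sampled level at
    the nearest grid point at or before *time_point*; disabled nodes keep
    their stored initial level (they were frozen during the run).
    """
    levels = series.levels_at(time_point, network)  # raises outside the span
    out = network
    for node in network.nodes:
        if node.enabled:
            out = out.set_initial_level(node.name, levels[node.name])
    return out
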