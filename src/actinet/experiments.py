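"""In-silico experiment protocols and data-comparison utilities.

These are the operations a modeller performs on top of raw simulation:
knocking nodes out, replaying a trajectory point as a new initial state to
build multi-stage protocols (the circadian phase-shift experiment),
sweeping rate constants against reference time courses, normalising raw
measurement tables onto the 0-100 activity scale, and quantifying
oscillation (period, amplitude, per-cycle phase offsets).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .engine import TimeSeries, continue_from, simulate
from .netmodel import Network

__all__ = [
    "ReferenceData",
    "SweepResult",
    "knockout",
    "phase_shift_resync",
    "parameter_sweep",
    "fit_score",
    "normalize_to_max",
    "complement_percent",
    "detect_oscillation",
    "cycle_peak_times",
    "phase_difference",
    "interaction_graph",
    "downstream_interactions",
]

#: Peak prominence (0-100 activity units) below which a local maximum is
#: treated as quantisation ripple, not a real oscillation peak.
DEFAULT_PROMINENCE = 10.0

#: Fraction of a series discarded as initial transient before measuring
#: oscillation.
DEFAULT_TRANSIENT_FRACTION = 0.2


@dataclass
class ReferenceData:
    """Experimental (or synthetic) reference time courses, 0-100 scale.

    ``table`` has a strictly increasing time index and one column per
    node; ``provenance`` optionally labels each column's origin.
    """

    table: pd.DataFrame
    provenance: dict[str, str] | None = None

    def __post_init__(self) -> None:
        t = self.table.index.to_numpy(dtype=float)
        if len(t) and not np.all(np.diff(t) > 0):
            raise ValueError("reference time points must be strictly increasing")
        vals = self.table.to_numpy(dtype=float)
        if vals.size and (np.nanmin(vals) < -1e-9 or np.nanmax(vals) > 100 + 1e-9):
            raise ValueError("reference values must lie in [0, 100]")

    @property
    def times(self) -> np.ndarray:
        return self.table.index.to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="time", float_format="%.6g")

    @classmethod
    def from_csv(cls, path) -> "ReferenceData":
        return cls(pd.read_csv(path, index_col="time"))


@dataclass
class SweepResult:
    """Grid-search outcome: assignments ranked by ascending fit score."""

    ranking: list[tuple[dict[str, float], float]]
    grid: dict[str, Sequence[float]]

    @property
    def best(self) -> tuple[dict[str, float], float]:
        return self.ranking[0]

    def to_frame(self) -> pd.DataFrame:
        rows = [{**assign, "score": score} for assign, score in self.ranking]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# perturbations
# ---------------------------------------------------------------------------


def knockout(network: Network, node_names: Iterable[str]) -> Network:
    """Disable the listed nodes (they source nothing and receive nothing)."""
    out = network
    for name in node_names:
        out = out.set_enabled(name, False)
    return out


def interaction_graph(network: Network) -> nx.DiGraph:
    """Directed node-to-node influence graph (one edge per source-target pair)."""
    g = nx.DiGraph()
    g.add_nodes_from(network.node_names())
    for it in network.interactions:
        for s in it.sources:
            g.add_edge(s, it.target)
    return g


def downstream_interactions(network: Network, node: str) -> list[str]:
    """Ids of interactions sourced by *node* or by anything reachable from it."""
    g = interaction_graph(network)
    reach = {node} | nx.descendants(g, node)
    return [it.id for it in network.interactions if any(s in reach for s in it.sources)]


def phase_shift_resync(
    network: Network,
    cry_node: str = "CRY",
    advance_hours: float = 12.0,
    post_days: float = 10.0,
    mode: str = "uniform",
    seed: int = 0,
    sample_step: float | None = None,
) -> TimeSeries:
    """Shift the light/dark phase and watch the clock resynchronise.

    Protocol (state-copy continuation throughout): simulate one day; copy
    the state at a minimum of *cry_node* ("night"); disable everything
    except the subnetwork that drives *cry_node*; let that subnetwork run
    alone for *advance_hours* (the external light/dark cycle
    desynchronises from the frozen internal clock); copy the end state;
    re-enable the rest; simulate *post_days* days.  Returns the final
    multi-day series.  Times are in hours (the circadian model's unit).
    """
    network.node(cry_node)  # raise early on unknown node
    day = simulate(network, 24.0, mode=mode, seed=seed, sample_step=sample_step)
    cry = day.activity(cry_node)
    if np.ptp(cry) < 1e-9:
        raise ValueError(f"{cry_node!r} trajectory is flat; no low point to copy from")
    t_low = float(day.times[int(np.argmin(cry))])
    staged = continue_from(day, t_low, network)

    driver = {cry_node} | nx.ancestors(interaction_graph(network), cry_node)
    frozen = staged
    for name in staged.node_names():
        if name not in driver:
            frozen = frozen.set_enabled(name, False)

    if advance_hours > 0:
        alone = simulate(frozen, advance_hours, mode=mode, seed=seed + 1, sample_step=sample_step)
        frozen = continue_from(alone, advance_hours, frozen)

    resumed = frozen
    for node in network.nodes:  # restore original enabled flags
        resumed = resumed.set_enabled(node.name, node.enabled)
    return simulate(resumed, post_days * 24.0, mode=mode, seed=seed + 2, sample_step=sample_step)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def fit_score(series: TimeSeries, reference: ReferenceData) -> float:
    """Mean squared deviation between a simulation and reference data.

    The simulated series is linearly interpolated at each reference time
    point; squared differences are summed over all shared node columns and
    reference times, then divided by (number of points x columns).
    """
    shared = [c for c in reference.table.columns if c in series.node_names]
    if not shared:
        raise ValueError("no shared node columns between series and reference")
    times = reference.times
    total = 0.0
    for col in shared:
        sim = series.value_at(col, times)
        ref = reference.table[col].to_numpy(dtype=float)
        total += float(np.sum((sim - ref) ** 2))
    return total / (len(times) * len(shared))


def parameter_sweep(
    network: Network,
    param_grid: Mapping[str, Sequence[float]],
    reference: ReferenceData,
    mode: str = "center",
    seed: int = 0,
    sample_step: float | None = None,
) -> SweepResult:
    """Exhaustive grid search over interaction rate constants.

    ``param_grid`` maps interaction ids to candidate ``k`` values; every
    combination is simulated over the reference's time span (center mode
    by default) and scored with :func:`fit_score`; results are ranked by
    ascending score.
    """
    if not param_grid:
        raise ValueError("empty parameter grid")
    ids = list(param_grid)
    for iid in ids:
        network.interaction(iid)  # raise on unknown id
    duration = float(reference.times[-1])
    ranking: list[tuple[dict[str, float], float]] = []
    for combo in itertools.product(*(param_grid[i] for i in ids)):
        assignment = dict(zip(ids, combo))
        net = network
        for iid, k in assignment.items():
            net = net.set_k(iid, k)
        series = simulate(net, duration, mode=mode, seed=seed, sample_step=sample_step)
        ranking.append((assignment, fit_score(series, reference)))
    ranking.sort(key=lambda pair: pair[1])
    return SweepResult(ranking=ranking, grid={i: list(v) for i, v in param_grid.items()})


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------


def normalize_to_max(raw_table: pd.DataFrame, provenance: dict[str, str] | None = None) -> ReferenceData:
    """Scale each column so its maximum over the experiment becomes 100.

    This is the per-protein normalisation used for semi-quantitative data
    (e.g. western blots): only relative levels are meaningful, so each
    protein is expressed as a percentage of its own maximum.
    """
    table = raw_table.astype(float).copy()
    for col in table.columns:
        m = table[col].max()
        if not m > 0:
            raise ValueError(f"column {col!r} has no positive maximum")
        table[col] = table[col] * (100.0 / m)
    return ReferenceData(table, provenance)


def complement_percent(column: Sequence[float] | np.ndarray | pd.Series) -> np.ndarray:
    """Elementwise ``100 - x``: convert a precursor series to its product.

    Used when the data reports the *inactive* precursor (e.g. pro-caspase)
    and the model tracks the active form.
    """
    arr = np.asarray(column, dtype=float)
    if arr.size and (arr.min() < -1e-9 or arr.max() > 100 + 1e-9):
        raise ValueError("values must lie in [0, 100]")
    return 100.0 - arr


# ---------------------------------------------------------------------------
# oscillation metrics
# ---------------------------------------------------------------------------


def _peak_indices(values: np.ndarray, prominence: float) -> np.ndarray:
    """Cycle peaks: prominent local maxima, with near-equal neighbours
    merged when the trough between them is shallower than *prominence*
    (level quantisation wobbles a plateau top by one level, which would
    otherwise split one cycle peak into several)."""
    idx, _ = find_peaks(values, prominence=prominence)
    idx = list(idx)
    merged = True
    while merged and len(idx) > 1:
        merged = False
        for i in range(len(idx) - 1):
            a, b = idx[i], idx[i + 1]
            trough = float(np.min(values[a : b + 1]))
            if min(values[a], values[b]) - trough < prominence:
                del idx[i if values[a] < values[b] else i + 1]
                merged = True
                break
    return np.asarray(idx, dtype=int)


def _peaks(times: np.ndarray, values: np.ndarray, prominence: float) -> np.ndarray:
    return times[_peak_indices(values, prominence)]


def detect_oscillation(
    series: TimeSeries,
    node: str,
    transient_fraction: float = DEFAULT_TRANSIENT_FRACTION,
    prominence: float = DEFAULT_PROMINENCE,
) -> tuple[float, float] | None:
    """Mean period and peak-to-trough amplitude of a node's rhythm.

    The leading ``transient_fraction`` of the series is discarded; local
    maxima with prominence above *prominence* (activity units) are taken
    as cycle peaks.  Returns ``(period, amplitude)``, or ``None`` when
    fewer than two peaks survive (no sustained oscillation).
    """
    t = series.times
    v = series.activity(node)
    keep = t >= t[0] + transient_fraction * (t[-1] - t[0])
    t, v = t[keep], v[keep]
    peak_idx = _peak_indices(v, prominence)
    if len(peak_idx) < 2:
        return None
    period = float(np.mean(np.diff(t[peak_idx])))
    troughs = []
    for a, b in zip(peak_idx[:-1], peak_idx[1:]):
        troughs.append(v[a] - np.min(v[a : b + 1]))
    amplitude = float(np.mean(troughs))
    return period, amplitude


def cycle_peak_times(
    series: TimeSeries,
    node: str,
    transient_fraction: float = 0.0,
    prominence: float = DEFAULT_PROMINENCE,
) -> np.ndarray:
    """Times of a node's cycle peaks (after transient discard and merging)."""
    t = series.times
    start = t[0] + transient_fraction * (t[-1] - t[0])
    keep = t >= start
    return _peaks(t[keep], series.activity(node)[keep], prominence)


def phase_difference(
    series: TimeSeries,
    node_a: str,
    node_b: str,
    transient_fraction: float = 0.0,
    prominence: float = DEFAULT_PROMINENCE,
) -> np.ndarray:
    """Per-cycle peak offset of *node_b* relative to *node_a* (time units).

    For each peak of *node_a*, the offset to the nearest peak of *node_b*
    is wrapped into ``[-period/2, period/2]`` where the period is
    *node_a*'s.  Raises if either node does not oscillate.
    """
    osc_a = detect_oscillation(series, node_a, transient_fraction, prominence)
    osc_b = detect_oscillation(series, node_b, transient_fraction, prominence)
    if osc_a is None or osc_b is None:
        which = node_a if osc_a is None else node_b
        raise ValueError(f"node {which!r} does not oscillate")
    period = osc_a[0]
    peaks_a = cycle_peak_times(series, node_a, transient_fraction, prominence)
    peaks_b = cycle_peak_times(series, node_b, transient_fraction, prominence)
    offsets = []
    for pa in peaks_a:
        diff = peaks_b - pa
        near = diff[np.argmin(np.abs(diff))]
        wrapped = (near + period / 2) % period - period / 2
        offsets.append(wrapped)
    return np.asarray(offsets)
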