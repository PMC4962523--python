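"""Domain types for activity-level signalling networks.

A network is a static model: named species (*nodes*) carrying a discrete
activity level, and rate-parameterised *interactions* between them.  Each
node represents the whole pool of one molecular species; its single
dynamical variable is the fraction of that pool in the active form,
discretised to an integer level in ``[0, L]`` where ``L`` is the node's
user-chosen granularity.  Interactions raise (activation) or lower
(inhibition) the target's level one step at a time, at a speed set by a
single rate constant ``k`` — larger ``k``, faster interaction.

Networks are immutable values: every mutating operation returns a new
``Network`` and leaves its argument untouched.  Contract violations raise
immediately in the builder operations; :func:`validate` additionally audits
arbitrarily-constructed networks and *returns* the violations, which is what
the file readers use for diagnostics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ACTIVATION",
    "INHIBITION",
    "S1_REACTANT",
    "S2_REACTANT_SUBSTRATE",
    "AND",
    "SCENARIOS",
    "DEFAULT_LEVELS",
    "DEFAULT_UNCERTAINTY",
    "Node",
    "Interaction",
    "Network",
    "QualitativeRateScale",
    "DEFAULT_SCALE",
    "qualitative_to_k",
    "validate",
]

ACTIVATION = "activation"
INHIBITION = "inhibition"
SIGNS = (ACTIVATION, INHIBITION)

# Rate-law shapes ("scenarios"): enzyme-only, enzyme x substrate
# availability, and the two-enzyme product gate.  See `kinetics`.
S1_REACTANT = "S1_REACTANT"
S2_REACTANT_SUBSTRATE = "S2_REACTANT_SUBSTRATE"
AND = "AND"
SCENARIOS = (S1_REACTANT, S2_REACTANT_SUBSTRATE, AND)

#: Default granularity: activity reported on a 0-100 scale, one level = 1 %.
DEFAULT_LEVELS = 100

#: Default half-width of the nondeterministic firing window (fraction of
#: the expected step time).
DEFAULT_UNCERTAINTY = 0.05


@dataclass(frozen=True)
class Node:
    """A molecular species with ``levels + 1`` discrete activity states.

    ``enabled=False`` means the node is knocked out: it contributes zero
    activity to every interaction it sources, and interactions targeting it
    never fire, but its stored level is retained.
    """

    name: str
    levels: int = DEFAULT_LEVELS
    initial_level: int = 0
    enabled: bool = True

    @property
    def initial_fraction(self) -> float:
        return self.initial_level / self.levels


@dataclass(frozen=True)
class Interaction:
    """A directed influence on one target node.

    ``sources`` holds one node name for the S1/S2 scenarios, or exactly two
    for the AND gate (both must be active for the interaction to proceed).
    ``k`` is the rate constant in units of full-activity-range fractions per
    model time unit; ``uncertainty`` is the half-width ``u`` of the firing
    window ``[Δt(1-u), Δt(1+u)]`` around the expected step time.
    ``rate_label`` optionally records the qualitative label ("slow", ...)
    that ``k`` was resolved from, so files can round-trip it.
    """

    id: str
    sources: tuple[str, ...]
    target: str
    sign: str
    scenario: str
    k: float
    uncertainty: float = DEFAULT_UNCERTAINTY
    rate_label: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sources", tuple(self.sources))

    def contract_violations(self) -> list[str]:
        """Type-level invariant violations of this interaction alone."""
        out: list[str] = []
        if self.sign not in SIGNS:
            out.append(f"interaction {self.id!r}: unknown sign {self.sign!r}")
        if self.scenario not in SCENARIOS:
            out.append(f"interaction {self.id!r}: unknown scenario {self.scenario!r}")
        n = len(self.sources)
        if self.scenario == AND and n != 2:
            out.append(f"interaction {self.id!r}: AND scenario requires exactly 2 sources, got {n}")
        if self.scenario in (S1_REACTANT, S2_REACTANT_SUBSTRATE) and n != 1:
            out.append(f"interaction {self.id!r}: scenario {self.scenario} requires exactly 1 source, got {n}")
        if not isinstance(self.k, (int, float)) or not math.isfinite(self.k) or not self.k > 0:
            out.append(f"interaction {self.id!r}: k must be a positive finite real, got {self.k!r}")
        if not 0 <= self.uncertainty < 1:
            out.append(f"interaction {self.id!r}: uncertainty must lie in [0, 1), got {self.uncertainty}")
        return out


class QualitativeRateScale:
    """Ordered mapping of the five verbal speed labels to rate constants.

    The mapping must be strictly increasing along
    very slow < slow < medium < fast < very fast.  The default is a
    geometric ladder centred on "medium" = 1.0, multiplied by a
    user-settable base rate.
    """

    LABELS = ("very slow", "slow", "medium", "fast", "very fast")
    _DEFAULT_MULTIPLIERS = (0.25, 0.5, 1.0, 2.0, 4.0)

    def __init__(self, mapping: Mapping[str, float] | None = None, *, base_rate: float = 0.01):
        if mapping is None:
            mapping = {l: m * base_rate for l, m in zip(self.LABELS, self._DEFAULT_MULTIPLIERS)}
        missing = [l for l in self.LABELS if l not in mapping]
        if missing:
            raise ValueError(f"rate scale is missing labels: {missing}")
        values = [float(mapping[l]) for l in self.LABELS]
        if any(v <= 0 for v in values):
            raise ValueError("rate scale values must be positive")
        if any(b <= a for a, b in zip(values, values[1:])):
            raise ValueError("rate scale must be strictly increasing from 'very slow' to 'very fast'")
        self._mapping = dict(zip(self.LABELS, values))

    def __getitem__(self, label: str) -> float:
        try:
            return self._mapping[label]
        except KeyError:
            raise KeyError(f"unknown rate label {label!r}; expected one of {list(self.LABELS)}") from None

    def items(self):
        return self._mapping.items()

    def __eq__(self, other) -> bool:
        return isinstance(other, QualitativeRateScale) and self._mapping == other._mapping

    def __repr__(self) -> str:
        return f"QualitativeRateScale({self._mapping})"


#: Module-wide default scale (base rate 0.01 per time unit).
DEFAULT_SCALE = QualitativeRateScale()


def qualitative_to_k(label: str, scale: QualitativeRateScale | None = None) -> float:
    """Resolve a verbal speed label to its rate constant via *scale*."""
    return (scale or DEFAULT_SCALE)[label]


@dataclass(frozen=True)
class Network:
    """An immutable signalling-network model: nodes, interactions, time unit.

    ``time_unit`` is a declared label only (e.g. "min", "h"); no unit
    conversion is ever performed.
    """

    nodes: tuple[Node, ...] = ()
    interactions: tuple[Interaction, ...] = ()
    time_unit: str = "min"

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(self, "interactions", tuple(self.interactions))

    # -- lookups -----------------------------------------------------------

    def node(self, name: str) -> Node:
        for n in self.nodes:
            if n.name == name:
                return n
        raise KeyError(f"unknown node {name!r}")

    def has_node(self, name: str) -> bool:
        return any(n.name == name for n in self.nodes)

    def node_names(self) -> list[str]:
        return [n.name for n in self.nodes]

    def interaction(self, iid: str) -> Interaction:
        for i in self.interactions:
            if i.id == iid:
                return i
        raise KeyError(f"unknown interaction {iid!r}")

    def interactions_targeting(self, name: str) -> list[Interaction]:
        return [i for i in self.interactions if i.target == name]

    # -- construction ------------------------------------------------------

    def add_node(
        self,
        name: str,
        levels: int = DEFAULT_LEVELS,
        initial_level: int = 0,
        enabled: bool = True,
    ) -> "Network":
        """Return a network extended with one node; prior content unchanged."""
        if self.has_node(name):
            raise ValueError(f"duplicate node name {name!r}")
        if not name:
            raise ValueError("node name must be non-empty")
        if levels < 1:
            raise ValueError(f"node {name!r}: levels must be >= 1, got {levels}")
        if not 0 <= initial_level <= levels:
            raise ValueError(f"node {name!r}: initial_level {initial_level} outside [0, {levels}]")
        node = Node(name=name, levels=levels, initial_level=initial_level, enabled=enabled)
        return replace(self, nodes=self.nodes + (node,))

    def add_interaction(
        self,
        sources: str | Sequence[str],
        target: str,
        sign: str,
        scenario: str = S2_REACTANT_SUBSTRATE,
        k: float = 1.0,
        uncertainty: float = DEFAULT_UNCERTAINTY,
        id: str | None = None,
        rate_label: str | None = None,
    ) -> "Network":
        """Return a network with one appended interaction (fresh id).

        ``sources`` may be a single name or a sequence of names; arity must
        match the scenario.  Endpoints must already exist in the network.
        """
        srcs = (sources,) if isinstance(sources, str) else tuple(sources)
        for name in (*srcs, target):
            if not self.has_node(name):
                raise KeyError(f"interaction endpoint {name!r} is not a node of this network")
        if id is None:
            arrow = "-|" if sign == INHIBITION else "->"
            base = f"{'+'.join(srcs)}{arrow}{target}"
            id = base
            n = 1
            existing = {i.id for i in self.interactions}
            while id in existing:
                n += 1
                id = f"{base}#{n}"
        elif any(i.id == id for i in self.interactions):
            raise ValueError(f"duplicate interaction id {id!r}")
        inter = Interaction(
            id=id,
            sources=srcs,
            target=target,
            sign=sign,
            scenario=scenario,
            k=k,
            uncertainty=uncertainty,
            rate_label=rate_label,
        )
        bad = inter.contract_violations()
        if bad:
            raise ValueError("; ".join(bad))
        return replace(self, interactions=self.interactions + (inter,))

    # -- point edits -------------------------------------------------------

    def _replace_node(self, name: str, **changes) -> "Network":
        self.node(name)  # raise early on unknown node
        nodes = tuple(replace(n, **changes) if n.name == name else n for n in self.nodes)
        return replace(self, nodes=nodes)

    def set_enabled(self, name: str, flag: bool) -> "Network":
        """Knock a node out (``False``) or back in (``True``)."""
        return self._replace_node(name, enabled=bool(flag))

    def set_initial_level(self, name: str, level: int) -> "Network":
        return self._replace_node(name, initial_level=int(level))

    def set_initial_fraction(self, name: str, fraction: float) -> "Network":
        """Set a node's initial level to the nearest level to ``fraction * L``.

        This is how stimulus doses are applied: a dose of X relative to a
        reference dose R becomes the fraction ``min(1, X / R)``.
        """
        node = self.node(name)
        if not 0 <= fraction <= 1:
            raise ValueError(f"initial fraction must lie in [0, 1], got {fraction}")
        return self.set_initial_level(name, round(fraction * node.levels))

    def set_k(self, iid: str, k: float) -> "Network":
        self.interaction(iid)
        inters = tuple(replace(i, k=float(k), rate_label=None) if i.id == iid else i for i in self.interactions)
        return replace(self, interactions=inters)

    def scale_k(self, iids: Iterable[str], factor: float) -> "Network":
        iids = set(iids)
        unknown = iids - {i.id for i in self.interactions}
        if unknown:
            raise KeyError(f"unknown interaction ids: {sorted(unknown)}")
        inters = tuple(
            replace(i, k=i.k * factor, rate_label=None) if i.id in iids else i for i in self.interactions
        )
        return replace(self, interactions=inters)

    # -- audit -------------------------------------------------------------

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty iff well-formed)."""
        violations: list[str] = []
        seen: set[str] = set()
        for n in self.nodes:
            if n.name in seen:
                violations.append(f"duplicate node name {n.name!r}")
            seen.add(n.name)
            if n.levels < 1:
                violations.append(f"node {n.name!r}: levels {n.levels} < 1")
            elif not 0 <= n.initial_level <= n.levels:
                violations.append(
                    f"node {n.name!r}: initial_level {n.initial_level} outside [0, {n.levels}]"
                )
        seen_ids: set[str] = set()
        for i in self.interactions:
            if i.id in seen_ids:
                violations.append(f"duplicate interaction id {i.id!r}")
            seen_ids.add(i.id)
            for name in (*i.sources, i.target):
                if name not in seen:
                    violations.append(f"interaction {i.id!r}: endpoint {name!r} is not a node")
            violations.extend(i.contract_violations())
        return violations


def validate(network: Network) -> list[str]:
    """Functional alias for :meth:`Network.validate`."""
    return network.validate()
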