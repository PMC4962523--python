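"""File formats: network JSON documents, Cytoscape SIF import, CSV tables.

One JSON document holds one network.  The document is deliberately
minimal and diffable::

    {
      "schema_version": 1,
      "time_unit": "min",
      "nodes": [
        {"name": "MEK", "levels": 100, "initial_level": 100, "enabled": true}
      ],
      "interactions": [
        {"id": "MEK->ERK", "sources": ["MEK"], "target": "ERK",
         "sign": "activation", "scenario": "S1_REACTANT",
         "k": 0.000526, "uncertainty": 0.0526}
      ],
      "layout": { ... }            // optional, ignored by computation
    }

``k`` may instead be one of the five qualitative labels ("very slow" ...
"very fast"), which is resolved through the configured rate scale on read
and written back as the label, so files round-trip what the modeller
typed.  A document parses successfully iff the decoded network passes
:func:`actinet.netmodel.validate`; violations are reported with the
offending field's path.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

from .netmodel import (
    DEFAULT_LEVELS,
    DEFAULT_SCALE,
    DEFAULT_UNCERTAINTY,
    Interaction,
    Network,
    Node,
    QualitativeRateScale,
    S2_REACTANT_SUBSTRATE,
    ACTIVATION,
    INHIBITION,
)

__all__ = ["SchemaError", "read_network", "write_network", "import_sif"]

SCHEMA_VERSION = 1


class SchemaError(ValueError):
    """A network document violates the schema; message names the field."""


def _require(doc: Mapping, key: str, types, where: str):
    if key not in doc:
        raise SchemaError(f"{where}: missing required field {key!r}")
    val = doc[key]
    if not isinstance(val, types):
        raise SchemaError(f"{where}.{key}: expected {types}, got {type(val).__name__}")
    return val


def read_network(path, scale: QualitativeRateScale | None = None) -> Network:
    """Read a network document; qualitative k labels resolve via *scale*."""
    scale = scale or DEFAULT_SCALE
    text = Path(path).read_text()
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise SchemaError(f"{path}: document must be a JSON object")
    version = _require(doc, "schema_version", int, str(path))
    if version != SCHEMA_VERSION:
        raise SchemaError(f"{path}: unknown schema_version {version} (expected {SCHEMA_VERSION})")
    time_unit = doc.get("time_unit", "min")

    nodes = []
    for i, nd in enumerate(_require(doc, "nodes", list, str(path))):
        where = f"nodes[{i}]"
        if not isinstance(nd, dict):
            raise SchemaError(f"{where}: expected an object")
        nodes.append(
            Node(
                name=_require(nd, "name", str, where),
                levels=int(nd.get("levels", DEFAULT_LEVELS)),
                initial_level=int(nd.get("initial_level", 0)),
                enabled=bool(nd.get("enabled", True)),
            )
        )

    inters = []
    for i, it in enumerate(_require(doc, "interactions", list, str(path))):
        where = f"interactions[{i}]"
        if not isinstance(it, dict):
            raise SchemaError(f"{where}: expected an object")
        k_raw = _require(it, "k", (int, float, str), where)
        if isinstance(k_raw, str):
            try:
                k = scale[k_raw]
            except KeyError as exc:
                raise SchemaError(f"{where}.k: {exc.args[0]}") from exc
            label = k_raw
        else:
            k, label = float(k_raw), None
        sources = _require(it, "sources", list, where)
        inters.append(
            Interaction(
                id=str(it.get("id", f"i{i}")),
                sources=tuple(str(s) for s in sources),
                target=_require(it, "target", str, where),
                sign=_require(it, "sign", str, where),
                scenario=str(it.get("scenario", S2_REACTANT_SUBSTRATE)),
                k=k,
                uncertainty=float(it.get("uncertainty", DEFAULT_UNCERTAINTY)),
                rate_label=label,
            )
        )

    net = Network(nodes=tuple(nodes), interactions=tuple(inters), time_unit=str(time_unit))
    violations = net.validate()
    if violations:
        raise SchemaError(f"{path}: invalid network: " + "; ".join(violations))
    return net


def write_network(network: Network, path) -> None:
    """Write a network document (lossless for all computational fields)."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "time_unit": network.time_unit,
        "nodes": [
            {
                "name": n.name,
                "levels": n.levels,
                "initial_level": n.initial_level,
                "enabled": n.enabled,
            }
            for n in network.nodes
        ],
        "interactions": [
            {
                "id": it.id,
                "sources": list(it.sources),
                "target": it.target,
                "sign": it.sign,
                "scenario": it.scenario,
                "k": it.rate_label if it.rate_label is not None else it.k,
                "uncertainty": it.uncertainty,
            }
            for it in network.interactions
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


#: Default mapping from SIF relation tokens to (sign, scenario).
DEFAULT_SIF_RELATIONS = {
    "activates": (ACTIVATION, S2_REACTANT_SUBSTRATE),
    "inhibits": (INHIBITION, S2_REACTANT_SUBSTRATE),
}


def import_sif(
    path,
    relations: Mapping[str, tuple[str, str]] | None = None,
    levels: int = DEFAULT_LEVELS,
    initial_level: int = 0,
    k: float = 1.0,
    uncertainty: float = DEFAULT_UNCERTAINTY,
    time_unit: str = "min",
) -> Network:
    """Import a Cytoscape SIF topology skeleton.

    Each line reads ``SOURCE <relation> TARGET [TARGET2 ...]``; the
    relation token is mapped to a (sign, scenario) pair through
    *relations* (default: "activates"/"inhibits").  Nodes are created
    with the given default granularity and initial level, interactions
    with the default ``k``.  Unknown relation tokens raise.
    """
    relations = dict(DEFAULT_SIF_RELATIONS if relations is None else relations)
    net = Network(time_unit=time_unit)
    pending: list[tuple[str, str, str]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) == 1:  # isolated node
            if not net.has_node(parts[0]):
                net = net.add_node(parts[0], levels=levels, initial_level=initial_level)
            continue
        if len(parts) < 3:
            raise SchemaError(f"{path}:{lineno}: expected 'SOURCE relation TARGET...', got {line!r}")
        src, rel, targets = parts[0], parts[1], parts[2:]
        if rel not in relations:
            raise SchemaError(
                f"{path}:{lineno}: unmappable relation token {rel!r}; known: {sorted(relations)}"
            )
        for name in (src, *targets):
            if not net.has_node(name):
                net = net.add_node(name, levels=levels, initial_level=initial_level)
        for tgt in targets:
            pending.append((src, rel, tgt))
    for src, rel, tgt in pending:
        sign, scenario = relations[rel]
        net = net.add_interaction(src, tgt, sign, scenario, k=k, uncertainty=uncertainty)
    assert net.validate() == []
    return net
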