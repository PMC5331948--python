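"""Serialization: networks as GraphML / edge-list TSV, configs as YAML/JSON.

GraphML is the lossless format (node ``capacity``/``module`` attributes,
edge ``weight``, graph-level topology label all survive a round trip); the
edge-list TSV is a lowest-common-denominator export with columns
``source  target  weight``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import networkx as nx
import pandas as pd
import yaml

from .dynamics import SimConfig
from .topology import DEFAULT_CAPACITY, HTTNetwork


def write_graphml(net: HTTNetwork, path) -> None:
    g = net.graph.copy()
    g.graph["topology_label"] = net.topology_label
    nx.write_graphml(g, path)


def read_graphml(path) -> HTTNetwork:
    g = nx.read_graphml(path, node_type=int)
    label = g.graph.pop("topology_label", "custom")
    for n in g.nodes:
        if "capacity" in g.nodes[n]:
            g.nodes[n]["capacity"] = int(g.nodes[n]["capacity"])
        if "module" in g.nodes[n]:
            g.nodes[n]["module"] = int(g.nodes[n]["module"])
    return HTTNetwork(g, topology_label=label)


def write_edgelist_tsv(net: HTTNetwork, path) -> None:
    rows = [
        (u, v, net.graph.edges[u, v]["weight"])
        for u, v in sorted(tuple(sorted(e)) for e in net.graph.edges)
    ]
    pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(
        path, sep="\t", index=False
    )


def read_edgelist_tsv(
    path, *, capacity: int = DEFAULT_CAPACITY, n_species: int | None = None
) -> HTTNetwork:
    """Read a ``source target weight`` TSV.

    Node ids must be positive integers; isolated trailing species can be
    declared via ``n_species``.  Capacities are not representable in an
    edge list and default to ``capacity``.
    """
    df = pd.read_csv(path, sep="\t")
    g = nx.Graph()
    if n_species is not None:
        g.add_nodes_from(range(1, n_species + 1))
    for row in df.itertuples(index=False):
        g.add_edge(int(row.source), int(row.target), weight=float(row.weight))
    for n in g.nodes:
        g.nodes[n]["capacity"] = capacity
    return HTTNetwork(g, topology_label="custom")


def load_sim_config(path) -> SimConfig:
    """SimConfig from a YAML or JSON file mirroring its field names."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise ValueError(f"config file {path} must contain a mapping")
    return SimConfig(**data)


def save_sim_config(config: SimConfig, path) -> None:
    path = Path(path)
    data = {k: getattr(config, k) for k in SimConfig.__dataclass_fields__}
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
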