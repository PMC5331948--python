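"""Deterministic toy inputs for tests, docs and demos."""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np

from .diversity import BetaMatrix, PresenceMatrix
from .io import write_graphml
from .topology import HTTNetwork

FIXTURE_KINDS = ("tiny-net", "block-beta", "toy-presence")


def tiny_net(capacity: int = 20) -> HTTNetwork:
    """6 species in two modules of 3 (triangles) joined by one bridge."""
    g = nx.Graph()
    g.add_nodes_from(range(1, 7))
    for a, b in [(1, 2), (1, 3), (2, 3), (4, 5), (4, 6), (5, 6), (3, 4)]:
        g.add_edge(a, b, weight=1.0)
    for n in g.nodes:
        g.nodes[n]["capacity"] = capacity
        g.nodes[n]["module"] = 1 if n <= 3 else 2
    return HTTNetwork(g, topology_label="modular")


def block_beta() -> BetaMatrix:
    """4 species in two perfectly separated pairs (within 0.1, between 0.9)."""
    v = np.full((4, 4), 0.9)
    v[0, 1] = v[1, 0] = v[2, 3] = v[3, 2] = 0.1
    np.fill_diagonal(v, 0.0)
    return BetaMatrix(v)


def toy_presence(seed: int = 0) -> PresenceMatrix:
    """6 species x 8 families random incidence (each family in >=1 species)."""
    rng = np.random.default_rng(seed)
    while True:
        vals = rng.random((6, 8)) < 0.5
        if vals.any(axis=0).all() and vals.any(axis=1).all():
            return PresenceMatrix(vals)


def make_fixtures(kind: str, seed: int = 0, outdir=".") -> list[Path]:
    """Write one fixture kind (or 'all') to ``outdir``; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    kinds = FIXTURE_KINDS if kind == "all" else (kind,)
    paths = []
    for k in kinds:
        if k == "tiny-net":
            p = outdir / "tiny_net.graphml"
            write_graphml(tiny_net(), p)
        elif k == "block-beta":
            p = outdir / "block_beta.tsv"
            block_beta().to_tsv(p)
        elif k == "toy-presence":
            p = outdir / "toy_presence.tsv"
            toy_presence(seed).to_tsv(p)
        else:
            raise ValueError(f"unknown fixture kind {k!r}; expected {FIXTURE_KINDS}")
        paths.append(p)
    return paths
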