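"""Generation, perturbation and inspection of HTT networks.

An HTT (horizontal transposon transfer) network is a graph whose nodes are
species genomes acting as transposable-element (TE) reservoirs and whose
edges represent ecological connections along which TE "molecular vehicles"
(viruses, parasites, ...) can carry TE copies between genomes.  Each node
carries a reservoir capacity — the maximal number of TE copies the genome
can hold — and each edge a positive weight representing the density of
vehicles transiting that link.

Five stylised topologies are supported: complete, random (Erdős–Rényi),
scale-free (preferential attachment), modular (stochastic-block) and
bipartite.  Arbitrary user networks are handled as ``custom``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

TOPOLOGY_LABELS = ("complete", "random", "scale_free", "modular", "bipartite", "custom")

DEFAULT_CAPACITY = 100
DEFAULT_WEIGHT = 1.0


class NetworkSpecError(ValueError):
    """Raised when a topology specification is infeasible or inconsistent."""


class GenerationError(RuntimeError):
    """Raised when network generation cannot satisfy its post-conditions."""


@dataclass
class HTTNetwork:
    """A weighted species network with per-species TE reservoir capacities.

    Parameters
    ----------
    graph
        Undirected :class:`networkx.Graph` whose nodes are species ids
        (contiguous integers starting at 1).  Edges carry a positive
        ``weight`` attribute; nodes carry a positive-integer ``capacity``
        and, for modular/bipartite networks, an integer ``module``.
    topology_label
        One of ``complete, random, scale_free, modular, bipartite, custom``.
    """

    graph: nx.Graph
    topology_label: str = "custom"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.topology_label not in TOPOLOGY_LABELS:
            raise NetworkSpecError(
                f"unknown topology label {self.topology_label!r}; "
                f"expected one of {TOPOLOGY_LABELS}"
            )
        self._validate()

    # -- basic accessors -------------------------------------------------
    @property
    def species_ids(self) -> list[int]:
        return sorted(self.graph.nodes)

    @property
    def n_species(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def capacities(self) -> dict[int, int]:
        return {n: self.graph.nodes[n]["capacity"] for n in self.species_ids}

    @property
    def module_assignment(self) -> dict[int, int] | None:
        if all("module" in self.graph.nodes[n] for n in self.graph.nodes):
            return {n: self.graph.nodes[n]["module"] for n in self.species_ids}
        return None

    def edge_set(self) -> set[tuple[int, int]]:
        """Edges as a set of sorted pairs (canonical undirected form)."""
        return {tuple(sorted(e)) for e in self.graph.edges}

    def is_connected(self) -> bool:
        return self.n_species > 0 and nx.is_connected(self.graph)

    def copy(self) -> "HTTNetwork":
        return HTTNetwork(self.graph.copy(), self.topology_label, dict(self.meta))

    # -- validation ------------------------------------------------------
    def _validate(self) -> None:
        g = self.graph
        if any(u == v for u, v in g.edges):
            raise NetworkSpecError("self-loops are not allowed")
        ids = self.species_ids
        if ids and ids != list(range(1, len(ids) + 1)):
            raise NetworkSpecError(
                "species ids must be contiguous integers starting at 1"
            )
        for n in g.nodes:
            g.nodes[n].setdefault("capacity", DEFAULT_CAPACITY)
            cap = g.nodes[n]["capacity"]
            if not (isinstance(cap, (int, np.integer)) and cap >= 1):
                raise NetworkSpecError(f"capacity of species {n} must be an integer >= 1")
        for u, v in g.edges:
            g.edges[u, v].setdefault("weight", DEFAULT_WEIGHT)
            if g.edges[u, v]["weight"] <= 0:
                raise NetworkSpecError(f"edge ({u},{v}) has non-positive weight")
        if self.topology_label == "bipartite":
            mod = self.module_assignment
            if mod is None:
                raise NetworkSpecError("bipartite network requires module assignment")
            for u, v in g.edges:
                if mod[u] == mod[v]:
                    raise NetworkSpecError(
                        f"bipartite network has within-set edge ({u},{v})"
                    )


def _relabel_1based(g: nx.Graph) -> nx.Graph:
    return nx.relabel_nodes(g, {n: i + 1 for i, n in enumerate(sorted(g.nodes))})


def _apply_attrs(
    g: nx.Graph,
    capacity: int | Mapping[int, int],
    weight: float,
) -> None:
    for n in g.nodes:
        g.nodes[n]["capacity"] = (
            int(capacity[n]) if isinstance(capacity, Mapping) else int(capacity)
        )
    for u, v in g.edges:
        g.edges[u, v].setdefault("weight", float(weight))


def _connect_components(g: nx.Graph, rng: np.random.Generator, weight: float) -> int:
    """Join components with random bridging edges; returns #edges added."""
    comps = [sorted(c) for c in nx.connected_components(g)]
    added = 0
    while len(comps) > 1:
        a = comps.pop(rng.integers(len(comps)))
        b = comps.pop(rng.integers(len(comps)))
        u = a[rng.integers(len(a))]
        v = b[rng.integers(len(b))]
        g.add_edge(u, v, weight=float(weight))
        added += 1
        comps.append(sorted(set(a) | set(b)))
    return added


def generate_network(
    topology: str,
    n_species: int,
    *,
    mean_degree: float | None = None,
    density: float | None = None,
    n_modules: int = 4,
    p_within: float = 0.6,
    p_between: float = 0.05,
    bipartite_sizes: tuple[int, int] | None = None,
    sf_method: str = "powerlaw",
    exact_edges: bool = False,
    capacity: int | Mapping[int, int] = DEFAULT_CAPACITY,
    weight: float = DEFAULT_WEIGHT,
    ensure_connected: bool = True,
    max_attempts: int = 50,
    seed: int | np.random.Generator = 0,
) -> HTTNetwork:
    """Generate an HTT network with one of the five stylised topologies.

    Parameters
    ----------
    topology
        ``complete``, ``random`` (Erdős–Rényi, Poisson degrees),
        ``scale_free`` (power-law degrees), ``modular`` (stochastic-block:
        denser within than between groups) or ``bipartite`` (two disjoint
        sets, edges only between sets).
    n_species
        Number of species nodes (ids 1..n_species).
    mean_degree, density
        Target connectivity for random/scale_free/bipartite; give one.
        Density is converted to a mean degree of ``density * (n-1)``.
    n_modules, p_within, p_between
        Modular topology: number of groups and Bernoulli edge
        probabilities within/between groups.
    bipartite_sizes
        Sizes of the two node sets; default even split.
    sf_method
        Scale-free generator.  ``powerlaw`` (default): configuration model
        on degrees sampled from a truncated power law whose exponent is
        solved to hit the target mean degree — produces both hubs and
        degree-1 leaves.  ``ba``: Barabási–Albert preferential attachment
        with ``m = round(mean_degree / 2)`` — heavy-tailed but with a
        minimum degree of m, i.e. no leaves.
    capacity
        Per-species reservoir capacity (scalar or mapping by species id).
    exact_edges
        Random topology only: draw a uniform spanning tree plus uniform
        extra non-edges so the network is connected with exactly
        ``round(n * mean_degree / 2)`` edges.  Use for comparative
        experiments where edge-count variance between instances must not
        confound a density gradient.
    ensure_connected
        Regenerate up to ``max_attempts`` times until connected; if still
        disconnected, bridge components with random edges (recorded in
        ``meta['bridging_edges']``).
    seed
        Integer seed or :class:`numpy.random.Generator`.

    Returns
    -------
    HTTNetwork
    """
    if n_species < 2:
        raise NetworkSpecError("n_species must be >= 2")
    if topology not in TOPOLOGY_LABELS or topology == "custom":
        raise NetworkSpecError(f"cannot generate topology {topology!r}")
    rng = np.random.default_rng(seed)

    if density is not None:
        if mean_degree is not None:
            raise NetworkSpecError("give mean_degree or density, not both")
        mean_degree = density * (n_species - 1)
    if mean_degree is not None and not (0 < mean_degree < n_species):
        raise NetworkSpecError(
            f"mean degree {mean_degree} infeasible for {n_species} species"
        )

    meta: dict = {"requested_mean_degree": mean_degree}
    g: nx.Graph | None = None
    for attempt in range(max_attempts):
        g = _generate_once(
            topology, n_species, mean_degree, n_modules, p_within, p_between,
            bipartite_sizes, sf_method, exact_edges, rng,
        )
        if not ensure_connected or nx.is_connected(g):
            break
    assert g is not None
    if ensure_connected and not nx.is_connected(g):
        added = _connect_components(g, rng, weight)
        meta["bridging_edges"] = added
        warnings.warn(
            f"{topology} network still disconnected after {max_attempts} attempts; "
            f"added {added} bridging edge(s)",
            stacklevel=2,
        )
    _apply_attrs(g, capacity, weight)
    return HTTNetwork(g, topology_label=topology, meta=meta)


def _generate_once(
    topology: str,
    n: int,
    mean_degree: float | None,
    n_modules: int,
    p_within: float,
    p_between: float,
    bipartite_sizes: tuple[int, int] | None,
    sf_method: str,
    exact_edges: bool,
    rng: np.random.Generator,
) -> nx.Graph:
    nx_seed = int(rng.integers(2**31 - 1))
    if topology == "complete":
        g = nx.complete_graph(n)
    elif topology == "random":
        if mean_degree is None:
            raise NetworkSpecError("random topology requires mean_degree or density")
        if exact_edges:
            m = round(mean_degree * n / 2)
            if m < n - 1:
                raise NetworkSpecError(
                    "exact_edges requires mean_degree >= 2(n-1)/n for connectivity"
                )
            g = nx.random_labeled_tree(n, seed=nx_seed)
            non_edges = [(u, v) for u in range(n) for v in range(u + 1, n)
                         if not g.has_edge(u, v)]
            extra = m - (n - 1)
            for idx in rng.choice(len(non_edges), size=extra, replace=False):
                g.add_edge(*non_edges[idx])
        else:
            p = mean_degree / (n - 1)
            g = nx.gnp_random_graph(n, p, seed=nx_seed)
    elif topology == "scale_free":
        if mean_degree is None:
            raise NetworkSpecError("scale_free topology requires mean_degree or density")
        if sf_method == "ba":
            # BA mean degree ~ 2m(1 - m/n); m = round(mean_degree/2) is the
            # standard choice at large n.
            m = max(1, round(mean_degree / 2))
            if m >= n:
                raise NetworkSpecError("mean_degree too large for preferential attachment")
            g = nx.barabasi_albert_graph(n, m, seed=nx_seed)
        elif sf_method == "powerlaw":
            g = _powerlaw_configuration_graph(n, mean_degree, rng)
        else:
            raise NetworkSpecError(f"unknown sf_method {sf_method!r}")
    elif topology == "modular":
        if not (0 <= p_between < p_within <= 1):
            raise NetworkSpecError("modular topology requires p_between < p_within")
        if n_modules < 2 or n_modules > n:
            raise NetworkSpecError("n_modules must be in [2, n_species]")
        sizes = [n // n_modules + (1 if i < n % n_modules else 0) for i in range(n_modules)]
        probs = [
            [p_within if i == j else p_between for j in range(n_modules)]
            for i in range(n_modules)
        ]
        g = nx.stochastic_block_model(sizes, probs, seed=nx_seed)
        g = nx.Graph(g)  # drop SBM bookkeeping
        labels = np.repeat(np.arange(1, n_modules + 1), sizes)
        for node, lab in zip(sorted(g.nodes), labels):
            g.nodes[node]["module"] = int(lab)
    elif topology == "bipartite":
        if bipartite_sizes is None:
            bipartite_sizes = (n // 2, n - n // 2)
        n1, n2 = bipartite_sizes
        if n1 + n2 != n or min(n1, n2) < 1:
            raise NetworkSpecError("bipartite set sizes must be positive and sum to n_species")
        if mean_degree is None:
            raise NetworkSpecError("bipartite topology requires mean_degree or density")
        # mean degree over all n nodes: n*k/2 expected edges = p*n1*n2
        p = mean_degree * n / (2 * n1 * n2)
        if p > 1:
            raise NetworkSpecError("mean_degree infeasible for bipartite set sizes")
        g = nx.bipartite.random_graph(n1, n2, p, seed=nx_seed)
        for node in g.nodes:
            g.nodes[node]["module"] = 1 if node < n1 else 2
        g.graph.pop("name", None)
    else:  # pragma: no cover
        raise NetworkSpecError(topology)
    g.graph.clear()  # drop generator bookkeeping (e.g. SBM partition lists)
    return _relabel_1based(g)


def _powerlaw_configuration_graph(
    n: int, mean_degree: float, rng: np.random.Generator, tol: float = 0.4
) -> nx.Graph:
    """Simple graph with power-law degrees at a target mean degree.

    Degrees are drawn from ``P(k) ~ k^-gamma`` on 1..n-1 with gamma solved
    so the expected degree equals ``mean_degree``; a configuration-model
    multigraph is then simplified (self-loops and parallel edges dropped).
    Degree sequences are resampled until the realised mean degree lands
    within ``tol`` of the target.
    """
    from scipy.optimize import brentq

    ks = np.arange(1, n, dtype=float)

    def _mean(gamma: float) -> float:
        w = ks ** (-gamma)
        w /= w.sum()
        return float(w @ ks)

    if not (_mean(5.0) <= mean_degree <= _mean(-1.0)):
        raise NetworkSpecError(
            f"mean_degree {mean_degree} out of range for power-law degrees on {n} nodes"
        )
    gamma = brentq(lambda g_: _mean(g_) - mean_degree, -1.0, 5.0)
    w = ks ** (-gamma)
    w /= w.sum()
    g = None
    for _ in range(200):
        degs = rng.choice(ks.astype(int), size=n, p=w)
        if degs.sum() % 2:
            continue
        cand = nx.configuration_model(degs, seed=int(rng.integers(2**31 - 1)))
        cand = nx.Graph(cand)
        cand.remove_edges_from(nx.selfloop_edges(cand))
        g = cand
        if abs(2 * cand.number_of_edges() / n - mean_degree) <= tol:
            break
    assert g is not None
    return g


def shuffle_edges(
    net: HTTNetwork,
    n_shuffles: int,
    seed: int | np.random.Generator = 0,
    *,
    method: str = "double_edge_swap",
    max_tries_factor: int = 100,
) -> HTTNetwork:
    """Perturb a network by rewiring edges; returns a new network.

    The default ``double_edge_swap`` picks two edges (a,b),(c,d) and rewires
    them to (a,d),(c,b), preserving every node's degree, so the perturbation
    isolates *which* species are linked from *how many* links each has.
    ``n_shuffles = 0`` returns a structurally identical copy.  The
    alternative ``random_rewire`` moves one endpoint of a random edge to a
    uniformly random non-adjacent node (degrees not preserved).

    Node capacities and the topology label are carried over; effective swap
    count is recorded in ``meta['effective_shuffles']``.
    """
    if n_shuffles < 0:
        raise ValueError("n_shuffles must be >= 0")
    if method not in ("double_edge_swap", "random_rewire"):
        raise ValueError(f"unknown shuffle method {method!r}")
    rng = np.random.default_rng(seed)
    out = net.copy()
    g = out.graph
    if n_shuffles == 0:
        out.meta["effective_shuffles"] = 0
        return out
    if g.number_of_edges() < 2:
        raise ValueError("need at least 2 edges to shuffle")

    done = 0
    tries = 0
    max_tries = max_tries_factor * n_shuffles
    nodes = out.species_ids
    while done < n_shuffles and tries < max_tries:
        tries += 1
        edges = list(g.edges)
        if method == "double_edge_swap":
            i, j = rng.choice(len(edges), size=2, replace=False)
            (a, b), (c, d) = edges[i], edges[j]
            if rng.integers(2):
                c, d = d, c
            # proposed: (a,d) and (c,b)
            if len({a, b, c, d}) < 4:
                continue
            if g.has_edge(a, d) or g.has_edge(c, b):
                continue
            w1 = g.edges[a, b]["weight"]
            w2 = g.edges[c, d]["weight"]
            g.remove_edge(a, b)
            g.remove_edge(c, d)
            g.add_edge(a, d, weight=w1)
            g.add_edge(c, b, weight=w2)
        else:
            a, b = edges[rng.integers(len(edges))]
            if rng.integers(2):
                a, b = b, a
            candidates = [v for v in nodes if v != a and v != b and not g.has_edge(a, v)]
            if not candidates:
                continue
            v = candidates[rng.integers(len(candidates))]
            w = g.edges[a, b]["weight"]
            g.remove_edge(a, b)
            g.add_edge(a, v, weight=w)
        done += 1
    if done < n_shuffles:
        warnings.warn(
            f"only {done}/{n_shuffles} edge shuffles achieved after {tries} tries",
            stacklevel=2,
        )
    out.meta["effective_shuffles"] = done
    return out


def degree_summary(net: HTTNetwork) -> dict:
    """Degree sequence (sorted descending), mean degree and density."""
    degs = sorted((d for _, d in net.graph.degree), reverse=True)
    n = net.n_species
    mean = 2 * net.n_edges / n if n else 0.0
    dens = nx.density(net.graph)
    return {"degree_sequence": degs, "mean_degree": mean, "density": dens}
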