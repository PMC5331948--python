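"""Stochastic simulation of TE copy-number dynamics on an HTT network.

Each node of the network is one representative genome (a species-level TE
reservoir) holding an integer number of copies of each TE family.  One
simulation iteration applies, synchronously and per copy:

1. *Transposition* — every copy duplicates within its genome with
   probability ``u_transposition``; duplications that would push the genome
   past its reservoir capacity are rejected.
2. *Horizontal transfer (HTT)* — every copy attempts a jump with
   probability ``u_transposition / htt_ratio``; on an attempt, a neighbour
   of the source species is drawn with probability proportional to edge
   weight and one new copy establishes there unless the recipient genome is
   at capacity (a capacity-rejected attempt is *not* a successful HTT).
3. *Loss* — every copy is removed with probability ``loss_prob``
   (default 0, i.e. off).

Intragenomic dynamics are therefore much faster than intergenomic ones
(ratio ``htt_ratio``, default 100), and a run usually stops when a target
number of successful HTTs has accumulated — the simulation's natural clock
for comparing networks — rather than at a fixed horizon.

Every successful event is logged; replaying the log over the initial state
reproduces the final copy-number matrix exactly (a conservation check used
in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .topology import HTTNetwork


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a TE-flow simulation.

    Attributes
    ----------
    n_species, n_families
        Matrix dimensions of the simulated community.
    capacity
        Maximal number of TE copies a genome can carry of each family
        (``capacity_mode='per_family'``, the default) or in total across
        families (``'per_species'``).  The per-family cap is the default
        because a hard per-genome total is filled almost entirely by the
        ~100x faster intragenomic transposition, which starves horizontal
        transfer and makes large HTT-count stop criteria unreachable.
        ``None`` (the default) uses the per-node capacities stored on the
        network (themselves defaulting to 100); an explicit integer
        overrides them uniformly.
    u_transposition
        Per-copy per-iteration duplication probability.
    htt_ratio
        Ratio rho >= 1 between transposition and HTT rates; the per-copy
        HTT attempt probability is ``u_transposition / htt_ratio``.
    target_htt_count
        Stop once this many successful HTTs have occurred.
    max_iterations
        Safety cap; runs hitting it are flagged truncated.
    loss_prob
        Per-copy per-iteration loss probability (TE decay/silencing).
    htt_success
        What counts as a successful HTT toward ``target_htt_count``.
        ``colonization`` (default): establishment of a family in a genome
        that did not carry it — transfers of an already-present family are
        redundant (the family is already amplifying internally) and are
        neither counted nor applied.  This makes the stop criterion mean
        the same thing at every transposition:HTT rate ratio.  ``copy``:
        any transfer that establishes a new copy counts, including into
        genomes already carrying the family.
    seed
        Default RNG seed for runs that are not handed an explicit seed.
    """

    n_species: int = 20
    n_families: int = 30
    capacity: int | None = None
    u_transposition: float = 0.01
    htt_ratio: float = 100.0
    target_htt_count: int = 150
    max_iterations: int = 200_000
    loss_prob: float = 0.0
    capacity_mode: str = "per_family"
    htt_success: str = "colonization"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.u_transposition <= 1):
            raise ConfigError("u_transposition must be in [0, 1]")
        if self.htt_ratio < 1:
            raise ConfigError("htt_ratio must be >= 1")
        if self.target_htt_count < 1:
            raise ConfigError("target_htt_count must be >= 1")
        if self.n_families < 1 or self.n_species < 1:
            raise ConfigError("n_species and n_families must be >= 1")
        if not (0 <= self.loss_prob < 1):
            raise ConfigError("loss_prob must be in [0, 1)")
        if self.capacity_mode not in ("per_species", "per_family"):
            raise ConfigError("capacity_mode must be 'per_species' or 'per_family'")
        if self.capacity is not None and self.capacity < 1:
            raise ConfigError("capacity must be >= 1 (or None to use network capacities)")
        if self.htt_success not in ("colonization", "copy"):
            raise ConfigError("htt_success must be 'colonization' or 'copy'")

    @property
    def u_htt(self) -> float:
        return self.u_transposition / self.htt_ratio


class Event(NamedTuple):
    iteration: int
    type: str  # transposition | htt | loss
    family: int  # 1-based family id
    source: int  # 1-based species id
    target: int  # 1-based species id for htt, else 0


class EventLog:
    """Ordered record of all successful simulation events."""

    def __init__(self, events: Iterable[Event] = ()) -> None:
        self.events: list[Event] = list(events)

    def append(self, ev: Event) -> None:
        self.events.append(ev)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def count(self, type_: str) -> int:
        return sum(1 for e in self.events if e.type == type_)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.events, columns=Event._fields)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "EventLog":
        df = pd.read_csv(path, sep="\t")
        return cls(Event(*row) for row in df.itertuples(index=False))


@dataclass
class SimState:
    """Mutable state of a running simulation."""

    copies: np.ndarray  # (n_species, n_families) non-negative ints
    iteration: int = 0
    htt_count: int = 0
    rng: np.random.Generator = field(default_factory=np.random.default_rng)

    @property
    def species_totals(self) -> np.ndarray:
        return self.copies.sum(axis=1)


@dataclass
class SimResult:
    """Final state plus event log and run diagnostics."""

    state: SimState
    log: EventLog
    config: SimConfig
    initial_copies: np.ndarray
    truncated: bool = False
    failed: bool = False
    capacity_rejections: int = 0
    redundant_transfers: int = 0

    @property
    def copies(self) -> np.ndarray:
        return self.state.copies


class _NetCache:
    """Per-species neighbour arrays and cumulative edge weights."""

    __slots__ = ("neighbors", "cumweights", "capacities")

    def __init__(self, net: HTTNetwork, config: SimConfig | None = None) -> None:
        ids = net.species_ids
        self.neighbors: list[np.ndarray] = []
        self.cumweights: list[np.ndarray] = []
        g = net.graph
        for s in ids:
            nbrs = sorted(g.neighbors(s))
            w = np.array([g.edges[s, t]["weight"] for t in nbrs], dtype=float)
            self.neighbors.append(np.asarray(nbrs, dtype=np.int64))
            self.cumweights.append(np.cumsum(w))
        if config is not None and config.capacity is not None:
            self.capacities = np.full(len(ids), config.capacity, dtype=np.int64)
        else:
            self.capacities = np.array(
                [g.nodes[s]["capacity"] for s in ids], dtype=np.int64
            )


def init_state(
    config: SimConfig,
    net: HTTNetwork,
    *,
    start_species: int | None = None,
    rng: np.random.Generator | None = None,
) -> SimState:
    """Seed the community: one founding copy per family.

    For multi-family runs each family starts in a uniformly random species;
    a single-family run may pin the founding species via ``start_species``.
    """
    if config.n_species != net.n_species:
        raise ConfigError(
            f"config.n_species={config.n_species} does not match network "
            f"({net.n_species} species)"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed)
    copies = np.zeros((config.n_species, config.n_families), dtype=np.int64)
    if start_species is not None:
        if start_species not in net.graph:
            raise ConfigError(f"start species {start_species} not in network")
        copies[start_species - 1, :] = 1
    else:
        starts = rng.integers(config.n_species, size=config.n_families)
        copies[starts, np.arange(config.n_families)] = 1
    return SimState(copies=copies, iteration=0, htt_count=0, rng=rng)


def step(
    state: SimState,
    net: HTTNetwork | _NetCache,
    config: SimConfig,
    log: EventLog | None = None,
    *,
    htt_budget: int | None = None,
) -> dict:
    """Advance the state by one synchronous iteration, in place.

    Returns counters: ``capacity_rejections`` (transfer attempts refused
    because the recipient reservoir is full) and ``redundant_transfers``
    (attempts on a family the recipient already carries, in colonization
    mode).  ``htt_budget`` caps the successful HTTs still accepted this
    iteration (attempts beyond it are discarded), so runs can stop exactly
    at their target count.
    """
    cache = net if isinstance(net, _NetCache) else _NetCache(net, config)
    rng = state.rng
    copies = state.copies
    caps = cache.capacities
    it = state.iteration + 1
    rejections = 0
    redundant = 0
    colonize = config.htt_success == "colonization"

    # 1. transposition, capped by reservoir capacity
    if config.capacity_mode == "per_species":
        room = caps - copies.sum(axis=1)
    else:
        room = None
    if config.u_transposition > 0:
        if room is not None:
            open_rows = np.flatnonzero(room > 0)
            if open_rows.size:
                births = rng.binomial(copies[open_rows], config.u_transposition)
                for idx, s in enumerate(open_rows):
                    b = births[idx]
                    total = int(b.sum())
                    if total == 0:
                        continue
                    r = int(room[s])
                    if total > r:
                        b = rng.multivariate_hypergeometric(b, r)
                    copies[s] += b
                    if log is not None:
                        for f in np.flatnonzero(b):
                            for _ in range(int(b[f])):
                                log.append(Event(it, "transposition", f + 1, s + 1, 0))
        else:
            births = rng.binomial(copies, config.u_transposition)
            np.minimum(births, caps[:, None] - copies, out=births)
            np.maximum(births, 0, out=births)
            if births.any():
                copies += births
                if log is not None:
                    for s, f in zip(*np.nonzero(births)):
                        for _ in range(int(births[s, f])):
                            log.append(Event(it, "transposition", f + 1, s + 1, 0))

    # 2. horizontal transfer attempts
    budget = np.inf if htt_budget is None else htt_budget
    attempts = rng.binomial(copies, config.u_htt)
    if attempts.any():
        totals = copies.sum(axis=1)
        for s, f in zip(*np.nonzero(attempts)):
            nbrs = cache.neighbors[s]
            if nbrs.size == 0:
                continue
            cw = cache.cumweights[s]
            for _ in range(int(attempts[s, f])):
                if budget <= 0:
                    break
                t_id = nbrs[np.searchsorted(cw, rng.random() * cw[-1], side="right")]
                t = t_id - 1
                if colonize and copies[t, f] > 0:
                    redundant += 1
                    continue
                if config.capacity_mode == "per_species":
                    has_room = totals[t] < caps[t]
                else:
                    has_room = copies[t, f] < caps[t]
                if has_room:
                    copies[t, f] += 1
                    totals[t] += 1
                    state.htt_count += 1
                    budget -= 1
                    if log is not None:
                        log.append(Event(it, "htt", f + 1, s + 1, int(t_id)))
                else:
                    rejections += 1
            if budget <= 0:
                break

    # 3. loss
    if config.loss_prob > 0:
        deaths = rng.binomial(copies, config.loss_prob)
        if deaths.any():
            copies -= deaths
            if log is not None:
                for s, f in zip(*np.nonzero(deaths)):
                    for _ in range(int(deaths[s, f])):
                        log.append(Event(it, "loss", f + 1, s + 1, 0))

    state.iteration = it
    return {"capacity_rejections": rejections, "redundant_transfers": redundant}


def run_to_htt_count(
    config: SimConfig,
    net: HTTNetwork,
    *,
    rng: np.random.Generator | int | None = None,
    keep_log: bool = True,
) -> SimResult:
    """Run a multi-family simulation until ``target_htt_count`` HTTs.

    Stops exactly at the target (surplus attempts in the final iteration are
    discarded), or at ``max_iterations`` with ``truncated=True``; if every
    family goes extinct first (possible with ``loss_prob > 0``) the partial
    result is flagged ``failed=True``.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    state = init_state(config, net, rng=rng)
    initial = state.copies.copy()
    log = EventLog() if keep_log else None
    cache = _NetCache(net, config)
    rejections = 0
    redundant = 0
    failed = False
    while state.htt_count < config.target_htt_count and state.iteration < config.max_iterations:
        counters = step(
            state, cache, config, log,
            htt_budget=config.target_htt_count - state.htt_count,
        )
        rejections += counters["capacity_rejections"]
        redundant += counters["redundant_transfers"]
        if config.loss_prob > 0 and not state.copies.any():
            failed = True
            break
    return SimResult(
        state=state,
        log=log if log is not None else EventLog(),
        config=config,
        initial_copies=initial,
        truncated=state.htt_count < config.target_htt_count and not failed,
        failed=failed,
        capacity_rejections=rejections,
        redundant_transfers=redundant,
    )


@dataclass
class Trajectory:
    """Single-family spread: first iteration at which x species are infected.

    ``first_passage[x-1]`` is the iteration count at which the family was
    first present in ``x`` species (NaN if never reached before the run
    ended).  With ``loss_prob=0`` the infected count is non-decreasing.
    """

    start_species: int
    first_passage: np.ndarray  # length n_species, float with NaN
    n_iterations: int
    status: str  # completed | truncated | extinct

    def max_infected(self) -> int:
        reached = ~np.isnan(self.first_passage)
        return int(np.max(np.flatnonzero(reached)) + 1) if reached.any() else 0


def run_single_family(
    config: SimConfig,
    net: HTTNetwork,
    start_species: int,
    *,
    rng: np.random.Generator | int | None = None,
) -> Trajectory:
    """Track the spread of one TE family from a given founding species.

    The stop criterion here is saturation (all species infected) or
    ``max_iterations``; the HTT-count target does not apply.
    """
    cfg = replace(config, n_families=1)
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(cfg.seed if rng is None else rng)
    state = init_state(cfg, net, start_species=start_species, rng=rng)
    cache = _NetCache(net, cfg)
    n = cfg.n_species
    fp = np.full(n, np.nan)
    fp[0] = 0.0
    best = 1
    status = "truncated"
    while state.iteration < cfg.max_iterations:
        step(state, cache, cfg, None)
        infected = int(np.count_nonzero(state.copies[:, 0]))
        if infected == 0:
            status = "extinct"
            break
        while best < infected:
            best += 1
            fp[best - 1] = state.iteration
        if infected == n:
            status = "completed"
            break
    return Trajectory(
        start_species=start_species,
        first_passage=fp,
        n_iterations=state.iteration,
        status=status,
    )


def replay_event_log(initial_copies: np.ndarray, log: EventLog) -> np.ndarray:
    """Re-apply an event log to an initial copies matrix.

    Used as the conservation oracle: the result must equal the simulation's
    final matrix exactly.
    """
    copies = np.array(initial_copies, dtype=np.int64, copy=True)
    for ev in log:
        if ev.type == "transposition":
            copies[ev.source - 1, ev.family - 1] += 1
        elif ev.type == "htt":
            copies[ev.target - 1, ev.family - 1] += 1
        elif ev.type == "loss":
            copies[ev.source - 1, ev.family - 1] -= 1
        else:
            raise ValueError(f"unknown event type {ev.type!r}")
    return copies
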