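"""Beta-matrix stability and discrimination experiments.

Three questions about the emergent beta matrix are answered here:

* How similar are two beta matrices? — :func:`mantel`, the Mantel
  correlation between distance matrices with a label-permutation test.
* How fast does the beta matrix degrade as the generating network is
  perturbed? — :func:`shuffle_experiment`: simulate a reference beta
  matrix, rewire the network by a growing number of edge shuffles,
  re-simulate, and track the Mantel correlation against the reference.
  :func:`htt_count_sensitivity` repeats this across HTT-count stop values.
* How does topology shape single-family spread? —
  :func:`propagation_experiment`: first-passage times to x infected
  species over many founding conditions.

All experiments use hierarchical RNG seeding (master seed -> per-network
-> per-replicate streams), so results are exactly reproducible and adding
replicates does not disturb existing ones.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diversity import BetaMatrix, beta_matrix, presence_matrix
from .dynamics import SimConfig, Trajectory, run_single_family, run_to_htt_count
from .topology import HTTNetwork, generate_network, shuffle_edges


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    denom = math.sqrt(float(x @ x) * float(y @ y))
    if denom == 0:
        return math.nan
    return float(x @ y) / denom


def mantel(
    a: BetaMatrix,
    b: BetaMatrix,
    n_permutations: int = 999,
    seed: int | np.random.Generator = 0,
    *,
    method: str = "pearson",
    exact: bool = False,
) -> dict:
    """Mantel correlation between two distance matrices.

    ``r`` is the Pearson (or Spearman, via ``method``) correlation of the
    off-diagonal upper-triangle entries.  ``p`` is one-sided (upper tail)
    from permuting the species labels of ``b``, with the +1 correction in
    numerator and denominator; ``exact=True`` enumerates all n!
    permutations instead (only sensible for small n).

    Returns ``{"r": float, "p": float | None, "n_permutations": int}``;
    if either triangle has zero variance, ``r`` is NaN and no p-value is
    computed.
    """
    if a.species_ids != b.species_ids:
        raise ValueError("matrices must share the same species set and ordering")
    n = a.n_species
    if n < 3:
        raise ValueError("Mantel test requires at least 3 species")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")

    va = a.condensed()
    vb = b.condensed()
    if method == "spearman":
        from scipy.stats import rankdata

        va = rankdata(va)

        def _vec(m: np.ndarray) -> np.ndarray:
            iu = np.triu_indices(n, 1)
            return rankdata(m[iu])
    else:

        def _vec(m: np.ndarray) -> np.ndarray:
            iu = np.triu_indices(n, 1)
            return m[iu]

    r_obs = _pearson(va, _vec(b.values) if method == "spearman" else vb)
    if math.isnan(r_obs):
        return {"r": math.nan, "p": None, "n_permutations": 0}

    if exact:
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            p_idx = np.array(perm)
            r_perm = _pearson(va, _vec(b.values[np.ix_(p_idx, p_idx)]))
            total += 1
            if r_perm >= r_obs - 1e-12:
                count += 1
        return {"r": r_obs, "p": count / total, "n_permutations": total}

    if n_permutations <= 0:
        return {"r": r_obs, "p": None, "n_permutations": 0}
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        p_idx = rng.permutation(n)
        r_perm = _pearson(va, _vec(b.values[np.ix_(p_idx, p_idx)]))
        if r_perm >= r_obs - 1e-12:
            count += 1
    return {
        "r": r_obs,
        "p": (count + 1) / (n_permutations + 1),
        "n_permutations": n_permutations,
    }


@dataclass
class ShuffleExperimentTable:
    """Tidy record of Mantel correlations across edge-shuffle levels."""

    table: pd.DataFrame  # columns: n_shuffles, network, rep, mantel_r
    n_failed: int = 0

    def aggregate(self) -> pd.DataFrame:
        """Mean and SD of Mantel r per shuffle level (NaN rows excluded)."""
        ok = self.table.dropna(subset=["mantel_r"])
        g = ok.groupby("n_shuffles")["mantel_r"]
        out = pd.DataFrame({"mean_r": g.mean(), "sd_r": g.std(ddof=1), "n": g.size()})
        return out.reset_index()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


DEFAULT_TOPOLOGY_SPEC: dict = {"topology": "scale_free", "mean_degree": 4}
DEFAULT_SHUFFLE_LEVELS = (0, 1, 2, 5, 10, 20)


def _child_seeds(ss: np.random.SeedSequence, k: int) -> list[np.random.SeedSequence]:
    return ss.spawn(k)


def _simulate_beta(
    config: SimConfig, net: HTTNetwork, rng: np.random.Generator
) -> BetaMatrix | None:
    res = run_to_htt_count(config, net, rng=rng, keep_log=False)
    if res.truncated or res.failed:
        return None
    return beta_matrix(presence_matrix(res))


def shuffle_experiment(
    config: SimConfig,
    topology_spec: Mapping | None = None,
    shuffle_levels: Sequence[int] = DEFAULT_SHUFFLE_LEVELS,
    n_networks: int = 10,
    n_reps: int = 5,
    seed: int = 0,
) -> ShuffleExperimentTable:
    """Edge-shuffle perturbation experiment.

    For each of ``n_networks`` reference networks: simulate a reference
    beta matrix; then for every shuffle level and replicate, rewire the
    reference network by that many degree-preserving edge shuffles,
    re-simulate, and record the Mantel correlation of the new beta matrix
    against the reference.  Level 0 re-simulates the unchanged network and
    so measures pure simulation stochasticity.

    Defaults are a reduced scale (10 networks x 5 replicates) of the
    published design (50 scale-free networks x 10 replicates, 20 species /
    30 families / 150 HTTs).
    """
    if 0 not in shuffle_levels:
        raise ValueError("shuffle_levels must include 0 (stability baseline)")
    spec = dict(DEFAULT_TOPOLOGY_SPEC if topology_spec is None else topology_spec)
    topology = spec.pop("topology")
    rows = []
    n_failed = 0
    master = np.random.SeedSequence(seed)
    for net_idx, net_ss in enumerate(master.spawn(n_networks)):
        children = net_ss.spawn(2 + len(shuffle_levels) * n_reps)
        gen_ss, ref_ss = children[0], children[1]
        net = generate_network(topology, config.n_species, seed=np.random.default_rng(gen_ss), **spec)
        beta_ref = _simulate_beta(config, net, np.random.default_rng(ref_ss))
        if beta_ref is None:
            n_failed += len(shuffle_levels) * n_reps
            continue
        k = 2
        for level in shuffle_levels:
            for rep in range(n_reps):
                rng = np.random.default_rng(children[k])
                k += 1
                pert = shuffle_edges(net, level, seed=rng) if level else net
                beta_rep = _simulate_beta(config, pert, rng)
                if beta_rep is None:
                    n_failed += 1
                    r = math.nan
                else:
                    r = mantel(beta_ref, beta_rep, n_permutations=0)["r"]
                rows.append((level, net_idx, rep, r))
    table = pd.DataFrame(rows, columns=["n_shuffles", "network", "rep", "mantel_r"])
    return ShuffleExperimentTable(table, n_failed=n_failed)


def htt_count_sensitivity(
    config: SimConfig,
    topology_spec: Mapping | None = None,
    htt_targets: Sequence[int] = (50, 100, 150),
    shuffle_levels: Sequence[int] = DEFAULT_SHUFFLE_LEVELS,
    n_networks: int = 10,
    n_reps: int = 5,
    seed: int = 0,
) -> dict[int, ShuffleExperimentTable]:
    """Shuffle experiment repeated over HTT-count stop criteria.

    The correlation level is expected to rise with the number of successful
    HTTs (more transfer events imprint the network structure more deeply on
    TE composition), while the decreasing-in-shuffles trend holds for all.
    """
    out: dict[int, ShuffleExperimentTable] = {}
    master = np.random.SeedSequence(seed)
    for target, t_ss in zip(htt_targets, master.spawn(len(htt_targets))):
        cfg = replace(config, target_htt_count=int(target))
        out[int(target)] = shuffle_experiment(
            cfg, topology_spec, shuffle_levels, n_networks, n_reps,
            seed=int(t_ss.generate_state(1)[0]),
        )
    return out


@dataclass
class PropagationSummary:
    """First-passage statistics of single-family spread on one network.

    ``stats`` has one row per x = 1..N with quartiles of the iteration at
    which x species were first infected and the proportion of trajectories
    that ever reached x.
    """

    label: str
    first_passage: np.ndarray  # (n_trajectories, n_species), NaN = not reached
    stats: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        fp = self.first_passage
        n_traj, n = fp.shape
        rows = []
        for x in range(1, n + 1):
            col = fp[:, x - 1]
            reached = col[~np.isnan(col)]
            prop = len(reached) / n_traj if n_traj else 0.0
            if len(reached):
                q1, med, q3 = np.percentile(reached, [25, 50, 75])
            else:
                q1 = med = q3 = math.nan
            rows.append((x, prop, q1, med, q3))
        self.stats = pd.DataFrame(
            rows, columns=["x", "proportion_reaching", "q1", "median", "q3"]
        )

    def proportion_exceeding(self, x: int, within: float | None = None) -> float:
        """Proportion of trajectories that infected more than x species.

        ``within`` applies an observation window: only trajectories whose
        (x+1)-th infection happened by that iteration count.
        """
        if x >= self.first_passage.shape[1]:
            return 0.0
        col = self.first_passage[:, x]  # column x is "reached x+1 species"
        hit = ~np.isnan(col) if within is None else (col <= within)
        return float(np.count_nonzero(hit) / self.first_passage.shape[0])

    def iqr_at(self, x: int) -> float:
        row = self.stats.loc[self.stats["x"] == x].iloc[0]
        return float(row["q3"] - row["q1"])

    def median_at(self, x: int) -> float:
        return float(self.stats.loc[self.stats["x"] == x, "median"].iloc[0])


def propagation_experiment(
    config: SimConfig,
    networks: Sequence[HTTNetwork] | Mapping[str, HTTNetwork],
    n_reps_per_start: int = 20,
    seed: int = 0,
) -> dict[str, PropagationSummary]:
    """Single-family propagation dynamics across networks.

    For each network, a single founding copy is placed in turn in every
    species, with ``n_reps_per_start`` replicates per founding species
    (default 20 starts x 20 reps = 400 trajectories on a 20-species
    network), and the first-passage iteration to each infected-species
    count x is aggregated.  Trajectories truncated at ``max_iterations``
    still count in the proportion-reaching denominators.
    """
    if isinstance(networks, Mapping):
        items = list(networks.items())
    else:
        items = [(net.topology_label + f"_{i}", net) for i, net in enumerate(networks)]
    n = items[0][1].n_species
    if any(net.n_species != n for _, net in items):
        raise ValueError("all networks must share the same species count")
    out: dict[str, PropagationSummary] = {}
    master = np.random.SeedSequence(seed)
    for (label, net), net_ss in zip(items, master.spawn(len(items))):
        run_seeds = net_ss.spawn(n * n_reps_per_start)
        fp = np.empty((n * n_reps_per_start, n))
        k = 0
        for start in range(1, n + 1):
            for _ in range(n_reps_per_start):
                traj = run_single_family(
                    config, net, start, rng=np.random.default_rng(run_seeds[k])
                )
                fp[k] = traj.first_passage
                k += 1
        out[label] = PropagationSummary(label=label, first_passage=fp)
    return out
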