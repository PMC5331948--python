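"""Inference of a plausible HTT network from an observed beta matrix.

Three tractable reconstruction routes, in increasing sophistication:

* :func:`infer_by_threshold` — put an edge wherever Jaccard similarity
  (1 - beta) clears a threshold; the beta matrix "used as it is".
* :func:`mutual_information_scores` — score each species pair by the
  mutual information between their binary TE-family profiles, i.e. how
  redundant the two genomes' TE contents are.
* :func:`abc_reconstruct` — approximate-Bayesian-computation-style
  selection: simulate TE dynamics on candidate networks and rank them by
  how close (Mantel correlation) their simulated beta matrices come to the
  observed one.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .comparison import mantel
from .diversity import BetaMatrix, PresenceMatrix, beta_matrix, presence_matrix
from .dynamics import SimConfig, run_to_htt_count
from .topology import HTTNetwork


@dataclass
class EdgeScoreMatrix:
    """Symmetric species x species edge scores with a method label."""

    values: np.ndarray
    species_ids: list[int]
    method: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.species_ids, columns=self.species_ids)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="species")


def infer_by_threshold(b: BetaMatrix, threshold: float, *, capacity: int = 100) -> HTTNetwork:
    """Threshold the similarity matrix into a putative HTT network.

    Edge (i, j) present iff ``1 - beta(i, j) >= threshold``; edge weights
    are the similarities.  Raising the threshold can only remove edges.
    """
    if not (0 <= threshold <= 1):
        raise ValueError("threshold must be in [0, 1]")
    sim = b.similarity()
    g = nx.Graph()
    g.add_nodes_from(b.species_ids)
    n = b.n_species
    for i in range(n):
        for j in range(i + 1, n):
            if sim[i, j] >= threshold:
                g.add_edge(
                    b.species_ids[i], b.species_ids[j], weight=max(float(sim[i, j]), 1e-12)
                )
    if g.number_of_edges() == 0:
        warnings.warn("threshold produced an edgeless network", stacklevel=2)
    elif g.number_of_edges() == n * (n - 1) // 2:
        warnings.warn("threshold produced a complete network", stacklevel=2)
    for node in g.nodes:
        g.nodes[node]["capacity"] = capacity
    return HTTNetwork(g, topology_label="custom", meta={"threshold": threshold})


def _binary_mi(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information (bits) between two binary vectors."""
    n = len(x)
    mi = 0.0
    for a in (0, 1):
        pa = np.count_nonzero(x == a) / n
        if pa == 0:
            continue
        for b_ in (0, 1):
            pb = np.count_nonzero(y == b_) / n
            pab = np.count_nonzero((x == a) & (y == b_)) / n
            if pab > 0 and pb > 0:
                mi += pab * math.log2(pab / (pa * pb))
    return max(mi, 0.0)


def mutual_information_scores(p: PresenceMatrix) -> EdgeScoreMatrix:
    """Mutual information between the TE-family profiles of species pairs.

    Estimated by the plug-in (maximum-likelihood) estimator on the
    empirical 2x2 joint distribution over families, in bits.  The diagonal
    holds each profile's marginal entropy (MI of a profile with itself).
    """
    if p.values.shape[1] < 2:
        raise ValueError("need at least 2 families")
    x = p.values.astype(int)
    n = p.n_species
    scores = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            scores[i, j] = scores[j, i] = _binary_mi(x[i], x[j])
    return EdgeScoreMatrix(scores, list(p.species_ids), method="mutual_information")


def abc_reconstruct(
    beta_obs: BetaMatrix,
    candidates: list[HTTNetwork],
    config: SimConfig,
    n_sims_per_candidate: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Rank candidate networks by closeness of simulated to observed beta.

    For each candidate, ``n_sims_per_candidate`` independent TE-flow
    simulations produce beta matrices whose Mantel correlations with
    ``beta_obs`` are averaged; candidates are ranked by mean r
    (descending), ties broken by lower SD.  This is the selection step of
    simulation-based (ABC) inference, not posterior sampling.

    Returns a DataFrame with columns ``candidate, mean_r, sd_r,
    n_effective, rank``, ordered best-first.
    """
    if not candidates:
        raise ValueError("need at least one candidate network")
    for c in candidates:
        if c.n_species != beta_obs.n_species:
            raise ValueError("candidates must share the species set of beta_obs")
    master = np.random.SeedSequence(seed)
    rows = []
    for idx, (cand, c_ss) in enumerate(zip(candidates, master.spawn(len(candidates)))):
        rs = []
        for run_ss in c_ss.spawn(n_sims_per_candidate):
            res = run_to_htt_count(config, cand, rng=np.random.default_rng(run_ss), keep_log=False)
            if res.truncated or res.failed:
                continue
            r = mantel(beta_obs, beta_matrix(presence_matrix(res)), n_permutations=0)["r"]
            if not math.isnan(r):
                rs.append(r)
        if len(rs) < n_sims_per_candidate:
            warnings.warn(
                f"candidate {idx}: only {len(rs)}/{n_sims_per_candidate} "
                "simulations usable",
                stacklevel=2,
            )
        mean_r = float(np.mean(rs)) if rs else -math.inf
        sd_r = float(np.std(rs, ddof=1)) if len(rs) > 1 else math.inf
        rows.append((idx, mean_r, sd_r, len(rs)))
    df = pd.DataFrame(rows, columns=["candidate", "mean_r", "sd_r", "n_effective"])
    df = df.sort_values(["mean_r", "sd_r"], ascending=[False, True], kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)
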