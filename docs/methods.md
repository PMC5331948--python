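# Methods

## The model

An HTT network is an undirected graph. Nodes are species-level TE
reservoirs: each node is a single representative genome (no within-species
population genetics), described by a non-negative integer copy count per TE
family. Edges are ecological connections; an edge weight represents the
density of molecular vehicles on that link and biases where transfer
attempts land. Node capacity is the reservoir's amplification limit.

One simulation iteration is synchronous and per copy:

1. **Transposition.** Every copy duplicates with probability `u`.
   Duplications that would exceed the capacity are rejected; when a genome
   has some room but more successful duplications than room, the accepted
   subset is drawn uniformly (multivariate hypergeometric), so no family is
   systematically favoured.
2. **Horizontal transfer.** Every copy attempts a jump with probability
   `u/ρ`. The recipient is a neighbour of the source species drawn with
   probability proportional to edge weight. The attempt *succeeds* —
   increments the HTT counter that drives the stop criterion — only if it
   colonizes a genome that did not already carry the family. Attempts on
   an already-colonized recipient are recorded as redundant and have no
   effect; attempts on a full reservoir are capacity-rejected.
3. **Loss.** Every copy is removed with probability `loss_prob`
   (default 0; enabling it models TE decay/silencing and makes family
   extinction possible, which runs report as a failure flag).

Multi-family runs seed one founding copy per family in a uniformly random
species and stop at the first moment the cumulative successful-HTT count
reaches its target (surplus attempts in the final iteration are discarded,
so the count is exact). Single-family runs seed one copy in a chosen
species and record the first-passage iteration at which x = 1..N species
carry the family.

Every applied event (duplication, colonization, loss) is logged; replaying
the log over the initial state reproduces the final copy matrix exactly,
which the test suite uses as a conservation check.

### Why HTT success = colonization

Two definitions of "successful HTT" are defensible: any transferred copy
that establishes (including into genomes already carrying the family), or
only colonizations of naive genomes. We measured both under the
edge-shuffle experiment: with the per-copy definition the Mantel-vs-shuffle
curves differ systematically between rate ratios ρ = 100 and ρ = 1000
(at ρ = 100 a large share of the success budget is spent on duplicate
transfers into not-yet-saturated recipients, while at ρ = 1000 recipients
saturate between transfers and duplicates get capacity-rejected). With the
colonization definition the stop criterion fixes the number of *new
presences* regardless of ρ, and the curves coincide to well within one SD
— the behaviour expected of a stop criterion chosen precisely to make
results rate-ratio-insensitive. Colonization is therefore the default;
`htt_success="copy"` restores the alternative.

### Why capacity is per family

With a hard per-genome total (capacity shared across families),
intragenomic transposition — two orders of magnitude faster than transfer —
fills essentially all reservoir room before transfers can accumulate: on
20 species × 30 families with capacity 100 and ρ = 100, only ~40
colonizations are ever possible, and the number reachable scales as
capacity/ρ. A per-family cap (each genome can amplify each family up to the
capacity) keeps the reservoir limit meaningful while leaving horizontal
colonization unconstrained by unrelated families, and makes the standard
150-HTT stop criterion reachable at any ρ. `capacity_mode="per_species"`
restores the shared-total variant.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `n_species` | 20 | network nodes |
| `n_families` | 30 | independent TE families |
| `capacity` | network's (100) | max copies per genome per family |
| `u_transposition` | 0.01 | per-copy duplication probability / iteration |
| `htt_ratio` (ρ) | 100 | transposition:transfer rate ratio; transfer prob = u/ρ |
| `target_htt_count` | 150 | stop criterion: successful colonizations |
| `loss_prob` | 0 | per-copy loss probability / iteration |
| `max_iterations` | 200 000 | safety cap (runs are flagged truncated) |

The 20/30/150 scale and ρ ∈ {100, 1000} are the standard conditions for
the β-matrix experiments; `u = 0.01` and capacity 100 set the intragenomic
time scale (a genome saturates a family in ≈ 460 iterations) without
affecting presence/absence conclusions.

## Topology generators

* **complete** — all pairs linked.
* **random** — Erdős–Rényi G(n, p) with `p = mean_degree/(n−1)` (Poisson
  degrees). `exact_edges=True` instead builds a uniform spanning tree plus
  uniform extra edges: connected by construction with exactly
  `round(n·mean_degree/2)` edges. Use it in comparative experiments where
  the G(n, p) edge-count variance (sd ≈ 0.6 in mean degree at n = 20)
  would confound a density gradient.
* **scale_free** — by default a configuration model on degrees sampled
  from `P(k) ∝ k^−γ` on 1..n−1, with γ solved numerically so the expected
  degree hits the target; self-loops/multi-edges are dropped and degree
  sequences resampled until the realized mean degree is within 0.4 of the
  target. This realizes a power-law degree distribution with both hubs and
  degree-1 leaves. The Barabási–Albert alternative (`sf_method="ba"`) is
  heavy-tailed but has minimum degree `m = round(mean_degree/2)`; at
  n = 20 that floor removes the slow-start trajectories that make
  scale-free propagation diverse, which is why it is not the default.
* **modular** — stochastic-block Bernoulli edges, `p_within ≫ p_between`,
  equal-sized groups (remainder spread over the first groups).
* **bipartite** — two node sets, Bernoulli edges between sets only, edge
  probability set from the target mean degree.

All generators regenerate up to 50 times until connected, then, if still
disconnected, bridge components with uniformly random edges (count recorded
in `meta`; a warning is emitted). Generation is reproducible: identical
spec + seed gives an identical edge set.

**Edge shuffling** is a degree-preserving double-edge swap: edges (a,b),
(c,d) → (a,d),(c,b), rejected if it would create a self-loop or duplicate.
Degree preservation isolates *which* species are linked from *how many*
links each has. A `random_rewire` mode (move one endpoint anywhere
non-adjacent) is available when degree preservation is not wanted.

## β matrix and clustering

Presence is `copies ≥ min_copies` (default 1). β is the Jaccard distance
on family sets; two TE-free genomes are defined identical (β = 0) and an
empty genome is maximally distant from a non-empty one (β = 1) — cases the
simulations never produce but user data might. Clustering is scipy
agglomerative (average linkage by default) on β as a distance; blocks come
from cutting into a requested number of clusters, or automatically at the
largest gap in merge heights. An all-equal β matrix returns a single block
with a warning. Scipy's deterministic merge order plus the id-ordered
input makes the output reproducible; partitions are invariant to species
permutation up to relabelling whenever merge heights are untied.

## Mantel and the experiments

The Mantel statistic is the Pearson correlation of the upper-triangle
entries (Spearman by flag); significance is one-sided (upper tail) by
permuting species labels of one matrix, with the +1 correction, or by
exhaustive enumeration of all n! permutations (`exact=True`, used as the
small-n oracle). Zero variance in either triangle flags r as undefined.

`shuffle_experiment` measures β-matrix stability and discrimination: per
reference network, a reference β matrix is simulated; per shuffle level and
replicate, the network is rewired and re-simulated, and Mantel r against
the reference is recorded. Level 0 re-simulates the unchanged network and
so measures pure simulation stochasticity — its mean is the ceiling for
all other levels. Defaults are a reduced scale (10 networks × 5 replicates)
of the published design (50 × 10); the full scale is one argument away.
`htt_count_sensitivity` repeats the experiment across stop-criterion
values; `propagation_experiment` runs single-family spread from every
founding species (20 × 20 = 400 trajectories per 20-species network by
default) and aggregates first-passage quartiles and the proportion of
trajectories reaching each x.

All experiments use hierarchical seeding (master `SeedSequence` spawning
per-network, then per-replicate streams): results are bit-reproducible and
adding replicates does not disturb existing ones.

### Observation window for propagation contrasts

With no loss, any trajectory on a connected network eventually contaminates
every species, so "proportion of trajectories exceeding x species" is
informative only within a finite window. The propagation acceptance checks
run trajectories essentially to saturation (6000-iteration cap) and apply
a 2000-iteration window — about the median time for a mean-degree-3 random
network to reach 15/20 species — to the proportion statistic only;
first-passage quartiles and IQRs use the uncensored times, since censoring
would cut off exactly the slow tail whose width distinguishes scale-free
propagation.

## Network reconstruction

`infer_by_threshold` places an edge where Jaccard similarity (1 − β) clears
a threshold — monotone by construction. `mutual_information_scores` uses
the plug-in (maximum-likelihood) estimator on each species pair's 2×2 joint
over families, in bits, with 0·log 0 = 0; no bias correction is applied
because family counts are small and the score is a ranking heuristic.
`abc_reconstruct` ranks candidate networks by the mean Mantel r between
their simulated β matrices and the observed one (ties broken by lower SD);
it is the selection step of simulation-based inference, not posterior
sampling.

## What the synthetic world does and does not establish

The generator and simulator emulate idealized communities: species are
exchangeable single genomes, families are independent and identical in
rate, links are binary unless weighted explicitly, and no vertical descent,
selection, or TE sequence evolution exists. A green test therefore
establishes properties of TE *flow on a topology* — stability and decay of
the β signature, density and modularity effects on spread — not claims
about real genomic data, where shared families can arise vertically and
family assignment is itself inferential. The empirical-data entry point
(a presence/absence TSV) deliberately accepts that caveat as the user's
responsibility.

## Known limitations

* Transfer attempt rate per genome is degree-independent (a copy picks one
  neighbour per attempt); models where hub out-flow scales with degree
  would sharpen hub effects beyond what is reproduced here.
* The configuration-model scale-free generator leaves mean-degree jitter
  of up to ±0.4 between instances; comparative experiments should pool
  instances or match partners to the realized degree.
* `run_to_htt_count` can stall (and flag truncation) if the target exceeds
  the number of reachable colonizations, e.g. on very small or fragmented
  networks.
* Directed networks are not modeled; host–parasite asymmetry is expressed
  only through bipartite structure.
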