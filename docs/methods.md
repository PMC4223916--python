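# Methods

`flowscope` analyses *flows* on directed weighted networks rather than the
strength of connections alone. Its four stages share a single dynamical
object — a continuous-time random walk on the graph — and are designed for
networks such as follower graphs, food webs or trade networks, where an
edge `u → v` expresses a directed relationship (here: *u* has declared
interest in *v*) and symmetrizing the adjacency destroys information.

## The teleported walk and Markov Stability

The discrete transition matrix is PageRank-style:

    M[i, :] = τ · a_i / Σ_j a_ij + (1 − τ)/N        (non-dangling rows)
    M[i, :] = 1/N                                   (dangling rows)

with retention `τ ∈ (0, 1]`, default **τ = 0.85**; for symmetric
(undirected) connected inputs the default is τ = 1, since continuous time
removes periodicity concerns. Teleportation guarantees ergodicity and a
unique stationary distribution π on arbitrary digraphs. π is found by
power iteration on the lazy chain `(M + I)/2` (same fixed point, always
aperiodic) to `‖πM − π‖₁ < 1e−12`, capped at 10⁵ iterations.

The walker moves **along** edge orientation — along declared interest.
Content travels the opposite way; statements about "attracting flow" refer
to the attention walk.

The continuous-time propagator is `P(t) = expm(t(M − I))`, computed
densely (`scipy.linalg.expm`); the quality of a partition with indicator
matrix H at Markov time t is the flow autocovariance

    r(t, H) = trace[ Hᵀ (Π P(t) − π πᵀ) H ],   Π = diag(π),

equivalently `trace(Hᵀ B(t) H)` with the symmetrized
`B(t) = (Π P(t) + P(t)ᵀ Π)/2 − π πᵀ`. Exact anchor points: the all-in-one
partition scores 0 at every t; singletons at t = 0 score `1 − Σ π²`;
r → 0 for every partition as t → ∞. Small t rewards fine flow
containment, large t coarse containment, so scanning t produces a
multi-resolution family of partitions.

## Optimization and robustness

B(t) is maximized by a generalized Louvain heuristic that works directly
on the dense quality matrix (the null model is already inside B): greedy
node moves with strictly positive gains from a singleton start, multilevel
aggregation, node order shuffled by the seed. A final pass merges
community pairs whose merge changes the objective by less than 1e−12,
which breaks the all-zero-matrix tie toward the all-in-one partition.

The sweep defaults to 100 logarithmically spaced times in [10⁻², 10¹] and
100 restarts per time; the seeded restarts give, per time, the best
partition and the mean pairwise variation of information of the restarts
(`vi_runs`), and across times the VI matrix `vi_cross`. Tests and the
acceptance script run reduced grids (24 points, 4 restarts at N ≤ 100),
which the recovery experiments below show is already sufficient at these
problem sizes.

**Plateau selection.** A robust partition is a maximal contiguous window
of the grid in which `vi_runs ≤ vi_tol`, all pairwise `vi_cross ≤ vi_tol`,
and at least `min_plateau` (default 5) grid points; defaults
`vi_tol = 0.02·ln N`. The representative is the modal partition of the
window. The variation of information uses natural logarithms, is a metric,
and is bounded by ln N.

## Interest distance

Given a sweep, the interest distance of node j from a vantage node v is
the earliest grid time at which j and v share a community. Nodes never
co-clustered within the scanned range get a sentinel (`inf`); a node that
joins and later leaves keeps its earliest join time and is flagged
non-persistent. Batches (nodes joining at the same grid time) are ranked
by π descending. A group vantage is served by a wrapper that takes the
community containing a named seed node at a reference time and measures
distances from that time onward. The distance is grid-quantized: its
resolution is the grid spacing.

## Role-based similarity (RBS)

Each node's feature vector collects its scaled counts of incoming and
outgoing walks of all lengths (walks, not simple paths — node repetition
allowed):

    in-block  column k:  αᵏ (Aᵀ)ᵏ 1
    out-block column k:  αᵏ  Aᵏ   1        k = 1 … K_max

with `α = β/λ₁`, `β = 0.95` by default and λ₁ the spectral radius of A,
so columns decay geometrically and "all lengths" converges. λ₁ is
computed by power iteration on the shifted matrix A + I (aperiodic, and
`ρ(A+I) = ρ(A)+1` exactly for nonnegative A); nilpotent adjacency (DAG —
finitely many walks) is detected exactly and α defaults to 1. With
`K_max = "auto"` the iteration stops when both column norms drop below
1e−8 of the largest earlier column, capped at 4N.

Cosine similarity of feature rows gives the N×N matrix Y ∈ [0, 1]
(features are nonnegative). Y is invariant to a global rescaling of edge
weights, and nodes equivalent under an automorphism have y = 1.

## The relaxed minimum spanning tree (RMST)

Similarities convert to the chord distance of unit feature rows,
`d_ij = √(2(1 − y_ij))`. The RMST keeps the MST of the complete distance
graph (Kruskal, lexicographic tie-break for permutation stability) and
every pair whose direct distance beats the tree's bottleneck path after a
local-scale relaxation:

    keep (i, j)  ⇔  (i, j) ∈ MST   or   mlink_ij + γ(d_i + d_j) > d_ij

where `mlink_ij` is the maximum edge on the unique MST path and `d_i` the
nearest-neighbour distance of i. Guarantees: the output contains the MST
(hence is connected), the edge set is monotonically non-decreasing in γ,
and γ = 0 with distinct distances returns exactly the MST (minimax-path
property). Kept edges carry similarity weights y (floored at 1e−12 so
zero-similarity tree edges still keep the graph structurally connected).
Default **γ = 0.5** for the standalone RMST artifact.

## Flow roles

Roles are communities of the role-similarity graph, found with the same
stability sweep (τ = 1; the graph is undirected), so the number of roles
is whatever the most robust plateau says. Three deliberate choices differ
from the generic sweep, all motivated by the geometry of walk-count
features:

1. **Role-graph density (γ_role = 60).** Walk-count features of a
   homogeneous node class form a densely sampled low-dimensional cloud:
   nearest-neighbour distances are orders of magnitude smaller than the
   class diameter. At γ = 0.5 the RMST therefore reduces each class to a
   chain-like band whose internal diffusion time exceeds the leakage time
   between classes — clusters blur before they cohere, at any Markov
   time. Role detection needs the opposite trade-off from manifold
   visualization: a near-dense graph (large γ) keeps within-class mixing
   fast, while near-orthogonal classes stay separated because their
   cross-class edges carry near-zero similarity weight.
2. **Strict plateaus (vi_tol = 0.01, 12 restarts).** Near-duplicate
   feature rows produce slowly creeping granular partitions whose
   consecutive VI stays under a loose tolerance; requiring essentially
   exact reproducibility across restarts and times admits only genuine
   plateaus.
3. **Plateau eligibility.** The singleton and all-in-one plateaus exist
   for every network (the t → 0 and t → ∞ limits) and are ignored; a
   plateau truncated by the grid boundary has unknown true extent, so
   boundary windows are eligible only when no interior plateau exists.
   Among eligible windows the longest wins (ties: lowest mean restart
   VI); if none qualifies the partition at the median grid time is
   returned with a `fallback` flag.

Detected roles are relabeled by descending mean in-strength in the
original network, giving a stable, interpretable order; if all feature
rows are identical (vertex-transitive graphs) a single role is returned
directly. Role profiles report, per role, the mean `log1p` unscaled walk
count at every length and direction.

## Role mixes and organigrams

A community's role mix is the exact fraction of its members in each role.
Mixes are clustered with plain squared-Euclidean k-means on the raw
fractions (50 seeded restarts, best inertia); `k = "auto"` selects
k ∈ 2…min(8, #communities−1) by maximum mean silhouette, and identical
mixes short-circuit to a degenerate single cluster. A hook converts an
externally supplied per-node count table (e.g. retweets) into per-role
cumulative distributions; no such data ships with the package.

## Synthetic generators

All generators return the ground truth with the network, are bit-identical
for a fixed seed, and regenerate with derived seeds (≤ 20 attempts) until
weakly connected.

- **Directed SBM** (`generate_directed_sbm`): independent Bernoulli edges
  per ordered pair; defaults 4 blocks × 25 nodes, p_in = 0.3,
  p_out = 0.02 — a strong planted partition for recovery experiments.
- **Flow trap** (`generate_flow_trap`): within a block, each selected
  unordered pair is oriented forward along the shorter arc of a random
  circular ordering, so walkers circulate; between blocks, single-direction
  edges all follow a fixed random total order on the blocks. Expected
  in+out degree is uniform by construction. The canonical conditions use
  **p_in = p_out = 0.35** for 2 blocks × 20: then the symmetrized network
  is a homogeneous weighted random graph — the planted structure carries
  no density signal at all and is visible only to the directed analysis.
  This is the sharpest version of the benchmark: any undirected method
  sees pure noise.
- **Role template** (`generate_role_planted`): 20 references (followed by
  mediators w.p. 0.5, follow nobody), 20 mediators (follow references
  w.p. 0.5, followed by listeners w.p. 0.3), 60 listeners (follow
  mediators, no followers). The pure relay chain listener → mediator →
  reference keeps each class unimodal in feature space; letting listeners
  also follow references directly splits the listener class into genuine
  sub-roles (by the number of direct reference follows) and makes a
  three-role ground truth ill-posed. A side effect of the pinned
  probabilities is that mediators have higher raw in-degree (≈18) than
  references (≈10); references still dominate length-≥2 incoming walks
  and PageRank, which is what "attracting flow" means dynamically.
- **Hierarchical SBM** (`generate_hierarchical_sbm`): two-level nested
  blocks for interest-distance experiments.
- **Toys**: cycle, path, in/out stars, ring of directed cliques.

## What the synthetic conditions do and do not show

The generators emulate the structural mechanisms the method targets —
density-based flow communities, orientation-only (trap) communities,
hierarchy, and walk-profile role classes — under Bernoulli wiring with
homogeneous classes. They do not emulate heavy-tailed degree
distributions, reciprocity correlations, attribute-driven mixing, or the
scale (N ≈ 10³) of real follower networks; passing recovery tests here
demonstrates correctness of the machinery and the directionality
mechanism, not field performance on any particular real dataset.

## Numerical choices and limitations

- Dense linear algebra throughout; the propagator is a dense `expm`.
  Intended scale is N up to a few thousand; cost is O(N³) per Markov time.
- Zero-gain Louvain moves are disallowed; degenerate merges use a 1e−12
  threshold. With a fixed master seed the entire sweep is bit-reproducible
  (per-(time, run) seeds are spawned by counter).
- The stationary π of reducible chains at τ = 1 is whichever stationary
  point the lazy iteration converges to; uniqueness needs τ < 1.
- Interest distances are quantized to the grid; "unreached" depends on
  the scanned range.
- `unscaled()` walk counts are recomputed exactly from the adjacency when
  representable; otherwise columns are divided by αᵏ (float round-off
  ~1e−9 relative).
- Plateau windows use a greedy left-to-right scan; a window is maximal
  with respect to its own starting point.
- Organigram k-means on raw fractions treats roles symmetrically; no
  compositional (log-ratio) transform is applied.
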