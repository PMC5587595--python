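# Methods

## Problem

Under Lin's structural controllability, a directed network G(V, E) with N
nodes can be fully controlled by injecting independent signals into a
Minimum Input Set (MIS) of driver nodes. Finding an MIS reduces to maximum
bipartite matching: split every node n into an out-copy n^out and an in-copy
n^in, turn each directed edge (u, v) into the bipartite edge u^out–v^in, and
compute a maximum matching M\* of the resulting graph B(V^out, V^in, E). The
in-nodes left unmatched by M\* form an MIS, of size max(N − |M\*|, 1).
Because M\* is rarely unique, different matchings yield different MISs; a
node belonging to at least one MIS is a *possible input node*, and the union
of all MISs is the quantity of interest — it separates nodes that must
always be driven, nodes that may be driven, and nodes that never need to be.

## The algorithm

Enumerating all maximum matchings is exponential. The package instead uses a
reachability characterisation: fixing any one maximum matching M with
unmatched in-node set D,

* every member of D is a possible input node, and
* a matched node n is a possible input node **iff** n^in is reachable from
  some m^in (m ∈ D) by an alternating path (edges alternately outside and
  inside M). Such a path necessarily has even length, starting with a
  non-matching edge at m^in and ending with a matching edge at n^in.

Sufficiency is constructive: exchanging matched and unmatched edges along
the path gives another maximum matching of equal size whose unmatched set is
D − {m} + {n}. Necessity follows from the symmetric difference M ⊕ M′ with
any maximum matching M′ that leaves n unmatched: the component containing
n^in is an even alternating path that must terminate at an in-node unmatched
by M, i.e. a root. The same argument shows a strict dichotomy used by the
test-suite: an input node m has an empty reachable set K_m exactly when m
belongs to *every* MIS.

The search is rooted on the in-side (the driver side): from an in-node the
BFS crosses non-matching edges to out-nodes, from an out-node it continues
only through its matching edge. This is precisely the final (failed) phase
of Hopcroft–Karp, so all possible input nodes fall out of one maximum
matching computation at total cost O(N^1/2 L). The implementation exposes
both routes — the final-phase hook and an independent plain alternating BFS
run after convergence — and the tests require them to agree exactly.

Per-input substituting sets K_m are computed by one restricted BFS per root.
A node reachable from two roots belongs to both K-sets, so K-sets come from
per-root sweeps (worst case O(|D|·L)), not from the single shared
predecessor tree; the union harvest itself never pays that cost, and
`control_profile(..., with_substitutes=False)` skips it entirely on large
graphs. Reported substituting sets are relative to the one computed
matching; only their union with D — the possible-input set — is
matching-invariant, and the invariance tests permute node and edge order to
confirm it.

### Conventions and degenerate inputs

* **Perfect matching.** No in-node is unmatched, yet at least one input is
  always required; any single node then works as the MIS. The package
  reports the smallest label as the canonical MIS, all nodes as possible
  inputs, and `substitutes = None` (requesting K-sets raises instead of
  fabricating them). Classification calls every node `sometimes_input`
  (for N = 1, `always_input`, since the only MIS is that node).
* **Edgeless or single-node graphs.** All in-nodes are unmatched; the MIS is
  the whole node set.
* **Self-loops** are kept by default — the bipartite edge n^out–n^in lets a
  node satisfy its own matching — with a flag to drop them. Duplicate edges
  are removed on input (matching is defined on simple bipartite graphs).
* **Determinism.** Internal indices follow first appearance in the input;
  the matcher contains no randomness; all emitted sets are sorted by label.
  The augmenting DFS is iterative, so recursion depth never limits graph
  size.

## Oracles

Correctness is established against two independent routes. The enumeration
oracle walks every out-node in index order, branching over its free
in-neighbours or leaving it unmatched, pruned by the known maximum size;
within its budget (default 16 nodes, 10^6 matchings) it yields every
maximum matching exactly once, and the union of their unmatched in-node
sets is ground truth. The removal-test baseline is the earlier O(NL)
algorithm: a matched node n is a possible input iff deleting n^in leaves
the maximum matching size unchanged, decided by a single augmenting-path
search from n's freed partner. The acceptance suite requires exact
agreement of all three routes on a 2000-graph sweep (n ≤ 8, densities
0.05–0.9), and `verify_mis` independently certifies every swapped MIS by
re-matching the restricted bipartite graph.

## Synthetic networks

`gen_scale_free` emulates the directed scale-free networks used for the
density and timing experiments: growth by dual preferential attachment.
Each new node draws Poisson(⟨k⟩/4) out-edges, attaching to existing targets
with probability proportional to in-degree, and Poisson(⟨k⟩/4) in-edges from
sources proportional to out-degree, starting from a small seed ring. Pure
linear attachment gives both degree tails the Barabási–Albert exponent 3
(measured 2.8–3.0 by a Hill estimator at n = 10^5); other exponents are
available through a uniform attachment offset a = (r − 3)⟨k⟩/4. The realised
⟨k⟩ = 2L/N lands within a few percent of target, and output is simple and
byte-reproducible per seed.

The Poisson spread of per-node edge counts is deliberate. Two rejected
variants illustrate why: a single-edge-per-step α/β/γ growth mixture leaves
~11% of nodes with in-degree 0 at every density, so the possible-input
union percolates and its density n_pd stops falling with ⟨k⟩; a
hard-minimum dual attachment (exactly ⌈⟨k⟩/4⌉ edges per side) makes
matchings exactly perfect above ⟨k⟩ ≈ 12, collapsing n_pd to the
perfect-matching convention. Poisson counts keep a small, density-dependent
mass of degree-0 nodes, so matchings approach but never reach perfection —
the regime in which the mean n_pd falls monotonically with ⟨k⟩
(0.60, 0.53, 0.48, 0.44, 0.39, 0.34 for ⟨k⟩ = 6…16 at n = 10^4, 20 seeds),
the behaviour the density experiments probe.

One feature of this family deserves flagging. Near ⟨k⟩ ≈ 14–16 the
alternating-path reachability from the (by then very few) unmatched
in-nodes sits at a percolation transition: per realisation, the union of
all MISs either stays confined near the degree-0 periphery (n_pd ≈ 0.07 at
⟨k⟩ = 16) or sweeps a giant alternating cluster (n_pd ≈ 0.83), in roughly
even proportion, at n = 10^4 and 3×10^4 alike. The MIS size itself is
stable (≈ 0.036 N at ⟨k⟩ = 16); only the substitutability union is
bimodal. The mean trend is therefore real but noisy at the dense end, and
the trend test averages 20 seeds per ⟨k⟩ rather than the minimum five.

What the generator does not emulate: degree–degree correlations,
reciprocity, clustering, and community structure of real networks. Passing
tests on these graphs demonstrate the algorithm's correctness (which the
enumeration oracle establishes on arbitrary digraphs anyway) and the
qualitative density trend, not quantitative n_pd values for any real
system; n_pd at a given ⟨k⟩ is generator-dependent.

## Problem sizes and tolerances

The acceptance suite uses: a 2000-graph oracle sweep with n ≤ 8 (exhaustive
enumeration stays trivial there while still covering perfect matchings,
isolated nodes and dense digraphs); 100 graphs × 20 permutations for
matching invariance; n = 10^4 with twenty seeds per ⟨k⟩ for the density
trend (see the percolation caveat above); and a single n = 10^5, ⟨k⟩ = 8 network for the complexity direction
check, where the single-matching harvest must finish within seconds and the
removal baseline at least 10× slower (measured ≈ 100× in this
implementation — the gap grows with N, so the margin is structural, not a
tuned constant). Equality assertions are exact set comparisons throughout;
no numeric tolerances enter except the generator's ±10% band on realised
⟨k⟩ and the [2.5, 3.5] acceptance band on the Hill exponent estimate, both
dominated by sampling noise at the test sizes.

## Known limitations

* Substituting sets cost O(|D|·L) in the worst case; for networks with very
  large MISs request the profile without them.
* The enumeration oracle is exponential by design and refuses graphs beyond
  its budget rather than attempting polynomial-delay enumeration.
* Edge-list files cannot express a node with no edges; isolated nodes
  survive in-memory analysis but not a write/read round-trip.
* Structural controllability uses only the zero/non-zero pattern of edge
  weights; nothing here addresses control energy, time-to-control, or the
  dominating-set (MDS) framework for undirected networks.
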