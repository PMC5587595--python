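# netctrl

**All possible driver nodes of a directed network under structural
controllability — from a single maximum matching.**

## The problem

A directed network G(V, E) — a gene-regulatory network, a food web, a
signalling or social network — is structurally controllable from a set of
*input* (driver) nodes if external signals injected there can steer the
whole system between arbitrary states. A Minimum Input Set (MIS) follows
from maximum bipartite matching: split each node n into n^out and n^in,
turn every edge (u, v) into the bipartite edge u^out–v^in, and compute a
maximum matching M\*; the unmatched in-nodes are an MIS, of size
max(N − |M\*|, 1).

Maximum matchings are rarely unique, so different MISs exist and a node may
be a driver under one and dispensable under another. The union of all MISs —
the **possible input nodes** — is what tells you which nodes *must*, *may*,
or *never need to* receive a control signal. Enumerating all maximum
matchings to get that union is exponential; testing every node by deletion
costs O(NL).

`netctrl` computes the union from **one** matching, in O(N^1/2 L): a matched
node n is a possible input iff n^in is reachable from some unmatched m^in by
an alternating path (even length, starting unmatched, ending matched).
Flipping that path's edges exchanges m for n in the MIS, so the same search
also yields, for every input node m, its **substituting set** K_m — the
nodes that can replace m one-for-one — and the substitutability profile
p_i = s_i/N with s_i = |K_i|.

## Worked example

The bundled 10-node demonstration network (`synthgen.fixture("substitution_demo")`):

```python
from netctrl import synthgen, control_profile

g = synthgen.fixture("substitution_demo")
prof = control_profile(g)
print("MIS:", sorted(prof.mis))
print("possible inputs:", sorted(prof.possible_inputs))
print("n_pd:", prof.n_pd)
for label, s_i, p_i in prof.ranked_profile():
    print(f"input {label}: s_i={s_i} p_i={p_i}")
```

prints

```
MIS: ['10', '8']
possible inputs: ['10', '4', '6', '8', '9']
n_pd: 0.5
input 8: s_i=2 p_i=0.2
input 10: s_i=1 p_i=0.1
```

Two of the ten nodes suffice as drivers, but five different nodes can play
that role: the computed MIS {8, 10} is one choice among several (e.g.
{4, 10} is another — node 8's substituting set is {4, 6}), `n_pd = 0.5`
says half the network is potentially a driver, and input 8 is the more
replaceable of the two (two stand-ins versus one for input 10).
`swap_mis(g, m, "8", "4")` materialises the exchange and returns the new
maximum matching plus the new MIS. Nodes are classified
`always_input` / `sometimes_input` / `never_input` accordingly — an input
node with an empty substituting set is in *every* MIS.

The same pipeline from the shell:

```bash
ctrl gen --family scale_free --n 10000 --k 8 --seed 1 -o sf.tsv
ctrl compute -i sf.tsv --no-substitutes -o report.json
ctrl classify -i sf.tsv -o nodes.tsv
ctrl oracle -i sf.tsv --method removal
```

Edge lists are plain text (`SOURCE<ws>TARGET`, `#` comments); reports embed
the tool version, configuration and input checksum, so reruns are
byte-identical.

## Correctness

The fast harvest is held against two independent oracles: exhaustive
enumeration of *all* maximum matchings (small graphs, budgeted) and the
earlier O(NL) node-removal algorithm; all three must agree exactly. Every
claimed substitute is validated by re-matching (`verify_mis`), and the
reported sets are invariant under node/edge permutations. See
`docs/methods.md` for the algorithm, its conventions (perfect matchings,
self-loops) and the synthetic-network generator.

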